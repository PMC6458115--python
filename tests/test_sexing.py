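"""Quick-FISH and qPCR sexing calculators plus the nonparametric tests."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from satellitome.scenarios import simulate_qpcr_record, simulate_spot_counts
from satellitome.sexing import (
    InconsistentReplicatesError,
    QpcrRecord,
    SpotCountTable,
    call_sex_qpcr,
    call_sex_quickfish,
    delta_ct_rq,
    kruskal_wallis,
    mann_whitney_u,
    read_qpcr_table,
    read_spot_counts,
    shapiro_wilk,
)


# ------------------------------------------------------------------ quick-FISH

def test_quickfish_all_three_spots_is_female():
    t = SpotCountTable("s1", (3,) * 50)
    assert call_sex_quickfish(t).call == "female"


def test_quickfish_male_with_dropout_cells():
    """54 two-spot cells plus 6 one-spot dropouts: informative denominator
    is 54/54, so the call is male at majority 0.8."""
    t = SpotCountTable("s2", (2,) * 54 + (1,) * 6)
    c = call_sex_quickfish(t, min_cells=20, majority=0.8)
    assert c.call == "male"
    assert c.n_informative == 54
    assert c.fraction_three == 0.0


def test_quickfish_exact_tie_is_ambiguous():
    t = SpotCountTable("s3", (2,) * 20 + (3,) * 20)
    assert call_sex_quickfish(t).call == "ambiguous"


def test_quickfish_too_few_cells_gives_reason():
    t = SpotCountTable("s4", (3,) * 10 + (1,) * 30)
    c = call_sex_quickfish(t, min_cells=20)
    assert c.call == "ambiguous"
    assert "informative" in c.reason


def test_quickfish_invariant_to_order_and_duplication():
    counts = (3, 2, 3, 3, 1, 3) * 10
    base = call_sex_quickfish(SpotCountTable("s", counts))
    shuffled = call_sex_quickfish(SpotCountTable("s", tuple(sorted(counts))))
    doubled = call_sex_quickfish(SpotCountTable("s", counts * 2))
    assert base.call == shuffled.call == doubled.call
    assert base.fraction_three == shuffled.fraction_three == doubled.fraction_three


def test_quickfish_sanity_cap():
    with pytest.raises(ValueError):
        call_sex_quickfish(SpotCountTable("s", (3, 9)))


# ------------------------------------------------------------------------ qPCR

def test_delta_ct_identities():
    r = QpcrRecord("s", (24.0, 24.2), (24.0, 24.2))
    out = delta_ct_rq(r)
    assert out.delta_ct == pytest.approx(0.0)
    assert out.rq == pytest.approx(1.0)
    plus = delta_ct_rq(QpcrRecord("s", (25.0, 25.0), (24.0, 24.0)))
    minus = delta_ct_rq(QpcrRecord("s", (23.0, 23.0), (24.0, 24.0)))
    assert plus.rq == pytest.approx(0.5)
    assert minus.rq == pytest.approx(2.0)


def test_rq_monotone_and_reciprocal():
    rqs = [delta_ct_rq(QpcrRecord("s", (24.0 + d, 24.0 + d), (24.0, 24.0))).rq
           for d in (-2.0, -1.0, 0.0, 1.0, 2.0)]
    assert all(a > b for a, b in zip(rqs, rqs[1:]))
    up = delta_ct_rq(QpcrRecord("s", (25.5, 25.5), (24.0, 24.0))).rq
    dn = delta_ct_rq(QpcrRecord("s", (22.5, 22.5), (24.0, 24.0))).rq
    assert up * dn == pytest.approx(1.0)


def test_delta_ct_rejects_inconsistent_replicates():
    with pytest.raises(InconsistentReplicatesError):
        delta_ct_rq(QpcrRecord("s", (24.0, 25.0), (24.0, 24.1)))


def test_simulated_w_target_separates_sexes(rng):
    """ΔCt lower in females by >=3 cycles: RQ ratio female/male >= 8."""
    f = delta_ct_rq(simulate_qpcr_record("female", rng, "f1"))
    m = delta_ct_rq(simulate_qpcr_record("male", rng, "m1"))
    assert m.delta_ct - f.delta_ct >= 3.0
    assert f.rq / m.rq >= 8.0


def test_call_sex_qpcr_midpoint_rule():
    def rec(sid, rq):
        dct = -math.log2(rq)
        return QpcrRecord(sid, (24.0 + dct, 24.0 + dct), (24.0, 24.0))

    calib = {
        "female": [rec("cf1", 8.0), rec("cf2", 9.0)],
        "male": [rec("cm1", 0.1), rec("cm2", 0.12)],
    }
    calls = call_sex_qpcr([rec("t", 7.0)], calibration=calib)
    assert calls[0][1] == "female"
    # exactly at an explicit threshold: ambiguous
    calls = call_sex_qpcr([rec("t", 1.0)], threshold_rq=1.0)
    assert calls[0][1] == "ambiguous"
    with pytest.raises(ValueError):
        call_sex_qpcr([rec("t", 2.0)], calibration={"male": calib["male"]})


# ---------------------------------------------------------------- Mann-Whitney

def _oracle_u_p(a, b):
    """Brute force: U from pairwise comparisons; p by enumerating every
    assignment of the pooled values to the two groups."""
    def u_stat(x, y):
        return sum(1.0 if xi < yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y)

    ua = u_stat(a, b)
    ub = u_stat(b, a)
    u = min(ua, ub)
    pooled = list(a) + list(b)
    total = at_or_below = 0
    for idx in combinations(range(len(pooled)), len(a)):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if min(u_stat(ga, gb), u_stat(gb, ga)) <= u + 1e-9:
            at_or_below += 1
    return u, at_or_below / total


def test_mwu_worked_example():
    res = mann_whitney_u([1, 2], [3, 4])
    assert res.statistic_value == 0.0
    assert res.p_value == pytest.approx(1 / 3)


def test_mwu_identical_multisets():
    res = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert res.statistic_value == pytest.approx(9 / 2)
    assert res.p_value == 1.0


def test_mwu_matches_enumeration_oracle(rng):
    for _ in range(40):
        na = int(rng.integers(1, 7))
        nb = int(rng.integers(1, 13 - na))
        a = list(rng.integers(0, 6, size=na).astype(float))
        b = list(rng.integers(0, 6, size=nb).astype(float))
        res = mann_whitney_u(a, b)
        u, p = _oracle_u_p(a, b)
        assert res.statistic_value == pytest.approx(u)
        assert res.p_value == pytest.approx(p)


def test_mwu_invariant_under_monotone_transform(rng):
    a = list(rng.normal(size=8))
    b = list(rng.normal(1.0, size=9))
    base = mann_whitney_u(a, b)
    warped = mann_whitney_u([math.exp(x) for x in a], [math.exp(x) for x in b])
    assert base.statistic_value == warped.statistic_value
    assert base.p_value == warped.p_value


def test_mwu_large_sample_tracks_scipy(rng):
    a = list(rng.normal(size=30))
    b = list(rng.normal(0.8, size=35))
    res = mann_whitney_u(a, b)
    ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert res.p_value == pytest.approx(ref.pvalue, abs=0.01)


# ---------------------------------------------------------------- Shapiro-Wilk

def test_shapiro_power_on_skewed_data(rng):
    rejected = sum(
        shapiro_wilk(list(rng.exponential(size=100))).p_value < 0.01 for _ in range(100)
    )
    assert rejected >= 95


def test_shapiro_calibration_under_null(rng):
    pvals = [shapiro_wilk(list(rng.normal(size=50))).p_value for _ in range(200)]
    ks = sps.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_shapiro_input_contract():
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 2.0])
    with pytest.raises(ValueError):
        shapiro_wilk([3.0] * 10)


# -------------------------------------------------------------- Kruskal-Wallis

def test_kruskal_three_separated_groups_rank_formula():
    """No ties: H = 12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1) = 12.5."""
    res = kruskal_wallis([[1, 2, 3, 4, 5], [11, 12, 13, 14, 15], [21, 22, 23, 24, 25]])
    assert res.statistic_value == pytest.approx(12.5)


def test_kruskal_identical_groups():
    res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
    assert res.statistic_value == 0.0
    assert res.p_value == 1.0


def test_kruskal_two_groups_consistent_with_mwu(rng):
    a = list(rng.normal(size=50))
    b = list(rng.normal(0.5, size=50))
    kw = kruskal_wallis([a, b])
    mw = mann_whitney_u(a, b)
    assert kw.p_value == pytest.approx(mw.p_value, abs=0.02)


def test_kruskal_input_contract():
    with pytest.raises(ValueError):
        kruskal_wallis([[1.0]])
    with pytest.raises(ValueError):
        kruskal_wallis([[1.0], []])


# ------------------------------------------------------------------- table IO

def test_spot_count_round_trip(tmp_path):
    p = tmp_path / "spots.tsv"
    p.write_text(
        "specimen\tcell_index\tcount\n"
        + "".join(f"s1\t{i}\t3\n" for i in range(25))
        + "".join(f"s2\t{i}\t2\n" for i in range(25))
    )
    tables = {t.specimen_id: t for t in read_spot_counts(p)}
    assert call_sex_quickfish(tables["s1"]).call == "female"
    assert call_sex_quickfish(tables["s2"]).call == "male"


def test_qpcr_table_round_trip(tmp_path):
    p = tmp_path / "qpcr.tsv"
    p.write_text(
        "specimen\tchannel\treplicate\tct\n"
        "s1\ttarget\t1\t20.5\ns1\ttarget\t2\t20.6\n"
        "s1\treference\t1\t24.0\ns1\treference\t2\t24.1\n"
    )
    recs = read_qpcr_table(p)
    assert len(recs) == 1
    out = delta_ct_rq(recs[0])
    assert out.delta_ct == pytest.approx(-3.5)
    assert out.rq == pytest.approx(2**3.5)


# --------------------------------------------------------------- end-to-end

def test_synthetic_specimens_classify_perfectly(rng):
    """Twenty specimens at the 90% expected-signal rate, 40-90 cells each:
    both calculators call every specimen correctly."""
    sexes = ["female" if i % 2 == 0 else "male" for i in range(20)]
    for i, sex in enumerate(sexes):
        t = simulate_spot_counts(sex, rng, f"s{i}")
        assert call_sex_quickfish(t).call == sex
    calib = {
        "female": [simulate_qpcr_record("female", rng, f"cf{i}") for i in range(3)],
        "male": [simulate_qpcr_record("male", rng, f"cm{i}") for i in range(3)],
    }
    records = [simulate_qpcr_record(sex, rng, f"q{i}") for i, sex in enumerate(sexes)]
    calls = call_sex_qpcr(records, calibration=calib)
    assert [c[1] for c in calls] == sexes
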