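"""Satellite mining: quality filter, clustering, tandem calls, masking, loop."""

import numpy as np
import pytest

from satellitome._align import identity_to_unit, revcomp
from satellitome.discovery import (
    cluster_reads,
    detect_tandem_period,
    mask_reads,
    quality_filter_reads,
    run_discovery_loop,
    sample_reads,
)
from satellitome.reads import Read, ReadSet
from satellitome.scenarios import random_monomer
from satellitome.simdata import FamilySpec, ReadSimConfig, plant_satellites, simulate_reads

Q30, Q2 = "?", "#"


def _mk(seqs, qual=None, label="female"):
    return ReadSet(
        [Read(f"r{i}/1", s, (qual or Q30 * len(s))[: len(s)]) for i, s in enumerate(seqs)],
        label,
    )


# ------------------------------------------------------------ quality filter

def test_quality_filter_keeps_clean_reads():
    rs = _mk(["A" * 250, "C" * 250])
    out = quality_filter_reads(rs, 4, 20, 250)
    assert out.n_reads == 2


def test_quality_filter_drops_pair_on_low_tail():
    good = Read("p1/1", "A" * 250, Q30 * 250)
    bad = Read("p1/2", "A" * 250, Q30 * 220 + Q2 * 30)
    out = quality_filter_reads(ReadSet([good, bad], "x"), 4, 20, 250)
    assert out.n_reads == 0  # mate dropped together


def test_quality_filter_matches_window_scan_oracle(rng):
    """Brute-force position-by-position window re-scan on random qualities."""
    window, minq, minlen = 4, 20, 30
    for _ in range(50):
        n = int(rng.integers(window, 120))
        quals = rng.integers(2, 41, size=n)
        qstr = "".join(chr(33 + q) for q in quals)
        read = Read("r/1", "A" * n, qstr)
        out = quality_filter_reads(ReadSet([read], "x"), window, minq, minlen)
        # oracle
        cut = n
        for i in range(n - window + 1):
            if quals[i : i + window].mean() < minq:
                cut = i
                break
        if cut < minlen:
            assert out.n_reads == 0
        else:
            assert out.n_reads == 1 and len(out.reads[0].seq) == cut


# --------------------------------------------------------------------- sample

def test_sample_reads_edge_cases():
    rs = _mk(["ACGT" * 10] * 8)
    assert sample_reads(rs, 8, 1).reads == rs.reads  # n = n_reads: identity
    assert sample_reads(rs, 0, 1).n_reads == 0
    assert sample_reads(rs, 3, 5).reads == sample_reads(rs, 3, 5).reads
    with pytest.raises(ValueError):
        sample_reads(rs, 9, 1)


# ------------------------------------------------------------------ clustering

def test_single_monomer_reads_form_one_cluster(rng):
    mono = random_monomer(rng, 50)
    tandem = mono * 20
    reads = [tandem[i : i + 250] for i in range(0, 700, 37)]
    clusters = cluster_reads(_mk(reads), min_cluster_size=5)
    assert len(clusters) == 1
    assert clusters[0].size == len(reads)


def test_two_distant_monomers_give_two_clusters(rng):
    """Oracle: cluster membership must split along monomer of origin for
    families sharing no clustering k-mers."""
    from satellitome._kmers import canonical_kmers

    while True:
        a, b = random_monomer(rng, 60), random_monomer(rng, 55)
        ka = set(canonical_kmers((a + a), 13).tolist())
        kb = set(canonical_kmers((b + b), 13).tolist())
        if not (ka & kb):
            break
    reads_a = [(a * 10)[i : i + 250] for i in range(0, 300, 43)]
    reads_b = [((b * 10))[i : i + 250] for i in range(0, 300, 43)]
    clusters = cluster_reads(_mk(reads_a + reads_b), min_cluster_size=5)
    assert len(clusters) == 2
    ids_a = {f"r{i}/1" for i in range(len(reads_a))}
    for cl in clusters:
        assert cl.member_read_ids <= ids_a or not (cl.member_read_ids & ids_a)


def test_background_reads_do_not_cluster(rng):
    """Reads of unlinked single-copy sequence: chance k-mer collisions alone
    never connect enough reads to reach the cluster-size floor."""
    genome = random_monomer(rng, 600_000)
    starts = rng.integers(0, len(genome) - 250, size=300)
    reads = [genome[s : s + 250] for s in starts]
    clusters = cluster_reads(_mk(reads), min_cluster_size=5)
    assert clusters == []


# ------------------------------------------------------------ tandem detection

def test_exact_repeat_period_and_monomer():
    call = detect_tandem_period("ACGTA" * 20, 0.7)
    assert call.period == 5
    assert call.match_fraction_at_period == 1.0
    assert call.monomer_consensus in {"ACGTA"[i:] + "ACGTA"[:i] for i in range(5)}


def test_homopolymer_period_one():
    assert detect_tandem_period("A" * 40, 0.7).period == 1


def test_non_repetitive_contig_returns_none(rng):
    assert detect_tandem_period(random_monomer(rng, 250), 0.7) is None


def test_mutated_monomer_recovery_over_trials(rng):
    """60-nt monomer x15 with 5% substitutions: period and >=95%-identical
    monomer recovered in >=95 of 100 trials."""
    from satellitome.catalog import circular_identity

    ok = 0
    for _ in range(100):
        mono = random_monomer(rng, 60)
        contig = "".join(
            "".join(
                (c if rng.random() >= 0.05 else "ACGT"[rng.integers(4)]) for c in mono
            )
            for _ in range(15)
        )
        call = detect_tandem_period(contig, 0.7)
        if call and call.period == 60 and circular_identity(call.monomer_consensus, mono) >= 0.95:
            ok += 1
    assert ok >= 95


# --------------------------------------------------------------------- masking

def test_mask_reads_empty_catalog_is_identity(tiny_reads):
    female, _, _ = tiny_reads
    out = mask_reads(female, [], 0.8)
    assert out.reads == female.reads


def test_mask_removes_exact_tandem_read(rng):
    mono = random_monomer(rng, 40)
    rs = _mk([(mono * 8)[:250], random_monomer(rng, 250)])
    out = mask_reads(rs, [mono], 0.95)
    assert [r.id for r in out] == ["r1/1"]


def test_mask_leakage_on_synthetic_pool(rng):
    """Surviving reads equal the true-background reads, <=1% leakage."""
    spec = FamilySpec("f", random_monomer(rng, 55), 120, 120, 2, 0.02)
    g = plant_satellites([spec], 150_000, seed=21)
    female, _, origins = simulate_reads(
        g, ReadSimConfig(n_read_pairs=1500, per_base_error_rate=0.001, seed=22)
    )
    intervals = [(a.start, a.end) for a in g.arrays if a.sex == "female"]
    is_sat = []
    for o in origins["female"]:
        ov = sum(max(0, min(o.end, e) - max(o.start, s)) for s, e in intervals)
        is_sat.append(ov / (o.end - o.start) > 0.5)
    out = mask_reads(female, [spec.monomer], 0.8)
    surviving = {r.id for r in out}
    sat_ids = {r.id for r, s in zip(female.reads, is_sat) if s}
    leaked = len(surviving & sat_ids)
    assert leaked <= 0.01 * max(1, len(sat_ids))


# ------------------------------------------------------------------- main loop

@pytest.fixture(scope="module")
def one_family_pool():
    rng = np.random.default_rng(31)
    spec = FamilySpec("f", random_monomer(rng, 50), 400, 400, 2, 0.02)
    g = plant_satellites([spec], 500_000, seed=31)
    f, m, _ = simulate_reads(
        g, ReadSimConfig(n_read_pairs=1200, per_base_error_rate=0.001, seed=32)
    )
    return spec, f, m


def test_single_family_found_round_one_and_terminates(one_family_pool):
    from satellitome.catalog import circular_identity
    from satellitome.discovery import DiscoveryLog

    spec, f, m = one_family_pool
    log = DiscoveryLog()
    found = run_discovery_loop(f, m, round0_n=600, max_rounds=5, seed=1, log=log)
    assert len(found) >= 1
    assert found[0].round_found == 1
    assert circular_identity(found[0].monomer, spec.monomer) >= 0.9
    assert len(log.rounds) <= 3  # terminates as soon as a round adds nothing


def test_max_rounds_one_equals_single_pass(one_family_pool):
    _, f, m = one_family_pool
    single = run_discovery_loop(f, m, round0_n=600, max_rounds=1, seed=1)
    first = run_discovery_loop(f, m, round0_n=600, max_rounds=5, seed=1)
    assert [d.monomer for d in single] == [
        d.monomer for d in first if d.round_found == 1
    ]


def test_pool_shrinkage_and_idempotent_termination(one_family_pool):
    from satellitome.discovery import DiscoveryLog

    spec, f, m = one_family_pool
    log = DiscoveryLog()
    found = run_discovery_loop(f, m, round0_n=600, max_rounds=5, seed=3, log=log)
    sizes = [(r["pool_female"], r["pool_male"]) for r in log.rounds]
    assert all(a >= b for (a, _), (b, _) in zip(sizes, sizes[1:]))
    assert all(a >= b for (_, a), (_, b) in zip(sizes, sizes[1:]))
    # rerunning on the masked pool yields nothing new
    masked_f = mask_reads(f, [d.monomer for d in found], 0.8)
    masked_m = mask_reads(m, [d.monomer for d in found], 0.8)
    again = run_discovery_loop(masked_f, masked_m, round0_n=600, max_rounds=2, seed=4)
    from satellitome.catalog import circular_identity

    assert not any(
        circular_identity(d.monomer, spec.monomer) >= 0.8 for d in again
    )


def test_reverse_strand_reads_cluster_with_forward(rng):
    mono = random_monomer(rng, 50)
    fwd = [(mono * 10)[i : i + 250] for i in range(0, 200, 31)]
    rev = [revcomp(s) for s in fwd[:3]]
    clusters = cluster_reads(_mk(fwd + rev), min_cluster_size=5)
    assert len(clusters) == 1
    assert clusters[0].size == len(fwd) + len(rev)


def test_masked_read_identity_is_strand_symmetric(rng):
    mono = random_monomer(rng, 45)
    read = (mono * 8)[3:253]
    assert identity_to_unit(read, mono) >= 0.99
    assert identity_to_unit(revcomp(read), mono) >= 0.99
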