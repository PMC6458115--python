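"""Non-invasive sexing calculators and the nonparametric tests behind them.

Two independent diagnostics for a ZW/ZZ system in which a W-specific
satellite probe is co-hybridised with an autosomal control:

* quick-FISH spot counting — interphase cells show two signals in a ZZ male
  (the autosomal pair) and three in a ZW female (plus the W locus); a
  specimen is called from the majority count over its informative cells.
* qPCR ΔCt relative quantification — the W-linked satellite's cycle
  threshold against a single-copy reference gene; RQ = 2^(-ΔCt) is higher
  in females in proportion to W copy number.

The statistics mirror the reporting style such studies use: Shapiro-Wilk
for normality, then Mann-Whitney U / Kruskal-Wallis on the nonparametric
branch, two-sided throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    statistic_value: float
    p_value: float
    group_sizes: tuple[int, ...]


# ------------------------------------------------------------------ quick-FISH

@dataclass(frozen=True)
class SpotCountTable:
    specimen_id: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("at least one cell required")
        if any(c < 0 for c in self.counts):
            raise ValueError("negative spot count")


@dataclass(frozen=True)
class QuickFishCall:
    specimen_id: str
    call: str  # female | male | ambiguous
    n_cells: int
    n_informative: int
    fraction_three: float | None
    reason: str = ""


def call_sex_quickfish(
    table: SpotCountTable,
    min_cells: int = 20,
    majority: float = 0.8,
    max_count: int = 6,
) -> QuickFishCall:
    """Majority vote over informative (2- or 3-spot) cells.

    Cells with other counts — signal dropout, overlapping nuclei — are
    excluded from the denominator but reported. Counts above ``max_count``
    are rejected as implausible.
    """
    if any(c > max_count for c in table.counts):
        raise ValueError(f"spot count exceeds sanity cap {max_count}")
    informative = [c for c in table.counts if c in (2, 3)]
    n_inf = len(informative)
    if n_inf < min_cells:
        return QuickFishCall(
            table.specimen_id, "ambiguous", len(table.counts), n_inf, None,
            f"only {n_inf} informative cells (< {min_cells})",
        )
    frac3 = sum(1 for c in informative if c == 3) / n_inf
    if frac3 >= majority:
        call = "female"
    elif 1 - frac3 >= majority:
        call = "male"
    else:
        call = "ambiguous"
    return QuickFishCall(table.specimen_id, call, len(table.counts), n_inf, frac3)


# ------------------------------------------------------------------------ qPCR

@dataclass(frozen=True)
class QpcrRecord:
    specimen_id: str
    ct_target: tuple[float, ...]
    ct_reference: tuple[float, ...]
    sex_label: str | None = None

    def __post_init__(self) -> None:
        for ch in (self.ct_target, self.ct_reference):
            if len(ch) < 2:
                raise ValueError("at least two replicates per channel")
            if any(not (0 < c < 45) for c in ch):
                raise ValueError("Ct values must lie in (0, 45)")


@dataclass(frozen=True)
class DeltaCtResult:
    specimen_id: str
    delta_ct: float
    sem: float
    rq: float


class InconsistentReplicatesError(ValueError):
    pass


def _sem(xs: tuple[float, ...]) -> float:
    if len(xs) < 2:
        return 0.0
    return float(np.std(xs, ddof=1) / math.sqrt(len(xs)))


def delta_ct_rq(
    record: QpcrRecord,
    inconsistency_threshold: float = 0.5,
    efficiency: float = 2.0,
) -> DeltaCtResult:
    """ΔCt = mean(Ct_target) - mean(Ct_reference); RQ = efficiency^(-ΔCt).

    A channel whose replicate range exceeds ``inconsistency_threshold``
    cycles marks the record as inconsistent and it is rejected, matching the
    practice of discarding samples with irreproducible Ct. SEM propagates
    as the root sum of squares of the two channel SEMs.
    """
    for name, ch in (("target", record.ct_target), ("reference", record.ct_reference)):
        if max(ch) - min(ch) > inconsistency_threshold:
            raise InconsistentReplicatesError(
                f"{record.specimen_id}: {name} replicate range "
                f"{max(ch) - min(ch):.2f} > {inconsistency_threshold}"
            )
    dct = float(np.mean(record.ct_target) - np.mean(record.ct_reference))
    sem = math.sqrt(_sem(record.ct_target) ** 2 + _sem(record.ct_reference) ** 2)
    return DeltaCtResult(record.specimen_id, dct, sem, efficiency ** (-dct))


def call_sex_qpcr(
    records: list[QpcrRecord],
    threshold_rq: float | None = None,
    calibration: dict[str, list[QpcrRecord]] | None = None,
    inconsistency_threshold: float = 0.5,
    efficiency: float = 2.0,
) -> list[tuple[str, str, float]]:
    """Per-specimen (id, call, RQ) for a W-linked qPCR target.

    The decision threshold is either given or derived as the geometric
    midpoint of the mean RQ of known-sex calibration groups (both sexes
    required). RQ above threshold calls female; exactly at threshold is
    ambiguous.
    """
    if not records:
        raise ValueError("no records")
    if threshold_rq is None:
        if not calibration or not calibration.get("female") or not calibration.get("male"):
            raise ValueError("either threshold_rq or calibration with both sexes is required")
        gm = {}
        for sex, recs in calibration.items():
            rqs = [
                delta_ct_rq(r, inconsistency_threshold, efficiency).rq for r in recs
            ]
            gm[sex] = math.exp(float(np.mean(np.log(rqs))))
        threshold_rq = math.sqrt(gm["female"] * gm["male"])
    out = []
    for r in records:
        rq = delta_ct_rq(r, inconsistency_threshold, efficiency).rq
        if rq > threshold_rq:
            call = "female"
        elif rq < threshold_rq:
            call = "male"
        else:
            call = "ambiguous"
        out.append((r.specimen_id, call, rq))
    return out


# ------------------------------------------------------------------ statistics

def _u_statistic(ranks_a: np.ndarray, n_a: int, n_b: int) -> tuple[float, float]:
    u_a = float(ranks_a.sum() - n_a * (n_a + 1) / 2)
    u_b = n_a * n_b - u_a
    return u_a, u_b


def mann_whitney_u(a: list[float], b: list[float], exact_limit: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U with midrank ties.

    U is the smaller of the two one-sided statistics. For pooled sizes up to
    ``exact_limit`` the p-value is exact: all C(n, n_a) assignments of the
    pooled (tied) values to the groups are enumerated and p is the fraction
    with min-U at or below the observed one. Larger samples use the normal
    approximation with tie correction and continuity correction.
    """
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    pooled = np.asarray(list(a) + list(b), dtype=float)
    ranks = sps.rankdata(pooled)
    u_a, u_b = _u_statistic(ranks[:n_a], n_a, n_b)
    u = min(u_a, u_b)
    n = n_a + n_b
    if n <= exact_limit:
        total = 0
        at_or_below = 0
        for idx in combinations(range(n), n_a):
            ua, ub = _u_statistic(ranks[list(idx)], n_a, n_b)
            total += 1
            if min(ua, ub) <= u + 1e-9:
                at_or_below += 1
        p = at_or_below / total
    else:
        mu = n_a * n_b / 2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        sigma2 = n_a * n_b / 12 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (u - mu + 0.5) / math.sqrt(sigma2)
            p = min(1.0, 2 * sps.norm.cdf(z))
    return TestResult("U", u, p, (n_a, n_b))


def shapiro_wilk(x: list[float]) -> TestResult:
    """Shapiro-Wilk normality test (delegated to a vetted implementation)."""
    n = len(x)
    if not (3 <= n <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if len(set(x)) == 1:
        raise ValueError("constant sample")
    w, p = sps.shapiro(x)
    return TestResult("W", float(w), float(p), (n,))


def kruskal_wallis(groups: list[list[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    sizes = tuple(len(g) for g in groups)
    flat = [v for g in groups for v in g]
    if len(set(flat)) == 1:
        return TestResult("H", 0.0, 1.0, sizes)
    h, p = sps.kruskal(*groups)
    return TestResult("H", float(h), float(p), sizes)


# ------------------------------------------------------------------- table IO

def read_spot_counts(path: str | Path) -> list[SpotCountTable]:
    """TSV with columns specimen, cell_index, count (header required)."""
    per: dict[str, list[int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            per.setdefault(parts[idx["specimen"]], []).append(int(parts[idx["count"]]))
    return [SpotCountTable(s, tuple(c)) for s, c in per.items()]


def read_qpcr_table(path: str | Path) -> list[QpcrRecord]:
    """TSV with columns specimen, channel (target|reference), replicate, ct."""
    per: dict[str, dict[str, list[float]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            spec = parts[idx["specimen"]]
            per.setdefault(spec, {"target": [], "reference": []})[
                parts[idx["channel"]]
            ].append(float(parts[idx["ct"]]))
    return [
        QpcrRecord(s, tuple(ch["target"]), tuple(ch["reference"]))
        for s, ch in per.items()
    ]


def write_calls(calls: list[tuple[str, str, float | None]], method: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("specimen\tmethod\tcall\tscore\n")
        for spec, call, score in calls:
            s = "" if score is None else f"{score:.4g}"
            fh.write(f"{spec}\t{method}\t{call}\t{s}\n")
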