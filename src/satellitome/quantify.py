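"""Comparative abundance, divergence and W-candidate ranking.

Equal-size read samples from the female and male libraries are aligned to
the satellite catalog; per-family abundance is the proportion of aligned
nucleotides over all library nucleotides, divergence is the
aligned-nt-weighted Kimura two-parameter distance of reads to their
consensus, and the repeat landscape is that abundance histogrammed by
divergence. The subtractive landscape (female minus male, per bin) and the
F/M abundance ratio flag families accumulating on the female-limited W
chromosome: an autosomal family sits near F/M = 1, a W-linked one is
strongly female-enriched or absent from the male library altogether.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._align import best_tandem_alignment
from ._kmers import canonical_kmers
from .discovery import sample_reads
from .reads import ReadSet


# ------------------------------------------------------------------ subsample

def subsample_equal(
    female: ReadSet, male: ReadSet, n: int | str = "min", seed: int = 0
) -> tuple[ReadSet, ReadSet]:
    """Downsample both libraries to the same read count (default: the smaller).

    Equalising library sizes before masking is what makes the two abundance
    columns directly comparable.
    """
    if n == "min":
        n = min(female.n_reads, male.n_reads)
    if not isinstance(n, int) or n < 0:
        raise ValueError("n must be a non-negative integer or 'min'")
    if n > min(female.n_reads, male.n_reads):
        raise ValueError("n exceeds a library size")
    return (
        sample_reads(female, n, seed * 2 + 1),
        sample_reads(male, n, seed * 2 + 2),
    )


# ------------------------------------------------------------------- alignment

@dataclass(frozen=True)
class MaskingHit:
    read_id: str
    family_id: str
    aligned_nt: int
    transitions: int
    transversions: int
    identity: float

    @property
    def p(self) -> float:
        """Transition proportion of the aligned columns."""
        return self.transitions / self.aligned_nt

    @property
    def q(self) -> float:
        """Transversion proportion of the aligned columns."""
        return self.transversions / self.aligned_nt


@dataclass(frozen=True)
class CatalogEntry:
    family_id: str
    consensus: str


def read_catalog_fasta(path) -> list[CatalogEntry]:
    entries = []
    with open(path) as fh:
        name, chunks = None, []
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    entries.append(CatalogEntry(name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
        if name is not None:
            entries.append(CatalogEntry(name, "".join(chunks)))
    return entries


def align_to_catalog(
    reads: ReadSet,
    catalog: list[CatalogEntry],
    min_identity: float = 0.7,
    min_length: int = 20,
    k: int = 13,
) -> list[MaskingHit]:
    """Best-scoring local alignment of each read against the catalog.

    Each read is aligned (both strands, circular-aware via tandem tiling)
    to every catalog variant it shares a canonical k-mer with; the single
    highest-scoring trimmed alignment wins, preventing abundance
    double-counting. Hits shorter than ``min_length`` aligned nucleotides
    or below ``min_identity`` are discarded. Substitution columns are split
    into transitions (A<->G, C<->T) and transversions.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    entry_kmers = [np.unique(canonical_kmers(e.consensus + e.consensus, k)) for e in catalog]
    all_kmers = np.unique(np.concatenate(entry_kmers))
    hits: list[MaskingHit] = []
    for r in reads:
        rk = canonical_kmers(r.seq, k)
        if rk.size == 0 or all_kmers.size == 0:
            continue
        idx = np.clip(np.searchsorted(all_kmers, rk), 0, all_kmers.size - 1)
        if not np.any(all_kmers[idx] == rk):
            continue
        best = None
        for e, ek in zip(catalog, entry_kmers):
            j = np.clip(np.searchsorted(ek, rk), 0, ek.size - 1)
            if not np.any(ek[j] == rk):
                continue
            aln = best_tandem_alignment(r.seq, e.consensus)
            if aln is None:
                continue
            s = aln.summary(trim_ends=True)
            score = s.matches - 2 * (s.mismatches + s.query_insertions + s.target_deletions)
            if best is None or score > best[0]:
                best = (score, e.family_id, s)
        if best is None:
            continue
        _, family_id, s = best
        if s.aligned_nt >= min_length and s.identity >= min_identity:
            hits.append(
                MaskingHit(
                    r.id, family_id, s.aligned_nt, s.transitions, s.transversions, s.identity
                )
            )
    return hits


# ------------------------------------------------------------------- abundance

def abundance(
    hits: list[MaskingHit], reads: ReadSet, denominator: str = "nt"
) -> dict[str, float]:
    """Per-family aligned fraction of the library.

    ``denominator="nt"`` (default) divides summed aligned nucleotides by the
    summed read lengths; ``"reads"`` divides the count of hit reads by the
    read count instead.
    """
    if reads.n_reads == 0:
        raise ValueError("empty library")
    out: dict[str, float] = {}
    if denominator == "nt":
        total = reads.total_nt()
        for h in hits:
            out[h.family_id] = out.get(h.family_id, 0.0) + h.aligned_nt / total
    elif denominator == "reads":
        for h in hits:
            out[h.family_id] = out.get(h.family_id, 0.0) + 1 / reads.n_reads
    else:
        raise ValueError("denominator must be 'nt' or 'reads'")
    return out


# ------------------------------------------------------------------ divergence

class K2PSaturationError(ValueError):
    """P, Q outside the Kimura two-parameter log domain (distance saturated)."""


def kimura2p(P: float, Q: float) -> float:
    """Kimura two-parameter distance K = -1/2 ln[(1-2P-Q) sqrt(1-2Q)].

    P and Q are the transition and transversion proportions of the aligned
    columns. Raises :class:`K2PSaturationError` when the log domain is
    violated (too diverged to correct).
    """
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        raise K2PSaturationError(f"saturated: P={P}, Q={Q}")
    return -0.5 * math.log(a * math.sqrt(b))


def hit_divergence_percent(hit: MaskingHit) -> float | None:
    """K2P distance of one hit to its consensus, in percent; None if saturated."""
    try:
        return 100.0 * kimura2p(hit.p, hit.q)
    except K2PSaturationError:
        return None


def family_divergence(hits: list[MaskingHit]) -> float | None:
    """Aligned-nt-weighted mean K2P divergence (percent) of a family's hits.

    Returns None for an empty hit list (family absent from the library —
    printed as a dash in tables); saturated hits are excluded from the mean.
    """
    num = den = 0.0
    for h in hits:
        d = hit_divergence_percent(h)
        if d is None:
            continue
        num += d * h.aligned_nt
        den += h.aligned_nt
    return num / den if den else None


# ------------------------------------------------------------------ landscapes

@dataclass(frozen=True)
class RepeatLandscape:
    family_id: str
    bin_width: float
    values: tuple[float, ...]  # abundance fraction per bin, lower edge i*bin_width

    @property
    def bins(self) -> list[tuple[float, float]]:
        return [(i * self.bin_width, v) for i, v in enumerate(self.values)]

    def total(self) -> float:
        return float(sum(self.values))


_MAX_DIVERGENCE = 100.0


def build_landscape(
    hits: list[MaskingHit],
    reads: ReadSet,
    bin_width: float = 1.0,
    family_id: str = "all",
) -> RepeatLandscape:
    """Histogram of per-hit abundance contributions over K2P divergence bins.

    Every hit contributes ``aligned_nt / library nt`` to the bin holding its
    divergence, so the bins sum exactly to the abundance computed from the
    same hits; saturated hits land in the top bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(math.ceil(_MAX_DIVERGENCE / bin_width))
    values = np.zeros(n_bins)
    total = reads.total_nt()
    for h in hits:
        d = hit_divergence_percent(h)
        b = n_bins - 1 if d is None else min(int(d // bin_width), n_bins - 1)
        values[b] += h.aligned_nt / total
    return RepeatLandscape(family_id, bin_width, tuple(values))


def subtract_landscapes(female: RepeatLandscape, male: RepeatLandscape) -> RepeatLandscape:
    """Per-bin female - male difference; positive bins mark female excess."""
    if female.bin_width != male.bin_width:
        raise ValueError("bin widths differ")
    n = max(len(female.values), len(male.values))
    f = np.zeros(n)
    m = np.zeros(n)
    f[: len(female.values)] = female.values
    m[: len(male.values)] = male.values
    return RepeatLandscape(female.family_id, female.bin_width, tuple(f - m))


# ------------------------------------------------------------------- F/M ratio

ABSENT_IN_MALE = math.inf


def fm_ratio(abundance_female: float, abundance_male: float) -> float | None:
    """Female/male abundance quotient.

    Returns ``math.inf`` (absent-in-male flag) when the family has female
    abundance but none in the male library, and None when absent from both.
    """
    if abundance_female < 0 or abundance_male < 0:
        raise ValueError("abundances must be non-negative")
    if abundance_male > 0:
        return abundance_female / abundance_male
    if abundance_female > 0:
        return ABSENT_IN_MALE
    return None


@dataclass(frozen=True)
class AbundanceRecord:
    family_id: str
    abundance_female: float
    abundance_male: float
    divergence_female: float | None
    divergence_male: float | None
    fm: float | None

    @property
    def absent_in_male(self) -> bool:
        return self.fm is not None and math.isinf(self.fm)


def make_records(
    hits_female: list[MaskingHit],
    hits_male: list[MaskingHit],
    reads_female: ReadSet,
    reads_male: ReadSet,
    denominator: str = "nt",
) -> list[AbundanceRecord]:
    ab_f = abundance(hits_female, reads_female, denominator)
    ab_m = abundance(hits_male, reads_male, denominator)
    fams = sorted(set(ab_f) | set(ab_m))
    by_fam_f: dict[str, list[MaskingHit]] = {f: [] for f in fams}
    by_fam_m: dict[str, list[MaskingHit]] = {f: [] for f in fams}
    for h in hits_female:
        by_fam_f[h.family_id].append(h)
    for h in hits_male:
        by_fam_m[h.family_id].append(h)
    return [
        AbundanceRecord(
            fam,
            ab_f.get(fam, 0.0),
            ab_m.get(fam, 0.0),
            family_divergence(by_fam_f[fam]),
            family_divergence(by_fam_m[fam]),
            fm_ratio(ab_f.get(fam, 0.0), ab_m.get(fam, 0.0)),
        )
        for fam in fams
    ]


def rank_candidates(records: list[AbundanceRecord], top_k: int) -> list[AbundanceRecord]:
    """Top W-chromosome candidates by F/M ratio.

    Families absent from the male library outrank every finite ratio and are
    ordered among themselves by female abundance, mirroring the layout of
    published candidate tables.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    present = [r for r in records if r.fm is not None]
    absent = sorted(
        (r for r in present if r.absent_in_male),
        key=lambda r: (-r.abundance_female, r.family_id),
    )
    finite = sorted(
        (r for r in present if not r.absent_in_male),
        key=lambda r: (-r.fm, -r.abundance_female, r.family_id),
    )
    return (absent + finite)[:top_k]


# ---------------------------------------------------------------- file output

def write_abundance_table(records: list[AbundanceRecord], path) -> None:
    def fmt(x, pct=False):
        if x is None:
            return "-"
        if isinstance(x, float) and math.isinf(x):
            return "absent_in_male"
        return f"{x * 100:.6f}" if pct else f"{x:.6g}"

    with open(path, "w") as fh:
        fh.write(
            "family_id\tabundance_female_pct\tabundance_male_pct\t"
            "divergence_female_pct\tdivergence_male_pct\tfm_ratio\n"
        )
        for r in records:
            fh.write(
                f"{r.family_id}\t{fmt(r.abundance_female, pct=True)}\t"
                f"{fmt(r.abundance_male, pct=True)}\t{fmt(r.divergence_female)}\t"
                f"{fmt(r.divergence_male)}\t{fmt(r.fm)}\n"
            )


def write_landscape_tsv(landscapes: list[RepeatLandscape], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tbin_lower_pct\tvalue\n")
        for ls in landscapes:
            for lower, v in ls.bins:
                if v != 0:
                    fh.write(f"{ls.family_id}\t{lower:g}\t{v:.8g}\n")
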