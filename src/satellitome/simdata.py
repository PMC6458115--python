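"""Synthetic ZW/ZZ genome pairs with planted satellite arrays.

The generator emulates the study design this pipeline targets: one female
(ZW) and one male (ZZ) short-read library, 2x250 bp paired-end, in which
satellite DNA families sit as head-to-tail tandem arrays embedded in
single-copy background. Linkage is a label on each family — ``autosomal``
and ``Z`` families are planted in both sexes, ``W`` families only in the
female — because the downstream mathematics needs only per-library
nucleotide fractions, not chromosome structure.

Every random choice flows from an explicit seed, and the truth table is
computed from the strings actually emitted (post-mutation lengths), so
recovery tests compare against exact bookkeeping rather than expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._align import revcomp
from .reads import Read, ReadSet, write_paired_fastq

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class FamilySpec:
    """A planted satellite family: the ground truth a run should recover."""

    family_id: str
    monomer: str
    copies_female: int
    copies_male: int
    n_arrays: int = 1
    per_copy_substitution_rate: float = 0.0
    indel_rate: float = 0.0
    linkage: str = "autosomal"  # autosomal | Z | W

    def __post_init__(self) -> None:
        if not self.monomer or set(self.monomer) - set(_BASES):
            raise ValueError(f"{self.family_id}: monomer must be non-empty ACGT")
        if not (5 <= len(self.monomer) <= 2000):
            raise ValueError(f"{self.family_id}: monomer length outside 5..2000 nt")
        if self.linkage not in ("autosomal", "Z", "W"):
            raise ValueError(f"{self.family_id}: bad linkage {self.linkage!r}")
        if self.linkage == "W" and self.copies_male != 0:
            raise ValueError(f"{self.family_id}: W-linked family cannot have male copies")
        if min(self.copies_female, self.copies_male) < 0 or self.n_arrays < 1:
            raise ValueError(f"{self.family_id}: negative copies or n_arrays < 1")
        if not (0 <= self.per_copy_substitution_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError(f"{self.family_id}: rates must be in [0,1)")


@dataclass(frozen=True)
class PlacedArray:
    family_id: str
    sex: str  # female | male
    seq_index: int
    start: int  # 0-based, half-open
    end: int
    n_copies: int


@dataclass(frozen=True)
class TruthRecord:
    true_nt_fraction_female: float
    true_nt_fraction_male: float
    true_fm_ratio: float | None  # math.inf = absent in male; None = absent in both


@dataclass
class GenomePair:
    female_sequences: list[str]
    male_sequences: list[str]
    truth: dict[str, TruthRecord]
    arrays: list[PlacedArray]
    specs: list[FamilySpec] = field(default_factory=list)

    def sequences(self, sex: str) -> list[str]:
        return self.female_sequences if sex == "female" else self.male_sequences

    def array_intervals(self, sex: str) -> dict[int, list[tuple[int, int, str]]]:
        out: dict[int, list[tuple[int, int, str]]] = {}
        for a in self.arrays:
            if a.sex == sex:
                out.setdefault(a.seq_index, []).append((a.start, a.end, a.family_id))
        for v in out.values():
            v.sort()
        return out


@dataclass(frozen=True)
class ReadSimConfig:
    read_length: int = 250
    paired: bool = True
    insert_mean: int = 450
    insert_sd: int = 40
    n_read_pairs: int = 10_000
    per_base_error_rate: float = 0.001
    seed: int = 0
    quality_char: str = "?"  # Phred+33 Q30
    lowq_tail_fraction: float = 0.0  # fraction of reads given a low-quality tail
    lowq_tail_length: int = 30
    lowq_char: str = "#"  # Q2

    def __post_init__(self) -> None:
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")


def _mutate_copy(monomer: str, sub_rate: float, indel_rate: float, rng: np.random.Generator) -> str:
    if sub_rate == 0 and indel_rate == 0:
        return monomer
    out = []
    for base in monomer:
        r = rng.random()
        if indel_rate and r < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(_BASES[rng.integers(4)])  # insertion before the base
            out.append(base)
            continue
        if rng.random() < sub_rate:
            # transition:transversion 2:1
            if rng.random() < 2 / 3:
                out.append(_TRANSITION[base])
            else:
                out.append(_TRANSVERSIONS[base][rng.integers(2)])
        else:
            out.append(base)
    return "".join(out)


def _build_array(spec: FamilySpec, n_copies: int, rng: np.random.Generator) -> str:
    return "".join(
        _mutate_copy(spec.monomer, spec.per_copy_substitution_rate, spec.indel_rate, rng)
        for _ in range(n_copies)
    )


def _split_copies(total: int, n_arrays: int) -> list[int]:
    base, extra = divmod(total, n_arrays)
    counts = [base + (1 if i < extra else 0) for i in range(n_arrays)]
    return [c for c in counts if c > 0]


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_background(length: int, rng: np.random.Generator) -> str:
    return _BASE_BYTES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def plant_satellites(
    specs: list[FamilySpec],
    background_length_per_sex: int,
    seed: int,
) -> GenomePair:
    """Embed each family's tandem arrays at random positions in random background.

    Arrays are inserted (never overwritten), so they cannot overlap; the truth
    table is recomputed from the emitted strings.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    if len({s.family_id for s in specs}) != len(specs):
        raise ValueError("duplicate family_id in specs")
    rng = np.random.default_rng(seed)

    sequences: dict[str, list[str]] = {}
    placed: list[PlacedArray] = []
    planted_nt: dict[str, dict[str, int]] = {s.family_id: {"female": 0, "male": 0} for s in specs}
    totals: dict[str, int] = {}

    for sex in ("female", "male"):
        arrays: list[tuple[str, str, int]] = []  # (family_id, sequence, n_copies)
        for spec in specs:
            copies = spec.copies_female if sex == "female" else spec.copies_male
            if copies == 0:
                continue
            for n in _split_copies(copies, spec.n_arrays):
                arrays.append((spec.family_id, _build_array(spec, n, rng), n))
        sat_nt = sum(len(a[1]) for a in arrays)
        if sat_nt >= background_length_per_sex:
            raise ValueError("total planted satellite length must be < background length")
        background = _random_background(background_length_per_sex, rng)
        # insertion points in background coordinates; splice in sorted order
        points = sorted(rng.integers(0, background_length_per_sex + 1, size=len(arrays)))
        order = rng.permutation(len(arrays))
        pieces: list[str] = []
        prev = 0
        offset = 0
        for point, idx in zip(points, order):
            fam, arr, ncop = arrays[idx]
            pieces.append(background[prev:point])
            start = point + offset
            pieces.append(arr)
            placed.append(PlacedArray(fam, sex, 0, start, start + len(arr), ncop))
            planted_nt[fam][sex] += len(arr)
            offset += len(arr)
            prev = point
        pieces.append(background[prev:])
        genome = "".join(pieces)
        sequences[sex] = [genome]
        totals[sex] = len(genome)

    truth: dict[str, TruthRecord] = {}
    for spec in specs:
        ff = planted_nt[spec.family_id]["female"] / totals["female"]
        fm = planted_nt[spec.family_id]["male"] / totals["male"]
        if fm > 0:
            ratio: float | None = ff / fm
        elif ff > 0:
            ratio = math.inf
        else:
            ratio = None
        truth[spec.family_id] = TruthRecord(ff, fm, ratio)

    return GenomePair(sequences["female"], sequences["male"], truth, placed, list(specs))


@dataclass(frozen=True)
class ReadOrigin:
    seq_index: int
    start: int
    end: int
    strand: str


def simulate_reads(
    genome: GenomePair, cfg: ReadSimConfig
) -> tuple[ReadSet, ReadSet, dict[str, list[ReadOrigin]]]:
    """Uniform paired-end fragment sampling with i.i.d. substitution errors.

    Returns female and male read sets (mates interleaved, ``/1``/``/2``
    suffixes) plus per-library fragment origins for truth-aware checks.
    """
    rng = np.random.default_rng(cfg.seed)
    out: dict[str, ReadSet] = {}
    origins: dict[str, list[ReadOrigin]] = {}
    for sex in ("female", "male"):
        seqs = genome.sequences(sex)
        for s in seqs:
            if len(s) <= cfg.insert_mean:
                raise ValueError("genome sequences must be longer than insert_mean")
        lengths = np.array([len(s) for s in seqs], dtype=float)
        prefix = sex[0].upper()
        reads: list[Read] = []
        orig: list[ReadOrigin] = []
        for i in range(cfg.n_read_pairs):
            si = int(rng.choice(len(seqs), p=lengths / lengths.sum()))
            seq = seqs[si]
            ins = int(np.clip(round(rng.normal(cfg.insert_mean, cfg.insert_sd)),
                              cfg.read_length, len(seq)))
            start = int(rng.integers(0, len(seq) - ins + 1))
            frag = seq[start : start + ins]
            r1 = frag[: cfg.read_length]
            r2 = revcomp(frag[-cfg.read_length :]) if cfg.paired else ""
            r1 = _apply_errors(r1, cfg.per_base_error_rate, rng)
            stem = f"{prefix}{i:07d}"
            q1 = _quality(cfg, rng)
            reads.append(Read(f"{stem}/1", r1, q1))
            orig.append(ReadOrigin(si, start, start + cfg.read_length, "+"))
            if cfg.paired:
                r2 = _apply_errors(r2, cfg.per_base_error_rate, rng)
                q2 = _quality(cfg, rng)
                reads.append(Read(f"{stem}/2", r2, q2))
                orig.append(ReadOrigin(si, start + ins - cfg.read_length, start + ins, "-"))
        out[sex] = ReadSet(reads, sex)
        origins[sex] = orig
    return out["female"], out["male"], origins


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        alt = _BASES[rng.integers(4)]
        while alt == chars[i]:
            alt = _BASES[rng.integers(4)]
        chars[i] = alt
    return "".join(chars)


def _quality(cfg: ReadSimConfig, rng: np.random.Generator) -> str:
    q = cfg.quality_char * cfg.read_length
    if cfg.lowq_tail_fraction > 0 and rng.random() < cfg.lowq_tail_fraction:
        tail = min(cfg.lowq_tail_length, cfg.read_length)
        q = q[: cfg.read_length - tail] + cfg.lowq_char * tail
    return q


# ---------------------------------------------------------------- file output

def write_truth_table(genome: GenomePair, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "family_id\tlinkage\tmonomer_length\t"
            "true_fraction_female\ttrue_fraction_male\tfm_ratio\n"
        )
        by_id = {s.family_id: s for s in genome.specs}
        for fam, rec in genome.truth.items():
            spec = by_id[fam]
            if rec.true_fm_ratio is None:
                ratio = "NA"
            elif math.isinf(rec.true_fm_ratio):
                ratio = "absent_in_male"
            else:
                ratio = f"{rec.true_fm_ratio:.6g}"
            fh.write(
                f"{fam}\t{spec.linkage}\t{len(spec.monomer)}\t"
                f"{rec.true_nt_fraction_female:.8g}\t{rec.true_nt_fraction_male:.8g}\t{ratio}\n"
            )


def write_monomer_fasta(specs: list[FamilySpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in specs:
            fh.write(f">{s.family_id} linkage={s.linkage} rul={len(s.monomer)}\n{s.monomer}\n")


def write_libraries(
    female: ReadSet, male: ReadSet, outdir: str | Path
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "female_1": outdir / "female_1.fastq",
        "female_2": outdir / "female_2.fastq",
        "male_1": outdir / "male_1.fastq",
        "male_2": outdir / "male_2.fastq",
    }
    write_paired_fastq(female, paths["female_1"], paths["female_2"])
    write_paired_fastq(male, paths["male_1"], paths["male_2"])
    return paths
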