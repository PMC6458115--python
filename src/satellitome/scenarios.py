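"""Canned synthetic study designs used by the analysis drivers and tests.

Each scenario fixes the planted family set — monomer lengths, genomic
fractions, per-copy divergence, linkage — once, as the conditions the
pipeline is exercised under; the seed only moves the random monomer
sequences and array placements, never the design.
"""

from __future__ import annotations

import numpy as np

from .catalog import circular_identity
from .sexing import QpcrRecord, SpotCountTable
from .simdata import FamilySpec

_BASES = "ACGT"


def random_monomer(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _distinct_monomers(
    rng: np.random.Generator, lengths: list[int], max_identity: float = 0.7
) -> list[str]:
    """Random monomers kept mutually below ``max_identity`` circular identity."""
    for _ in range(50):
        monomers = [random_monomer(rng, L) for L in lengths]
        ok = all(
            circular_identity(monomers[i], monomers[j]) < max_identity
            for i in range(len(monomers))
            for j in range(i + 1, len(monomers))
        )
        if ok:
            return monomers
    raise RuntimeError("could not draw mutually distinct monomers")


def _specs(
    rng: np.random.Generator,
    lengths: list[int],
    fractions: list[float],
    w_indices: set[int],
    sub_rates: list[float],
    n_arrays: list[int],
    background: int,
) -> list[FamilySpec]:
    monomers = _distinct_monomers(rng, lengths)
    total = background / (1.0 - sum(fractions))
    specs = []
    for i, (mono, frac) in enumerate(zip(monomers, fractions)):
        copies = max(n_arrays[i], round(frac * total / len(mono)))
        w = i in w_indices
        specs.append(
            FamilySpec(
                family_id=f"fam{i + 1}",
                monomer=mono,
                copies_female=copies,
                copies_male=0 if w else copies,
                n_arrays=n_arrays[i],
                per_copy_substitution_rate=sub_rates[i],
                linkage="W" if w else "autosomal",
            )
        )
    return specs


def small_scenario(seed: int = 0, background: int = 600_000) -> list[FamilySpec]:
    """Three families (one W-linked) at end-to-end testable sizes.

    Sized so a full pipeline run — discovery through haplotype networks —
    completes in seconds while every stage still has signal to find.
    """
    rng = np.random.default_rng(seed)
    return _specs(
        rng,
        lengths=[50, 63, 41],
        fractions=[0.02, 0.008, 0.004],
        w_indices={2},
        sub_rates=[0.03, 0.03, 0.03],
        n_arrays=[2, 2, 1],
        background=background,
    )


def quantify_scenario(seed: int = 0, background: int = 400_000) -> list[FamilySpec]:
    """Five families spanning 0.1-3% of genome nucleotides, one W-linked.

    The abundance-recovery conditions: moderate per-copy divergence so the
    K2P landscape has structure, W family at 0.6% of the female genome.
    """
    rng = np.random.default_rng(seed)
    return _specs(
        rng,
        lengths=[53, 72, 41, 64, 37],
        fractions=[0.03, 0.012, 0.006, 0.003, 0.001],
        w_indices={2},
        sub_rates=[0.05, 0.08, 0.05, 0.10, 0.05],
        n_arrays=[3, 2, 2, 2, 1],
        background=background,
    )


def discovery_scenario(seed: int = 0, background: int = 3_000_000) -> list[FamilySpec]:
    """Five mutually <70%-identical families for the mining-loop conditions.

    One abundant autosomal family (2% of nucleotides) dominates round-one
    clusters; a rare W-linked family at 0.07% should only surface in a later
    round, after the abundant families are masked out of the pool. The
    background is sized so a clustering round samples the genome well below
    1x coverage — the regime real satellite mining operates in, where
    single-copy reads rarely overlap and only repeats form clusters.
    """
    rng = np.random.default_rng(seed)
    return _specs(
        rng,
        lengths=[52, 67, 44, 58, 36],
        fractions=[0.02, 0.01, 0.005, 0.002, 0.0007],
        w_indices={2, 4},
        sub_rates=[0.03, 0.03, 0.03, 0.03, 0.02],
        n_arrays=[2, 2, 2, 2, 1],
        background=background,
    )


def simulate_spot_counts(
    sex: str,
    rng: np.random.Generator,
    specimen_id: str = "spec",
    n_cells: tuple[int, int] = (40, 90),
    expected_rate: float = 0.9,
) -> SpotCountTable:
    """Interphase spot counts for one specimen of known sex.

    A ZW female cell shows the expected three signals (two autosomal, one W)
    with probability ``expected_rate``, otherwise a dropout or an overlap
    artifact; a ZZ male cell shows two. Cell counts are drawn uniformly from
    the ``n_cells`` range, matching the 40-90 cells scored per specimen in
    practice.
    """
    expected = 3 if sex == "female" else 2
    n = int(rng.integers(n_cells[0], n_cells[1] + 1))
    counts = []
    for _ in range(n):
        if rng.random() < expected_rate:
            counts.append(expected)
        elif rng.random() < 0.7:
            counts.append(max(0, expected - 1 - int(rng.random() < 0.2)))
        else:
            counts.append(expected + 1)
    return SpotCountTable(specimen_id, tuple(counts))


def simulate_qpcr_record(
    sex: str,
    rng: np.random.Generator,
    specimen_id: str = "spec",
    w_delta_ct_female: float = -3.5,
    w_delta_ct_male: float = 3.5,
    replicate_sd: float = 0.1,
    n_replicates: int = 2,
) -> QpcrRecord:
    """qPCR replicates for a W-linked target against a single-copy reference.

    The female carries many W copies, so her target amplifies ~3.5 cycles
    earlier than the reference; in the male the target is near-absent and
    crosses threshold late.
    """
    ref = 24.0 + rng.normal(0, 0.3)
    delta = w_delta_ct_female if sex == "female" else w_delta_ct_male
    ct_ref = tuple(float(ref + rng.normal(0, replicate_sd)) for _ in range(n_replicates))
    ct_tgt = tuple(
        float(ref + delta + rng.normal(0, replicate_sd)) for _ in range(n_replicates)
    )
    return QpcrRecord(specimen_id, ct_tgt, ct_ref, sex_label=sex)
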