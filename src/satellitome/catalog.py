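"""Hierarchical satellite cataloguing.

Discovered monomers are grouped by sequence identity into three nested
levels — variants (>95%), families (>80%) and superfamilies (>40%) — by
single-linkage clustering, and families receive catalog names of the form
``<prefix>SatNNN-RUL`` ranked by decreasing abundance in the female library.

Monomers are circular sequences with arbitrary phase and strand, so the
identity measure aligns one partner against a tandem tiling of the other
with free end gaps (the standard satellite-literature convention) and takes
the best over both strands and both directions; identity is
1 - edit distance / query length (equal to matches / alignment columns for
substitution-only divergence, and independent of aligner tie-breaking).

One subtlety drives the grouping design: an optimal global DNA alignment of
two *unrelated* monomers already scores ~55% identity (the alignment
"twilight floor" — the optimiser finds chance agreements), so a 40%
superfamily cut applied to raw identity alone would connect everything.
The homology searches this cataloguing emulates are seeded local searches,
for which unrelated pairs simply produce no hit. Grouping therefore
requires a pair to share an exact seed word (default 11 nt, canonical, on
the doubled sequences) before its identity can create an edge; thresholds
then apply to raw identity among seeded pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import edlib
import networkx as nx

from ._align import revcomp, tile_to_length
from ._kmers import canonical_kmers, shares_kmer


@dataclass(frozen=True)
class SatVariant:
    consensus: str
    rul: int
    at_content: float
    abundance_female: float = 0.0
    abundance_male: float = 0.0

    @classmethod
    def from_consensus(
        cls, consensus: str, abundance_female: float = 0.0, abundance_male: float = 0.0
    ) -> "SatVariant":
        at = (consensus.count("A") + consensus.count("T")) / len(consensus)
        return cls(consensus, len(consensus), at, abundance_female, abundance_male)


@dataclass(frozen=True)
class SatFamily:
    family_id: str
    variants: tuple[SatVariant, ...]
    representative: SatVariant

    @property
    def abundance_female(self) -> float:
        return sum(v.abundance_female for v in self.variants)

    @property
    def abundance_male(self) -> float:
        return sum(v.abundance_male for v in self.variants)

    @property
    def rul(self) -> int:
        return self.representative.rul


@dataclass(frozen=True)
class Superfamily:
    sf_id: int
    families: tuple[SatFamily, ...]


def _one_way_identity(query: str, target: str) -> float:
    """Identity of the whole query against a tandem tiling of the target:
    1 - edit_distance/len(query), best strand.

    Distance-based rather than path-based, so the value is independent of
    how the aligner breaks ties between equally-distant alignments; for
    substitution-only divergence it equals matches/alignment-columns.
    """
    best = 0.0
    for t in (target, revcomp(target)):
        ref = tile_to_length(t, len(query) + 2 * len(t))
        d = edlib.align(query, ref, mode="HW")["editDistance"]
        if d < 0:
            continue
        best = max(best, 1.0 - d / len(query))
    return max(0.0, best)


def circular_identity(a: str, b: str) -> float:
    """Best rotation- and strand-aware identity between two monomers, in [0,1]."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return max(_one_way_identity(a, b), _one_way_identity(b, a))


def canonical_monomer(m: str) -> str:
    """Lexicographically smallest rotation of ``m`` or its reverse complement.

    A stable, phase- and strand-free representative: idempotent, and equal
    for any two observations of the same circular sequence.
    """
    if not m:
        raise ValueError("monomer must be non-empty")
    candidates = []
    for s in (m, revcomp(m)):
        doubled = s + s
        candidates.extend(doubled[i : i + len(s)] for i in range(len(s)))
    return min(candidates)


@dataclass(frozen=True)
class Hierarchy:
    variants: tuple[SatVariant, ...]
    families: tuple[SatFamily, ...]
    superfamilies: tuple[Superfamily, ...]
    #: per input index: (variant_group, family_group, superfamily_group)
    membership: tuple[tuple[int, int, int], ...]


def _components(n: int, edges: list[tuple[int, int, float]], threshold: float) -> list[int]:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((i, j) for i, j, w in edges if w > threshold)
    label = [0] * n
    comps = sorted(nx.connected_components(g), key=min)
    for ci, comp in enumerate(comps):
        for i in comp:
            label[i] = ci
    return label


def shares_seed(a: str, b: str, seed_size: int = 11) -> bool:
    """True when the doubled sequences share an exact canonical seed word —
    the precondition for a seeded homology search to report any hit."""
    ka = canonical_kmers(a + a, seed_size)
    kb = canonical_kmers(b + b, seed_size)
    return shares_kmer(ka, kb)


def group_hierarchy(
    monomers: list[SatVariant],
    variant_threshold: float = 0.95,
    family_threshold: float = 0.80,
    superfamily_threshold: float = 0.40,
    seed_size: int = 11,
) -> Hierarchy:
    """Single-linkage grouping at the three identity thresholds.

    The same weighted identity graph is cut at each threshold, so the
    partitions are nested by construction: every variant group lies inside
    one family, every family inside one superfamily. A pair can only form
    an edge when it shares a ``seed_size`` exact word (see module notes on
    the alignment twilight floor).
    """
    if not monomers:
        raise ValueError("monomer list must be non-empty")
    if not variant_threshold > family_threshold > superfamily_threshold:
        raise ValueError("thresholds must be strictly decreasing")
    n = len(monomers)
    seeds = [canonical_kmers(m.consensus + m.consensus, seed_size) for m in monomers]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if not shares_kmer(seeds[i], seeds[j]):
                continue
            w = circular_identity(monomers[i].consensus, monomers[j].consensus)
            if w > superfamily_threshold:
                edges.append((i, j, w))
    v_label = _components(n, edges, variant_threshold)
    f_label = _components(n, edges, family_threshold)
    s_label = _components(n, edges, superfamily_threshold)

    def _merge_variants(indices: list[int]) -> SatVariant:
        members = [monomers[i] for i in indices]
        rep = max(members, key=lambda v: (v.abundance_female, v.abundance_male, v.consensus))
        return replace(
            rep,
            abundance_female=sum(v.abundance_female for v in members),
            abundance_male=sum(v.abundance_male for v in members),
        )

    v_groups: dict[int, list[int]] = {}
    for i, lab in enumerate(v_label):
        v_groups.setdefault(lab, []).append(i)
    merged = {lab: _merge_variants(idx) for lab, idx in v_groups.items()}

    fam_variants: dict[int, dict[int, SatVariant]] = {}
    for lab, var in merged.items():
        fam_lab = f_label[v_groups[lab][0]]
        fam_variants.setdefault(fam_lab, {})[lab] = var

    families: dict[int, SatFamily] = {}
    for fam_lab, vars_by_lab in fam_variants.items():
        vs = tuple(
            sorted(
                vars_by_lab.values(),
                key=lambda v: (-v.abundance_female, -v.abundance_male, v.consensus),
            )
        )
        families[fam_lab] = SatFamily("", vs, vs[0])

    sf_members: dict[int, list[SatFamily]] = {}
    for fam_lab, fam in families.items():
        any_idx = next(i for i, l in enumerate(f_label) if l == fam_lab)
        sf_members.setdefault(s_label[any_idx], []).append(fam)
    superfamilies = []
    for rank, (sf_lab, fams) in enumerate(
        sorted(
            sf_members.items(),
            key=lambda kv: -sum(f.abundance_female for f in kv[1]),
        ),
        start=1,
    ):
        fams_sorted = tuple(sorted(fams, key=lambda f: -f.abundance_female))
        superfamilies.append(Superfamily(rank, fams_sorted))

    membership = tuple((v_label[i], f_label[i], s_label[i]) for i in range(n))
    return Hierarchy(
        tuple(merged.values()),
        tuple(families.values()),
        tuple(superfamilies),
        membership,
    )


def assign_names(
    families: list[SatFamily], prefix: str, pad: int = 3
) -> list[SatFamily]:
    """Catalog names ``<prefix>SatNNN-RUL`` ranked by female abundance.

    Ties break by male abundance, then lexicographic representative
    consensus, so the naming is a pure function of the catalog content.
    """
    if len({id(f) for f in families}) != len(families):
        raise ValueError("duplicate family objects in input")
    for f in families:
        if f.abundance_female is None:
            raise ValueError("female abundance required for naming")
    ranked = sorted(
        families,
        key=lambda f: (-f.abundance_female, -f.abundance_male, f.representative.consensus),
    )
    return [
        replace(f, family_id=f"{prefix}Sat{i:0{pad}d}-{f.rul}")
        for i, f in enumerate(ranked, start=1)
    ]


def write_catalog_fasta(hierarchy: Hierarchy, named: list[SatFamily], path) -> None:
    sf_of = {}
    for sf in hierarchy.superfamilies:
        for fam in sf.families:
            sf_of[fam.representative.consensus] = sf.sf_id
    with open(path, "w") as fh:
        for fam in named:
            sf = sf_of.get(fam.representative.consensus, 0)
            fh.write(
                f">{fam.family_id} sf={sf} variants={len(fam.variants)}\n"
                f"{fam.representative.consensus}\n"
            )


def write_hierarchy_tsv(named: list[SatFamily], hierarchy: Hierarchy, path) -> None:
    sf_of = {}
    for sf in hierarchy.superfamilies:
        for fam in sf.families:
            sf_of[fam.representative.consensus] = sf.sf_id
    with open(path, "w") as fh:
        fh.write("variant_id\tfamily_id\tsf_id\trul\tat_content\n")
        for fam in named:
            sf = sf_of.get(fam.representative.consensus, 0)
            for vi, var in enumerate(fam.variants, start=1):
                fh.write(
                    f"{fam.family_id}.v{vi}\t{fam.family_id}\t{sf}\t"
                    f"{var.rul}\t{var.at_content:.4f}\n"
                )
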