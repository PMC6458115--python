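"""Monomer haplotype networks for selected satellite families.

Full-length monomer copies are excised straight from reads: a read is
aligned against a tandem tiling of the family consensus, and every copy
whose full consensus span lies inside the read is cut out, oriented to the
consensus strand and phased to consensus position 0 (rotations therefore
never create artificial haplotypes). Identical sequences collapse into
haplotypes with per-library counts; haplotypes seen once across both
libraries (singletons) are discarded; and a minimum spanning tree over
pairwise mutational steps summarises the family's intragenomic
diversification. On a female-heterogametic (ZW) system, W-restricted
haplotypes show up as female-only nodes hanging off shared ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import networkx as nx

from ._align import best_tandem_alignment, parse_cigar
from ._kmers import canonical_kmers, shares_kmer
import numpy as np

from .reads import ReadSet


@dataclass(frozen=True)
class Monomer:
    sequence: str
    source_read: str
    source_library: str
    family_id: str


@dataclass(frozen=True)
class Haplotype:
    sequence: str
    count_female: int
    count_male: int

    @property
    def total(self) -> int:
        return self.count_female + self.count_male


@dataclass(frozen=True)
class HaplotypeGraph:
    haplotypes: tuple[Haplotype, ...]
    edges: tuple[tuple[int, int, int], ...]  # (node_a, node_b, steps)
    tree_flag: bool

    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)


# -------------------------------------------------------------------- harvest

def harvest_monomers(
    reads: ReadSet,
    family_consensus: str,
    family_id: str,
    min_identity: float = 0.8,
    k: int = 13,
) -> list[Monomer]:
    """Excise every complete, phased monomer copy from each read.

    A copy is complete when the alignment covers consensus positions
    0..RUL entirely within the read; flanking partial copies are dropped.
    Copies below ``min_identity`` to the consensus are rejected.
    """
    rul = len(family_consensus)
    read_len = min((len(r.seq) for r in reads), default=0)
    if reads.n_reads and rul >= read_len:
        raise ValueError(
            f"consensus ({rul} nt) not shorter than reads ({read_len} nt): not harvestable"
        )
    fam_kmers = np.unique(canonical_kmers(family_consensus + family_consensus, k))
    out: list[Monomer] = []
    for r in reads:
        if not shares_kmer(canonical_kmers(r.seq, k), fam_kmers):
            continue
        aln = best_tandem_alignment(r.seq, family_consensus)
        if aln is None:
            continue
        # map each tandem-reference position to the query interval it aligns to
        qpos: dict[int, tuple[int, int]] = {}  # ref pos -> (q_lo, q_hi)
        match_at: dict[int, bool] = {}
        for qi, ti, op in aln.columns():
            if ti < 0:
                continue
            if qi >= 0:
                lo, hi = qpos.get(ti, (qi, qi + 1))
                qpos[ti] = (min(lo, qi), max(hi, qi + 1))
                match_at[ti] = op in "=M" and aln.query[qi] == aln.ref[ti]
            else:
                qpos.setdefault(ti, (-1, -1))
                match_at[ti] = False
        if not qpos:
            continue
        t_lo, t_hi = min(qpos), max(qpos) + 1
        first_copy = -(-t_lo // rul)  # first period starting inside the alignment
        p = first_copy
        while (p + 1) * rul <= t_hi:
            span = range(p * rul, (p + 1) * rul)
            covered = all(t in qpos for t in span)
            if covered:
                ident = sum(match_at[t] for t in span) / rul
                q_cols = [qpos[t] for t in span if qpos[t][0] >= 0]
                if ident >= min_identity and q_cols:
                    q_lo = min(c[0] for c in q_cols)
                    q_hi = max(c[1] for c in q_cols)
                    out.append(
                        Monomer(aln.query[q_lo:q_hi], r.id, reads.library_label, family_id)
                    )
            p += 1
    return out


# ------------------------------------------------------------------- collapse

def collapse_haplotypes(
    monomers: list[Monomer], drop_singletons: bool = True
) -> list[Haplotype]:
    """Exact-sequence grouping with per-library counts.

    A singleton is a sequence observed exactly once across both libraries
    combined; with ``drop_singletons`` those are removed.
    """
    fams = {m.family_id for m in monomers}
    if len(fams) > 1:
        raise ValueError(f"monomers from multiple families: {sorted(fams)}")
    counts: dict[str, list[int]] = {}
    for m in monomers:
        c = counts.setdefault(m.sequence, [0, 0])
        c[0 if m.source_library == "female" else 1] += 1
    haps = [Haplotype(seq, cf, cm) for seq, (cf, cm) in counts.items()]
    if drop_singletons:
        haps = [h for h in haps if h.total >= 2]
    haps.sort(key=lambda h: (-h.total, h.sequence))
    return haps


# ------------------------------------------------------------------ distances

def star_align(haplotypes: list[Haplotype], consensus: str) -> list[str]:
    """Project each haplotype onto consensus columns (star alignment).

    Every output string has the consensus length: per consensus position the
    aligned haplotype base, or ``-`` where the haplotype has a deletion.
    Insertions relative to the consensus are dropped — an approximation to a
    full multiple alignment, adequate for near-RUL-length monomers.
    """
    out = []
    for h in haplotypes:
        res = edlib.align(h.sequence, consensus, mode="NW", task="path")
        cols = ["-"] * len(consensus)
        qi = ti = 0
        for n, op in parse_cigar(res["cigar"]):
            for _ in range(n):
                if op in "=XM":
                    cols[ti] = h.sequence[qi]
                    qi += 1
                    ti += 1
                elif op == "I":
                    qi += 1
                else:
                    ti += 1
        out.append("".join(cols))
    return out


def pairwise_steps(a: str, b: str) -> int:
    """Mutational steps between two aligned sequences: differing columns,
    gaps counted as a fifth state."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    return sum(x != y for x, y in zip(a, b))


def distance_matrix(haplotypes: list[Haplotype], consensus: str | None = None) -> list[list[int]]:
    seqs = [h.sequence for h in haplotypes]
    if consensus is not None or len({len(s) for s in seqs}) > 1:
        if consensus is None:
            raise ValueError("unequal haplotype lengths require a consensus for star alignment")
        seqs = star_align(haplotypes, consensus)
    n = len(seqs)
    d = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d[i][j] = d[j][i] = pairwise_steps(seqs[i], seqs[j])
    return d


# ------------------------------------------------------------------------ MST

class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_mst(haplotypes: list[Haplotype], distances: list[list[int]]) -> HaplotypeGraph:
    """Kruskal MST with abundance-aware deterministic tie-breaking.

    Among equal-weight edges, those touching higher-total-count haplotypes
    are taken first (goeBURST-style), then ties fall back to the
    lexicographic order of the endpoint sequences — the result is a pure
    function of the inputs, and total weight is minimal regardless of
    tie-breaking.
    """
    n = len(haplotypes)
    if n == 0:
        raise ValueError("at least one haplotype required")
    for i in range(n):
        if distances[i][i] != 0:
            raise ValueError("distance matrix diagonal must be zero")
        for j in range(i + 1, n):
            if distances[i][j] != distances[j][i]:
                raise ValueError("distance matrix must be symmetric")
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            ca, cb = haplotypes[i].total, haplotypes[j].total
            key = (
                distances[i][j],
                -max(ca, cb),
                -min(ca, cb),
                min(haplotypes[i].sequence, haplotypes[j].sequence),
                max(haplotypes[i].sequence, haplotypes[j].sequence),
            )
            edges.append((key, i, j))
    edges.sort()
    dsu = _DSU(n)
    chosen = []
    for key, i, j in edges:
        if dsu.union(i, j):
            chosen.append((i, j, key[0]))
            if len(chosen) == n - 1:
                break
    return HaplotypeGraph(tuple(haplotypes), tuple(chosen), True)


# --------------------------------------------------------------------- export

def to_networkx(graph: HaplotypeGraph) -> nx.Graph:
    g = nx.Graph()
    for i, h in enumerate(graph.haplotypes):
        g.add_node(
            i,
            sequence=h.sequence,
            count_female=h.count_female,
            count_male=h.count_male,
            total=h.total,
        )
    for i, j, w in graph.edges:
        g.add_edge(i, j, steps=w)
    return g


def export_graphml(graph: HaplotypeGraph, path) -> None:
    nx.write_graphml(to_networkx(graph), path)


def export_dot(graph: HaplotypeGraph, path) -> None:
    """DOT output with node size proportional to haplotype abundance."""
    with open(path, "w") as fh:
        fh.write("graph haplotypes {\n  node [shape=circle];\n")
        for i, h in enumerate(graph.haplotypes):
            size = 0.3 + 0.1 * h.total
            fh.write(
                f'  n{i} [width={size:.2f}, label="{h.total}", '
                f'count_female={h.count_female}, count_male={h.count_male}];\n'
            )
        for i, j, w in graph.edges:
            fh.write(f'  n{i} -- n{j} [label="{w}"];\n')
        fh.write("}\n")


def write_haplotype_table(haplotypes: list[Haplotype], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount_female\tcount_male\ttotal\n")
        for h in haplotypes:
            fh.write(f"{h.sequence}\t{h.count_female}\t{h.count_male}\t{h.total}\n")
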