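"""Monomer harvesting, haplotype collapse and minimum spanning trees."""

from itertools import product

import networkx as nx
import numpy as np
import pytest

from satellitome._align import revcomp
from satellitome.monomer_net import (
    Haplotype,
    Monomer,
    build_mst,
    collapse_haplotypes,
    distance_matrix,
    export_dot,
    export_graphml,
    harvest_monomers,
    pairwise_steps,
    star_align,
    to_networkx,
)
from satellitome.reads import Read, ReadSet
from satellitome.scenarios import random_monomer


def _mk(seqs, label="female"):
    return ReadSet([Read(f"r{i}/1", s, "?" * len(s)) for i, s in enumerate(seqs)], label)


# -------------------------------------------------------------------- harvest

def test_harvest_phase_zero_read_yields_all_copies(rng):
    mono = random_monomer(rng, 50)
    read = mono * 5  # 250 nt, phase 0
    out = harvest_monomers(_mk([read]), mono, "fam")
    assert len(out) == 5
    assert all(m.sequence == mono for m in out)


def test_harvest_shifted_read_drops_partial_flanks(rng):
    mono = random_monomer(rng, 50)
    read = (mono * 6)[20:270]  # phase 20: 4 complete copies inside
    out = harvest_monomers(_mk([read]), mono, "fam")
    assert len(out) == 4
    assert all(m.sequence == mono for m in out)


def test_harvest_no_alignment_gives_nothing(rng):
    out = harvest_monomers(_mk([random_monomer(rng, 250)]), random_monomer(rng, 50), "fam")
    assert out == []


def test_harvest_reverse_strand_normalized(rng):
    mono = random_monomer(rng, 50)
    out = harvest_monomers(_mk([revcomp(mono * 5)]), mono, "fam")
    assert len(out) == 5
    assert all(m.sequence == mono for m in out)


def test_harvest_rejects_consensus_longer_than_reads(rng):
    with pytest.raises(ValueError):
        harvest_monomers(_mk(["ACGT" * 20]), random_monomer(rng, 120), "fam")


def test_harvest_count_conservation(rng):
    """Sum of haplotype totals (pre-filter) equals harvested monomer count."""
    mono = random_monomer(rng, 40)
    reads = [(mono * 8)[i : i + 250] for i in (0, 13, 27)]
    monos = harvest_monomers(_mk(reads), mono, "fam")
    haps = collapse_haplotypes(monos, drop_singletons=False)
    assert sum(h.total for h in haps) == len(monos)


# ------------------------------------------------------------------- collapse

def _mono(seq, lib="female"):
    return Monomer(seq, "r", lib, "fam")


def test_collapse_and_singleton_filter():
    monos = [_mono("AAAA")] * 3 + [_mono("CCCC")]
    assert len(collapse_haplotypes(monos, True)) == 1
    assert collapse_haplotypes(monos, True)[0].total == 3
    assert len(collapse_haplotypes(monos, False)) == 2


def test_collapse_planted_counts():
    seqs = ["A" * 10, "C" * 10, "G" * 10, "T" * 10, "AC" * 5]
    counts = [10, 8, 4, 2, 1]
    monos = [
        _mono(s, "female" if i % 2 == 0 else "male")
        for s, c in zip(seqs, counts)
        for i in range(c)
    ]
    haps = collapse_haplotypes(monos, True)
    assert len(haps) == 4
    assert [h.total for h in haps] == [10, 8, 4, 2]


def test_collapse_tracks_sex_counts():
    monos = [_mono("AAAA", "female")] * 2 + [_mono("AAAA", "male")] * 3
    h = collapse_haplotypes(monos, True)[0]
    assert (h.count_female, h.count_male, h.total) == (2, 3, 5)


def test_collapse_rejects_mixed_families():
    with pytest.raises(ValueError):
        collapse_haplotypes(
            [Monomer("AAAA", "r", "female", "f1"), Monomer("CCCC", "r", "female", "f2")], True
        )


# ------------------------------------------------------------------ distances

def test_pairwise_steps_counts_columns(rng):
    assert pairwise_steps("ACGT", "ACGT") == 0
    assert pairwise_steps("ACGT", "ACTT") == 1
    assert pairwise_steps("AC-T", "ACTT") == 1  # gap is a fifth state
    for _ in range(10):
        a = random_monomer(rng, 30)
        b = random_monomer(rng, 30)
        assert pairwise_steps(a, b) == sum(x != y for x, y in zip(a, b))
    with pytest.raises(ValueError):
        pairwise_steps("ACGT", "ACG")


def test_star_alignment_handles_indels(rng):
    cons = random_monomer(rng, 40)
    deleted = cons[:10] + cons[11:]  # one deletion
    haps = [Haplotype(cons, 2, 0), Haplotype(deleted, 2, 0)]
    aligned = star_align(haps, cons)
    assert len(aligned[0]) == len(aligned[1]) == 40
    assert pairwise_steps(aligned[0], aligned[1]) == 1


# ------------------------------------------------------------------------ MST

def _haps(counts):
    return [Haplotype(f"{'ACGT'[i % 4]}{i:03d}", c, 0) for i, c in enumerate(counts)]


def _exhaustive_min_weight(d):
    """All spanning trees of K_n via Pruefer sequences; minimum total weight."""
    n = len(d)
    if n == 1:
        return 0
    if n == 2:
        return d[0][1]
    best = None
    for seq in product(range(n), repeat=n - 2):
        g = nx.from_prufer_sequence(list(seq))
        w = sum(d[u][v] for u, v in g.edges)
        best = w if best is None else min(best, w)
    return best


def test_mst_two_nodes():
    g = build_mst(_haps([3, 2]), [[0, 4], [4, 0]])
    assert g.edges == ((0, 1, 4),)
    assert g.tree_flag


def test_mst_worked_example_weight_four():
    """d(1,2)=1, d(1,3)=1, d(1,4)=3, d(2,3)=2, d(2,4)=2, d(3,4)=2:
    enumeration of all 16 spanning trees gives minimum weight 4."""
    d = [
        [0, 1, 1, 3],
        [1, 0, 2, 2],
        [1, 2, 0, 2],
        [3, 2, 2, 0],
    ]
    haps = _haps([10, 5, 3, 1])
    g = build_mst(haps, d)
    assert g.total_weight() == 4 == _exhaustive_min_weight(d)
    assert len(g.edges) == 3
    # the weight-2 edge to node 3 must touch the highest-count eligible node
    e4 = next(e for e in g.edges if 3 in e[:2])
    assert e4[:2] == (1, 3)  # count 5 beats count 3


def test_mst_star_truth():
    k = 5
    d = [[0] + [1] * k] + [[1] + [2] * k for _ in range(k)]
    for i in range(1, k + 1):
        d[i][i] = 0
    g = build_mst(_haps([9] + [1] * k), d)
    assert g.total_weight() == k
    assert all(0 in e[:2] for e in g.edges)


def test_mst_matches_exhaustive_enumeration(rng):
    for _ in range(25):
        n = int(rng.integers(2, 7))
        m = rng.integers(1, 9, size=(n, n))
        d = ((m + m.T) // 2).tolist()
        for i in range(n):
            d[i][i] = 0
        g = build_mst(_haps(rng.integers(1, 9, size=n).tolist()), d)
        assert g.total_weight() == _exhaustive_min_weight(d)


def test_mst_rejects_bad_matrix():
    with pytest.raises(ValueError):
        build_mst(_haps([1, 1]), [[0, 1], [2, 0]])
    with pytest.raises(ValueError):
        build_mst(_haps([1, 1]), [[1, 1], [1, 0]])
    with pytest.raises(ValueError):
        build_mst([], [])


# --------------------------------------------------------------------- export

def test_graphml_round_trip(tmp_path):
    haps = _haps([5, 3, 2])
    d = [[0, 1, 2], [1, 0, 1], [2, 1, 0]]
    g = build_mst(haps, d)
    path = tmp_path / "t.graphml"
    export_graphml(g, path)
    back = nx.read_graphml(path)
    assert back.number_of_nodes() == 3
    assert back.number_of_edges() == 2
    weights = sorted(a["steps"] for _, _, a in back.edges(data=True))
    assert weights == sorted(w for _, _, w in g.edges)
    totals = sum(a["total"] for _, a in back.nodes(data=True))
    assert totals == sum(h.total for h in haps)


def test_export_empty_graph_is_valid(tmp_path):
    from satellitome.monomer_net import HaplotypeGraph

    g = HaplotypeGraph((), (), True)
    export_graphml(g, tmp_path / "e.graphml")
    export_dot(g, tmp_path / "e.dot")
    assert nx.read_graphml(tmp_path / "e.graphml").number_of_nodes() == 0
    assert "graph haplotypes" in (tmp_path / "e.dot").read_text()


def test_dot_export_single_node(tmp_path):
    g = build_mst(_haps([4]), [[0]])
    p = tmp_path / "t.dot"
    export_dot(g, p)
    text = p.read_text()
    assert "graph haplotypes" in text and "n0" in text


def test_sex_partition_recovery(rng):
    """Female-only haplotypes descending from one W founder stay together in
    the MST, attached to the shared (autosomal) part — in >=90% of 50 seeds."""
    ok = 0
    seeds = 50
    for s in range(seeds):
        r = np.random.default_rng(1000 + s)
        cons = random_monomer(r, 60)

        def mutate(seq, k):
            out = list(seq)
            for p in r.choice(len(seq), size=k, replace=False):
                alt = "ACGT"[r.integers(4)]
                while alt == out[p]:
                    alt = "ACGT"[r.integers(4)]
                out[p] = alt
            return "".join(out)

        shared = [cons] + [mutate(cons, 1) for _ in range(3)]
        founder = mutate(cons, 5)
        w_only = [founder] + [mutate(founder, 1) for _ in range(2)]
        haps = [Haplotype(h, 3, 3) for h in shared] + [Haplotype(h, 3, 0) for h in w_only]
        g = build_mst(haps, distance_matrix(haps, cons))
        nxg = to_networkx(g)
        w_nodes = [i for i, h in enumerate(haps) if h.count_male == 0]
        sub = nxg.subgraph(w_nodes)
        if nx.number_connected_components(sub) == 1:
            ok += 1
    assert ok >= 0.9 * seeds
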