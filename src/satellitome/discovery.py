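"""Iterative satellite discovery from unassembled reads.

The mining loop re-creates, at desk scale, the iterative protocol used for
satellitome characterisation: sample a batch of reads from the female and
male libraries jointly, cluster them by shared k-mer content, test each
cluster's consensus for tandem periodicity, add new monomers to the
catalog, mask catalog-matching reads out of the pool, and repeat — doubling
the sample after the first round and then holding it constant — until a
round yields nothing new. Masking is what lets rare (often W-linked)
families surface in later rounds once the abundant families stop dominating
the clusters.

Cluster-shape triage by eye is replaced by a quantitative self-match
periodicity test (the dotplot criterion made programmatic).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

import edlib

from ._align import revcomp, identity_to_unit, parse_cigar
from ._kmers import canonical_kmers, encode_sequence
from .catalog import circular_identity
from .reads import Read, ReadSet


# ------------------------------------------------------------ quality / sample

def quality_filter_reads(
    reads: ReadSet, window: int = 4, min_mean_q: int = 20, min_len: int = 250
) -> ReadSet:
    """Sliding-window quality trimming with paired-drop semantics.

    Each read is truncated at the start of the first length-``window`` window
    whose mean Phred quality falls below ``min_mean_q``; reads shorter than
    ``min_len`` afterwards are dropped, and a dropped read takes its mate
    (same identifier stem) with it.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    kept: dict[str, list[Read]] = {}
    failed: set[str] = set()
    order: list[str] = []
    for r in reads:
        stem = r.stem
        if stem not in kept and stem not in failed:
            order.append(stem)
        q = np.frombuffer(r.qual.encode("ascii"), dtype=np.uint8).astype(float) - 33
        cut = len(q)
        if len(q) >= window:
            means = np.convolve(q, np.ones(window) / window, mode="valid")
            bad = np.flatnonzero(means < min_mean_q)
            if bad.size:
                cut = int(bad[0])
        elif q.mean() < min_mean_q:
            cut = 0
        if cut < min_len:
            failed.add(stem)
            kept.pop(stem, None)
        elif stem not in failed:
            kept.setdefault(stem, []).append(Read(r.id, r.seq[:cut], r.qual[:cut]))
    out = [r for stem in order if stem in kept for r in kept[stem]]
    return reads.replace(out)


def sample_reads(reads: ReadSet, n: int, seed: int) -> ReadSet:
    """Uniform sample of ``n`` reads without replacement, order-preserving."""
    if n > reads.n_reads:
        raise ValueError(f"cannot sample {n} from {reads.n_reads} reads")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(reads.n_reads, size=n, replace=False))
    return reads.replace([reads.reads[i] for i in idx])


# ------------------------------------------------------------------ clustering

@dataclass(frozen=True)
class ReadCluster:
    member_read_ids: frozenset[str]
    consensus_contig: str
    size: int


def _kmer_matrix(seqs: list[str], k: int) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Binary reads-by-kmers incidence matrix over canonical k-mers."""
    per_read = [canonical_kmers(s, k) for s in seqs]
    counts = np.array([a.size for a in per_read])
    allk = np.concatenate(per_read) if per_read else np.empty(0, dtype=np.int64)
    uniq, inv = np.unique(allk, return_inverse=True)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    data = np.ones(allk.size, dtype=np.int32)
    mat = sparse.csr_matrix((data, inv, indptr), shape=(len(seqs), uniq.size))
    return mat, counts


def cluster_reads(
    reads: ReadSet,
    min_kmer_share: float = 0.2,
    k: int = 13,
    min_cluster_size: int = 5,
) -> list[ReadCluster]:
    """Connected components of the k-mer-sharing read graph.

    Two reads are joined when they share at least ``min_kmer_share`` of the
    smaller read's distinct canonical k-mers; components of at least
    ``min_cluster_size`` reads are reported with a majority-vote consensus
    laid out against the best-connected member (the anchor).
    """
    if reads.n_reads == 0:
        return []
    seqs = [r.seq for r in reads]
    if k > max(len(s) for s in seqs):
        raise ValueError("k exceeds read length")
    mat, counts = _kmer_matrix(seqs, k)
    shared = (mat @ mat.T).tocoo()
    i, j, c = shared.row, shared.col, shared.data
    off = i < j
    i, j, c = i[off], j[off], c[off]
    floor = np.minimum(counts[i], counts[j]) * min_kmer_share
    keep = c >= np.maximum(floor, 1)
    adj = sparse.coo_matrix(
        (np.ones(keep.sum()), (i[keep], j[keep])), shape=(len(seqs), len(seqs))
    )
    n_comp, labels = connected_components(adj, directed=False)
    # connectivity weight per read: total shared kmers over kept edges
    weight = np.zeros(len(seqs))
    np.add.at(weight, i[keep], c[keep])
    np.add.at(weight, j[keep], c[keep])

    clusters: list[ReadCluster] = []
    for lab in range(n_comp):
        members = np.flatnonzero(labels == lab)
        if members.size < min_cluster_size:
            continue
        # anchor on the most repeat-dense member (fewest distinct k-mers: a
        # tandem read of period p carries ~p distinct k-mers, a single-copy
        # read ~read length), so junction reads half in background never
        # anchor the layout; connectivity breaks ties
        order = sorted(members, key=lambda mi: (counts[mi], -weight[mi], mi))
        anchor = order[0]
        consensus = _cluster_consensus(seqs, members, anchor)
        clusters.append(
            ReadCluster(
                frozenset(reads.reads[m].id for m in members),
                consensus,
                int(members.size),
            )
        )
    clusters.sort(key=lambda cl: -cl.size)
    return clusters


def _cluster_consensus(seqs: list[str], members: np.ndarray, anchor: int) -> str:
    """Majority base per anchor column, voted by members aligned to the anchor.

    Each member contributes its central half (so phase-shifted tandem reads
    can land anywhere inside the anchor); columns with no votes keep the
    anchor base. The contig length equals the anchor read length.
    """
    target = seqs[anchor]
    votes = [Counter() for _ in range(len(target))]
    for b, i in zip(target, range(len(target))):
        votes[i][b] += 1
    for m in members:
        if m == anchor:
            continue
        s = seqs[m]
        core = s[len(s) // 4 : len(s) // 4 + max(len(s) // 2, 1)]
        best = None
        for q in (core, revcomp(core)):
            res = edlib.align(q, target, mode="HW", task="path")
            if res["editDistance"] >= 0 and (best is None or res["editDistance"] < best[0]):
                best = (res["editDistance"], q, res)
        if best is None:
            continue
        _, q, res = best
        ti = res["locations"][0][0]
        qi = 0
        for n, op in parse_cigar(res["cigar"]):
            if op in "=XM":
                for _ in range(n):
                    votes[ti][q[qi]] += 1
                    ti += 1
                    qi += 1
            elif op == "I":
                qi += n
            else:
                ti += n
    return "".join(max(sorted(v.items()), key=lambda kv: kv[1])[0] for v in votes)


# ------------------------------------------------------------ tandem detection

@dataclass(frozen=True)
class TandemCall:
    contig: str
    period: int
    match_fraction_at_period: float
    monomer_consensus: str


def detect_tandem_period(contig: str, min_match_fraction: float = 0.7) -> TandemCall | None:
    """Self-match periodicity test: the programmatic dotplot.

    For each lag L up to half the contig, the fraction of positions with
    ``contig[i] == contig[i+L]`` is computed; the smallest qualifying lag
    wins, except that a lag within 10% of it with a strictly higher match
    fraction is preferred (guards against a noise-shortened period). The
    monomer consensus is the majority base over the L-phased columns.
    """
    if len(contig) < 20:
        raise ValueError("contig shorter than 20 nt")
    codes = encode_sequence(contig)
    n = len(codes)
    qualifying: list[tuple[int, float]] = []
    for lag in range(1, n // 2 + 1):
        frac = float(np.mean(codes[:-lag] == codes[lag:]))
        if frac >= min_match_fraction:
            qualifying.append((lag, frac))
    if not qualifying:
        return None
    l0, f0 = qualifying[0]
    best_lag, best_frac = l0, f0
    for lag, frac in qualifying:
        if lag <= l0 * 1.1 and frac > best_frac:
            best_lag, best_frac = lag, frac
    monomer = _phased_consensus(contig, best_lag)
    return TandemCall(contig, best_lag, best_frac, monomer)


def _phased_consensus(contig: str, period: int) -> str:
    out = []
    for j in range(period):
        col = contig[j::period]
        out.append(max(sorted(Counter(col).items()), key=lambda kv: kv[1])[0])
    return "".join(out)


# --------------------------------------------------------------------- masking

def _matches_any(seq: str, catalog: list[str], min_identity: float) -> bool:
    half = len(seq) // 2
    for m in catalog:
        if (
            identity_to_unit(seq, m) >= min_identity
            or identity_to_unit(seq[:half], m) >= min_identity
            or identity_to_unit(seq[half:], m) >= min_identity
        ):
            return True
    return False


def mask_reads(
    reads: ReadSet,
    catalog: list[str],
    min_identity: float = 0.8,
    k: int = 13,
    kmer_cache: dict[str, np.ndarray] | None = None,
) -> ReadSet:
    """Remove reads matching any catalog monomer; return the survivors.

    A read is masked when the full read or either half aligns to a tandem
    tiling of a monomer (either strand) at ``min_identity``; a sorted
    canonical-k-mer index over the catalog prescreens reads so background
    reads are rejected without alignment. ``kmer_cache`` (read id -> sorted
    canonical k-mers) avoids re-encoding reads across masking rounds.
    """
    if not catalog:
        return reads.replace(list(reads))
    cat_kmers = np.unique(
        np.concatenate([canonical_kmers(m + m, k) for m in catalog])
    )
    survivors = []
    for r in reads:
        if kmer_cache is not None:
            rk = kmer_cache.get(r.id)
            if rk is None:
                rk = kmer_cache[r.id] = canonical_kmers(r.seq, k)
        else:
            rk = canonical_kmers(r.seq, k)
        hit = False
        if rk.size and cat_kmers.size:
            idx = np.clip(np.searchsorted(cat_kmers, rk), 0, cat_kmers.size - 1)
            if np.any(cat_kmers[idx] == rk):
                hit = _matches_any(r.seq, catalog, min_identity)
        if not hit:
            survivors.append(r)
    return reads.replace(survivors)


# ------------------------------------------------------------------- main loop

@dataclass(frozen=True)
class DiscoveredMonomer:
    monomer: str
    period: int
    match_fraction: float
    round_found: int
    cluster_size: int


@dataclass
class DiscoveryLog:
    rounds: list[dict] = field(default_factory=list)


def run_discovery_loop(
    female: ReadSet,
    male: ReadSet,
    round0_n: int,
    max_rounds: int = 8,
    seed: int = 0,
    k: int = 13,
    min_kmer_share: float = 0.2,
    min_cluster_size: int = 5,
    min_match_fraction: float = 0.7,
    mask_min_identity: float = 0.8,
    new_monomer_max_identity: float = 0.8,
    log: DiscoveryLog | None = None,
) -> list[DiscoveredMonomer]:
    """Sample -> cluster -> tandem-call -> mask, iterated to convergence.

    Round 1 samples ``round0_n`` reads per library; round 2 doubles that and
    later rounds keep the doubled size. A monomer is new when its circular
    identity to every catalog entry is below ``new_monomer_max_identity``.
    The loop stops when a round adds nothing or after ``max_rounds``.
    """
    if round0_n > min(female.n_reads, male.n_reads):
        raise ValueError("round0_n exceeds a library size")
    pool_f, pool_m = female, male
    kmer_cache: dict[str, np.ndarray] = {}
    found: list[DiscoveredMonomer] = []
    n = round0_n
    for rnd in range(1, max_rounds + 1):
        sf = sample_reads(pool_f, min(n, pool_f.n_reads), seed * 1000 + 2 * rnd)
        sm = sample_reads(pool_m, min(n, pool_m.n_reads), seed * 1000 + 2 * rnd + 1)
        joined = ReadSet(list(sf) + list(sm), "joined")
        clusters = cluster_reads(joined, min_kmer_share, k, min_cluster_size)
        new: list[DiscoveredMonomer] = []
        for cl in clusters:
            call = detect_tandem_period(cl.consensus_contig, min_match_fraction)
            if call is None:
                continue
            known = any(
                circular_identity(call.monomer_consensus, d.monomer) >= new_monomer_max_identity
                for d in found + new
            )
            if not known:
                new.append(
                    DiscoveredMonomer(
                        call.monomer_consensus, call.period,
                        call.match_fraction_at_period, rnd, cl.size,
                    )
                )
        if log is not None:
            log.rounds.append(
                {
                    "round": rnd,
                    "sampled_per_library": n,
                    "pool_female": pool_f.n_reads,
                    "pool_male": pool_m.n_reads,
                    "clusters": len(clusters),
                    "new_monomers": len(new),
                }
            )
        if not new:
            break
        found.extend(new)
        # survivors already failed the existing catalog: masking against the
        # round's new monomers alone is equivalent and much cheaper
        new_monomers = [d.monomer for d in new]
        pool_f = mask_reads(pool_f, new_monomers, mask_min_identity, k, kmer_cache)
        pool_m = mask_reads(pool_m, new_monomers, mask_min_identity, k, kmer_cache)
        if rnd == 1:
            n = 2 * round0_n
    return found


def write_monomer_calls(found: list[DiscoveredMonomer], path) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(found, start=1):
            fh.write(
                f">mon{i:03d} round={d.round_found} period={d.period} "
                f"match={d.match_fraction:.3f} cluster_size={d.cluster_size}\n"
                f"{d.monomer}\n"
            )


def write_round_log(log: DiscoveryLog, path) -> None:
    cols = ["round", "sampled_per_library", "pool_female", "pool_male", "clusters", "new_monomers"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in log.rounds:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
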