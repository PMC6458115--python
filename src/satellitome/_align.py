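"""Pairwise alignment primitives shared across the pipeline.

All alignment goes through edlib (banded Myers bit-vector edit distance).
Satellite monomers are circular sequences observed at arbitrary phase and
strand, so every comparison here is made circular-aware by tiling one
partner into a short tandem reference before aligning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

#: purine/pyrimidine classes used to split substitutions into transitions
#: (A<->G, C<->T) and transversions (everything else)
_PURINES = frozenset("AG")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def is_transition(a: str, b: str) -> bool:
    """True when a->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    return (a in _PURINES) == (b in _PURINES)


def tile_to_length(unit: str, min_length: int) -> str:
    """Concatenate head-to-tail copies of *unit* up to at least *min_length*."""
    n = -(-min_length // len(unit))
    return unit * n


@dataclass(frozen=True)
class AlignmentSummary:
    """Column counts of one pairwise alignment (query vs target)."""

    matches: int
    mismatches: int
    transitions: int
    transversions: int
    query_insertions: int
    target_deletions: int
    query_start: int
    query_end: int  # half-open, in query coordinates
    target_start: int
    target_end: int

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.query_insertions + self.target_deletions

    @property
    def aligned_nt(self) -> int:
        """Query nucleotides sitting in match/mismatch columns."""
        return self.matches + self.mismatches

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _walk_columns(query: str, target: str, cigar: str, t0: int):
    """Yield (qpos, tpos, op) per alignment column; qpos/tpos are -1 for gaps."""
    qi, ti = 0, t0
    for n, op in parse_cigar(cigar):
        for _ in range(n):
            if op in "=XM":
                yield qi, ti, op
                qi += 1
                ti += 1
            elif op == "I":  # consumes query only
                yield qi, -1, op
                qi += 1
            else:  # D, consumes target only
                yield -1, ti, op
                ti += 1


def summarize_alignment(
    query: str,
    target: str,
    cigar: str,
    target_start: int,
    trim_ends: bool = False,
    match_score: int = 1,
    penalty: int = 2,
) -> AlignmentSummary:
    """Tally an edlib alignment; optionally trim to the best-scoring segment.

    With ``trim_ends`` the maximal-scoring contiguous run of columns
    (match ``+match_score``, mismatch/gap ``-penalty``) is kept, turning the
    glocal edlib alignment into a local one — the tails of a read that run
    off a satellite array into background score negatively and are clipped.
    """
    cols = list(_walk_columns(query, target, cigar, target_start))
    scores = []
    for qi, ti, op in cols:
        if op in "=M" and qi >= 0 and ti >= 0 and query[qi] == target[ti]:
            scores.append(match_score)
        else:
            scores.append(-penalty)
    lo, hi = 0, len(cols)
    if trim_ends and cols:
        # Kadane: best-scoring contiguous column range
        best, best_lo, best_hi = float("-inf"), 0, 0
        run, run_lo = 0, 0
        for i, s in enumerate(scores):
            if run <= 0:
                run, run_lo = s, i
            else:
                run += s
            if run > best:
                best, best_lo, best_hi = run, run_lo, i + 1
        lo, hi = best_lo, best_hi

    matches = mism = ts = tv = qins = tdel = 0
    q_lo = q_hi = t_lo = t_hi = -1
    for qi, ti, op in cols[lo:hi]:
        if op == "I":
            qins += 1
        elif op == "D":
            tdel += 1
        else:
            qb, tb = query[qi], target[ti]
            if qb == tb:
                matches += 1
            else:
                mism += 1
                if is_transition(qb, tb):
                    ts += 1
                else:
                    tv += 1
        if qi >= 0:
            if q_lo < 0:
                q_lo = qi
            q_hi = qi + 1
        if ti >= 0:
            if t_lo < 0:
                t_lo = ti
            t_hi = ti + 1
    if q_lo < 0:
        q_lo = q_hi = 0
    if t_lo < 0:
        t_lo = t_hi = 0
    return AlignmentSummary(matches, mism, ts, tv, qins, tdel, q_lo, q_hi, t_lo, t_hi)


def glocal_align(query: str, target: str) -> dict:
    """edlib HW alignment (whole query, free target ends) with path."""
    return edlib.align(query, target, mode="HW", task="path")


@dataclass(frozen=True)
class TandemAlignment:
    """Best glocal alignment of an oriented read against a tandem tiling."""

    strand: str  # "+" read as given, "-" its reverse complement
    query: str  # the oriented read
    ref: str  # tandem tiling of the unit
    cigar: str
    target_start: int
    edit_distance: int

    def columns(self):
        return _walk_columns(self.query, self.ref, self.cigar, self.target_start)

    def summary(self, trim_ends: bool = False) -> AlignmentSummary:
        return summarize_alignment(
            self.query, self.ref, self.cigar, self.target_start, trim_ends=trim_ends
        )


def best_tandem_alignment(read: str, unit: str) -> TandemAlignment | None:
    """Align *read* against a tandem tiling of *unit*, best of both strands."""
    ref = tile_to_length(unit, len(read) + 2 * len(unit))
    best = None
    for strand, q in (("+", read), ("-", revcomp(read))):
        res = edlib.align(q, ref, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best.edit_distance:
            best = TandemAlignment(
                strand, q, ref, res["cigar"], res["locations"][0][0], res["editDistance"]
            )
    return best


def align_to_tandem(
    read: str,
    unit: str,
    trim_ends: bool = True,
) -> tuple[AlignmentSummary, str] | None:
    """Best alignment of *read* against a tandem tiling of *unit*, both strands.

    Returns ``(summary, strand)``; coordinates of the summary refer to the
    tandem reference and to the oriented read.
    """
    aln = best_tandem_alignment(read, unit)
    if aln is None:
        return None
    return aln.summary(trim_ends=trim_ends), aln.strand


def identity_to_unit(read: str, unit: str) -> float:
    """Whole-read identity against the closer strand of a tandem tiling.

    Identity is edit-based, ``1 - dist/len(read)``: a read made of monomer
    copies scores near 1 regardless of phase.
    """
    ref = tile_to_length(unit, len(read) + 2 * len(unit))
    d = min(
        edlib.align(read, ref, mode="HW")["editDistance"],
        edlib.align(revcomp(read), ref, mode="HW")["editDistance"],
    )
    return 1.0 - d / len(read)
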