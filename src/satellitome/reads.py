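"""Read-set container and FASTQ input/output.

A :class:`ReadSet` is the unit every stage operates on: an ordered list of
reads plus the library label (``female`` or ``male``) that downstream
comparative statistics key on. Mates carry ``/1``/``/2`` identifier
suffixes; pair-aware operations group reads by the identifier stem.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator


class Read(NamedTuple):
    id: str
    seq: str
    qual: str

    @property
    def stem(self) -> str:
        """Identifier without the mate suffix."""
        rid = self.id
        if len(rid) > 2 and rid[-2] == "/" and rid[-1] in "12":
            return rid[:-2]
        return rid


@dataclass
class ReadSet:
    reads: list[Read]
    library_label: str = ""

    def __post_init__(self) -> None:
        for r in self.reads:
            if not r.seq:
                raise ValueError(f"empty sequence for read {r.id!r}")

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def total_nt(self) -> int:
        return sum(len(r.seq) for r in self.reads)

    def replace(self, reads: Iterable[Read]) -> "ReadSet":
        return ReadSet(list(reads), self.library_label)


def read_fastq(path: str | Path, library_label: str = "") -> ReadSet:
    with open(path) as fh:
        reads = [Read(rid.split()[0], seq, qual) for rid, seq, qual in FastqGeneralIterator(fh)]
    return ReadSet(reads, library_label)


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def write_paired_fastq(reads: ReadSet, path1: str | Path, path2: str | Path) -> None:
    """Split an interleaved read set into /1 and /2 files."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in reads:
            fh = f2 if r.id.endswith("/2") else f1
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")
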