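#!/usr/bin/env python
"""Run the iterative satellite-mining loop on the simulated libraries.

Round one clusters a sample of reads from both sexes jointly; discovered
tandem monomers are masked out of the pool, the sample is doubled once,
and the loop repeats until a round finds nothing new. Expect the abundant
autosomal families in round one and the rare W-linked family, if it is
caught at all, only after masking. Writes discovered monomers and the
per-round log under results/analysis/discover/.
"""

from pathlib import Path

from satellitome.pipeline import PipelineConfig, discover_stage
from satellitome.reads import Read, ReadSet, read_fastq

SIM = Path("results/analysis/sim")
OUT = Path("results/analysis/discover")


def load_library(stem: str, label: str) -> ReadSet:
    a = read_fastq(SIM / f"{stem}_1.fastq", label)
    b = read_fastq(SIM / f"{stem}_2.fastq", label)
    reads = [r for pair in zip(a.reads, b.reads) for r in pair]
    return ReadSet(reads, label)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig.from_yaml(SIM.parent / "config.yaml")
    female = load_library("female", "female")
    male = load_library("male", "male")
    found = discover_stage(cfg, female, male, OUT)
    by_round: dict[int, int] = {}
    for d in found:
        by_round[d.round_found] = by_round.get(d.round_found, 0) + 1
    for rnd in sorted(by_round):
        print(f"round {rnd}: {by_round[rnd]} new monomer(s)")
    print(f"{len(found)} monomers total -> {OUT}/discovered_monomers.fasta")


if __name__ == "__main__":
    main()
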