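#!/usr/bin/env python
"""Build monomer haplotype networks for the top W-candidate families.

Harvests full-length monomers straight from the reads of both libraries,
collapses exact duplicates into haplotypes with per-sex counts, discards
singletons, and writes minimum spanning trees (GraphML + DOT) under
results/analysis/monomer_nets/. On a W-linked family the male count of
every haplotype should be zero; on a shared family, female-only haplotypes
hang off the shared core — the signature of W-restricted diversification.
"""

from pathlib import Path

from satellitome.monomer_net import (
    build_mst,
    collapse_haplotypes,
    distance_matrix,
    export_dot,
    export_graphml,
    harvest_monomers,
    write_haplotype_table,
)
from satellitome.pipeline import PipelineConfig
from satellitome.quantify import read_catalog_fasta

SIM = Path("results/analysis/sim")
QUANT = Path("results/analysis/quantify")
OUT = Path("results/analysis/monomer_nets")


def main() -> None:
    import importlib.util

    spec = importlib.util.spec_from_file_location(
        "discover_driver", Path(__file__).parent / "02_discover.py"
    )
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)

    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig.from_yaml(SIM.parent / "config.yaml")
    female = mod.load_library("female", "female")
    male = mod.load_library("male", "male")
    catalog = {e.family_id: e.consensus for e in read_catalog_fasta(QUANT / "catalog.fasta")}

    # candidate order from the ranked table
    fams = []
    with open(QUANT / "candidates.tsv") as fh:
        next(fh)
        fams = [line.split("\t")[0] for line in fh]

    built = 0
    for fam in fams:
        if built >= cfg.n_mst_families:
            break
        cons = catalog.get(fam)
        if cons is None or len(cons) >= cfg.read_length:
            continue
        monomers = []
        for lib in (female, male):
            monomers.extend(harvest_monomers(lib, cons, fam, cfg.harvest_min_identity))
        haps = collapse_haplotypes(monomers, cfg.drop_singletons)
        if len(haps) < 2:
            continue
        graph = build_mst(haps, distance_matrix(haps, cons))
        stem = OUT / f"mst_{fam}"
        write_haplotype_table(haps, f"{stem}.haplotypes.tsv")
        export_graphml(graph, f"{stem}.graphml")
        export_dot(graph, f"{stem}.dot")
        n_w_only = sum(1 for h in haps if h.count_male == 0)
        print(
            f"{fam}: {len(monomers)} monomers -> {len(haps)} haplotypes "
            f"({n_w_only} female-only), MST weight {graph.total_weight()}"
        )
        built += 1


if __name__ == "__main__":
    main()
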