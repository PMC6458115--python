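#!/usr/bin/env python
"""Catalog the discovered monomers and quantify both libraries against them.

Groups monomers into variants/families/superfamilies (>95/80/40% circular
identity among seeded pairs), names families by decreasing female
abundance, subsamples the libraries to equal size, aligns every read to
the catalog, and writes the abundance table, the female/male/subtractive
repeat landscapes and the ranked W-candidate table under
results/analysis/quantify/. Prints the candidate ranking — the W-linked
families should head it with the absent-in-male flag or a large F/M ratio.
"""

import math
from pathlib import Path

from satellitome.discovery import DiscoveredMonomer
from satellitome.pipeline import PipelineConfig, catalog_quantify_stage

SIM = Path("results/analysis/sim")
DISC = Path("results/analysis/discover")
OUT = Path("results/analysis/quantify")


def load_monomers() -> list[DiscoveredMonomer]:
    found = []
    with open(DISC / "discovered_monomers.fasta") as fh:
        header = None
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                header = line
            elif line:
                kv = dict(p.split("=") for p in header.split()[1:])
                found.append(
                    DiscoveredMonomer(
                        line, int(kv["period"]), float(kv["match"]),
                        int(kv["round"]), int(kv["cluster_size"]),
                    )
                )
    return found


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
    named, records, candidates, _ = catalog_quantify_stage(
        cfg, load_monomers(), female, male, OUT
    )
    print(f"{len(named)} families catalogued; top candidates by F/M ratio:")
    for r in candidates[:10]:
        fm = "absent_in_male" if (r.fm and math.isinf(r.fm)) else f"{r.fm:.2f}"
        print(
            f"  {r.family_id}: F={r.abundance_female:.5%} "
            f"M={r.abundance_male:.5%} F/M={fm}"
        )


if __name__ == "__main__":
    main()
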