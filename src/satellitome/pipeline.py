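"""End-to-end orchestration: simulate -> discover -> catalog -> quantify ->
monomer networks -> report.

A single :class:`PipelineConfig` drives every stage; each stage draws its
seed from the master seed through a fixed counter scheme, so any stage can
be rerun on its own inputs and reproduce the same downstream outputs. The
run manifest records the config, per-stage seeds and SHA-256 checksums of
every artifact, making byte-level reproducibility checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .catalog import SatVariant, assign_names, circular_identity, group_hierarchy
from .catalog import write_catalog_fasta, write_hierarchy_tsv
from .discovery import DiscoveryLog, quality_filter_reads, run_discovery_loop
from .discovery import write_monomer_calls, write_round_log
from .monomer_net import (
    build_mst,
    collapse_haplotypes,
    distance_matrix,
    export_dot,
    export_graphml,
    harvest_monomers,
    write_haplotype_table,
)
from .quantify import (
    CatalogEntry,
    align_to_catalog,
    build_landscape,
    make_records,
    rank_candidates,
    subsample_equal,
    subtract_landscapes,
    write_abundance_table,
    write_landscape_tsv,
)
from .reads import ReadSet
from . import scenarios
from .simdata import (
    GenomePair,
    ReadSimConfig,
    plant_satellites,
    simulate_reads,
    write_libraries,
    write_monomer_fasta,
    write_truth_table,
)

log = logging.getLogger("satellitome")

_STAGES = ("simulate", "discover", "catalog", "quantify", "monomer_net", "report")


@dataclass
class PipelineConfig:
    master_seed: int = 7
    # simulate
    scenario: str = "discovery"  # discovery | quantify | small
    background_length_per_sex: int = 3_000_000
    n_read_pairs: int = 12_000
    read_length: int = 250
    insert_mean: int = 450
    insert_sd: int = 40
    per_base_error_rate: float = 0.001
    # discover
    round0_n: int = 3000
    max_rounds: int = 6
    k: int = 13
    min_kmer_share: float = 0.2
    min_cluster_size: int = 5
    min_match_fraction: float = 0.7
    mask_min_identity: float = 0.8
    # catalog
    variant_threshold: float = 0.95
    family_threshold: float = 0.80
    superfamily_threshold: float = 0.40
    name_prefix: str = "Sim"
    # quantify
    subsample_n: str | int = "min"
    align_min_identity: float = 0.7
    align_min_length: int = 20
    bin_width: float = 1.0
    top_k: int = 31
    w_ratio_threshold: float = 5.0
    # monomer networks
    n_mst_families: int = 2
    drop_singletons: bool = True
    harvest_min_identity: float = 0.8
    version: str = __version__

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed: master * 1009 + stage index (mod 2^31)."""
        return (self.master_seed * 1009 + _STAGES.index(stage)) % (2**31)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    records: list
    candidates: list
    truth_scores: dict | None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_stage(cfg: PipelineConfig, outdir: Path) -> tuple[GenomePair, ReadSet, ReadSet]:
    seed = cfg.stage_seed("simulate")
    builders = {
        "quantify": scenarios.quantify_scenario,
        "discovery": scenarios.discovery_scenario,
        "small": scenarios.small_scenario,
    }
    specs = builders[cfg.scenario](seed, cfg.background_length_per_sex)
    genome = plant_satellites(specs, cfg.background_length_per_sex, seed)
    rcfg = ReadSimConfig(
        read_length=cfg.read_length,
        insert_mean=cfg.insert_mean,
        insert_sd=cfg.insert_sd,
        n_read_pairs=cfg.n_read_pairs,
        per_base_error_rate=cfg.per_base_error_rate,
        seed=seed + 1,
    )
    female, male, _ = simulate_reads(genome, rcfg)
    write_libraries(female, male, outdir)
    write_truth_table(genome, outdir / "truth.tsv")
    write_monomer_fasta(specs, outdir / "planted_monomers.fasta")
    log.info("[simulate] %d read pairs/sex, %d families", cfg.n_read_pairs, len(specs))
    return genome, female, male


def discover_stage(cfg: PipelineConfig, female: ReadSet, male: ReadSet, outdir: Path):
    seed = cfg.stage_seed("discover")
    female = quality_filter_reads(female, min_len=min(cfg.read_length, 250))
    male = quality_filter_reads(male, min_len=min(cfg.read_length, 250))
    dlog = DiscoveryLog()
    found = run_discovery_loop(
        female,
        male,
        round0_n=min(cfg.round0_n, female.n_reads, male.n_reads),
        max_rounds=cfg.max_rounds,
        seed=seed,
        k=cfg.k,
        min_kmer_share=cfg.min_kmer_share,
        min_cluster_size=cfg.min_cluster_size,
        min_match_fraction=cfg.min_match_fraction,
        mask_min_identity=cfg.mask_min_identity,
        log=dlog,
    )
    write_monomer_calls(found, outdir / "discovered_monomers.fasta")
    write_round_log(dlog, outdir / "discovery_rounds.tsv")
    log.info("[discover] %d monomers over %d rounds", len(found), len(dlog.rounds))
    return found


def catalog_quantify_stage(
    cfg: PipelineConfig, found, female: ReadSet, male: ReadSet, outdir: Path
):
    seed = cfg.stage_seed("quantify")
    sub_f, sub_m = subsample_equal(female, male, cfg.subsample_n, seed)
    # provisional alignment against raw monomers to get naming abundances
    provisional = [CatalogEntry(f"prov{i}", d.monomer) for i, d in enumerate(found)]
    hits_f = align_to_catalog(sub_f, provisional, cfg.align_min_identity, cfg.align_min_length, cfg.k)
    hits_m = align_to_catalog(sub_m, provisional, cfg.align_min_identity, cfg.align_min_length, cfg.k)
    ab_f: dict[str, float] = {}
    ab_m: dict[str, float] = {}
    for h in hits_f:
        ab_f[h.family_id] = ab_f.get(h.family_id, 0.0) + h.aligned_nt / sub_f.total_nt()
    for h in hits_m:
        ab_m[h.family_id] = ab_m.get(h.family_id, 0.0) + h.aligned_nt / sub_m.total_nt()
    variants = [
        SatVariant.from_consensus(d.monomer, ab_f.get(f"prov{i}", 0.0), ab_m.get(f"prov{i}", 0.0))
        for i, d in enumerate(found)
    ]
    hierarchy = group_hierarchy(
        variants, cfg.variant_threshold, cfg.family_threshold, cfg.superfamily_threshold
    )
    named = assign_names(list(hierarchy.families), cfg.name_prefix)
    write_catalog_fasta(hierarchy, named, outdir / "catalog.fasta")
    write_hierarchy_tsv(named, hierarchy, outdir / "hierarchy.tsv")

    entries = [
        CatalogEntry(fam.family_id, v.consensus) for fam in named for v in fam.variants
    ]
    hits_f = align_to_catalog(sub_f, entries, cfg.align_min_identity, cfg.align_min_length, cfg.k)
    hits_m = align_to_catalog(sub_m, entries, cfg.align_min_identity, cfg.align_min_length, cfg.k)
    records = make_records(hits_f, hits_m, sub_f, sub_m)
    write_abundance_table(records, outdir / "abundance.tsv")

    landscapes_f, landscapes_m, landscapes_sub = [], [], []
    by_fam = {r.family_id for r in records}
    for fam in sorted(by_fam):
        lf = build_landscape([h for h in hits_f if h.family_id == fam], sub_f, cfg.bin_width, fam)
        lm = build_landscape([h for h in hits_m if h.family_id == fam], sub_m, cfg.bin_width, fam)
        landscapes_f.append(lf)
        landscapes_m.append(lm)
        landscapes_sub.append(subtract_landscapes(lf, lm))
    write_landscape_tsv(landscapes_f, outdir / "landscape_female.tsv")
    write_landscape_tsv(landscapes_m, outdir / "landscape_male.tsv")
    write_landscape_tsv(landscapes_sub, outdir / "landscape_subtractive.tsv")

    candidates = rank_candidates(records, cfg.top_k) if records else []
    write_abundance_table(candidates, outdir / "candidates.tsv")
    log.info("[quantify] %d families, %d candidates", len(records), len(candidates))
    return named, records, candidates, (sub_f, sub_m)


def monomer_net_stage(cfg: PipelineConfig, named, candidates, sub_f, sub_m, outdir: Path):
    by_id = {fam.family_id: fam for fam in named}
    done = 0
    for rec in candidates:
        if done >= cfg.n_mst_families:
            break
        fam = by_id.get(rec.family_id)
        if fam is None or fam.rul >= cfg.read_length:
            continue
        monomers = []
        for lib in (sub_f, sub_m):
            monomers.extend(
                harvest_monomers(
                    lib, fam.representative.consensus, fam.family_id,
                    cfg.harvest_min_identity, cfg.k,
                )
            )
        haps = collapse_haplotypes(monomers, cfg.drop_singletons)
        if len(haps) < 2:
            continue
        d = distance_matrix(haps, fam.representative.consensus)
        graph = build_mst(haps, d)
        stem = outdir / f"mst_{rec.family_id}"
        write_haplotype_table(haps, f"{stem}.haplotypes.tsv")
        export_graphml(graph, f"{stem}.graphml")
        export_dot(graph, f"{stem}.dot")
        done += 1
    log.info("[monomer_net] built %d haplotype networks", done)
    return done


def score_against_truth(
    genome: GenomePair, named, records, w_ratio_threshold: float
) -> dict:
    """Recall/precision of W-linkage calls against the planted truth.

    Catalog families are matched to planted families by best circular
    identity (>= 0.7); a family is called W when its F/M ratio is the
    absent-in-male flag or exceeds the threshold. W recall and precision
    are scored over the matched (i.e. discovered and quantified) families —
    how often the F/M ratio classifies linkage correctly — while
    ``family_recall`` reports separately what fraction of planted families
    the catalog captured at all.
    """
    rec_by_id = {r.family_id: r for r in records}
    truth_linkage = {s.family_id: s.linkage for s in genome.specs}
    matched: dict[str, str] = {}
    for fam in named:
        best, best_id = 0.0, None
        for s in genome.specs:
            ident = circular_identity(fam.representative.consensus, s.monomer)
            if ident > best:
                best, best_id = ident, s.family_id
        if best >= 0.7 and best_id is not None:
            matched[fam.family_id] = best_id
    tp = fp = 0
    called_w_truth: set[str] = set()
    for fam_id, truth_id in matched.items():
        r = rec_by_id.get(fam_id)
        if r is None or r.fm is None:
            continue
        called_w = math.isinf(r.fm) or r.fm > w_ratio_threshold
        if called_w:
            if truth_linkage[truth_id] == "W":
                tp += 1
                called_w_truth.add(truth_id)
            else:
                fp += 1
    w_truth = {f for f, l in truth_linkage.items() if l == "W"} & set(matched.values())
    recall = len(called_w_truth) / len(w_truth) if w_truth else 1.0
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    family_recall = len(set(matched.values())) / len(truth_linkage)
    return {
        "family_recall": family_recall,
        "w_recall": recall,
        "w_precision": precision,
        "n_matched": len(matched),
    }


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> PipelineResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")

    genome, female, male = simulate_stage(cfg, outdir)
    found = discover_stage(cfg, female, male, outdir)
    if not found:
        raise RuntimeError("stage 'discover' produced no monomers")
    named, records, candidates, (sub_f, sub_m) = catalog_quantify_stage(
        cfg, found, female, male, outdir
    )
    monomer_net_stage(cfg, named, candidates, sub_f, sub_m, outdir)
    scores = score_against_truth(genome, named, records, cfg.w_ratio_threshold)
    with open(outdir / "truth_scores.json", "w") as fh:
        json.dump(scores, fh, indent=2)

    manifest = {
        "version": cfg.version,
        "config": dataclasses.asdict(cfg),
        "stage_seeds": {s: cfg.stage_seed(s) for s in _STAGES},
        "checksums": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(outdir, manifest, records, candidates, scores)
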