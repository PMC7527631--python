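"""Stage orchestration: simulate -> qc -> kinship/structure -> ld -> gwas ->
multiqtl -> cross-location regions, each stage writing its table plus a log
entry with parameter provenance.  Deterministic given (config, seed)."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import crossloc, gwas, io, ld, multiqtl, qc, simulate, structure
from .config import RunConfig
from .io import FLOAT_FMT
from .types import MarkerPanel

log = logging.getLogger("scafqtl")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _log_stage(config: RunConfig, stage: str, params: dict) -> None:
    entry = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), "params": params}
    with open(config.path("run_log.jsonl"), "a") as fh:
        fh.write(json.dumps(entry) + "\n")
    log.info("stage %s: %s", stage, params)


def stage_simulate(config: RunConfig) -> tuple[MarkerPanel, pd.DataFrame, simulate.Truth]:
    sim_kwargs = dict(config.simulation)
    traits = sim_kwargs.pop("traits", None)
    if traits is not None:
        sim_kwargs["traits"] = tuple(simulate.TraitConfig(**t) for t in traits)
    sim = simulate.SimulationConfig(seed=config.seed, **sim_kwargs)
    _, subpop = simulate.simulate_subpop_frequencies(sim)
    panel, index, assignment = simulate.simulate_pooled_genotypes(subpop, sim)
    phenotypes, truth = simulate.simulate_phenotypes(panel, sim)
    io.write_panel(panel, config.path("scores.tsv"), config.path("markers.tsv"))
    io.write_scaffold_index(index, config.path("scaffolds.fai"))
    io.write_phenotypes(phenotypes, config.path("phenotypes.csv"))
    io.write_json(truth.to_dict(), config.path("truth.json"))
    pd.Series(assignment, index=panel.accessions, name="subpop").to_csv(
        config.path("subpops.tsv"), sep="\t"
    )
    freq = qc.scores_to_frequency_table(panel)
    io.write_frequency_table(freq, config.path("frequencies.tsv"))
    _log_stage(config, "simulate", {"seed": config.seed, "n_accessions": sim.n_accessions,
                                    "n_markers": sim.n_markers})
    return panel, phenotypes, truth


def stage_qc(config: RunConfig) -> MarkerPanel:
    freq_path = config.frequency_table or config.path("frequencies.tsv")
    table, flagged = io.read_frequency_table(freq_path)
    if not flagged.empty:
        flagged.to_csv(config.path("flagged_rows.tsv"), sep="\t", index=False)
    result = qc.select_markers(table, config.qc)
    io.write_panel(result.panel, config.path("scores.qc.tsv"), config.path("markers.qc.tsv"))
    result.rejections.to_csv(config.path("qc_rejections.tsv"), sep="\t", index=False)
    index = io.read_scaffold_index(config.scaffold_index or config.path("scaffolds.fai"))
    summary = qc.qc_summary(result, index, config.genome_size_bp)
    io.write_json(summary, config.path("qc_summary.json"))
    _log_stage(config, "qc", {"thresholds": vars(config.qc), **{k: v for k, v in summary.items()
                                                                if k != "unplaced_scaffolds"}})
    return result.panel


def _load_panel(config: RunConfig, prefer_qc: bool = True) -> MarkerPanel:
    if config.scores and config.marker_meta:
        return io.read_panel(config.scores, config.marker_meta)
    qc_scores = config.path("scores.qc.tsv")
    if prefer_qc and qc_scores.exists():
        return io.read_panel(qc_scores, config.path("markers.qc.tsv"))
    return io.read_panel(config.path("scores.tsv"), config.path("markers.tsv"))


def stage_structure(config: RunConfig) -> None:
    panel = _load_panel(config)
    kin = structure.vanraden_kinship(panel)
    io.write_kinship(kin.matrix, config.path("kinship.tsv"))
    coords, pct = structure.pcoa(kin)
    coords.to_csv(config.path("pcoa.tsv"), sep="\t", float_format=FLOAT_FMT)
    link = structure.kinship_dendrogram(kin)
    io.write_newick(link, kin.accessions, config.path("dendrogram.nwk"))
    clusters = structure.cut_clusters(link, kin.accessions, config.n_clusters)
    clusters.to_csv(config.path("clusters.tsv"), sep="\t")
    fst = structure.pairwise_fst(panel, clusters)
    fst.to_csv(config.path("fst_pairs.tsv"), sep="\t", index=False, float_format=FLOAT_FMT)
    structure.fst_matrix(fst).to_csv(config.path("fst_matrix.tsv"), sep="\t", float_format=FLOAT_FMT)
    _log_stage(config, "structure", {"n_clusters": config.n_clusters,
                                     "pcoa_pct_first2": [round(float(x), 3) for x in pct[:2]]})


def stage_ld(config: RunConfig) -> float:
    panel = _load_panel(config)
    index = io.read_scaffold_index(config.scaffold_index or config.path("scaffolds.fai"))
    profiles = ld.scaffold_ld_profile(panel, top_n=24, index=index)
    io_table = ld.ld_pairs_table(profiles)
    io_table.to_csv(config.path("ld_pairs.tsv"), sep="\t", index=False, float_format=FLOAT_FMT)
    baseline, threshold = ld.estimate_baseline_r2(profiles)
    io.write_json({"baseline_r2": baseline, "threshold_r2": threshold},
                  config.path("ld_baseline.json"))
    ld.plot_decay(profiles[:1], config.path("ld_decay.png"), threshold_r2=threshold)
    _log_stage(config, "ld", {"n_scaffolds": len(profiles), "baseline_r2": baseline})
    return threshold


def stage_gwas(config: RunConfig) -> dict[tuple[str, str], gwas.ScanResult]:
    panel = _load_panel(config)
    phenotypes = io.read_phenotypes(config.phenotypes or config.path("phenotypes.csv"))
    kin = structure.vanraden_kinship(panel)
    m_eff = gwas.effective_tests(panel)
    scans = {}
    for trait in sorted(phenotypes["trait"].unique()):
        for loc in sorted(phenotypes["location"].unique()):
            y = io.phenotype_vector(phenotypes, trait, loc)
            null = gwas.fit_null_lmm(y, kin)
            scan = gwas.scan_markers(panel, y, null, alpha=config.alpha, m_eff=m_eff,
                                     trait=trait, location=loc)
            scans[(trait, loc)] = scan
            stem = f"scan_{trait}_{loc}"
            scan.table.to_csv(config.path(stem + ".tsv"), sep="\t", index=False,
                              float_format=FLOAT_FMT)
            io.write_json({"trait": trait, "location": loc, "sigma_g2": scan.sigma_g2,
                           "sigma_e2": scan.sigma_e2, "m_eff": scan.m_eff,
                           "threshold_neglog10p": scan.threshold_neglog10p},
                          config.path(stem + ".json"))
    _log_stage(config, "gwas", {"m_eff": m_eff, "alpha": config.alpha,
                                "n_scans": len(scans)})
    return scans


def stage_multiqtl(config: RunConfig, scans=None) -> list:
    panel = _load_panel(config)
    phenotypes = io.read_phenotypes(config.phenotypes or config.path("phenotypes.csv"))
    if scans is None:
        scans = stage_gwas(config)
    models = []
    for (trait, loc), scan in scans.items():
        y = io.phenotype_vector(phenotypes, trait, loc)
        model = multiqtl.forward_select(scan, panel, y, r_collinear=config.r_collinear)
        models.append(model)
    io.write_models(models, config.path("multiqtl_models.json"))
    _log_stage(config, "multiqtl", {"r_collinear": config.r_collinear,
                                    "n_models": len(models),
                                    "total_qtls": sum(m.n_qtls for m in models)})
    return models


def stage_crossloc(config: RunConfig, models=None) -> dict:
    panel = _load_panel(config)
    if models is None:
        models = io.read_models(config.path("multiqtl_models.json"))
    regions_by_trait = {}
    locations = sorted({m.location for m in models})
    for trait in sorted({m.trait for m in models}):
        per_trait = [m for m in models if m.trait == trait]
        if len({m.location for m in per_trait}) < 2:
            continue
        regions_by_trait[trait] = crossloc.match_regions(per_trait, panel,
                                                         r_collinear=config.r_collinear)
    all_regions = [r for rs in regions_by_trait.values() for r in rs]
    io.write_regions(all_regions, config.path("qtl_regions.json"))
    crossloc.regions_table(all_regions, locations).to_csv(
        config.path("qtl_regions.tsv"), sep="\t", index=False
    )
    overlap = crossloc.cross_trait_overlap(regions_by_trait)
    overlap.to_csv(config.path("cross_trait_overlap.tsv"), sep="\t", index=False)
    _log_stage(config, "crossloc", {"n_regions": len(all_regions)})
    return regions_by_trait


STAGES = ("simulate", "qc", "structure", "ld", "gwas", "multiqtl", "crossloc")


def run_pipeline(config: RunConfig) -> None:
    """Run every stage in order; any failure aborts with the stage name."""
    scans = None
    for stage in STAGES:
        try:
            if stage == "simulate":
                if config.frequency_table or config.scores:
                    continue  # real inputs supplied; nothing to simulate
                stage_simulate(config)
            elif stage == "qc":
                stage_qc(config)
            elif stage == "structure":
                stage_structure(config)
            elif stage == "ld":
                stage_ld(config)
            elif stage == "gwas":
                scans = stage_gwas(config)
            elif stage == "multiqtl":
                stage_multiqtl(config, scans)
            elif stage == "crossloc":
                stage_crossloc(config)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(stage, exc) from exc
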