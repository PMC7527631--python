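"""Panel-scale validation experiments.

These routines run the full pipeline on synthetic panels whose parameters
are the package's reference study conditions (see the methods note) and
summarize what matters scientifically: calibration of the null (genomic
inflation, type-I error), power and false-discovery proportion of the
MultiQTL forward selection, cross-location region recovery, realized
differentiation and the LD baseline.  Both the test suite and the
reproduction script build on them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import crossloc, gwas, io, ld, multiqtl, simulate, structure
from .simulate import SimulationConfig, TraitConfig


def default_config(seed: int) -> SimulationConfig:
    """The reference panel: 150 accessions, 5 subpopulations, 5,000 clustered
    markers on 200 scaffolds, 3 locations, one trait with five 12% QTLs at
    broad-sense heritability 0.6 and full cross-location effect correlation."""
    return SimulationConfig(seed=seed)


def simulate_panel(config: SimulationConfig):
    _, sub = simulate.simulate_subpop_frequencies(config)
    panel, index, assignment = simulate.simulate_pooled_genotypes(sub, config)
    phenotypes, truth = simulate.simulate_phenotypes(panel, config)
    return panel, index, assignment, phenotypes, truth


def _models_for(panel, phenotypes, config, trait="T1"):
    kin = structure.vanraden_kinship(panel)
    m_eff = gwas.effective_tests(panel)
    models, scans = [], []
    for loc in config.locations:
        y = io.phenotype_vector(phenotypes, trait, loc)
        null = gwas.fit_null_lmm(y, kin)
        scan = gwas.scan_markers(panel, y, null, m_eff=m_eff, trait=trait, location=loc)
        scans.append(scan)
        models.append(multiqtl.forward_select(scan, panel, y))
    return models, scans, kin, m_eff


def recovery_experiment(seeds, trait: str = "T1") -> dict:
    """QTL recovery over replicate panels.

    Per seed: simulate the reference panel, scan each location, build the
    forward-selection models, and score them against the planted truth.
    Reports the mean detection power and false-discovery proportion, the
    fraction of planted QTLs recovered as cross-location regions, and the
    linking recovery of :func:`crossloc.match_regions` (among QTLs the
    per-location models detected in >= 2 locations, the fraction joined into
    a region).
    """
    powers, fdps, region_rec, linking = [], [], [], []
    for seed in seeds:
        config = default_config(seed)
        panel, _, _, phenotypes, truth = simulate_panel(config)
        models, _, _, _ = _models_for(panel, phenotypes, config, trait)
        rec = simulate.score_recovery(models, truth, panel)
        powers.append(rec["power"])
        fdps.append(rec["fdp"])
        regions = crossloc.match_regions(models, panel)
        X = panel.scores
        causal = truth.causal[trait]
        n_region_hit = 0
        n_multi, n_linked = 0, 0
        for c in causal:
            r = X.corrwith(X[c]).abs()
            in_region = any(
                any(r.get(mid, 0.0) >= 0.3 for mid in reg.markers) for reg in regions
            )
            if in_region:
                n_region_hit += 1
            locs_detected = {
                model.location
                for model in models
                for q in model.qtls
                if any(r.get(mid, 0.0) >= 0.3 for mid in [q.representative, *q.members])
            }
            if len(locs_detected) >= 2:
                n_multi += 1
                if in_region:
                    n_linked += 1
        region_rec.append(n_region_hit / len(causal))
        if n_multi:
            linking.append(n_linked / n_multi)
    return {
        "n_seeds": len(list(seeds)),
        "power": float(np.mean(powers)),
        "fdp": float(np.mean(fdps)),
        "region_recovery_of_planted": float(np.mean(region_rec)),
        "linking_recovery": float(np.mean(linking)) if linking else float("nan"),
        "per_seed_power": powers,
        "per_seed_fdp": fdps,
    }


def null_config(seed: int) -> SimulationConfig:
    """Structured null panel: 120 accessions, 5 subpopulations at FST 0.05,
    1,200 markers, one purely polygenic trait at H2 = 0.9 (the study's trait
    heritabilities run 0.88-0.96)."""
    trait = TraitConfig(name="null", n_qtls=0, qtl_fractions=(), h2=0.9)
    return SimulationConfig(
        seed=seed, n_accessions=120, n_subpops=5, fst_targets=(0.05,),
        n_scaffolds=60, markers_per_scaffold=20, locations=("L1",), traits=(trait,),
    )


def null_inflation_experiment(seeds) -> dict:
    """Genomic inflation with and without kinship correction on structured
    polygenic null panels, plus the Bonferroni-passing marker fraction."""
    lmm_inf, simple_inf, pass_frac = [], [], []
    for seed in seeds:
        config = null_config(seed)
        panel, _, _, phenotypes, _ = simulate_panel(config)
        kin = structure.vanraden_kinship(panel)
        m_eff = gwas.effective_tests(panel)
        y = io.phenotype_vector(phenotypes, "null", "L1")
        null = gwas.fit_null_lmm(y, kin)
        scan = gwas.scan_markers(panel, y, null, m_eff=m_eff)
        simple = gwas.ols_scan(panel.scores, y, m_eff=m_eff)
        lmm_inf.append(gwas.inflation_statistic(scan.table["p"].to_numpy()))
        simple_inf.append(gwas.inflation_statistic(simple.table["p"].to_numpy()))
        pass_frac.append(float(scan.table["pass_threshold"].mean()))
    return {
        "n_sims": len(list(seeds)),
        "lmm_inflation_median": float(np.median(lmm_inf)),
        "simple_inflation_median": float(np.median(simple_inf)),
        "bonferroni_pass_fraction": float(np.mean(pass_frac)),
        "per_sim_lmm": lmm_inf,
        "per_sim_simple": simple_inf,
    }


def collinearity_shape_experiment(seeds, trait: str = "T1") -> dict:
    """Sensitivity of the MultiQTL models to the collinearity threshold.

    Pools QTL counts and explained variances over all per-location models of
    the given panels across the r grid 0.1..0.9, and reports the relative
    change of both over the steady range {0.1, 0.2, 0.3} and the relative
    rise from r = 0.3 to r = 0.9.
    """
    totals: dict[float, list[float]] = {}
    for seed in seeds:
        config = default_config(seed)
        panel, _, _, phenotypes, _ = simulate_panel(config)
        _, scans, kin, m_eff = _models_for(panel, phenotypes, config, trait)
        for scan in scans:
            y = io.phenotype_vector(phenotypes, trait, scan.location)
            table = multiqtl.collinearity_scan(scan, panel, y)
            for _, row in table.iterrows():
                acc = totals.setdefault(round(float(row["r"]), 10), [0.0, 0.0])
                acc[0] += row["n_qtls"]
                acc[1] += row["explained_variance"]
    table = pd.DataFrame(
        [{"r": r, "n_qtls": v[0], "explained_variance": v[1]} for r, v in sorted(totals.items())]
    )
    by_r = table.set_index("r")
    steady = [0.1, 0.2, 0.3]
    n_steady = by_r.loc[steady, "n_qtls"]
    e_steady = by_r.loc[steady, "explained_variance"]
    out = {
        "table": table,
        "n_qtls_steady_change": float((n_steady.max() - n_steady.min()) / n_steady.loc[0.3]),
        "ev_steady_change": float((e_steady.max() - e_steady.min()) / e_steady.loc[0.3]),
        "n_qtls_rise": float((by_r.loc[0.9, "n_qtls"] - by_r.loc[0.3, "n_qtls"]) / by_r.loc[0.3, "n_qtls"]),
        "ev_rise": float(
            (by_r.loc[0.9, "explained_variance"] - by_r.loc[0.3, "explained_variance"])
            / by_r.loc[0.3, "explained_variance"]
        ),
    }
    return out


def panel_descriptives(seed: int) -> dict:
    """Realized differentiation and LD baseline of the reference panel."""
    import itertools

    config = default_config(seed)
    _, sub = simulate.simulate_subpop_frequencies(config)
    panel, index, assignment = simulate.simulate_pooled_genotypes(sub, config)
    pair_fst = [
        structure.fst_from_freqs(sub[[a, b]])[0]
        for a, b in itertools.combinations(range(sub.shape[0]), 2)
    ]
    clusters = pd.Series(assignment, index=panel.accessions)
    fst_pairs = structure.pairwise_fst(panel, clusters)
    profiles = ld.scaffold_ld_profile(panel, top_n=24, index=index)
    baseline, threshold = ld.estimate_baseline_r2(profiles)
    pairs = ld.ld_pairs_table(profiles)
    far = pairs[pairs["distance"] > 100_000]["r2"]
    return {
        "fst_subpop_mean": float(np.mean(pair_fst)),
        "fst_subpop_min": float(np.min(pair_fst)),
        "fst_subpop_max": float(np.max(pair_fst)),
        "fst_panel_min": float(fst_pairs["fst"].min()),
        "fst_panel_max": float(fst_pairs["fst"].max()),
        "ld_baseline_r2": float(baseline),
        "ld_far_median_r2": float(far.median()),
        "recommended_r2_threshold": float(threshold),
        "m_eff": float(gwas.effective_tests(panel)),
    }
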