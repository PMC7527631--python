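"""Synthetic panel generator: grids, drift targets, heritability, recovery scoring."""

import numpy as np
import pandas as pd
import pytest

from scafqtl import simulate, structure
from scafqtl.simulate import SimulationConfig, TraitConfig, Truth
from scafqtl.types import QTL, MultiQTLModel


class TestSubpopFrequencies:
    def test_zero_target_returns_ancestral_exactly(self):
        cfg = SimulationConfig(n_accessions=10, n_subpops=2, fst_targets=(0.0,),
                               n_scaffolds=5, markers_per_scaffold=4, seed=1)
        anc, sub = simulate.simulate_subpop_frequencies(cfg)
        assert np.array_equal(sub[0], anc)
        assert np.array_equal(sub[1], anc)

    def test_realized_fst_matches_target(self):
        cfg = SimulationConfig(n_accessions=10, n_subpops=2, fst_targets=(0.05,),
                               n_scaffolds=600, markers_per_scaffold=20, seed=3)
        _, sub = simulate.simulate_subpop_frequencies(cfg)
        ratio, _ = structure.fst_from_freqs(sub)
        assert ratio == pytest.approx(0.05, abs=0.01)

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_accessions=10, n_subpops=3, n_scaffolds=5,
                               markers_per_scaffold=4, fst_targets=(0.05,), seed=11)
        a1 = simulate.simulate_subpop_frequencies(cfg)
        a2 = simulate.simulate_subpop_frequencies(cfg)
        assert np.array_equal(a1[0], a2[0])
        assert np.array_equal(a1[1], a2[1])

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(fst_targets=(1.0,) * 5).validate()


class TestPooledGenotypes:
    def test_scores_on_pool_grid(self, small_panel, small_config):
        panel, _, _ = small_panel
        denom = 2 * small_config.pool_size
        scaled = panel.values() * denom
        assert np.allclose(scaled, np.round(scaled))

    def test_metadata_matches_marker_ids(self, small_panel):
        panel, index, _ = small_panel
        for mid in panel.markers[:20]:
            scaf, pos = mid.rsplit("_", 1)
            assert panel.meta.at[mid, "scaffold"] == scaf
            assert panel.meta.at[mid, "position"] == int(pos)
            assert scaf in index

    def test_scores_polarized_to_major_allele(self, small_panel):
        panel, _, _ = small_panel
        assert (panel.scores.mean(axis=0) >= 0.5 - 1e-9).all()

    def test_deterministic_given_seed(self, small_config):
        _, sub = simulate.simulate_subpop_frequencies(small_config)
        p1, _, _ = simulate.simulate_pooled_genotypes(sub, small_config)
        p2, _, _ = simulate.simulate_pooled_genotypes(sub, small_config)
        pd.testing.assert_frame_equal(p1.scores, p2.scores)


class TestPhenotypes:
    def _small_cfg(self, trait, seed=1):
        return SimulationConfig(n_accessions=80, n_subpops=2, fst_targets=(0.03,),
                                n_scaffolds=40, markers_per_scaffold=10,
                                locations=("L1", "L2"), traits=(trait,), seed=seed)

    def test_null_trait_is_pure_noise(self):
        trait = TraitConfig(name="null", n_qtls=0, qtl_fractions=(), h2=0.0)
        cfg = self._small_cfg(trait)
        _, sub = simulate.simulate_subpop_frequencies(cfg)
        panel, _, _ = simulate.simulate_pooled_genotypes(sub, cfg)
        phen, truth = simulate.simulate_phenotypes(panel, cfg)
        assert truth.causal["null"] == []
        y = phen[(phen.trait == "null") & (phen.location == "L1")]["value"]
        assert y.std() == pytest.approx(1.0, rel=0.3)

    def test_single_qtl_variance_partition(self):
        # one QTL at 50% variance, H2 = 0.5: R2 of y on the causal score ~ 0.5
        trait = TraitConfig(name="T", n_qtls=1, qtl_fractions=(0.5,), h2=0.5)
        r2s = []
        for seed in range(20):
            cfg = self._small_cfg(trait, seed=seed)
            _, sub = simulate.simulate_subpop_frequencies(cfg)
            panel, _, _ = simulate.simulate_pooled_genotypes(sub, cfg)
            phen, truth = simulate.simulate_phenotypes(panel, cfg)
            causal = truth.causal["T"][0]
            y = phen[(phen.trait == "T") & (phen.location == "L1")].set_index("accession")["value"]
            x = panel.scores[causal].reindex(y.index)
            r2s.append(np.corrcoef(x, y)[0, 1] ** 2)
        assert np.mean(r2s) == pytest.approx(0.5, abs=0.05)

    def test_full_gxe_correlation_gives_identical_effects(self):
        trait = TraitConfig(name="T", n_qtls=2, qtl_fractions=(0.2, 0.2), h2=0.5,
                            gxe_correlation=1.0)
        cfg = self._small_cfg(trait)
        _, sub = simulate.simulate_subpop_frequencies(cfg)
        panel, _, _ = simulate.simulate_pooled_genotypes(sub, cfg)
        _, truth = simulate.simulate_phenotypes(panel, cfg)
        assert truth.effects["T"]["L1"] == truth.effects["T"]["L2"]

    def test_inconsistent_fractions_rejected(self):
        trait = TraitConfig(name="T", n_qtls=2, qtl_fractions=(0.5, 0.4), h2=0.6)
        with pytest.raises(ValueError, match="exceed"):
            trait.validate()

    def test_causal_markers_near_orthogonal(self, small_config, small_panel):
        panel, _, _ = small_panel
        phen, truth = simulate.simulate_phenotypes(panel, small_config)
        causal = truth.causal["T1"]
        sub = panel.scores[causal]
        corr = np.abs(np.corrcoef(sub.to_numpy(), rowvar=False))
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 0.1
        scaffolds = panel.meta.loc[causal, "scaffold"]
        assert scaffolds.nunique() == len(causal)


class TestScoreRecovery:
    def _model(self, trait, loc, reps, panel):
        m = MultiQTLModel(trait=trait, location=loc)
        m.qtls = [QTL(representative=r, members=[], effect=1.0, se=0.1, wald=25.0,
                      p=1e-6, neglog10p=6.0, expl_var=0.2) for r in reps]
        return m

    def test_direct_count_oracle(self, small_panel, small_config):
        panel, _, _ = small_panel
        phen, truth = simulate.simulate_phenotypes(panel, small_config)
        causal = truth.causal["T1"]
        # 3 of 5 causal markers recovered exactly, plus 1 spurious pick that is
        # uncorrelated with every causal marker
        X = panel.scores
        r_to_causal = np.abs(np.corrcoef(X.to_numpy(), rowvar=False))
        causal_idx = [panel.markers.index(c) for c in causal]
        spurious = None
        for j, mid in enumerate(panel.markers):
            if mid in causal:
                continue
            if max(r_to_causal[j, ci] for ci in causal_idx) < 0.3:
                spurious = mid
                break
        model = self._model("T1", "L1", causal[:3] + [spurious], panel)
        rec = simulate.score_recovery([model], truth, panel)
        assert rec["power"] == pytest.approx(0.6)
        assert rec["fdp"] == pytest.approx(0.25)

    def test_representative_equal_causal_is_true_positive(self, small_panel, small_config):
        panel, _, _ = small_panel
        phen, truth = simulate.simulate_phenotypes(panel, small_config)
        causal = truth.causal["T1"]
        model = self._model("T1", "L1", [causal[0]], panel)
        rec = simulate.score_recovery([model], truth, panel)
        assert rec["n_false"] == 0 and rec["n_true"] == 1

    def test_empty_model_reports_zero_detections(self, small_panel, small_config):
        panel, _, _ = small_panel
        phen, truth = simulate.simulate_phenotypes(panel, small_config)
        model = MultiQTLModel(trait="T1", location="L1")
        rec = simulate.score_recovery([model], truth, panel)
        assert rec["n_detected"] == 0
        assert rec["fdp"] == 0.0


class TestTruthRoundTrip:
    def test_json_round_trip(self, small_panel, small_config):
        panel, _, _ = small_panel
        _, truth = simulate.simulate_phenotypes(panel, small_config)
        back = Truth.from_dict(truth.to_dict())
        assert back.causal == truth.causal
        assert back.effects == truth.effects
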