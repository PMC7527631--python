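"""Mixed-model scan: REML, GLS oracle equivalence, effective tests, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scafqtl import gwas, io, simulate, structure
from scafqtl.types import Kinship, MarkerPanel


def _random_panel(rng, n=30, m=100, prefix="s"):
    scores = pd.DataFrame(
        rng.random((n, m)), index=[f"a{i}" for i in range(n)],
        columns=[f"{prefix}{j // 10 + 1}_{j % 10 + 1}" for j in range(m)],
    )
    meta = pd.DataFrame(
        {"marker_id": scores.columns,
         "scaffold": [c.rsplit("_", 1)[0] for c in scores.columns],
         "position": [int(c.rsplit("_", 1)[1]) for c in scores.columns],
         "major_allele": "A", "minor_allele": "C"}
    ).set_index("marker_id")
    return MarkerPanel(scores, meta)


class TestNullModel:
    def test_no_genetic_variance_reduces_to_ols(self, rng):
        n = 40
        K = pd.DataFrame(np.eye(n), index=[f"a{i}" for i in range(n)],
                         columns=[f"a{i}" for i in range(n)])
        y = pd.Series(rng.standard_normal(n), index=K.index)
        null = gwas.fit_null_lmm(y, K)
        # K = I makes sg2 and se2 unidentifiable individually; their sum is
        # the phenotypic variance and the fit flags the boundary
        assert null.sigma_g2 + null.sigma_e2 == pytest.approx(np.var(y, ddof=1), rel=0.1)

    def test_variance_component_recovery(self, rng):
        # known (sg2, se2) = (2, 1); median estimates over replicates near truth
        n, reps = 50, 60
        A = rng.random((n, 120))
        K = A @ A.T / 120
        K = K / np.diag(K).mean()
        labels = [f"a{i}" for i in range(n)]
        Kdf = pd.DataFrame(K, index=labels, columns=labels)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        est_g, est_e = [], []
        for _ in range(reps):
            g = L @ rng.standard_normal(n) * np.sqrt(2.0)
            e = rng.standard_normal(n)
            null = gwas.fit_null_lmm(pd.Series(g + e, index=labels), Kdf)
            est_g.append(null.sigma_g2)
            est_e.append(null.sigma_e2)
        assert np.median(est_g) == pytest.approx(2.0, rel=0.25)
        assert np.median(est_e) == pytest.approx(1.0, rel=0.25)

    def test_optimum_beats_grid(self, rng):
        # REML log-likelihood at the optimizer's delta >= 100-point grid best
        for _ in range(5):
            n = 50
            A = rng.random((n, 80))
            K = A @ A.T / 80
            labels = [f"a{i}" for i in range(n)]
            y = pd.Series(rng.standard_normal(n) + A[:, 0], index=labels)
            null = gwas.fit_null_lmm(y, pd.DataFrame(K, index=labels, columns=labels))
            eig, U = np.linalg.eigh(K)
            eta = U.T @ y.to_numpy()
            ones = U.T @ np.ones(n)
            grid = np.linspace(-12, 12, 100)
            best = max(gwas.reml_loglik(g, np.clip(eig, 0, None), eta, ones) for g in grid)
            assert null.loglik >= best - 1e-9

    def test_non_finite_phenotype_rejected(self, small_kinship):
        y = pd.Series(np.nan, index=small_kinship.accessions)
        with pytest.raises(ValueError):
            gwas.fit_null_lmm(y, small_kinship)


class TestScan:
    def test_identity_kinship_equals_ols_squared_t(self, rng):
        panel = _random_panel(rng)
        y = pd.Series(rng.standard_normal(30), index=panel.accessions)
        scan = gwas.ols_scan(panel.scores, y)
        for mid in panel.markers[:20]:
            x = panel.scores[mid].to_numpy()
            res = stats.linregress(x, y.to_numpy())
            tsq = (res.slope / res.stderr) ** 2
            row = scan.table.set_index("marker_id").loc[mid]
            assert row["wald"] == pytest.approx(tsq, abs=1e-8)
            assert row["p"] == pytest.approx(stats.chi2.sf(tsq, 1), abs=1e-8)

    def test_scan_matches_brute_force_gls(self, rng):
        # fixed variance components: rotated scan == direct GLS on a 30x100 toy
        panel = _random_panel(rng)
        n = 30
        A = rng.random((n, 50))
        K = 0.5 * np.eye(n) + 0.5 * A @ A.T / 50  # well-conditioned
        Kdf = pd.DataFrame(K, index=panel.accessions, columns=panel.accessions)
        g = np.linalg.cholesky(K) @ rng.standard_normal(n)  # heritable trait
        y = pd.Series(np.sqrt(2.0) * g + rng.standard_normal(n), index=panel.accessions)
        null = gwas.fit_null_lmm(y, Kdf)
        assert not null.boundary
        scan = gwas.scan_markers(panel, y, null).table.set_index("marker_id")
        Vmat = K + null.delta * np.eye(n)  # up to the overall scale
        yv = y.to_numpy()
        for mid in panel.markers:
            W = np.column_stack([np.ones(n), panel.scores[mid].to_numpy()])
            ViW = np.linalg.solve(Vmat, W)
            cov = np.linalg.inv(W.T @ ViW)
            beta = cov @ ViW.T @ yv
            resid = yv - W @ beta
            scale = resid @ np.linalg.solve(Vmat, resid) / (n - 2)
            se = np.sqrt(scale * cov[1, 1])
            wald = (beta[1] / se) ** 2
            p = stats.chi2.sf(wald, 1)
            assert scan.loc[mid, "effect"] == pytest.approx(beta[1], abs=1e-8)
            assert scan.loc[mid, "p"] == pytest.approx(p, abs=1e-8)

    def test_perfect_signal_detected(self, rng):
        panel = _random_panel(rng)
        y = pd.Series(3.0 * panel.scores[panel.markers[7]].to_numpy(), index=panel.accessions)
        scan = gwas.ols_scan(panel.scores, y)
        row = scan.table.set_index("marker_id").loc[panel.markers[7]]
        assert row["p"] < 1e-12
        assert row["expl_var"] == pytest.approx(1.0, abs=1e-9)

    def test_permuted_phenotype_gives_uniform_p(self, rng):
        panel = _random_panel(rng, n=150, m=2000)
        y = pd.Series(rng.standard_normal(150), index=panel.accessions)
        y = pd.Series(rng.permutation(y.to_numpy()), index=panel.accessions)
        scan = gwas.ols_scan(panel.scores, y)
        stat = stats.kstest(scan.table["p"], "uniform")
        assert stat.pvalue > 0.01


class TestEffectiveTests:
    def test_orthogonal_markers_give_m(self):
        n = 64
        X = np.linalg.qr(np.random.default_rng(0).standard_normal((n, 10)))[0]
        scores = pd.DataFrame(X, index=[f"a{i}" for i in range(n)],
                              columns=[f"s1_{j + 1}" for j in range(10)])
        meta = pd.DataFrame({"marker_id": scores.columns, "scaffold": "s1",
                             "position": range(1, 11), "major_allele": "A",
                             "minor_allele": "C"}).set_index("marker_id")
        m_eff = gwas.effective_tests(MarkerPanel(scores, meta))
        assert m_eff == pytest.approx(10.0, abs=1e-6)

    def test_duplicated_marker_block_counts_once(self, rng):
        x = rng.random(30)
        scores = pd.DataFrame({f"s1_{j + 1}": x for j in range(10)},
                              index=[f"a{i}" for i in range(30)])
        meta = pd.DataFrame({"marker_id": scores.columns, "scaffold": "s1",
                             "position": range(1, 11), "major_allele": "A",
                             "minor_allele": "C"}).set_index("marker_id")
        assert gwas.effective_tests(MarkerPanel(scores, meta)) == pytest.approx(1.0, abs=1e-8)

    def test_compound_symmetric_block_closed_form(self):
        # 3 markers, pairwise r = 0.5: eigenvalues (2, 0.5, 0.5)
        # Li-Ji: f(2) = 1, f(0.5) = 0.5 -> M_eff = 2
        corr = np.full((3, 3), 0.5)
        np.fill_diagonal(corr, 1.0)
        lam = np.round(np.abs(np.linalg.eigvalsh(corr)), 8)
        m_eff = np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam)))
        assert m_eff == pytest.approx(2.0, abs=1e-9)
        # columns whose sample correlation is exactly compound-symmetric:
        # x_j = sqrt(0.5) e0 + sqrt(0.5) e_j over an exactly orthonormal basis
        rng = np.random.default_rng(1)
        n = 40
        Q, _ = np.linalg.qr(rng.standard_normal((n, 4)) - rng.standard_normal((1, 4)))
        Qc = Q - Q.mean(axis=0)
        Qc, _ = np.linalg.qr(Qc)
        cols = {f"s1_{j + 1}": np.sqrt(0.5) * Qc[:, 0] + np.sqrt(0.5) * Qc[:, j + 1]
                for j in range(3)}
        scores = pd.DataFrame(cols, index=[f"a{i}" for i in range(n)])
        meta = pd.DataFrame({"marker_id": scores.columns, "scaffold": "s1",
                             "position": range(1, 4), "major_allele": "A",
                             "minor_allele": "C"}).set_index("marker_id")
        assert gwas.effective_tests(MarkerPanel(scores, meta)) == pytest.approx(2.0, abs=1e-6)

    def test_threshold_formula(self):
        assert gwas.significance_threshold(0.05, 557) == pytest.approx(4.047, abs=5e-4)
        with pytest.raises(ValueError):
            gwas.significance_threshold(0.0, 10)


class TestDiagnostics:
    def test_structured_polygenic_contrast(self):
        trait = simulate.TraitConfig(name="poly", n_qtls=0, qtl_fractions=(), h2=0.9)
        cfg = simulate.SimulationConfig(
            n_accessions=100, n_subpops=5, fst_targets=(0.05,), n_scaffolds=50,
            markers_per_scaffold=20, locations=("L1",), traits=(trait,), seed=42,
        )
        _, sub = simulate.simulate_subpop_frequencies(cfg)
        panel, _, _ = simulate.simulate_pooled_genotypes(sub, cfg)
        phen, _ = simulate.simulate_phenotypes(panel, cfg)
        kin = structure.vanraden_kinship(panel)
        y = io.phenotype_vector(phen, "poly", "L1")
        diag = gwas.cumulative_p_diagnostic(panel, y, kin, n_sample=1000, seed=1)
        assert diag["simple_inflation"] > 1.2
        assert 0.85 < diag["lmm_inflation"] < 1.15

    def test_fixed_seed_gives_identical_subsample(self, small_panel, small_phenotypes, small_kinship):
        panel, _, _ = small_panel
        phen, _ = small_phenotypes
        y = io.phenotype_vector(phen, "T1", "L1")
        d1 = gwas.cumulative_p_diagnostic(panel, y, small_kinship, n_sample=50, seed=9)
        d2 = gwas.cumulative_p_diagnostic(panel, y, small_kinship, n_sample=50, seed=9)
        assert d1["markers"] == d2["markers"]
        assert np.allclose(d1["lmm_neglog10p"], d2["lmm_neglog10p"], equal_nan=True)
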