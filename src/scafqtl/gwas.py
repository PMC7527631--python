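"""Kinship-corrected single-marker association scans.

Model: y = mu + x a + g + e with g ~ N(0, sg2 K) and e ~ N(0, se2 I); the
marker term is fixed, the genomic relationship K absorbs population
structure.  Variance components are estimated once on the marker-free null
model by REML over the variance ratio delta = se2/sg2 (profiled after an
eigendecomposition of K), and the per-marker tests reuse that ratio
(P3D/EMMAX-style): each marker is fit by generalized least squares in the
rotated space, with the overall variance scale re-estimated from the
per-marker residuals, so that at K = I the Wald statistic reduces exactly to
the classical OLS squared-t.  Significance is assessed against chi2(1); the
genome-wide threshold is Bonferroni on the Li-Ji effective number of
independent tests, computed per scaffold and summed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import Kinship, MarkerPanel

_LOG_DELTA_RANGE = (-12.0, 12.0)
_DELTA_GRID = 256

#: median of chi2(1): reference for the inflation (lambda_GC) statistic
_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class NullModel:
    """REML fit of the marker-free mixed model plus the spectral cache."""

    sigma_g2: float
    sigma_e2: float
    delta: float  # se2 / sg2
    loglik: float
    eigenvalues: np.ndarray  # of K
    rotation: np.ndarray  # U' (eigenvectors transposed)
    accessions: list[str]
    boundary: bool = False  # sigma_g2 pinned at ~0

    @property
    def heritability(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


@dataclass
class ScanResult:
    table: pd.DataFrame  # per-marker statistics
    trait: str
    location: str
    sigma_g2: float
    sigma_e2: float
    threshold_neglog10p: float
    m_eff: float
    alpha: float

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["pass_threshold"]]


def reml_loglik(log_delta: float, eigvals: np.ndarray, eta: np.ndarray, xtvx_terms: np.ndarray) -> float:
    """Restricted log-likelihood of the null model at a given log variance ratio.

    ``eta`` are the rotated phenotype residual components and ``xtvx_terms``
    the rotated intercept components (U'1); constants independent of delta
    are dropped.
    """
    delta = math.exp(log_delta)
    w = 1.0 / (eigvals + delta)
    n = len(eigvals)
    q = 1  # intercept only
    xtvx = float(np.sum(xtvx_terms**2 * w))
    xtvy = float(np.sum(xtvx_terms * eta * w))
    ytvy = float(np.sum(eta**2 * w))
    rss = ytvy - xtvy**2 / xtvx
    if rss <= 0:
        return -np.inf
    sg2 = rss / (n - q)
    ll = -0.5 * (
        (n - q) * (math.log(2.0 * math.pi * sg2) + 1.0)
        + float(np.sum(np.log(eigvals + delta)))
        + math.log(xtvx)
    )
    return ll


def fit_null_lmm(y: pd.Series, kinship: Kinship | pd.DataFrame) -> NullModel:
    """REML variance components via eigendecomposition of K and a 1-D search
    over the ratio delta = se2/sg2 (dense grid + local refinement)."""
    mat = kinship.matrix if isinstance(kinship, Kinship) else kinship
    y = y.reindex(mat.index)
    if y.isna().any():
        missing = list(y.index[y.isna()])[:5]
        raise ValueError(f"phenotype missing or non-finite for accessions {missing}")
    yv = y.to_numpy(dtype=float)
    if not np.isfinite(yv).all():
        raise ValueError("non-finite phenotype values")
    K = mat.to_numpy(dtype=float)
    eigvals, U = np.linalg.eigh((K + K.T) / 2.0)
    eigvals = np.clip(eigvals, 0.0, None)
    Ut = U.T
    eta = Ut @ yv
    ones = Ut @ np.ones(len(yv))

    grid = np.linspace(*_LOG_DELTA_RANGE, _DELTA_GRID)
    lls = np.array([reml_loglik(g, eigvals, eta, ones) for g in grid])
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -reml_loglik(g, eigvals, eta, ones), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    log_delta = float(res.x) if -res.fun >= lls[best] else float(grid[best])
    delta = math.exp(log_delta)

    n, q = len(yv), 1
    w = 1.0 / (eigvals + delta)
    xtvx = float(np.sum(ones**2 * w))
    xtvy = float(np.sum(ones * eta * w))
    ytvy = float(np.sum(eta**2 * w))
    sg2 = (ytvy - xtvy**2 / xtvx) / (n - q)
    se2 = sg2 * delta
    boundary = log_delta >= _LOG_DELTA_RANGE[1] - 1e-6
    if boundary:
        # variance ratio pinned at the upper bound: effectively no genetic variance
        total = sg2 * (1.0 + delta)  # sg2*K + se2*I ~ total * I when sg2 -> 0
        sg2, se2 = 0.0, total
    return NullModel(
        sigma_g2=float(sg2),
        sigma_e2=float(se2),
        delta=float(delta),
        loglik=float(reml_loglik(log_delta, eigvals, eta, ones)),
        eigenvalues=eigvals,
        rotation=Ut,
        accessions=list(mat.index),
        boundary=boundary,
    )


def _rotated_weights(null: NullModel) -> np.ndarray:
    if null.boundary:
        return np.ones_like(null.eigenvalues)
    return 1.0 / (null.eigenvalues + null.delta)


def scan_markers(
    panel: MarkerPanel | pd.DataFrame,
    y: pd.Series,
    null: NullModel,
    alpha: float = 0.05,
    m_eff: float | None = None,
    trait: str = "trait",
    location: str = "loc",
) -> ScanResult:
    """Per-marker GLS scan at the null model's variance ratio.

    For each marker, the rotated weighted regression of y on [1, x] gives the
    effect estimate and its standard error; the overall variance scale is
    re-estimated per marker from the weighted residuals (df = n - 2), so the
    Wald statistic (effect/se)^2 equals the squared t of the corresponding
    exact GLS fit.  p-values come from chi2(1).  The per-marker explained
    variance is the squared correlation between the marker scores and the
    phenotype.
    """
    scores = panel.scores if isinstance(panel, MarkerPanel) else panel
    meta = panel.meta if isinstance(panel, MarkerPanel) else None
    y = y.reindex(scores.index)
    if y.isna().any():
        raise ValueError("phenotype not aligned to score accessions")
    yv = y.to_numpy(dtype=float)
    X = scores.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing scores in scan input")
    n, m = X.shape
    w = _rotated_weights(null)
    Ut = null.rotation
    ys = Ut @ yv
    ones = Ut @ np.ones(n)
    Xs = Ut @ X

    const = X.std(axis=0) == 0
    a11 = float(np.sum(w * ones**2))
    a12 = (w * ones) @ Xs
    a22 = w @ (Xs**2)
    b1 = float(np.sum(w * ones * ys))
    b2 = (w * ys) @ Xs
    det = a11 * a22 - a12**2
    det = np.where(det <= 0, np.nan, det)
    alpha_hat = (a11 * b2 - a12 * b1) / det
    mu_hat = (a22 * b1 - a12 * b2) / det
    ytwy = float(np.sum(w * ys**2))
    rss = ytwy - (mu_hat * b1 + alpha_hat * b2)
    rss = np.clip(rss, 0.0, None)
    dof = n - 2
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * a11 / det)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = (alpha_hat / se) ** 2
    pvals = stats.chi2.sf(wald, 1)
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
    neglog = -np.log10(pvals)

    sy = yv.std()
    with np.errstate(divide="ignore", invalid="ignore"):
        xc = X - X.mean(axis=0)
        yc = yv - yv.mean()
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        expl = ((xc.T @ yc) / denom) ** 2 if sy > 0 else np.zeros(m)

    if m_eff is None:
        m_eff = float(m)
    threshold = -math.log10(alpha / m_eff)

    table = pd.DataFrame(
        {
            "marker_id": scores.columns,
            "effect": alpha_hat,
            "se": se,
            "wald": wald,
            "p": pvals,
            "neglog10p": neglog,
            "expl_var": expl,
            "pass_threshold": neglog >= threshold,
        }
    )
    if meta is not None:
        table.insert(1, "scaffold", meta["scaffold"].to_numpy())
        table.insert(2, "position", meta["position"].to_numpy())
    if const.any():
        table.loc[const, ["effect", "se", "wald", "p", "neglog10p", "expl_var"]] = np.nan
        table.loc[const, "pass_threshold"] = False
    return ScanResult(
        table=table,
        trait=trait,
        location=location,
        sigma_g2=null.sigma_g2,
        sigma_e2=null.sigma_e2,
        threshold_neglog10p=threshold,
        m_eff=float(m_eff),
        alpha=alpha,
    )


def ols_scan(scores: pd.DataFrame, y: pd.Series, **kw) -> ScanResult:
    """Simple per-marker regression without kinship correction (K = I path)."""
    n = len(scores)
    ident = Kinship(matrix=pd.DataFrame(np.eye(n), index=scores.index, columns=scores.index), method="identity")
    null = NullModel(
        sigma_g2=0.0,
        sigma_e2=float(np.var(y.to_numpy(), ddof=1)),
        delta=float("inf"),
        loglik=float("nan"),
        eigenvalues=np.ones(n),
        rotation=np.eye(n),
        accessions=list(scores.index),
        boundary=True,
    )
    return scan_markers(scores, y, null, **kw)


def effective_tests(panel: MarkerPanel, block: str = "scaffold") -> float:
    """Li-Ji effective number of independent tests, per block, summed.

    Each block's correlation-matrix eigenvalues lambda contribute
    f(lambda) = 1{lambda >= 1} + (lambda - floor(lambda)); a single-marker
    block contributes 1.  Blocks default to scaffolds — the natural linkage
    unit in a fragmented assembly.
    """
    meta = panel.meta
    total = 0.0
    for _, mids in meta.groupby(block, sort=False).groups.items():
        mids = list(mids)
        if len(mids) == 1:
            total += 1.0
            continue
        sub = panel.scores[mids].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        # round before flooring: the Li-Ji fractional rule is discontinuous at
        # integers and eigenvalues like 2 - 1e-15 must count as 2
        lam = np.round(np.abs(np.linalg.eigvalsh(corr)), 8)
        total += float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    return min(total, float(panel.n_markers))


def significance_threshold(alpha: float, m_eff: float) -> float:
    """Bonferroni threshold on the -log10 p scale."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return -math.log10(alpha / m_eff)


def inflation_statistic(pvals: np.ndarray) -> float:
    """lambda_GC: median observed chi2(1) quantile over the chi2(1) median."""
    pvals = np.asarray(pvals, dtype=float)
    pvals = pvals[np.isfinite(pvals)]
    obs = stats.chi2.isf(np.clip(pvals, 1e-300, 1.0), 1)
    return float(np.median(obs) / _CHI2_MEDIAN)


def cumulative_p_diagnostic(
    panel: MarkerPanel,
    y: pd.Series,
    kinship: Kinship,
    n_sample: int = 3000,
    seed: int = 0,
) -> dict:
    """Observed vs expected -log10 p for the kinship model and the simple
    model on a random marker subset, plus inflation summaries.

    Expected quantiles are uniform order statistics (markers assumed unlinked
    to the causal polymorphisms).
    """
    rng = np.random.default_rng(seed)
    markers = list(panel.markers)
    if len(markers) > n_sample:
        pick = sorted(rng.choice(len(markers), size=n_sample, replace=False))
        sub = panel.subset([markers[i] for i in pick])
    else:
        sub = panel
    null = fit_null_lmm(y, kinship)
    lmm = scan_markers(sub, y, null)
    simple = ols_scan(sub.scores, y)
    m = sub.n_markers
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    return {
        "markers": sub.markers,
        "expected_neglog10p": expected,
        "lmm_neglog10p": np.sort(lmm.table["neglog10p"].to_numpy())[::-1],
        "simple_neglog10p": np.sort(simple.table["neglog10p"].to_numpy())[::-1],
        "lmm_inflation": inflation_statistic(lmm.table["p"].to_numpy()),
        "simple_inflation": inflation_statistic(simple.table["p"].to_numpy()),
    }
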