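"""Forward-selection MultiQTL models over significant markers.

A QTL is a group of significant, mutually collinear markers represented by
the member explaining the most phenotypic variance; a MultiQTL model is the
ordered set of non-collinear representatives.  Selection iterates: pick the
candidate with the largest explained variance conditional on the already
selected representatives, absorb every remaining candidate correlated with
it at |r| >= r_collinear into its group, and repeat.  In the default
conditional mode, selection stops when the best candidate's conditional
association no longer passes the genome-wide threshold; the marginal mode
keeps selecting until candidates are exhausted (used for the
collinearity-threshold sensitivity scan, where the group structure itself is
the quantity of interest).

Model explained variance is the squared correlation between the fitted
values of the ordinary regression on all representatives and the observed
phenotype — an approximation to trait heritability, reported unadjusted and
with a small-sample adjustment.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .gwas import ScanResult
from .ld import DEFAULT_R_COLLINEAR
from .types import QTL, MarkerPanel, MultiQTLModel


def _r2_of_fit(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """R^2 (squared correlation of fitted vs observed) of y ~ [1, X]."""
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    if fitted.std() == 0 or y.std() == 0:
        return 0.0, fitted
    r = np.corrcoef(fitted, y)[0, 1]
    return float(r * r), fitted


def model_explained_variance(scores: pd.DataFrame, representatives: list[str], y: pd.Series) -> float:
    """Independent-fit R^2 of the representative-marker design (refit check)."""
    if not representatives:
        return 0.0
    r2, _ = _r2_of_fit(scores[representatives].to_numpy(dtype=float), y.to_numpy(dtype=float))
    return r2


def forward_select(
    scan: ScanResult,
    panel: MarkerPanel | pd.DataFrame,
    y: pd.Series,
    r_collinear: float = DEFAULT_R_COLLINEAR,
    mode: str = "conditional",
    max_qtls: int | None = None,
) -> MultiQTLModel:
    """Build the MultiQTL model for one trait x location scan.

    ``mode='conditional'`` (default) requires each new representative to
    remain significant at the scan's genome-wide threshold given those
    already selected; ``mode='marginal'`` orders candidates by conditional
    explained variance but never stops early.  Ties are broken by smaller
    marginal p, then lexicographic marker id.
    """
    if mode not in ("conditional", "marginal"):
        raise ValueError(f"unknown mode {mode!r}")
    scores = panel.scores if isinstance(panel, MarkerPanel) else panel
    y = y.reindex(scores.index)
    yv = y.to_numpy(dtype=float)
    sig = scan.significant()
    model = MultiQTLModel(
        trait=scan.trait,
        location=scan.location,
        threshold_neglog10p=scan.threshold_neglog10p,
        r_collinear=r_collinear,
        n_significant=int(len(sig)),
    )
    if sig.empty:
        return model

    cand_ids = list(sig["marker_id"])
    stats_by_id = sig.set_index("marker_id")
    Xc = scores[cand_ids].to_numpy(dtype=float)
    Xc_centered = Xc - Xc.mean(axis=0)
    yc = yv - yv.mean()
    n = len(yv)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.atleast_2d(np.corrcoef(Xc, rowvar=False))

    remaining = np.ones(len(cand_ids), dtype=bool)
    selected: list[int] = []
    p_marginal = stats_by_id.loc[cand_ids, "p"].to_numpy(dtype=float)
    alpha_thr = scan.alpha / scan.m_eff

    # residualized working copies for conditional explained variance
    rx = Xc_centered.copy()
    ry = yc.copy()

    while remaining.any():
        if max_qtls is not None and len(selected) >= max_qtls:
            break
        ry_ss = float(ry @ ry)
        if ry_ss <= 0:
            break
        rx_ss = (rx**2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            partial_r2 = np.where(rx_ss > 1e-12, (rx.T @ ry) ** 2 / (rx_ss * ry_ss), 0.0)
        partial_r2[~remaining] = -np.inf
        # conditional explained variance (fraction of total y variance) keeps
        # the same ordering as partial r2 at a fixed step
        best_val = partial_r2[remaining].max()
        ties = np.flatnonzero(remaining & (partial_r2 >= best_val - 1e-12))
        if len(ties) > 1:
            order = sorted(ties, key=lambda i: (p_marginal[i], cand_ids[i]))
            best = order[0]
        else:
            best = int(ties[0])

        if mode == "conditional":
            # t-test of the candidate given selected representatives
            k = len(selected)
            dof = n - k - 2
            pr2 = max(min(partial_r2[best], 1.0 - 1e-15), 0.0)
            if dof <= 0:
                break
            tsq = pr2 / (1.0 - pr2) * dof
            p_cond = float(stats.chi2.sf(tsq, 1))
            if p_cond > alpha_thr:
                break

        selected.append(best)
        members = np.flatnonzero(remaining & (np.abs(corr[best]) >= r_collinear))
        remaining[members] = False
        remaining[best] = False

        # update residuals: project out the chosen column
        xb = rx[:, best].copy()
        xb_ss = float(xb @ xb)
        if xb_ss > 1e-12:
            ry = ry - xb * float(xb @ ry) / xb_ss
            rx = rx - np.outer(xb, (xb @ rx) / xb_ss)

        rep_id = cand_ids[best]
        row = stats_by_id.loc[rep_id]
        model.qtls.append(
            QTL(
                representative=rep_id,
                members=[cand_ids[i] for i in members if i != best],
                effect=float(row["effect"]),
                se=float(row["se"]),
                wald=float(row["wald"]),
                p=float(row["p"]),
                neglog10p=float(row["neglog10p"]),
                expl_var=float(row["expl_var"]),
            )
        )
        reps = [cand_ids[i] for i in selected]
        model.cumulative_explained.append(model_explained_variance(scores, reps, y))

    model.n_unassigned = int(remaining.sum())
    reps = [cand_ids[i] for i in selected]
    model.explained_variance = model_explained_variance(scores, reps, y)
    k = len(reps)
    if n - k - 1 > 0 and k > 0:
        model.adj_explained_variance = 1.0 - (1.0 - model.explained_variance) * (n - 1) / (n - k - 1)
    return model


def collinearity_scan(
    scan: ScanResult,
    panel: MarkerPanel | pd.DataFrame,
    y: pd.Series,
    r_grid=None,
) -> pd.DataFrame:
    """QTL count and model explained variance as the collinearity threshold
    varies (sensitivity check for the |r| >= 0.3 convention).

    Uses the marginal selection mode so the group structure — not the
    conditional stop rule — drives the counts: at r = 1 every significant
    marker becomes its own QTL; at r = 0 a single QTL holds them all.
    """
    if r_grid is None:
        r_grid = np.round(np.arange(0.1, 1.0, 0.1), 10)
    rows = []
    for r in r_grid:
        model = forward_select(scan, panel, y, r_collinear=float(r), mode="marginal")
        rows.append(
            {"r": float(r), "n_qtls": model.n_qtls, "explained_variance": model.explained_variance}
        )
    return pd.DataFrame(rows)


def significant_marker_pca(
    panel: MarkerPanel | pd.DataFrame,
    marker_info: pd.DataFrame,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of significant-marker allele-frequency profiles.

    ``marker_info`` has one row per significant marker with columns
    ``marker_id, neglog10p, location`` (the union over locations).  Markers
    are the observations, accession frequencies the variables.  Returns a
    frame with PC1, PC2, -log10 p and location per marker, plus the percent
    variance of all components.
    """
    scores = panel.scores if isinstance(panel, MarkerPanel) else panel
    mids = list(marker_info["marker_id"])
    if len(set(mids)) < 2:
        raise ValueError("PCA needs at least 2 distinct significant markers")
    profiles = scores[list(dict.fromkeys(mids))].to_numpy(dtype=float).T  # markers x accessions
    n_comp = min(profiles.shape[0], profiles.shape[1], 10)
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(profiles - profiles.mean(axis=0, keepdims=True))
    pct = 100.0 * pca.explained_variance_ratio_
    by_marker = pd.DataFrame(
        coords[:, :2], index=list(dict.fromkeys(mids)), columns=["PC1", "PC2"]
    )
    out = marker_info.copy()
    out["PC1"] = by_marker.loc[out["marker_id"], "PC1"].to_numpy()
    out["PC2"] = by_marker.loc[out["marker_id"], "PC2"].to_numpy()
    return out, pct
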