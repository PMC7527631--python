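"""Pairwise marker correlation, within-scaffold LD decay, collinearity threshold.

With a fragmented draft assembly, QTL boundaries cannot be mapped directly;
instead, squared allele-frequency correlations (r2) between markers on the
same scaffold are profiled against physical distance.  The long-distance
floor of r2 — rather than a recombination map — calibrates the threshold
used to call two markers collinear.  Score columns are polarized by the
panel major allele, so negative correlations are physically meaningful
linkage: collinearity is decided on |r| (equivalently r2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MarkerPanel

DEFAULT_R_COLLINEAR = 0.3  # |r| >= 0.3, i.e. r2 >= 0.09 (~0.1)


@dataclass
class LDProfile:
    scaffold: str
    pairs: pd.DataFrame  # columns id_a, id_b, distance, r2

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def marker_r2(panel: MarkerPanel | pd.DataFrame, a: str, b: str) -> float:
    """Squared Pearson correlation of two score columns across accessions."""
    scores = panel.scores if isinstance(panel, MarkerPanel) else panel
    x = scores[a].to_numpy(dtype=float)
    y = scores[b].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 accessions")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def correlation_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation (signed) of score columns."""
    r = np.corrcoef(scores.to_numpy(dtype=float), rowvar=False)
    r = np.atleast_2d(r)
    return pd.DataFrame(r, index=scores.columns, columns=scores.columns)


def scaffold_ld_profile(
    panel: MarkerPanel,
    scaffolds: list[str] | None = None,
    top_n: int | None = None,
    index=None,
) -> list[LDProfile]:
    """All within-scaffold marker pairs with distance = |pos_a - pos_b| and r2.

    Scaffolds may be given explicitly, or selected as the ``top_n`` longest
    (by scaffold index length when available, else by marker span).  Scaffolds
    with fewer than 2 markers are skipped.
    """
    meta = panel.meta
    if scaffolds is None:
        sizes = {}
        for scaf, grp in meta.groupby("scaffold"):
            if index is not None and scaf in index:
                sizes[scaf] = index.length(scaf)
            else:
                sizes[scaf] = int(grp["position"].max() - grp["position"].min())
        scaffolds = sorted(sizes, key=lambda s: (-sizes[s], s))
        if top_n is not None:
            scaffolds = scaffolds[:top_n]
    profiles = []
    for scaf in scaffolds:
        mids = meta.index[meta["scaffold"] == scaf]
        if len(mids) < 2:
            continue
        sub = panel.scores[list(mids)].to_numpy(dtype=float)
        pos = meta.loc[mids, "position"].to_numpy(dtype=int)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(sub, rowvar=False)
        iu, ju = np.triu_indices(len(mids), k=1)
        pairs = pd.DataFrame(
            {
                "id_a": np.asarray(mids)[iu],
                "id_b": np.asarray(mids)[ju],
                "distance": np.abs(pos[iu] - pos[ju]),
                "r2": r[iu, ju] ** 2,
            }
        )
        # zero-variance columns (pre-QC monomorphic markers) have undefined
        # correlation: those pairs are reported as missing and dropped here
        pairs = pairs.dropna(subset=["r2"]).reset_index(drop=True)
        profiles.append(LDProfile(scaffold=scaf, pairs=pairs))
    return profiles


def binned_decay(profile: LDProfile, n_bins: int = 12) -> pd.DataFrame:
    """Median r2 in log-spaced distance bins (distance-0 pairs go to the
    first bin); for Fig-style decay reporting."""
    pairs = profile.pairs
    d = pairs["distance"].to_numpy(dtype=float)
    dmax = max(d.max(), 1.0)
    edges = np.unique(np.concatenate([[0.0], np.geomspace(1.0, dmax + 1.0, n_bins)]))
    which = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = which == b
        if mask.any():
            rows.append(
                {"bin_lo": edges[b], "bin_hi": edges[b + 1],
                 "median_r2": float(np.median(pairs["r2"].to_numpy()[mask])),
                 "n_pairs": int(mask.sum())}
            )
    return pd.DataFrame(rows)


def estimate_baseline_r2(
    profiles: list[LDProfile],
    distal_fraction: float = 0.25,
    floor: float = 0.1,
) -> tuple[float, float]:
    """Long-distance r2 baseline and recommended collinearity threshold.

    Per scaffold, the baseline is the median r2 among the most distal
    ``distal_fraction`` of pairs; the panel baseline averages over scaffolds.
    The recommended threshold (on the r2 scale) is max(baseline, floor).
    Falls back to the configured floor when no distal pairs exist.
    """
    if not profiles:
        raise ValueError("need at least one LD profile")
    per_scaffold = []
    for prof in profiles:
        pairs = prof.pairs
        if pairs.empty:
            continue
        n_distal = max(1, int(round(distal_fraction * len(pairs))))
        distal = pairs.nlargest(n_distal, "distance")
        per_scaffold.append(float(np.median(distal["r2"])))
    if not per_scaffold:
        return floor, floor
    baseline = float(np.mean(per_scaffold))
    return baseline, max(baseline, floor)


def ld_pairs_table(profiles: list[LDProfile]) -> pd.DataFrame:
    """Concatenate profiles into one tidy (scaffold, id_a, id_b, distance, r2) frame."""
    frames = []
    for prof in profiles:
        df = prof.pairs.copy()
        df.insert(0, "scaffold", prof.scaffold)
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["scaffold", "id_a", "id_b", "distance", "r2"]
    )


def plot_decay(profiles: list[LDProfile], path, threshold_r2: float = 0.1) -> None:
    """Fig-style scatter of r2 against distance with the collinearity floor."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for prof in profiles:
        ax.scatter(prof.pairs["distance"], prof.pairs["r2"], s=4, alpha=0.3)
    ax.axhline(threshold_r2, color="red", lw=1)
    ax.set_xlabel("distance (bp)")
    ax.set_ylabel(r"$r^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
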