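"""Population structure: genomic relationship matrix, PCoA, dendrogram, FST.

The relationship matrix follows the VanRaden construction adapted to
pool-frequency "genotypes": with scores in [0, 1] instead of 0/1/2 dosages,
K = Z Z' / s where Z is the column-centered score matrix and
s = sum_j p_j (1 - p_j) with p_j the panel mean score of marker j.

Wright's fixation index between clusters is, per marker,

    FST = ( pbar (1 - pbar) - sum_i c_i p_i (1 - p_i) ) / ( pbar (1 - pbar) )

with p_i the allele frequency in cluster i, c_i its relative size and
pbar = sum_i c_i p_i.  The multi-marker summary is the ratio of sums of
numerators and denominators (Weir-style averaging), which is stable when
individual markers carry little information; per-marker ratios are also
available.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .types import Kinship, MarkerPanel


def vanraden_kinship(panel: MarkerPanel | pd.DataFrame) -> Kinship:
    """Genomic relationship matrix from a QC-passed score matrix."""
    scores = panel.scores if isinstance(panel, MarkerPanel) else panel
    X = scores.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing scores: kinship requires a QC-passed panel")
    p = X.mean(axis=0)
    Z = X - p
    s = float(np.sum(p * (1.0 - p)))
    if s <= 0:
        raise ValueError("all markers are monomorphic; kinship undefined")
    K = Z @ Z.T / s
    mat = pd.DataFrame(K, index=scores.index, columns=scores.index)
    return Kinship(matrix=mat, method="vanraden_freq", column_means=pd.Series(p, index=scores.columns), scale=s)


def pcoa(kinship: Kinship | pd.DataFrame, n_axes: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinate analysis of the kinship matrix.

    Eigendecomposition of the double-centered matrix; axes are ordered by
    eigenvalue and the percent variance of each positive axis is its
    eigenvalue over the sum of positive eigenvalues.
    Returns ``(coordinates, percent_variance)``.
    """
    mat = kinship.matrix if isinstance(kinship, Kinship) else kinship
    K = mat.to_numpy(dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship must be symmetric")
    if np.allclose(K, 0):
        raise ValueError("all-zero kinship")
    n = K.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ K @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(evals.max(), 1.0)
    total = evals[pos].sum()
    n_axes = min(n_axes, int(pos.sum()))
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    pct = 100.0 * evals[:n_axes] / total
    cols = [f"PCo{i + 1}" for i in range(n_axes)]
    return pd.DataFrame(coords, index=mat.index, columns=cols), pct


def kinship_dendrogram(kinship: Kinship | pd.DataFrame, method: str = "average") -> np.ndarray:
    """Hierarchical clustering of accessions on d(i,j) = max(K) - K(i,j),
    the maximum taken over off-diagonal similarities so the most similar pair
    (e.g. duplicated accessions) sits at distance zero.

    Returns the scipy linkage matrix (leaf order = accession order of K).
    """
    mat = kinship.matrix if isinstance(kinship, Kinship) else kinship
    K = mat.to_numpy(dtype=float)
    off = ~np.eye(len(K), dtype=bool)
    D = K[off].max() - K
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    D = (D + D.T) / 2.0  # guard against asymmetric rounding
    return linkage(squareform(D, checks=False), method=method)


def cut_clusters(link: np.ndarray, labels: list[str], k: int) -> pd.Series:
    """Cut a dendrogram into k clusters; returns accession -> cluster id (1..k)."""
    n = len(labels)
    if k > n:
        raise ValueError(f"cannot cut {n} leaves into {k} clusters")
    assign = fcluster(link, t=k, criterion="maxclust")
    return pd.Series(assign, index=labels, name="cluster")


def fst_from_freqs(freqs: np.ndarray, weights: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Wright's FST from cluster allele frequencies.

    ``freqs`` is (n_clusters, n_markers); ``weights`` the relative cluster
    sizes (uniform by default).  Markers monomorphic panel-wide (pbar 0 or 1)
    are skipped.  Returns ``(ratio_of_sums, per_marker)``; per-marker entries
    for skipped markers are NaN.
    """
    freqs = np.asarray(freqs, dtype=float)
    k = freqs.shape[0]
    w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, dtype=float) / np.sum(weights)
    pbar = w @ freqs
    denom = pbar * (1.0 - pbar)
    within = w @ (freqs * (1.0 - freqs))
    numer = denom - within
    keep = denom > 0
    per_marker = np.full(freqs.shape[1], np.nan)
    per_marker[keep] = numer[keep] / denom[keep]
    if not keep.any():
        raise ValueError("all markers monomorphic across clusters")
    ratio = float(numer[keep].sum() / denom[keep].sum())
    return ratio, per_marker


def pairwise_fst(
    panel: MarkerPanel | pd.DataFrame, clusters: pd.Series
) -> pd.DataFrame:
    """Pairwise Eq.-style FST between all cluster pairs of a scored panel.

    Cluster frequencies are mean accession scores; cluster weights are the
    relative cluster sizes within each pair.  Returns a tidy frame with
    columns cluster_a, cluster_b, fst, n_markers.
    """
    scores = panel.scores if isinstance(panel, MarkerPanel) else panel
    clusters = clusters.reindex(scores.index)
    if clusters.isna().any():
        raise ValueError("cluster map missing accessions")
    ids = sorted(clusters.unique())
    if len(ids) < 2:
        raise ValueError("need at least two clusters")
    means = {}
    sizes = {}
    for cid in ids:
        members = clusters.index[clusters == cid]
        if len(members) == 0:
            raise ValueError(f"empty cluster {cid}")
        means[cid] = scores.loc[members].mean(axis=0).to_numpy()
        sizes[cid] = len(members)
    rows = []
    for a, b in itertools.combinations(ids, 2):
        freqs = np.vstack([means[a], means[b]])
        w = np.array([sizes[a], sizes[b]], dtype=float)
        ratio, per_marker = fst_from_freqs(freqs, w)
        rows.append(
            {"cluster_a": a, "cluster_b": b, "fst": ratio,
             "n_markers": int(np.isfinite(per_marker).sum())}
        )
    return pd.DataFrame(rows)


def fst_matrix(pairwise: pd.DataFrame) -> pd.DataFrame:
    """Lower-triangle FST matrix from the tidy pairwise frame."""
    ids = sorted(set(pairwise["cluster_a"]) | set(pairwise["cluster_b"]))
    mat = pd.DataFrame(np.nan, index=ids, columns=ids)
    for _, row in pairwise.iterrows():
        a, b = row["cluster_a"], row["cluster_b"]
        lo, hi = (a, b) if ids.index(a) < ids.index(b) else (b, a)
        mat.loc[hi, lo] = row["fst"]
    return mat
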