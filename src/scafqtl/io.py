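"""Readers and writers for the pipeline's on-disk formats.

Tables are tab-separated with a header row; floats are written with 6
significant digits and round-trip to full printed precision.  The canonical
nucleotide-frequency layout is long format with one row per
(marker, accession):

    marker_id  scaffold  position  accession  A  C  G  T

Scores, kinship, scans and LD pairs are TSV; phenotypes are CSV
(``accession,trait,location,value``); MultiQTL models, QTL regions and
simulation truth are JSON; dendrograms are newick.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import META_COLUMNS, NUCLEOTIDES, MarkerPanel, MultiQTLModel, QTLRegion, ScaffoldIndex

FLOAT_FMT = "%.6g"

FREQ_COLUMNS = ["marker_id", "scaffold", "position", "accession", *NUCLEOTIDES]


class FormatError(ValueError):
    """Raised when a file does not follow the documented layout."""


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# nucleotide frequency tables


def read_frequency_table(path, sum_tol: float = 0.01) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long-format per-accession nucleotide frequency table.

    Returns ``(table, flagged)`` where ``flagged`` lists rows whose four
    frequencies do not sum to 1 within ``sum_tol`` (they are kept in the
    table; downstream QC decides their fate via the call-rate rule).

    Raises :class:`FormatError` on missing columns and ``ValueError`` on
    negative frequencies.
    """
    df = _read_tsv(path)
    return validate_frequency_table(df, sum_tol=sum_tol)


def validate_frequency_table(df: pd.DataFrame, sum_tol: float = 0.01) -> tuple[pd.DataFrame, pd.DataFrame]:
    missing = [c for c in FREQ_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"frequency table lacks columns {missing}")
    df = df[FREQ_COLUMNS].copy()
    freqs = df[list(NUCLEOTIDES)].to_numpy(dtype=float)
    if (freqs < 0).any():
        raise ValueError("negative nucleotide frequency")
    if (freqs > 1 + 1e-9).any():
        raise ValueError("nucleotide frequency above 1")
    total = freqs.sum(axis=1)
    bad = np.abs(total - 1.0) > sum_tol
    flagged = df.loc[bad].copy()
    flagged["freq_sum"] = total[bad]
    dup = df.duplicated(subset=["marker_id", "accession"])
    if dup.any():
        raise ValueError("duplicate (marker, accession) rows in frequency table")
    return df, flagged


def write_frequency_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# score matrices and marker metadata


def write_panel(panel: MarkerPanel, scores_path, meta_path) -> None:
    panel.scores.to_csv(scores_path, sep="\t", index_label="accession", float_format=FLOAT_FMT)
    meta = panel.meta.reset_index()
    meta.columns = META_COLUMNS
    meta.to_csv(meta_path, sep="\t", index=False)


def read_panel(scores_path, meta_path) -> MarkerPanel:
    scores = pd.read_csv(scores_path, sep="\t", index_col="accession").astype(float)
    meta = pd.read_csv(meta_path, sep="\t")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"marker metadata lacks columns {missing}")
    meta = meta.set_index("marker_id")
    return MarkerPanel(scores, meta)


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("accession", "trait", "location", "value") if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype table lacks columns {missing}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def phenotype_vector(phenotypes: pd.DataFrame, trait: str, location: str) -> pd.Series:
    """Accession-mean phenotype for one trait x location (missing cells dropped)."""
    sub = phenotypes[(phenotypes["trait"] == trait) & (phenotypes["location"] == location)]
    vec = sub.groupby("accession")["value"].mean().dropna()
    if vec.empty:
        raise ValueError(f"no phenotype values for trait {trait!r} at {location!r}")
    return vec


# ---------------------------------------------------------------------------
# scaffold index


def read_scaffold_index(path) -> ScaffoldIndex:
    """Read a FAI-style index; only the first two columns (name, length) are used."""
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] < 2:
        raise FormatError("scaffold index needs at least two columns (name, length)")
    lengths = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str), name="length_bp")
    return ScaffoldIndex(lengths)


def write_scaffold_index(index: ScaffoldIndex, path) -> None:
    index.lengths.to_csv(path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# kinship


def write_kinship(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="accession", float_format=FLOAT_FMT)


def read_kinship(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="accession")


# ---------------------------------------------------------------------------
# newick


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a one-line newick string.

    Node heights follow the ultrametric convention used for hclust trees:
    each merge sits at half its linkage distance, so two leaves merged at
    distance 1 get branch lengths 0.5 each.
    """
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels")
    n = len(labels)
    if n == 1:
        return f"{labels[0]};"

    def height(node: int) -> float:
        return 0.0 if node < n else linkage[node - n, 2] / 2.0

    def render(node: int) -> str:
        if node < n:
            return labels[node]
        left, right = int(linkage[node - n, 0]), int(linkage[node - n, 1])
        h = height(node)
        parts = [f"{render(c)}:{h - height(c):.6g}" for c in (left, right)]
        return "(" + ",".join(parts) + ")"

    return render(2 * n - 2) + ";"


def write_newick(linkage: np.ndarray, labels: list[str], path) -> None:
    Path(path).write_text(linkage_to_newick(linkage, labels) + "\n")


# ---------------------------------------------------------------------------
# JSON artifacts


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_models(models: list[MultiQTLModel], path) -> None:
    write_json([m.to_dict() for m in models], path)


def read_models(path) -> list[MultiQTLModel]:
    return [MultiQTLModel.from_dict(d) for d in read_json(path)]


def write_regions(regions: list[QTLRegion], path) -> None:
    write_json([r.to_dict() for r in regions], path)
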