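"""Shared domain containers for the pooled-accession GWAS pipeline.

The panel is genotyped as pools (default 8 diploids, i.e. 16 alleles per
accession), so the per-accession "genotype" at a marker is the frequency of
the panel-wide major allele — a value on the grid {0, 1/16, ..., 1} — rather
than a 0/1/2 dosage.  All positional information lives in draft-assembly
scaffold coordinates (1-based bp); marker ids follow the
``<scaffold>_<position>`` convention, e.g. ``scaffold56299_8302``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NUCLEOTIDES = ("A", "C", "G", "T")

#: column order of the marker metadata table
META_COLUMNS = ["marker_id", "scaffold", "position", "major_allele", "minor_allele"]


def marker_id(scaffold: str, position: int) -> str:
    """Canonical marker name ``<scaffold>_<position>``."""
    return f"{scaffold}_{int(position)}"


def split_marker_id(mid: str) -> tuple[str, int]:
    """Inverse of :func:`marker_id`; splits on the last underscore."""
    scaffold, _, pos = mid.rpartition("_")
    if not scaffold or not pos.isdigit():
        raise ValueError(f"marker id {mid!r} is not of the form <scaffold>_<position>")
    return scaffold, int(pos)


@dataclass
class MarkerPanel:
    """Accession x marker major-allele-proportion matrix plus marker metadata.

    ``scores`` is a DataFrame indexed by accession label with one column per
    marker id; ``meta`` is indexed by marker id with columns
    ``scaffold, position, major_allele, minor_allele``.
    """

    scores: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.scores.columns) != list(self.meta.index):
            # keep meta aligned to score columns; raise when a marker is unknown
            missing = set(self.scores.columns) - set(self.meta.index)
            if missing:
                raise ValueError(f"markers missing from metadata: {sorted(missing)[:5]}")
            self.meta = self.meta.loc[list(self.scores.columns)]
        if not self.meta.index.is_unique:
            raise ValueError("marker ids must be unique panel-wide")
        if (self.meta["position"] < 1).any():
            raise ValueError("positions are 1-based and must be >= 1")

    @property
    def accessions(self) -> list[str]:
        return list(self.scores.index)

    @property
    def markers(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_accessions(self) -> int:
        return self.scores.shape[0]

    @property
    def n_markers(self) -> int:
        return self.scores.shape[1]

    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)

    def subset(self, markers) -> "MarkerPanel":
        markers = list(markers)
        return MarkerPanel(self.scores[markers].copy(), self.meta.loc[markers].copy())


@dataclass
class ScaffoldIndex:
    """FAI-style scaffold -> length (bp) lookup."""

    lengths: pd.Series  # index scaffold, values length_bp

    def __post_init__(self) -> None:
        if not self.lengths.index.is_unique:
            raise ValueError("scaffold names must be unique")
        if (self.lengths <= 0).any():
            raise ValueError("scaffold lengths must be positive")
        self.lengths = self.lengths.astype(int)

    def __contains__(self, scaffold: str) -> bool:
        return scaffold in self.lengths.index

    def length(self, scaffold: str) -> int:
        return int(self.lengths[scaffold])


@dataclass
class Kinship:
    """Genomic relationship matrix over accessions (the K of the mixed model)."""

    matrix: pd.DataFrame
    method: str = "vanraden_freq"
    column_means: pd.Series | None = None
    scale: float = float("nan")

    @property
    def accessions(self) -> list[str]:
        return list(self.matrix.index)

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)


@dataclass
class QTL:
    """One QTL of a MultiQTL model: a collinear group with a representative."""

    representative: str
    members: list[str]
    effect: float
    se: float
    wald: float
    p: float
    neglog10p: float
    expl_var: float


@dataclass
class MultiQTLModel:
    """Forward-selection multi-locus model for one trait x location."""

    trait: str
    location: str
    qtls: list[QTL] = field(default_factory=list)
    explained_variance: float = 0.0
    adj_explained_variance: float = 0.0
    cumulative_explained: list[float] = field(default_factory=list)
    n_significant: int = 0
    n_unassigned: int = 0
    threshold_neglog10p: float = float("nan")
    r_collinear: float = 0.3

    @property
    def n_qtls(self) -> int:
        return len(self.qtls)

    @property
    def representatives(self) -> list[str]:
        return [q.representative for q in self.qtls]

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "location": self.location,
            "n_qtls": self.n_qtls,
            "explained_variance": self.explained_variance,
            "adj_explained_variance": self.adj_explained_variance,
            "cumulative_explained": self.cumulative_explained,
            "n_significant": self.n_significant,
            "n_unassigned": self.n_unassigned,
            "threshold_neglog10p": self.threshold_neglog10p,
            "r_collinear": self.r_collinear,
            "qtls": [
                {
                    "representative": q.representative,
                    "members": q.members,
                    "effect": q.effect,
                    "se": q.se,
                    "wald": q.wald,
                    "p": q.p,
                    "neglog10p": q.neglog10p,
                    "expl_var": q.expl_var,
                }
                for q in self.qtls
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MultiQTLModel":
        model = cls(
            trait=d["trait"],
            location=d["location"],
            explained_variance=d["explained_variance"],
            adj_explained_variance=d.get("adj_explained_variance", float("nan")),
            cumulative_explained=d.get("cumulative_explained", []),
            n_significant=d.get("n_significant", 0),
            n_unassigned=d.get("n_unassigned", 0),
            threshold_neglog10p=d.get("threshold_neglog10p", float("nan")),
            r_collinear=d.get("r_collinear", 0.3),
        )
        model.qtls = [
            QTL(
                representative=q["representative"],
                members=list(q["members"]),
                effect=q["effect"],
                se=q["se"],
                wald=q["wald"],
                p=q["p"],
                neglog10p=q["neglog10p"],
                expl_var=q["expl_var"],
            )
            for q in d["qtls"]
        ]
        return model


@dataclass
class QTLRegion:
    """Cross-location group of correlated representative QTL-markers."""

    region_id: str
    trait: str
    markers_by_location: dict[str, list[str]]
    n_locations: int
    scaffolds: list[str]
    chained: bool = False

    @property
    def markers(self) -> list[str]:
        out: list[str] = []
        for ms in self.markers_by_location.values():
            out.extend(ms)
        return sorted(set(out))

    def to_dict(self) -> dict:
        return {
            "region_id": self.region_id,
            "trait": self.trait,
            "markers_by_location": self.markers_by_location,
            "n_locations": self.n_locations,
            "scaffolds": self.scaffolds,
            "chained": self.chained,
        }
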