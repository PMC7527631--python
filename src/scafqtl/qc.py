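"""Informative-marker selection and major-allele-proportion scoring.

Four rules, applied in order, on per-accession nucleotide frequencies:

1. call rate: every accession must have a call at the marker (100% call rate);
2. frequency bounds: the panel-wide major allele frequency must not exceed
   ``major_max`` (default 0.98) and the second allele's frequency must reach
   ``maf_min`` (default 0.02);
3. biallelic: the two most frequent alleles must jointly account for at least
   ``biallelic_min`` (default 0.95) of the panel frequency mass;
4. variation: the sample standard deviation (ddof=1) of the per-accession
   major-allele frequency must be at least ``sd_min`` (default 0.1).

Survivors are scored per accession as the frequency of the panel-wide major
allele.  The major allele is defined panel-wide; exact frequency ties are
broken lexicographically (A < C < G < T).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import META_COLUMNS, NUCLEOTIDES, MarkerPanel, ScaffoldIndex

RULES = ("call_rate", "maf", "biallelic", "sd")


@dataclass
class QCThresholds:
    maf_min: float = 0.02
    major_max: float = 0.98
    biallelic_min: float = 0.95
    sd_min: float = 0.1
    call_rate_min: float = 1.0

    def __post_init__(self) -> None:
        for name in ("maf_min", "major_max", "biallelic_min", "sd_min", "call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold {name}={v} outside [0, 1]")


@dataclass
class QCResult:
    panel: MarkerPanel
    rejections: pd.DataFrame  # marker_id, rule (first violated)
    rule_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return self.panel.n_markers


def panel_allele_stats(freq_table: pd.DataFrame, n_accessions: int | None = None) -> pd.DataFrame:
    """Per-marker panel allele frequencies (mean over called accessions) and call rate.

    ``n_accessions`` defaults to the number of distinct accessions present in
    the table; pass it explicitly when some accessions are entirely uncalled.
    """
    if freq_table.empty:
        raise ValueError("empty frequency table")
    if n_accessions is None:
        n_accessions = freq_table["accession"].nunique()
    if n_accessions == 0:
        raise ValueError("zero accessions")
    grouped = freq_table.groupby("marker_id", sort=False)
    stats = grouped[list(NUCLEOTIDES)].mean()
    stats["call_rate"] = grouped.size() / n_accessions
    return stats


def _major_minor(panel_freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the two most frequent nucleotides; ties broken A<C<G<T."""
    # argsort is stable, so equal frequencies keep lexicographic nucleotide order
    order = np.argsort(-panel_freqs, axis=1, kind="stable")
    return order[:, 0], order[:, 1]


def select_markers(
    freq_table: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    n_accessions: int | None = None,
) -> QCResult:
    """Apply the four selection rules and score survivors.

    The rejection report records, per rejected marker, the first rule violated
    in the order call_rate, maf, biallelic, sd.
    """
    thr = thresholds or QCThresholds()
    if n_accessions is None:
        n_accessions = freq_table["accession"].nunique()
    stats = panel_allele_stats(freq_table, n_accessions=n_accessions)
    freqs = stats[list(NUCLEOTIDES)].to_numpy(dtype=float)
    major_idx, minor_idx = _major_minor(freqs)
    rows = np.arange(len(stats))
    major_freq = freqs[rows, major_idx]
    minor_freq = freqs[rows, minor_idx]

    rule = pd.Series("", index=stats.index, dtype=object)
    rule[(stats["call_rate"] < thr.call_rate_min).to_numpy()] = "call_rate"
    maf_bad = (minor_freq < thr.maf_min) | (major_freq > thr.major_max)
    rule[(rule == "") & maf_bad] = "maf"
    bi_bad = (major_freq + minor_freq) < thr.biallelic_min
    rule[(rule == "") & bi_bad] = "biallelic"

    # per-accession frequency of the panel-wide major allele (wide pivot)
    marker_order = list(stats.index)
    long = freq_table.set_index(["marker_id", "accession"])[list(NUCLEOTIDES)]
    wide = {
        nuc: long[nuc].unstack("accession")
        for nuc in NUCLEOTIDES
    }
    accessions = sorted(freq_table["accession"].unique())
    major_by_marker = pd.Series([NUCLEOTIDES[i] for i in major_idx], index=stats.index)
    stacked = np.empty((len(accessions), len(marker_order)))
    for nuc in NUCLEOTIDES:
        cols = major_by_marker == nuc
        if cols.any():
            block = wide[nuc].reindex(index=stats.index[cols], columns=accessions)
            stacked[:, cols.to_numpy()] = block.to_numpy().T
    scores_all = pd.DataFrame(stacked, index=accessions, columns=marker_order)

    sd = scores_all.std(axis=0, ddof=1)
    sd_bad = (sd < thr.sd_min) | sd.isna()
    rule[(rule == "") & sd_bad.reindex(stats.index).to_numpy()] = "sd"

    selected = [m for m in marker_order if rule[m] == ""]
    rejections = pd.DataFrame(
        {"marker_id": [m for m in marker_order if rule[m] != ""],
         "rule": [rule[m] for m in marker_order if rule[m] != ""]}
    )
    rule_counts = {r: int((rejections["rule"] == r).sum()) for r in RULES}

    coords = (
        freq_table.drop_duplicates("marker_id").set_index("marker_id")[["scaffold", "position"]]
    )
    minor_by_marker = pd.Series([NUCLEOTIDES[i] for i in minor_idx], index=stats.index)
    meta = pd.DataFrame(
        {
            "marker_id": selected,
            "scaffold": coords.loc[selected, "scaffold"].to_numpy() if selected else [],
            "position": coords.loc[selected, "position"].astype(int).to_numpy() if selected else [],
            "major_allele": major_by_marker.loc[selected].to_numpy() if selected else [],
            "minor_allele": minor_by_marker.loc[selected].to_numpy() if selected else [],
        },
        columns=META_COLUMNS,
    ).set_index("marker_id")
    scores = scores_all[selected].copy() if selected else pd.DataFrame(index=accessions)
    panel = MarkerPanel(scores, meta)
    return QCResult(panel=panel, rejections=rejections, rule_counts=rule_counts)


def check_marker(
    marker_rows: pd.DataFrame, n_accessions: int, thresholds: QCThresholds | None = None
) -> str:
    """Re-check one marker's rows against the rules; returns the first violated
    rule name or '' if the marker passes.  Independent slow path used to audit
    :func:`select_markers`."""
    thr = thresholds or QCThresholds()
    if len(marker_rows) < thr.call_rate_min * n_accessions:
        return "call_rate"
    freqs = marker_rows[list(NUCLEOTIDES)].mean().to_numpy(dtype=float)
    order = np.argsort(-freqs, kind="stable")
    major, minor = freqs[order[0]], freqs[order[1]]
    if minor < thr.maf_min or major > thr.major_max:
        return "maf"
    if major + minor < thr.biallelic_min:
        return "biallelic"
    per_acc = marker_rows[NUCLEOTIDES[order[0]]].to_numpy(dtype=float)
    if len(per_acc) < 2 or np.std(per_acc, ddof=1) < thr.sd_min:
        return "sd"
    return ""


def qc_summary(
    result: QCResult, index: ScaffoldIndex | None = None, genome_size_bp: int | None = None
) -> dict:
    """Coverage accounting over selected markers: scaffolds hit, cumulative
    scaffold length, genome fraction.  Markers on scaffolds absent from the
    index are listed as unplaced and excluded from the length sum."""
    scaffolds = sorted(set(result.panel.meta["scaffold"])) if result.n_selected else []
    out = {
        "n_selected": result.n_selected,
        "n_rejected": int(len(result.rejections)),
        "rule_counts": result.rule_counts,
        "n_scaffolds": len(scaffolds),
    }
    if index is not None:
        placed = [s for s in scaffolds if s in index]
        unplaced = [s for s in scaffolds if s not in index]
        covered = int(sum(index.length(s) for s in placed))
        out["n_scaffolds_placed"] = len(placed)
        out["unplaced_scaffolds"] = unplaced
        out["covered_length_bp"] = covered
        if genome_size_bp:
            out["genome_fraction"] = covered / genome_size_bp
    return out


def scores_to_frequency_table(panel: MarkerPanel) -> pd.DataFrame:
    """Rebuild a biallelic nucleotide-frequency table from a scored panel
    (major allele gets the score, minor allele the remainder).  Used for QC
    idempotence checks and for writing simulator output in the raw format."""
    records = []
    meta = panel.meta
    for mid in panel.markers:
        major = meta.at[mid, "major_allele"]
        minor = meta.at[mid, "minor_allele"]
        col = panel.scores[mid]
        for acc, score in col.items():
            row = {"marker_id": mid, "scaffold": meta.at[mid, "scaffold"],
                   "position": int(meta.at[mid, "position"]), "accession": acc,
                   "A": 0.0, "C": 0.0, "G": 0.0, "T": 0.0}
            row[major] = float(score)
            row[minor] = float(1.0 - score)
            records.append(row)
    return pd.DataFrame.from_records(records, columns=["marker_id", "scaffold", "position", "accession", *NUCLEOTIDES])
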