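"""Run configuration: thresholds, seed, per-stage output paths."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .qc import QCThresholds


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the input files themselves."""

    outdir: str = "scafqtl_out"
    seed: int = 0
    alpha: float = 0.05
    r_collinear: float = 0.3
    n_clusters: int = 5
    genome_size_bp: int | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    # inputs: either a frequency table to QC, or a pre-scored panel
    frequency_table: str | None = None
    scores: str | None = None
    marker_meta: str | None = None
    phenotypes: str | None = None
    scaffold_index: str | None = None
    # simulation block (used by the `simulate` stage), passed through verbatim
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha={self.alpha} outside (0, 1)")
        if not 0.0 <= self.r_collinear <= 1.0:
            raise ValueError(f"r_collinear={self.r_collinear} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc = QCThresholds(**raw.pop("qc", {}))
        return cls(qc=qc, **raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def path(self, name: str) -> Path:
        out = Path(self.outdir)
        out.mkdir(parents=True, exist_ok=True)
        return out / name
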