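"""Study configuration: factor levels, replication counts, seeds, output paths."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .montecarlo import TABLE1_FACTORS, DesignCondition, build_design

__all__ = ["StudyConfig"]


@dataclass
class StudyConfig:
    """Parameters of one Monte Carlo study run.

    ``cells`` optionally restricts the run to a list of condition ids (1-based
    within the design built from ``factors``); ``n_draws = 0`` disables the
    bootstrap, which is sufficient for bias and MSE outcomes.
    """

    factors: dict = field(default_factory=lambda: {k: list(v) for k, v in TABLE1_FACTORS.items()})
    R: int = 200
    n_draws: int = 0
    alpha: float = 0.05
    seed: int = 1
    baseline: str = "constant"
    outdir: str = "dtsmed-study"
    cells: Optional[Sequence[int]] = None
    engine: str = "vectorized"

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be at least 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.baseline not in ("constant", "per-interval"):
            raise ValueError("baseline must be 'constant' or 'per-interval'")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "StudyConfig":
        """Load from a YAML (or JSON, a YAML subset) mapping."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def design(self) -> list[DesignCondition]:
        cells = build_design(self.factors)
        if self.cells is not None:
            wanted = set(self.cells)
            missing = wanted - {c.id for c in cells}
            if missing:
                raise ValueError(f"unknown condition ids: {sorted(missing)}")
            cells = [c for c in cells if c.id in wanted]
        return cells
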