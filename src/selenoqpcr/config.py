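"""Run configuration shared by the statistics layer and the CLI."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Thresholds and cohort sizes governing a pipeline run.

    Parameters
    ----------
    alpha
        Two-tailed significance level for the Student's t-test (default 0.05).
    trend_floor
        Minimum |percent change| to call a trend; exactly this value is
        still ``no_change`` (the change must *exceed* the floor).
    tiers
        Upper edges of the first two trend brackets, giving tiers
        (floor, tiers[0]], (tiers[0], tiers[1]], (tiers[1], inf).
    max_ct
        Detectability cutoff: a gene x region stratum whose mean detected
        CT exceeds this many cycles is treated as not detected.
    max_nd_fraction
        Detectability cutoff on the fraction of not-detected wells.
    qvalues
        If true, append Benjamini-Hochberg q-values over combined p-values
        as an extra results column (no gatekeeping uses them).
    ct_noise_sd
        Gaussian CT noise, in cycles, used by simulation modes.
    n_discovery, n_replication
        Animals per group in each phase for simulation modes.
    seed
        Seed for all simulation randomness.
    """

    alpha: float = 0.05
    trend_floor: float = 10.0
    tiers: tuple[float, float] = (15.0, 20.0)
    max_ct: float = 35.0
    max_nd_fraction: float = 0.5
    qvalues: bool = False
    ct_noise_sd: float = 0.3
    n_discovery: int = 4
    n_replication: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        lo, hi = self.tiers
        if not (self.trend_floor < lo < hi):
            raise ValueError(
                "trend tiers must be strictly increasing above the trend "
                f"floor, got floor={self.trend_floor}, tiers={self.tiers}"
            )
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tiers"] = list(self.tiers)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides win over file values."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "tiers" in raw:
            raw["tiers"] = tuple(raw["tiers"])
        return cls(**raw)
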