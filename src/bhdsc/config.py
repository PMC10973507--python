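"""Pipeline configuration: every analysis constant in one validated place.

Defaults are the published analysis choices: 72 s bolus window, first 8
boluses averaged, 99th/99.9th percentile AIF/VOF selection, 20% SVD noise
threshold, hematocrit correction 1.45, brain density 1.05, and a 0.5 s /
8 s delay grid.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .params import BreathHoldProtocol


@dataclass
class PipelineConfig:
    # protocol
    prep_s: float = 10.0
    hold_s: float = 16.0
    recovery_s: float = 34.0
    n_blocks: int = 9
    final_baseline_s: float = 80.0
    TR: float = 2.0
    # preprocessing
    window_s: float = 72.0
    n_use: int = 8
    baseline_n: str = "10+10"
    detrend: bool = True
    # input-function selection
    aif_percentile: float = 99.0
    vof_percentile: float = 99.9
    short_delay_max_s: float = 0.5
    vof_delay_window_s: tuple = (1.5, 4.0)
    # kinetics
    k_H: float = 1.45
    rho: float = 1.05
    svd_threshold: float = 0.20
    # delay grid
    delay_step_s: float = 0.5
    delay_max_s: float = 8.0
    # misc
    seed: int = 0
    field_strength: float = 7.0
    extra: dict = field(default_factory=dict)

    def validate(self) -> "PipelineConfig":
        if not 0.0 <= self.svd_threshold < 1.0:
            raise ValueError(f"svd_threshold={self.svd_threshold} must lie in [0, 1)")
        if self.k_H <= 0 or self.rho <= 0:
            raise ValueError("k_H and rho must be positive")
        for name in ("prep_s", "hold_s", "recovery_s", "final_baseline_s",
                     "TR", "window_s", "delay_step_s", "delay_max_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.aif_percentile < 100 or not 0 < self.vof_percentile < 100:
            raise ValueError("selection percentiles must lie in (0, 100)")
        if self.n_use > self.n_blocks:
            raise ValueError("n_use cannot exceed n_blocks")
        if self.baseline_n not in ("10+10", "10total"):
            raise ValueError("baseline_n must be '10+10' or '10total'")
        steps = self.delay_max_s / self.delay_step_s
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("delay_step_s must divide delay_max_s")
        return self

    @property
    def protocol(self) -> BreathHoldProtocol:
        return BreathHoldProtocol(
            prep_s=self.prep_s, hold_s=self.hold_s, recovery_s=self.recovery_s,
            n_blocks=self.n_blocks, final_baseline_s=self.final_baseline_s,
            TR=self.TR,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vof_delay_window_s"] = list(self.vof_delay_window_s)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        if "vof_delay_window_s" in kwargs:
            kwargs["vof_delay_window_s"] = tuple(kwargs["vof_delay_window_s"])
        cfg = cls(**kwargs)
        cfg.extra.update(extra)
        return cfg.validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
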