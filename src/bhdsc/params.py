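"""Domain parameter types: field parameters, voxel compositions, the
breath-hold protocol, and bolus dynamics.

The signal model distinguishes three compartment families inside a voxel:
extravascular tissue, cerebrospinal fluid (CSF), and blood, with the blood
split into arterial, capillary and venous pools that carry their own
baseline oxygenation.  Field-strength-specific relaxation coefficients are
loaded from the packaged ``data/relaxation.yaml`` so they can be swapped
without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

BLOOD_POOLS = ("arterial", "capillary", "venous")

#: Baseline oxygenation fractions per blood pool. Arterial blood is
#: near-saturation; capillary/venous blood sits in the 0.60-0.80 band.
DEFAULT_Y_BASELINE = {"arterial": 0.98, "capillary": 0.65, "venous": 0.60}


def _load_relaxation_table() -> dict:
    with resources.files("bhdsc.data").joinpath("relaxation.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class FieldParams:
    """Field-strength-specific acquisition and relaxation parameters.

    The intravascular transverse relaxation rate follows the standard
    quadratic deoxyhemoglobin dependence ``R2*_iv(Y) = iv_a + iv_b*(1-Y)**2``
    (monotonically decreasing in oxygenation Y), and the extravascular
    contribution is linear in ``f_blood * (1 - Y)`` with field-dependent
    relaxivity ``r_ev`` (static dephasing regime).
    """

    field_strength: float
    TE: float
    TR: float
    r2s_tissue: float
    r2s_csf: float
    iv_a: float
    iv_b: float
    r_ev: float
    r_ev_by_class: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.TE <= 0 or self.TR <= 0:
            raise ValueError("TE and TR must be positive")
        if self.iv_b < 0 or self.r_ev < 0:
            raise ValueError("relaxivity coefficients must be non-negative")

    def r2s_iv(self, Y):
        """Intravascular R2* (1/s) for oxygenation fraction ``Y``."""
        Y = np.asarray(Y, dtype=float)
        return self.iv_a + self.iv_b * (1.0 - Y) ** 2

    def ev_relaxivity(self, vessel_class: str | None = None) -> float:
        """Extravascular relaxivity, optionally vessel-class specific."""
        if vessel_class is not None and vessel_class in self.r_ev_by_class:
            return float(self.r_ev_by_class[vessel_class])
        return self.r_ev

    @classmethod
    def from_field(cls, field_strength: float, **overrides) -> "FieldParams":
        """Build parameters for 3 T or 7 T from the packaged coefficients."""
        table = _load_relaxation_table()
        key = str(int(field_strength))
        if key not in table:
            raise ValueError(
                f"no relaxation parameters for field strength {field_strength}; "
                f"available: {sorted(k for k in table if k != 'TR')}"
            )
        entry = dict(table[key])
        entry.setdefault("TR", table.get("TR", 2.0))
        entry.update(overrides)
        return cls(field_strength=float(field_strength), **entry)


@dataclass(frozen=True)
class VoxelComposition:
    """Volume-fraction composition of one voxel.

    ``f_blood`` maps pool name -> volume fraction; ``Y_baseline`` maps pool
    name -> baseline oxygenation.  All fractions must be non-negative and
    sum to one with ``f_tissue`` and ``f_csf``.
    """

    f_tissue: float
    f_csf: float
    f_blood: dict
    Y_baseline: dict = field(default_factory=lambda: dict(DEFAULT_Y_BASELINE))
    vessel_class: str = "capillary/tissue"

    def __post_init__(self) -> None:
        fracs = [self.f_tissue, self.f_csf, *self.f_blood.values()]
        if any(f < 0 for f in fracs):
            raise ValueError("invalid composition: negative volume fraction")
        total = sum(fracs)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(
                f"invalid composition: fractions sum to {total:.6f}, expected 1"
            )
        for pool in self.f_blood:
            if pool not in BLOOD_POOLS:
                raise ValueError(f"unknown blood pool {pool!r}")
            if pool not in self.Y_baseline:
                raise ValueError(f"missing baseline oxygenation for {pool!r}")
            if not 0.0 <= self.Y_baseline[pool] <= 1.0:
                raise ValueError("oxygenation must lie in [0, 1]")

    @property
    def total_blood(self) -> float:
        return float(sum(self.f_blood.values()))

    def with_blood_volume(self, f_blood_total: float) -> "VoxelComposition":
        """Rescale the blood pools to a new total blood volume fraction.

        The removed/added volume is taken from/returned to tissue and CSF
        proportionally to their current fractions.
        """
        old = self.total_blood
        if old <= 0:
            raise ValueError("composition has no blood to rescale")
        delta = f_blood_total - old
        ev = self.f_tissue + self.f_csf
        if ev <= 0 and delta > 0:
            raise ValueError("no extravascular volume to displace")
        scale = f_blood_total / old
        new_blood = {p: f * scale for p, f in self.f_blood.items()}
        ev_scale = (ev - delta) / ev if ev > 0 else 0.0
        if ev_scale < 0:
            raise ValueError("blood volume exceeds available voxel volume")
        return replace(
            self,
            f_tissue=self.f_tissue * ev_scale,
            f_csf=self.f_csf * ev_scale,
            f_blood=new_blood,
        )


#: Blood-pool splits (arterial, capillary, venous) for the named presets.
_PRESET_SPLITS = {
    "arterial_dominated": (0.4, 0.3, 0.3),
    "capillary": (0.1, 0.6, 0.3),
    "venous_dominated": (0.1, 0.2, 0.7),
    "large_vessel_csf": (0.9, 0.0, 0.1),
}

COMPOSITION_PRESETS = tuple(_PRESET_SPLITS)


def composition_preset(
    name: str,
    f_blood_total: float | None = None,
    f_csf: float | None = None,
    include_csf: bool = True,
) -> VoxelComposition:
    """Return a named canonical voxel composition.

    Presets are stand-ins for typical cortical voxel compositions:
    three tissue-voxel presets (blood split dominated by the named pool,
    default 4% blood, 5% CSF) and a ``large_vessel_csf`` preset (30% blood
    adjacent to 25% CSF) used for the arterial-input-function geometry.
    ``include_csf=False`` replaces the CSF share with tissue, which switches
    off the CSF-blood contrast mechanism of the vasodilation dip.
    """
    if name not in _PRESET_SPLITS:
        raise ValueError(f"unknown preset {name!r}; choose from {COMPOSITION_PRESETS}")
    split = _PRESET_SPLITS[name]
    if f_blood_total is None:
        f_blood_total = 0.30 if name == "large_vessel_csf" else 0.04
    if f_csf is None:
        f_csf = 0.25 if name == "large_vessel_csf" else 0.05
    if not include_csf:
        f_csf = 0.0
    f_blood = {p: s * f_blood_total for p, s in zip(BLOOD_POOLS, split)}
    f_tissue = 1.0 - f_blood_total - f_csf
    return VoxelComposition(
        f_tissue=f_tissue, f_csf=f_csf, f_blood=f_blood, vessel_class=name
    )


@dataclass(frozen=True)
class BreathHoldProtocol:
    """Timing of the breath-hold paradigm.

    Each of the ``n_blocks`` blocks is 10 s of preparation with regular
    breathing, 16 s of breath-holding, and 34 s of regular breathing,
    followed by a final resting baseline.
    """

    prep_s: float = 10.0
    hold_s: float = 16.0
    recovery_s: float = 34.0
    n_blocks: int = 9
    final_baseline_s: float = 80.0
    TR: float = 2.0

    def __post_init__(self) -> None:
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if self.n_blocks < 1:
            raise ValueError("need at least one breath-hold block")

    @property
    def block_s(self) -> float:
        return self.prep_s + self.hold_s + self.recovery_s

    @property
    def total_s(self) -> float:
        return self.n_blocks * self.block_s + self.final_baseline_s

    @property
    def n_volumes(self) -> int:
        return int(round(self.total_s / self.TR))

    def block_start_s(self, i: int) -> float:
        return i * self.block_s

    def hold_onset_s(self, i: int) -> float:
        return self.block_start_s(i) + self.prep_s


def raised_cosine(t, onset_s: float, duration_s: float):
    """Smooth, compactly supported unit-peak bolus shape.

    ``0.5*(1 - cos(2*pi*(t-onset)/duration))`` on [onset, onset+duration],
    zero elsewhere.
    """
    t = np.asarray(t, dtype=float)
    x = (t - onset_s) / duration_s
    out = np.where((x >= 0) & (x <= 1), 0.5 * (1.0 - np.cos(2.0 * np.pi * x)), 0.0)
    return out


@dataclass(frozen=True)
class BolusDynamics:
    """Oxygenation and vasodilation time courses for one voxel.

    A breath-hold drives an oxygenation bolus (``dY_peak`` per blood pool,
    zero for near-saturated arterial blood) and a relative blood-volume
    increase ``dcbv_rel_peak`` (vasodilation), both following the same
    raised-cosine shape: the two effects share the local CO2 time course.
    The bolus onset lags the start of the breath-hold by ``onset_delay_s``
    (lung-to-brain CO2 transit, 10-15 s) plus the region delay ``delay_s``.
    """

    onset_delay_s: float = 12.0
    duration_s: float = 35.0
    delay_s: float = 0.0
    dY_peak: dict = field(
        default_factory=lambda: {"arterial": 0.0, "capillary": 0.14, "venous": 0.14}
    )
    dcbv_rel_peak: float = 0.0

    def bolus_shape(self, t, hold_onset_s: float = 0.0):
        """Unit-peak shape for a breath-hold starting at ``hold_onset_s``."""
        onset = hold_onset_s + self.onset_delay_s + self.delay_s
        return raised_cosine(t, onset, self.duration_s)

    def shape_train(self, t, protocol: BreathHoldProtocol | None = None):
        """Shape for a full protocol (sum over blocks) or a single bolus."""
        t = np.asarray(t, dtype=float)
        if protocol is None:
            return self.bolus_shape(t)
        out = np.zeros_like(t)
        for i in range(protocol.n_blocks):
            out += self.bolus_shape(t, protocol.hold_onset_s(i))
        return out

    def dY(self, t, pool: str, protocol: BreathHoldProtocol | None = None):
        return self.dY_peak.get(pool, 0.0) * self.shape_train(t, protocol)

    def dcbv_rel(self, t, protocol: BreathHoldProtocol | None = None):
        return self.dcbv_rel_peak * self.shape_train(t, protocol)
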