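"""QCM-D analysis: Sauerbrey mass and per-layer adsorbed mass.

For a rigid film on a quartz crystal microbalance, the areal mass added to
the sensor follows the Sauerbrey relation

    dm = -C * df / n,

with ``C`` the mass-sensitivity constant (17.7 ng cm^-2 Hz^-1 for 5 MHz
sensors), ``df`` the frequency shift at overtone ``n``. A frequency *drop*
therefore reports mass *gain*. Rigidity is checked by comparing the
dissipation-to-frequency ratio across overtones: a rigid film shows a
stable ratio and low dissipation per Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError, SchemaError

#: Sauerbrey sensitivity constant for 5 MHz sensors, ng / (cm^2 Hz).
SAUERBREY_C_5MHZ = 17.7


@dataclass(frozen=True)
class SauerbreyParams:
    C: float = SAUERBREY_C_5MHZ
    overtone: int = 3

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise InvalidParameterError(f"C must be > 0, got {self.C}")
        if self.overtone < 1:
            raise InvalidParameterError(f"overtone must be >= 1, got {self.overtone}")
        if self.overtone % 2 == 0:
            raise InvalidParameterError(f"overtone must be odd, got {self.overtone}")


@dataclass(frozen=True)
class QcmdTrace:
    """Frequency/dissipation trace with step annotations.

    ``times`` in minutes; ``delta_f`` and ``delta_d`` map each odd overtone
    number to its series (Hz and dimensionless dissipation respectively).
    ``steps`` are ordered, non-overlapping ``(label, start_min, end_min)``.
    """

    times: np.ndarray
    delta_f: dict[int, np.ndarray]
    delta_d: dict[int, np.ndarray]
    steps: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise SchemaError("trace times must be strictly increasing")
        object.__setattr__(self, "times", times)
        for n in self.delta_f:
            if n % 2 == 0 or n < 1:
                raise SchemaError(f"overtone numbers must be odd >= 1, got {n}")
            if len(self.delta_f[n]) != times.size:
                raise SchemaError(f"overtone {n} series length mismatch")
        prev_end = -math.inf
        for label, start, end in self.steps:
            if start >= end:
                raise SchemaError(f"step {label!r}: start must be < end")
            if start < prev_end:
                raise SchemaError(f"step {label!r} overlaps the previous step")
            prev_end = end

    @property
    def overtones(self) -> list[int]:
        return sorted(self.delta_f)

    def window_mask(self, start: float, end: float) -> np.ndarray:
        return (self.times >= start) & (self.times <= end)


@dataclass(frozen=True)
class LayerStep:
    label: str
    mass: float       # end-of-step areal mass, ng/cm^2
    increment: float  # change from the previous step (negative = stripping)


@dataclass(frozen=True)
class LayerMassProfile:
    steps: tuple[LayerStep, ...]

    @property
    def final_mass(self) -> float:
        return self.steps[-1].mass if self.steps else 0.0


@dataclass(frozen=True)
class RigidityResult:
    rigid: bool | None     # None = indeterminate (no usable frequency shift)
    spread: float          # relative spread of dD/(-df/n) across overtones
    mean_ratio: float      # mean dD per Hz of normalized frequency shift


def sauerbrey_mass(delta_f: float | np.ndarray, params: SauerbreyParams = SauerbreyParams()) -> float | np.ndarray:
    """Areal mass (ng/cm^2) from a frequency shift: ``-C * df / n``."""
    out = -params.C * np.asarray(delta_f, dtype=float) / params.overtone
    return float(out) if np.ndim(delta_f) == 0 else out


def rigidity_check(
    trace: QcmdTrace,
    window: tuple[float, float],
    spread_threshold: float = 0.20,
    ratio_threshold: float = 0.4e-6,
) -> RigidityResult:
    """Assess film rigidity over a time window.

    Computes dD / (-df/n) per overtone averaged over the window. The film
    is called rigid when the relative spread ((max-min)/mean) across
    overtones is below ``spread_threshold`` and the mean ratio is below
    ``ratio_threshold`` (dissipation per Hz). When frequency shifts are all
    near zero the ratio is indeterminate and ``rigid=None`` is returned.
    """
    mask = trace.window_mask(*window)
    if not mask.any():
        raise InvalidParameterError(f"window {window} contains no trace samples")
    if len(trace.overtones) < 2:
        raise InvalidParameterError("rigidity check needs >= 2 overtones")
    ratios = []
    for n in trace.overtones:
        df_norm = -np.mean(trace.delta_f[n][mask]) / n
        dd = np.mean(trace.delta_d[n][mask])
        if abs(df_norm) < 1e-9:
            continue
        ratios.append(dd / df_norm)
    if not ratios:
        return RigidityResult(rigid=None, spread=math.nan, mean_ratio=math.nan)
    ratios_arr = np.array(ratios)
    mean_ratio = float(np.mean(ratios_arr))
    if mean_ratio == 0.0:
        spread = 0.0
    else:
        spread = float((ratios_arr.max() - ratios_arr.min()) / abs(mean_ratio))
    rigid = spread <= spread_threshold and abs(mean_ratio) < ratio_threshold
    return RigidityResult(rigid=rigid, spread=spread, mean_ratio=mean_ratio)


def layer_masses(
    trace: QcmdTrace,
    params: SauerbreyParams = SauerbreyParams(),
    wash_window_min: float = 0.5,
    step_filter: str = "wash",
) -> LayerMassProfile:
    """End-of-step areal mass after each wash step, and per-step increments.

    The post-wash mass is the Sauerbrey mass of the chosen overtone's
    frequency shift averaged over the final ``wash_window_min`` minutes of
    each step whose label contains ``step_filter`` (noise-robust compared to
    a single last sample). Increments are successive differences; a wash
    that strips below the previous plateau yields a negative increment.
    """
    if params.overtone not in trace.delta_f:
        raise SchemaError(f"overtone {params.overtone} absent from trace")
    t0, t1 = trace.times[0], trace.times[-1]
    steps_out: list[LayerStep] = []
    prev_mass = 0.0
    for label, start, end in trace.steps:
        if start < t0 - 1e-9 or end > t1 + 1e-9:
            raise SchemaError(f"step {label!r} ({start}-{end} min) outside trace span")
        if step_filter and step_filter not in label:
            continue
        mask = trace.window_mask(max(start, end - wash_window_min), end)
        mean_df = float(np.mean(trace.delta_f[params.overtone][mask]))
        mass = float(sauerbrey_mass(mean_df, params))
        steps_out.append(LayerStep(label=label, mass=mass, increment=mass - prev_mass))
        prev_mass = mass
    return LayerMassProfile(steps=tuple(steps_out))
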