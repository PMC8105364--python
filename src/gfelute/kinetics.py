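"""First-order protein degradation kinetics.

A protein in solution that has reached folding/unfolding equilibrium loses
immunoassay-detectable concentration by pseudo-first-order kinetics,

    ln N(t) = ln N0 - k * t,

so the rate constant ``k`` (per hour) is the negative slope of a log-linear
regression of concentration on time and the half-life is ``ln 2 / k``.
Early time points, before the folding equilibrium is established, show a
faster apparent loss ("burst") and are excluded by fitting only inside a
time window (default 8-96 h).

Everything here works in hours and ng/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    AggregationError,
    InsufficientDataError,
    InvalidParameterError,
    NonPositiveConcentrationError,
)

#: Default fit window (hours), inclusive on both ends. The first ~4 h of a
#: degradation assay are not at folding equilibrium; 8 h onward isolates the
#: long-term first-order rate.
DEFAULT_WINDOW: tuple[float, float] = (8.0, 96.0)

LN2 = math.log(2.0)


@dataclass(frozen=True)
class Timecourse:
    """One replicate of a (time, concentration) degradation assay.

    Parameters
    ----------
    condition_label : str
        Experimental condition (e.g. ``"PBS-500"``).
    replicate_id : str
        Replicate identifier within the condition.
    samples : sequence of (float, float)
        ``(time_h, conc_ng_ml)`` pairs; times must be strictly increasing
        and concentrations finite and non-negative.
    """

    condition_label: str
    replicate_id: str
    samples: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        samples = tuple((float(t), float(c)) for t, c in self.samples)
        object.__setattr__(self, "samples", samples)
        times = [t for t, _ in samples]
        concs = [c for _, c in samples]
        if any(not math.isfinite(t) or t < 0 for t in times):
            raise InvalidParameterError("times must be finite and >= 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidParameterError(
                f"times must be strictly increasing in replicate "
                f"{self.replicate_id!r}"
            )
        if any(not math.isfinite(c) or c < 0 for c in concs):
            raise InvalidParameterError("concentrations must be finite and >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.samples])

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for _, c in self.samples])


@dataclass(frozen=True)
class FirstOrderFit:
    """Result of a log-linear first-order fit on one replicate.

    ``k`` is the per-hour rate constant (negative slope of ln C vs t).
    ``t_half`` is ``ln 2 / k`` for ``k > 0`` and ``+inf`` otherwise.
    ``positive_slope`` flags fits where the concentration *grew* over the
    window (``k < 0``): the fit is reported rather than rejected so that
    replicate aggregation stays auditable.
    """

    k: float
    t_half: float
    ln_n0: float
    r_squared: float
    window: tuple[float, float]
    n_points: int
    condition_label: str = ""
    replicate_id: str = ""
    positive_slope: bool = field(default=False)


@dataclass(frozen=True)
class FitSummary:
    """Replicate-level mean +/- SD of half-lives for one condition."""

    mean_t_half: float
    sd_t_half: float
    mean_r_squared: float
    n_replicates: int


def rate_from_half_life(t_half: float) -> float:
    """Convert a half-life (hours) to a first-order rate constant (1/h)."""
    if not math.isfinite(t_half) or t_half <= 0:
        raise InvalidParameterError(f"half-life must be finite and > 0, got {t_half}")
    return LN2 / t_half


def half_life_from_rate(k: float) -> float:
    """Convert a rate constant (1/h) to a half-life (hours); inf for k <= 0."""
    if not math.isfinite(k):
        raise InvalidParameterError(f"rate must be finite, got {k}")
    if k <= 0:
        return math.inf
    return LN2 / k


def decay_concentration(c0: float, k: float, t: float | np.ndarray) -> float | np.ndarray:
    """First-order decay ``c0 * exp(-k t)``.

    ``t`` may be a scalar or array of hours; ``c0`` in ng/mL, ``k`` in 1/h.
    """
    if c0 < 0:
        raise InvalidParameterError(f"c0 must be >= 0, got {c0}")
    if k < 0:
        raise InvalidParameterError(f"k must be >= 0, got {k}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidParameterError("t must be >= 0")
    out = c0 * np.exp(-k * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def fit_first_order(
    tc: Timecourse,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> FirstOrderFit:
    """Log-linear OLS fit of one replicate inside ``window`` (inclusive).

    Returns a :class:`FirstOrderFit` with ``k = -slope``. A positive slope
    (growing signal, possible with noisy flat data) yields ``k < 0`` with
    ``positive_slope=True`` and ``t_half = +inf`` rather than an error.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 samples inside the window.
    NonPositiveConcentrationError
        Any in-window concentration is <= 0 (log undefined).
    """
    t_min, t_max = window
    if not (t_min < t_max):
        raise InvalidParameterError(f"window must satisfy t_min < t_max, got {window}")
    times = tc.times
    concs = tc.concentrations
    mask = (times >= t_min) & (times <= t_max)
    t_in = times[mask]
    c_in = concs[mask]
    if t_in.size < 2:
        raise InsufficientDataError(
            f"replicate {tc.replicate_id!r}: {t_in.size} samples in window "
            f"{window}, need >= 2"
        )
    if np.any(c_in <= 0):
        bad = t_in[c_in <= 0][0]
        raise NonPositiveConcentrationError(
            f"replicate {tc.replicate_id!r}: concentration <= 0 at t = {bad} h"
        )
    log_c = np.log(c_in)
    if np.allclose(log_c, log_c[0]):
        # flat line: zero rate, no explained variance
        slope, intercept, r2 = 0.0, float(log_c[0]), 0.0
    else:
        res = stats.linregress(t_in, log_c)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue) ** 2
    k = -slope
    return FirstOrderFit(
        k=k,
        t_half=half_life_from_rate(k) if k > 0 else math.inf,
        ln_n0=intercept,
        r_squared=r2,
        window=(float(t_min), float(t_max)),
        n_points=int(t_in.size),
        condition_label=tc.condition_label,
        replicate_id=tc.replicate_id,
        positive_slope=k < 0,
    )


def fit_replicates(
    timecourses: Sequence[Timecourse],
    window: tuple[float, float] = DEFAULT_WINDOW,
    fit_of_mean: bool = False,
) -> list[FirstOrderFit]:
    """Fit each replicate independently (the default, statistically honest
    route) or, with ``fit_of_mean=True``, fit the replicate-mean curve.

    The fit-of-mean mode requires all replicates to share a sampling grid
    and returns a single-element list.
    """
    if not timecourses:
        raise InsufficientDataError("no timecourses supplied")
    if not fit_of_mean:
        return [fit_first_order(tc, window) for tc in timecourses]
    grids = {tuple(tc.times.tolist()) for tc in timecourses}
    if len(grids) != 1:
        raise InvalidParameterError("fit_of_mean requires a common sampling grid")
    mean_conc = np.mean([tc.concentrations for tc in timecourses], axis=0)
    mean_tc = Timecourse(
        condition_label=timecourses[0].condition_label,
        replicate_id="mean",
        samples=tuple(zip(timecourses[0].times.tolist(), mean_conc.tolist())),
    )
    return [fit_first_order(mean_tc, window)]


def summarize_fits(fits: Sequence[FirstOrderFit]) -> FitSummary:
    """Arithmetic mean and sample SD (n-1) of replicate half-lives.

    Raises
    ------
    InsufficientDataError
        Empty list.
    AggregationError
        Any fit has an infinite half-life (k <= 0); the offending replicate
        is named so it can be inspected rather than silently dropped.
    """
    if not fits:
        raise InsufficientDataError("cannot summarize an empty list of fits")
    for f in fits:
        if not math.isfinite(f.t_half):
            raise AggregationError(
                f"replicate {f.replicate_id!r} has non-finite half-life "
                f"(k = {f.k:.4g}); exclude or re-fit before summarizing"
            )
    halves = np.array([f.t_half for f in fits])
    r2s = np.array([f.r_squared for f in fits])
    sd = float(np.std(halves, ddof=1)) if halves.size > 1 else 0.0
    return FitSummary(
        mean_t_half=float(np.mean(halves)),
        sd_t_half=sd,
        mean_r_squared=float(np.mean(r2s)),
        n_replicates=int(halves.size),
    )
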