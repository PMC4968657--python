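"""Disintegration and clearance kinetics.

Integrity time courses recovered from ratio imaging are summarised by a
four-parameter logistic decay

    y(t) = a2 + (a1 - a2) / (1 + (t / x0)^p),

with initial plateau a1, final plateau a2, midpoint time x0 (hours) and steepness
exponent p. The integrity half-life is the earliest time at which the fitted
curve crosses 50 absolute percent,

    t_1/2 = x0 * ((a1 - a2)/(50 - a2) - 1)^(1/p),

reported as not-reached (None) when the final plateau sits at or above 50%.

Blood clearance of donor-only carriers is summarised by a mono-exponential
I(t) = I0 * 2^(-t / half_time).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LogisticParams",
    "LogisticDecayModel",
    "LogisticDecayResult",
    "ClearanceModel",
    "ClearanceResult",
    "KineticsError",
    "DegenerateFitError",
    "logistic",
    "half_life",
]


class KineticsError(ValueError):
    """Invalid kinetics input or failed fit."""


class DegenerateFitError(KineticsError):
    """The data cannot identify the model (e.g. a constant series)."""


def logistic(t, a1: float, a2: float, x0: float, p: float):
    """Four-parameter logistic decay evaluated at time(s) t (hours)."""
    t = np.asarray(t, dtype=float)
    out = a2 + (a1 - a2) / (1.0 + (t / x0) ** p)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LogisticParams:
    """Logistic decay parameters; plateaus in integrity %, x0 in hours.

    Invariants: x0 > 0, p > 0, 0 <= a2 <= a1 <= 110 (the ceiling allows modest
    noise overshoot above the physical 100%).
    """

    a1: float
    a2: float
    x0: float
    p: float

    def __post_init__(self) -> None:
        if not (self.x0 > 0):
            raise KineticsError(f"midpoint x0 must be > 0, got {self.x0}")
        if not (self.p > 0):
            raise KineticsError(f"steepness p must be > 0, got {self.p}")
        if not (0 <= self.a2 <= self.a1 <= 110):
            raise KineticsError(
                f"plateaus must satisfy 0 <= a2 <= a1 <= 110, got a1={self.a1}, a2={self.a2}"
            )

    def __call__(self, t):
        return logistic(t, self.a1, self.a2, self.x0, self.p)


def half_life(params: LogisticParams) -> Optional[float]:
    """Time (h) at which the fitted curve crosses 50 absolute percent.

    Closed form t = x0 * ((a1-a2)/(50-a2) - 1)^(1/p). Returns None (not reached)
    when the final plateau a2 >= 50, and 0.0 in the degenerate case a1 <= 50
    (the curve starts below the crossing).
    """
    if params.a2 >= 50.0:
        return None
    if params.a1 <= 50.0:
        return 0.0
    arg = (params.a1 - params.a2) / (50.0 - params.a2) - 1.0
    return params.x0 * arg ** (1.0 / params.p)


class LogisticDecayModel:
    """Least-squares logistic fit to an integrity time course.

    Parameters
    ----------
    times : sequence of float
        Post-injection times in hours, strictly positive and increasing.
    values : sequence of float
        Integrity percentages at those times.
    """

    MAX_NFEV = 2000

    def __init__(self, times: Sequence[float], values: Sequence[float]):
        t = np.asarray(times, dtype=float)
        y = np.asarray(values, dtype=float)
        if t.size != y.size:
            raise KineticsError("times and values must have equal length")
        if t.size < 4:
            raise KineticsError(f"logistic fit needs >= 4 points, got {t.size}")
        if np.any(t <= 0):
            raise KineticsError("logistic fit requires post-injection times > 0")
        if np.any(np.diff(t) <= 0):
            raise KineticsError("times must be strictly increasing")
        self.times = t
        self.values = y

    def default_start(self) -> LogisticParams:
        """a1 = first value, a2 = last value, x0 = time nearest the mid value, p = 2."""
        y = self.values
        a1 = float(max(y[0], y[-1] + 1e-3))
        a2 = float(max(min(y[-1], a1 - 1e-3), 0.0))
        mid = 0.5 * (a1 + a2)
        x0 = float(self.times[np.argmin(np.abs(y - mid))])
        return LogisticParams(a1=min(a1, 110.0), a2=a2, x0=max(x0, 1e-3), p=2.0)

    def fit(self, start: Optional[LogisticParams] = None) -> "LogisticDecayResult":
        if float(np.ptp(self.values)) < 1e-9:
            raise DegenerateFitError(
                "constant series: plateaus coincide and x0 is unidentifiable"
            )
        p0 = start if start is not None else self.default_start()
        t, y = self.times, self.values

        def residuals(theta):
            a1, a2, x0, p = theta
            return a2 + (a1 - a2) / (1.0 + (t / x0) ** p) - y

        tmax = float(t.max())
        sol = least_squares(
            residuals,
            x0=[p0.a1, p0.a2, p0.x0, p0.p],
            bounds=([0.0, 0.0, 1e-6, 1e-3], [110.0, 110.0, 100.0 * tmax, 50.0]),
            method="trf",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=self.MAX_NFEV,
        )
        if not sol.success:
            raise KineticsError(
                f"logistic fit did not converge: {sol.message}; last iterate {tuple(sol.x)}"
            )
        a1, a2, x0, p = (float(v) for v in sol.x)
        if a2 > a1:  # box bounds cannot forbid this ordering; the decay invariant does
            raise DegenerateFitError(
                f"fitted curve is increasing (a1={a1:.3g} < a2={a2:.3g}); "
                "the logistic decay model does not describe this series"
            )
        params = LogisticParams(a1=a1, a2=a2, x0=x0, p=p)
        rss = float(np.sum(sol.fun**2))
        return LogisticDecayResult(model=self, params=params, rss=rss)


@dataclass
class LogisticDecayResult:
    """Fitted logistic decay with half-life and export helpers."""

    model: LogisticDecayModel
    params: LogisticParams
    rss: float

    @property
    def n_points(self) -> int:
        return int(self.model.times.size)

    @property
    def half_life_h(self) -> Optional[float]:
        return half_life(self.params)

    def predict(self, t):
        return self.params(t)

    def curve(self, n: int = 200) -> np.ndarray:
        """Dense (t, y) grid over the observed time span, for plotting/export."""
        t = np.linspace(self.model.times.min(), self.model.times.max(), n)
        return np.column_stack([t, self.predict(t)])

    def to_json(self, path: Union[str, Path, None] = None, **extra) -> str:
        hl = self.half_life_h
        record = {
            "a1": self.params.a1,
            "a2": self.params.a2,
            "x0": self.params.x0,
            "p": self.params.p,
            "rss": self.rss,
            "half_life_h": hl if hl is None or math.isfinite(hl) else None,
            **extra,
        }
        text = json.dumps(record, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        hl = self.half_life_h
        hl_text = "not reached" if hl is None else f"{hl:.3g} h"
        return "\n".join(
            [
                "Logistic decay fit: y = a2 + (a1 - a2)/(1 + (t/x0)^p)",
                f"  n points: {self.n_points}   RSS: {self.rss:.3e}",
                f"  a1 = {self.params.a1:.4g} %   a2 = {self.params.a2:.4g} %",
                f"  x0 = {self.params.x0:.4g} h   p = {self.params.p:.4g}",
                f"  integrity half-life: {hl_text}",
            ]
        )


class ClearanceModel:
    """Mono-exponential blood-clearance fit I(t) = I0 * 2^(-t/half_time).

    Takes background-corrected intensity means (counts) at >= 3 timepoints.
    """

    def __init__(self, times: Sequence[float], intensities: Sequence[float]):
        t = np.asarray(times, dtype=float)
        y = np.asarray(intensities, dtype=float)
        if t.size != y.size:
            raise KineticsError("times and intensities must have equal length")
        if t.size < 3:
            raise KineticsError(f"clearance fit needs >= 3 points, got {t.size}")
        if np.any(np.diff(t) <= 0):
            raise KineticsError("times must be strictly increasing")
        if not np.any(y > 0):
            raise KineticsError("clearance fit needs at least one positive intensity")
        self.times = t
        self.intensities = y

    def fit(self) -> "ClearanceResult":
        t, y = self.times, self.intensities
        if float(np.ptp(y)) < 1e-12 or y[-1] >= y[0]:
            # No measurable decay over the observation window.
            return ClearanceResult(
                model=self,
                i0=float(y.mean()),
                half_time_h=math.inf,
                rss=float(np.sum((y - y.mean()) ** 2)),
                no_decay=True,
            )
        i0_guess = float(y[y > 0][0])
        # crude rate guess from endpoints
        pos = y > 0
        tspan = t[pos][-1] - t[pos][0]
        drop = max(y[pos][0] / max(y[pos][-1], 1e-12), 1.0 + 1e-9)
        ht_guess = max(tspan / math.log2(drop), 1e-3) if tspan > 0 else 1.0

        def residuals(theta):
            i0, ht = theta
            return i0 * np.exp2(-t / ht) - y

        sol = least_squares(
            residuals,
            x0=[i0_guess, ht_guess],
            bounds=([1e-9, 1e-6], [np.inf, np.inf]),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            max_nfev=2000,
        )
        if not sol.success:
            raise KineticsError(f"clearance fit did not converge: {sol.message}")
        return ClearanceResult(
            model=self,
            i0=float(sol.x[0]),
            half_time_h=float(sol.x[1]),
            rss=float(np.sum(sol.fun**2)),
        )


@dataclass
class ClearanceResult:
    """Fitted mono-exponential clearance."""

    model: ClearanceModel
    i0: float
    half_time_h: float
    rss: float
    no_decay: bool = False

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        out = self.i0 * np.exp2(-t / self.half_time_h)
        return out if out.ndim else float(out)

    def summary(self) -> str:
        ht = "no decay" if self.no_decay else f"{self.half_time_h:.3g} h"
        return "\n".join(
            [
                "Exponential clearance fit: I = I0 * 2^(-t / half_time)",
                f"  n points: {self.model.times.size}   RSS: {self.rss:.3e}",
                f"  I0 = {self.i0:.4g} counts   circulation half-time: {ht}",
            ]
        )
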