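"""Exponential calibration law linking nanocarrier integrity to the FRET proximity ratio.

Mixtures of intact donor+acceptor FRET nanocarriers with carriers holding the two
dyes separately define an operational integrity scale: 100% is the pure FRET
formulation, 0% the fully separated mixture at matched dye concentration. Imaging
such mixture plates gives a proximity ratio E = A/(A+D) per integrity level, and
the observed relation is well described by an exponential law

    E(x) = a + b * exp(c * x),    x = integrity in percent (0-100),

with a the ratio offset at full disintegration, b the amplitude and c the rate per
integrity point. The law is fitted by nonlinear least squares (``CalibrationModel``)
and inverted analytically to turn background-corrected in vivo ratios into
integrity percentages (``integrity_from_ratio``).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CalibrationParams",
    "CalibrationSeries",
    "CalibrationModel",
    "CalibrationResult",
    "CalibrationError",
    "DEFAULT_CALIBRATION",
    "ratio_from_integrity",
    "integrity_from_ratio",
    "BELOW_FLOOR",
    "ABOVE_CEILING",
    "IN_RANGE",
]

# Inversion range flags
IN_RANGE = "in_range"
BELOW_FLOOR = "below_floor"      # ratio at/below a: disintegrated beyond model range
ABOVE_CEILING = "above_ceiling"  # ratio at/above E(100)


class CalibrationError(ValueError):
    """Invalid calibration parameters, series, or a failed fit."""


@dataclass(frozen=True)
class CalibrationParams:
    """Parameters (a, b, c) of the exponential ratio-vs-integrity law.

    Invariants: a > 0, b > 0, c > 0 (strictly increasing law) and a + b < 1
    (the proximity ratio stays below 1 at 100% integrity).
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise CalibrationError(f"offset a must be > 0, got {self.a}")
        if not (self.b > 0):
            raise CalibrationError(f"amplitude b must be > 0, got {self.b}")
        if not (self.c > 0):
            raise CalibrationError(f"rate c must be > 0, got {self.c}")
        if not (self.a + self.b < 1):
            raise CalibrationError(
                f"a + b must be < 1 so the ratio stays below 1, got {self.a + self.b}"
            )

    def to_json(self, path: Union[str, Path, None] = None, **extra) -> str:
        record = {"a": self.a, "b": self.b, "c": self.c, **extra}
        text = json.dumps(record, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "CalibrationParams":
        p = Path(source)
        record = json.loads(p.read_text() if p.exists() else str(source))
        return cls(a=record["a"], b=record["b"], c=record["c"])


#: Published calibration of the Cy5.5/Cy7.5 lipid nano-emulsion imaging setup.
DEFAULT_CALIBRATION = CalibrationParams(a=0.14572, b=0.1254, c=0.01748)


def ratio_from_integrity(params: CalibrationParams, integrity) -> np.ndarray:
    """Evaluate the calibration law: proximity ratio at the given integrity (%).

    Accepts scalars or arrays; integrity must lie in [0, 100].
    """
    x = np.asarray(integrity, dtype=float)
    if np.any(x < 0) or np.any(x > 100):
        raise CalibrationError(f"integrity must be within [0, 100], got {integrity}")
    out = params.a + params.b * np.exp(params.c * x)
    return out if out.ndim else float(out)


def integrity_from_ratio(params: CalibrationParams, ratio: float):
    """Invert the calibration law: integrity (%) for a proximity ratio.

    Returns ``(integrity, flag)``. Ratios at or below the offset ``a`` clamp to 0
    with a ``below_floor`` flag (disintegration beyond the model range — common in
    vivo at late timepoints); ratios at or above E(100) clamp to 100 with
    ``above_ceiling``.
    """
    if not math.isfinite(ratio):
        raise CalibrationError(f"ratio must be finite, got {ratio}")
    ceiling = params.a + params.b * math.exp(params.c * 100.0)
    if ratio <= params.a + params.b:  # E(0) = a + b is the in-model floor
        if ratio <= params.a:
            return 0.0, BELOW_FLOOR
        # between a and a+b the log is negative: clamp into [0, 100] anyway
        x = math.log((ratio - params.a) / params.b) / params.c
        return max(x, 0.0), IN_RANGE if x >= 0 else BELOW_FLOOR
    if ratio >= ceiling:
        return 100.0, ABOVE_CEILING
    x = math.log((ratio - params.a) / params.b) / params.c
    return min(max(x, 0.0), 100.0), IN_RANGE


@dataclass
class CalibrationSeries:
    """Measured (integrity %, proximity ratio) records from a mixture plate.

    ``data`` columns: integrity_percent, ratio, and optionally sem. At least 4
    distinct integrity levels are required for fitting.
    """

    data: pd.DataFrame

    REQUIRED = ("integrity_percent", "ratio")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise CalibrationError(f"calibration series missing columns: {missing}")
        x = self.data["integrity_percent"].to_numpy(dtype=float)
        r = self.data["ratio"].to_numpy(dtype=float)
        if np.any(x < 0) or np.any(x > 100):
            raise CalibrationError("integrity levels must lie within [0, 100]")
        if np.any(r <= 0) or np.any(r >= 1):
            raise CalibrationError("ratios must lie strictly within (0, 1)")

    @property
    def n_levels(self) -> int:
        return int(self.data["integrity_percent"].nunique())

    @classmethod
    def from_records(
        cls,
        integrity_percent: Sequence[float],
        ratio: Sequence[float],
        sem: Optional[Sequence[float]] = None,
    ) -> "CalibrationSeries":
        frame = pd.DataFrame(
            {"integrity_percent": list(integrity_percent), "ratio": list(ratio)}
        )
        if sem is not None:
            frame["sem"] = list(sem)
        return cls(frame)

    @classmethod
    def from_csv(cls, path: Union[str, Path, io.IOBase]) -> "CalibrationSeries":
        return cls(pd.read_csv(path))

    def to_csv(self, path: Union[str, Path]) -> None:
        self.data.to_csv(path, index=False)


class CalibrationModel:
    """Nonlinear least-squares fit of E = a + b*exp(c*x) to a mixture series.

    Follows the statsmodels convention: construct from data, call :meth:`fit`,
    inspect the returned :class:`CalibrationResult`.
    """

    MAX_ITER = 500
    XTOL = 1e-10

    def __init__(self, series: CalibrationSeries):
        if series.n_levels < 4:
            raise CalibrationError(
                f"fitting needs >= 4 distinct integrity levels, got {series.n_levels}"
            )
        self.series = series
        self._x = series.data["integrity_percent"].to_numpy(dtype=float)
        self._y = series.data["ratio"].to_numpy(dtype=float)

    def default_start(self) -> CalibrationParams:
        """Heuristic start guaranteeing positive (a, b, c).

        a ~ just under min(ratio), b ~ observed ratio span, c from the log-slope
        of the span over the integrity range.
        """
        rmin, rmax = float(self._y.min()), float(self._y.max())
        span = max(rmax - rmin, 1e-6)
        a0 = max(rmin - 0.1 * span, 1e-4)
        b0 = max(rmin - a0, 1e-4)
        xrange = max(float(self._x.max() - self._x.min()), 1.0)
        c0 = math.log(max((rmax - a0) / b0, 1.0 + 1e-6)) / xrange
        return CalibrationParams(a=a0, b=b0, c=max(c0, 1e-6))

    def fit(self, start: Optional[CalibrationParams] = None) -> "CalibrationResult":
        p0 = start if start is not None else self.default_start()

        def residuals(theta):
            a, b, c = theta
            return a + b * np.exp(c * self._x) - self._y

        sol = least_squares(
            residuals,
            x0=[p0.a, p0.b, p0.c],
            bounds=([1e-9, 1e-9, 1e-9], [1.0, 1.0, 1.0]),
            method="trf",
            xtol=self.XTOL,
            max_nfev=self.MAX_ITER * 3,
        )
        if not sol.success:
            raise CalibrationError(
                f"calibration fit did not converge: {sol.message}; "
                f"last iterate a,b,c = {tuple(sol.x)}, residuals = {sol.fun.tolist()}"
            )
        a, b, c = (float(v) for v in sol.x)
        params = CalibrationParams(a=a, b=b, c=c)
        rss = float(np.sum(sol.fun**2))
        cov = _covariance(sol.jac, rss, self._x.size)
        return CalibrationResult(model=self, params=params, rss=rss, cov=cov)


def _covariance(jac: np.ndarray, rss: float, n: int) -> Optional[np.ndarray]:
    """Gauss-Newton covariance estimate; None when the problem is degenerate."""
    k = jac.shape[1]
    if n <= k:
        return None
    try:
        jtj_inv = np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        return None
    return jtj_inv * rss / (n - k)


@dataclass
class CalibrationResult:
    """Fitted calibration law with goodness-of-fit diagnostics."""

    model: CalibrationModel
    params: CalibrationParams
    rss: float
    cov: Optional[np.ndarray] = None

    @property
    def n_points(self) -> int:
        return int(self.model._x.size)

    @property
    def bse(self) -> Optional[np.ndarray]:
        """Standard errors of (a, b, c), or None when not estimable."""
        if self.cov is None:
            return None
        return np.sqrt(np.diag(self.cov))

    def predict(self, integrity) -> np.ndarray:
        return ratio_from_integrity(self.params, integrity)

    def invert(self, ratio: float):
        return integrity_from_ratio(self.params, ratio)

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        return self.params.to_json(path, rss=self.rss, n_points=self.n_points)

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Exponential calibration fit: E = a + b*exp(c * integrity%)",
            f"  n points: {self.n_points}   RSS: {self.rss:.3e}",
        ]
        for name, value, i in (("a", self.params.a, 0), ("b", self.params.b, 1), ("c", self.params.c, 2)):
            err = f" +/- {se[i]:.3g}" if se is not None else ""
            lines.append(f"  {name} = {value:.6g}{err}")
        lines.append(
            f"  E(0) = {self.predict(0):.5f}   E(100) = {self.predict(100):.5f}"
        )
        return "\n".join(lines)
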