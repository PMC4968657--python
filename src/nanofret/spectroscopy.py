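"""Cuvette-level spectral utilities: band maxima, proximity ratio, stability, quantum yield.

These operate on emission spectra of the donor/acceptor dye pair (Cy5.5-type
donor emitting near 700 nm, Cy7.5-type acceptor near 820-840 nm). The proximity
ratio E = A/(A+D) from the two band maxima is the same semi-quantitative FRET
statistic used on images; the relative quantum yield uses integrated band areas
against a reference dye of known yield under matched absorbance, with an
optional refractive-index correction:

    QY = QY_ref * (I_sample / I_ref) * (Abs_ref / Abs_sample) * (n_sample^2 / n_ref^2)

Band maxima and band areas are distinct statistics and both are exposed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "EmissionSpectrum",
    "SpectroscopyError",
    "DONOR_WINDOW_NM",
    "ACCEPTOR_WINDOW_NM",
    "band_maxima",
    "spectrum_proximity_ratio",
    "stability_series",
    "relative_quantum_yield",
]

#: Default emission windows bracketing the ~700 nm donor and ~820-840 nm acceptor bands.
DONOR_WINDOW_NM = (690.0, 760.0)
ACCEPTOR_WINDOW_NM = (790.0, 900.0)


class SpectroscopyError(ValueError):
    """Invalid spectrum or spectral operation."""


@dataclass
class EmissionSpectrum:
    """One corrected emission spectrum.

    ``absorbance`` at the excitation wavelength must be <= 0.1 when present
    (the dilute regime required for relative quantum-yield measurements).
    """

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    excitation_nm: float
    label: str = ""
    absorbance: Optional[float] = None

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.size != self.intensity.size:
            raise SpectroscopyError("wavelength and intensity grids differ in length")
        if self.wavelength_nm.size < 20:
            raise SpectroscopyError("spectrum needs >= 20 grid points")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise SpectroscopyError("wavelength grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise SpectroscopyError("intensities must be >= 0")
        if self.excitation_nm >= self.wavelength_nm[0]:
            raise SpectroscopyError("excitation must lie below the emission grid")
        if self.absorbance is not None and not (0 < self.absorbance <= 0.1):
            raise SpectroscopyError(
                f"absorbance must lie in (0, 0.1], got {self.absorbance}"
            )

    def integral(self) -> float:
        """Integrated emission over the full band (trapezoidal)."""
        return float(np.trapezoid(self.intensity, self.wavelength_nm))

    def to_csv(self, path: Union[str, Path]) -> None:
        path = Path(path)
        pd.DataFrame(
            {"wavelength_nm": self.wavelength_nm, "intensity": self.intensity}
        ).to_csv(path, index=False)
        sidecar = {
            "excitation_nm": self.excitation_nm,
            "label": self.label,
            "absorbance": self.absorbance,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "EmissionSpectrum":
        path = Path(path)
        table = pd.read_csv(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if not sidecar_path.exists():
            raise SpectroscopyError(f"missing spectrum sidecar: {sidecar_path}")
        meta = json.loads(sidecar_path.read_text())
        return cls(
            wavelength_nm=table["wavelength_nm"].to_numpy(),
            intensity=table["intensity"].to_numpy(),
            excitation_nm=meta["excitation_nm"],
            label=meta.get("label", ""),
            absorbance=meta.get("absorbance"),
        )


def _window_slice(spec: EmissionSpectrum, window: Tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo >= hi:
        raise SpectroscopyError(f"window must be (low, high), got {window}")
    grid = spec.wavelength_nm
    if lo < grid[0] or hi > grid[-1]:
        raise SpectroscopyError(
            f"window {window} lies outside the grid [{grid[0]}, {grid[-1]}] nm"
        )
    return (grid >= lo) & (grid <= hi)


def band_maxima(
    spec: EmissionSpectrum,
    donor_window: Tuple[float, float] = DONOR_WINDOW_NM,
    acceptor_window: Tuple[float, float] = ACCEPTOR_WINDOW_NM,
) -> Tuple[float, float]:
    """Maximum intensities (D, A) within the donor and acceptor emission windows."""
    if max(donor_window[0], acceptor_window[0]) < min(donor_window[1], acceptor_window[1]):
        raise SpectroscopyError("donor and acceptor windows must be disjoint")
    d = float(spec.intensity[_window_slice(spec, donor_window)].max())
    a = float(spec.intensity[_window_slice(spec, acceptor_window)].max())
    return d, a


def spectrum_proximity_ratio(
    spec: EmissionSpectrum,
    donor_window: Tuple[float, float] = DONOR_WINDOW_NM,
    acceptor_window: Tuple[float, float] = ACCEPTOR_WINDOW_NM,
) -> float:
    """E = A/(A+D) from the two band maxima; 0 for a donor-only spectrum."""
    d, a = band_maxima(spec, donor_window, acceptor_window)
    if a + d <= 0:
        raise SpectroscopyError("flat zero spectrum: proximity ratio undefined")
    return a / (a + d)


def stability_series(
    spectra: Sequence[Tuple[float, EmissionSpectrum]],
    donor_window: Tuple[float, float] = DONOR_WINDOW_NM,
    acceptor_window: Tuple[float, float] = ACCEPTOR_WINDOW_NM,
) -> pd.DataFrame:
    """Proximity ratio vs incubation time from (time_h, spectrum) pairs.

    Models the serum/water stability experiment: a stable formulation gives a
    flat E(t); acceptor-band loss gives a monotone decrease.
    """
    times = [t for t, _ in spectra]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise SpectroscopyError("incubation times must be strictly increasing")
    records = [
        {"time_h": t, "value": spectrum_proximity_ratio(s, donor_window, acceptor_window)}
        for t, s in spectra
    ]
    return pd.DataFrame(records)


def relative_quantum_yield(
    sample: EmissionSpectrum,
    reference: EmissionSpectrum,
    reference_qy: float,
    refractive_indices: Tuple[float, float] = (1.0, 1.0),
) -> float:
    """Relative fluorescence quantum yield against a reference dye.

    ``refractive_indices`` is (n_sample, n_reference); leave at (1, 1) to skip
    the solvent-index correction. Both spectra must carry absorbance values
    (<= 0.1, enforced by the spectrum invariant).
    """
    if not (0 < reference_qy <= 1):
        raise SpectroscopyError(f"reference QY must be a fraction in (0, 1], got {reference_qy}")
    if sample.absorbance is None or reference.absorbance is None:
        raise SpectroscopyError("both spectra must carry absorbance at excitation")
    n_sample, n_ref = refractive_indices
    if n_sample <= 0 or n_ref <= 0:
        raise SpectroscopyError("refractive indices must be positive")
    return (
        reference_qy
        * (sample.integral() / reference.integral())
        * (reference.absorbance / sample.absorbance)
        * (n_sample**2 / n_ref**2)
    )
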