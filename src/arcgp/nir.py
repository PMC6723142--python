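"""Savitzky-Golay derivative preprocessing of NIR reflectance spectra.

Raw spectra are absorbance stored as log(1/R) on an evenly spaced
wavelength grid (typically 400-2500 nm). The first and second
Savitzky-Golay derivatives (NIR1, NIR2) remove baseline offsets and
slopes and are used downstream as feature matrices for kernel
construction, exactly like marker matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .kernels import MarkerMatrix


@dataclass
class SpectraMatrix:
    """Lines x wavelengths absorbance matrix, log(1/R) units."""

    values: np.ndarray
    wavelengths: np.ndarray
    line_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("spectra must be a 2-D matrix")
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError("wavelength grid does not match spectra columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra contain non-finite values")
        dw = np.diff(self.wavelengths)
        if self.wavelengths.size < 2 or np.any(dw <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(dw, dw[0], rtol=1e-8, atol=1e-8):
            raise ValueError("wavelength grid must be evenly spaced")
        if len(self.line_ids) != self.values.shape[0]:
            raise ValueError("line_ids length does not match spectra rows")
        self.line_ids = [str(x) for x in self.line_ids]

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])


def sg_derivative(
    S: SpectraMatrix, order: int = 1, window: int = 11, polyorder: int = 2
) -> MarkerMatrix:
    """Savitzky-Golay smoothing derivative of each spectrum.

    Fits a ``polyorder`` polynomial in a sliding ``window`` and returns
    its ``order``-th derivative, scaled by the wavelength step so units
    are per nm (order 1) or per nm^2 (order 2). Edge wavelengths where
    the full window does not fit are dropped: padded derivatives have no
    spectral meaning. Exact for polynomial spectra of degree <= polyorder.
    """
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if polyorder < order:
        raise ValueError("polyorder must be >= derivative order")
    if window > S.wavelengths.size:
        raise ValueError("window exceeds the number of wavelengths")
    D = savgol_filter(
        S.values, window_length=window, polyorder=polyorder,
        deriv=order, delta=S.step, axis=1, mode="interp",
    )
    half = window // 2
    D = D[:, half: D.shape[1] - half]
    wl = S.wavelengths[half: S.wavelengths.size - half]
    return MarkerMatrix(
        D, list(S.line_ids), [f"{w:g}nm_d{order}" for w in wl], scaled=False
    )
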