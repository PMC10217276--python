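"""The six spectral pretreatment operators compared in the pipeline.

SNV (standard normal variate), VN (vector normalization), SG
(Savitzky-Golay) smoothing, FD/SD (first/second finite-difference
derivatives) and the SD-SG combination (second derivative followed by SG
smoothing). All operators act row-wise — each spectrum independently — and
preserve the grid length, so downstream stages see a constant variable
count regardless of method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectrumSet

__all__ = [
    "PretreatmentConfig",
    "snv",
    "vector_normalize",
    "sg_smooth",
    "derivative",
    "sd_sg",
    "apply",
    "METHODS",
]

METHODS = ("snv", "vn", "sg", "fd", "sd", "sd-sg", "none")


@dataclass
class PretreatmentConfig:
    method: str = "sd-sg"
    sg_window: int = 7
    sg_polyorder: int = 3
    # sensitivity toggle: smooth before differentiating instead of after
    smooth_first: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(
                f"unknown pretreatment {self.method!r}; valid methods: {METHODS}"
            )
        _check_sg(self.sg_window, self.sg_polyorder)


def _check_sg(window: int, polyorder: int) -> None:
    if window < 3 or window % 2 == 0:
        raise ValueError(f"SG window must be odd and >= 3, got {window}")
    if polyorder >= window:
        raise ValueError(
            f"SG polyorder ({polyorder}) must be smaller than the window ({window})"
        )


def snv(spectra: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: per-spectrum centering and unit-sd scaling.

    Removes per-sample offset and multiplicative scatter. Sample sd uses the
    n-1 denominator. A constant spectrum has no spread to normalize and is
    rejected by name.
    """
    x = spectra.absorbance
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(
            f"degenerate (constant) spectrum: {spectra.sample_ids[flat[0]]}"
        )
    return spectra.with_absorbance((x - mean) / sd)


def vector_normalize(spectra: SpectrumSet) -> SpectrumSet:
    """Scale each spectrum to unit Euclidean norm (scatter correction)."""
    x = spectra.absorbance
    norm = np.linalg.norm(x, axis=1, keepdims=True)
    zero = np.flatnonzero(norm.ravel() == 0)
    if zero.size:
        raise ValueError(f"all-zero spectrum: {spectra.sample_ids[zero[0]]}")
    return spectra.with_absorbance(x / norm)


def sg_smooth(spectra: SpectrumSet, window: int = 7, polyorder: int = 3) -> SpectrumSet:
    """Savitzky-Golay least-squares polynomial smoothing, length-preserving.

    Edges are handled by fitting the polynomial to the truncated one-sided
    window (scipy's ``mode="interp"``), so no points are lost.
    """
    _check_sg(window, polyorder)
    if window > spectra.n_wavelengths:
        raise ValueError("SG window exceeds the grid length")
    out = savgol_filter(
        spectra.absorbance, window_length=window, polyorder=polyorder,
        axis=1, mode="interp",
    )
    return spectra.with_absorbance(out)


def derivative(spectra: SpectrumSet, order: int) -> SpectrumSet:
    """First or second finite-difference spectral derivative.

    Order 1: central difference (x[i+1]-x[i-1])/(2*dlam), one-sided at the
    endpoints. Order 2: (x[i+1]-2x[i]+x[i-1])/dlam**2, with the one-sided
    three-point form reused at both endpoints. Units: absorbance per nm
    (per nm**2). Requires a uniform grid of >= 3 points.
    """
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    lam = spectra.wavelengths
    if lam.size < 3:
        raise ValueError("derivative needs a grid of at least 3 points")
    steps = np.diff(lam)
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
        raise ValueError("derivative requires a uniform wavelength grid")
    d = steps[0]
    x = spectra.absorbance
    out = np.empty_like(x)
    if order == 1:
        out[:, 1:-1] = (x[:, 2:] - x[:, :-2]) / (2 * d)
        out[:, 0] = (x[:, 1] - x[:, 0]) / d
        out[:, -1] = (x[:, -1] - x[:, -2]) / d
    else:
        out[:, 1:-1] = (x[:, 2:] - 2 * x[:, 1:-1] + x[:, :-2]) / d**2
        out[:, 0] = (x[:, 2] - 2 * x[:, 1] + x[:, 0]) / d**2
        out[:, -1] = (x[:, -1] - 2 * x[:, -2] + x[:, -3]) / d**2
    return spectra.with_absorbance(out)


def sd_sg(
    spectra: SpectrumSet,
    window: int = 7,
    polyorder: int = 3,
    smooth_first: bool = False,
) -> SpectrumSet:
    """Second derivative combined with SG smoothing.

    Default order is derivative-then-smooth: the second derivative removes
    baseline offset and drift, then SG suppresses the noise the
    differentiation amplified. ``smooth_first`` reverses the order for
    sensitivity checks.
    """
    if smooth_first:
        return derivative(sg_smooth(spectra, window, polyorder), order=2)
    return sg_smooth(derivative(spectra, order=2), window, polyorder)


def apply(spectra: SpectrumSet, config: PretreatmentConfig) -> SpectrumSet:
    """Dispatch to the configured operator; "none" is the identity."""
    m = config.method
    if m == "none":
        return spectra.with_absorbance(spectra.absorbance.copy())
    if m == "snv":
        return snv(spectra)
    if m == "vn":
        return vector_normalize(spectra)
    if m == "sg":
        return sg_smooth(spectra, config.sg_window, config.sg_polyorder)
    if m == "fd":
        return derivative(spectra, order=1)
    if m == "sd":
        return derivative(spectra, order=2)
    if m == "sd-sg":
        return sd_sg(
            spectra, config.sg_window, config.sg_polyorder, config.smooth_first
        )
    raise ValueError(f"unknown pretreatment {m!r}; valid methods: {METHODS}")
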