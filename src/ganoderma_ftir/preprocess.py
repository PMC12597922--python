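"""Spectral correction chain: ATR correction, baseline, smoothing, normalization.

The chain runs per spectrum in the fixed order ATR -> baseline -> smoothing ->
subtract/normalize.  ATR correction compensates the 1/nu dependence of the
evanescent-wave penetration depth by scaling absorbance with nu/nu_ref.
Baselines are estimated with asymmetric least squares (AsLS), smoothing is
Savitzky-Golay, and the final subtraction/normalization step maps each
spectrum to the [0, 1] range (min-max) or to a zero-mean unit-norm vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .dataset import SpectraSet

__all__ = [
    "PreprocessConfig",
    "atr_correct",
    "baseline_correct",
    "smooth",
    "subtract_normalize",
    "run_chain",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the four-step chain; each step can be disabled for ablations."""

    atr_reference_wavenumber: float = 1000.0
    baseline_smoothness: float = 1e6
    baseline_asymmetry: float = 0.01
    smooth_window: int = 11
    smooth_polyorder: int = 3
    normalize_mode: str = "minmax"  # or "vector"
    apply_atr: bool = True
    apply_baseline: bool = True
    apply_smooth: bool = True
    apply_normalize: bool = True

    def __post_init__(self) -> None:
        if self.smooth_window % 2 == 0 or self.smooth_window <= self.smooth_polyorder:
            raise ValueError("smooth_window must be odd and > smooth_polyorder")
        if not 0 < self.baseline_asymmetry < 1:
            raise ValueError("baseline_asymmetry must be in (0, 1)")
        if self.baseline_smoothness <= 0:
            raise ValueError("baseline_smoothness must be positive")
        if self.normalize_mode not in ("minmax", "vector"):
            raise ValueError("normalize_mode must be 'minmax' or 'vector'")


def atr_correct(spectra: SpectraSet, reference: float = 1000.0) -> SpectraSet:
    """Scale each absorbance value by nu/nu_ref (first-order penetration-depth
    compensation); the value at the reference wavenumber is unchanged."""
    wn = spectra.wavenumbers
    if not (wn.min() <= reference <= wn.max()):
        raise ValueError("reference wavenumber outside the grid range")
    return spectra.with_absorbance(spectra.absorbance * (wn / reference)[None, :])


def asls_baseline(
    y: np.ndarray, smoothness: float = 1e6, asymmetry: float = 0.01, n_iter: int = 10
) -> np.ndarray:
    """Asymmetric-least-squares baseline of a single spectrum (Eilers-Boelens).

    Solves (W + lambda D2'D2) z = W y iteratively, with weights ``asymmetry``
    above the current baseline and ``1 - asymmetry`` below, so peaks are
    largely ignored while the smooth underlying drift is tracked.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite input")
    n = y.size
    if n < 3:
        return np.zeros_like(y)
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = (smoothness * (d2.T @ d2)).tocsc()
    # upper banded form (bandwidth 2) for solveh_banded
    ab = np.zeros((3, n))
    ab[2] = penalty.diagonal(0)
    ab[1, 1:] = penalty.diagonal(1)
    ab[0, 2:] = penalty.diagonal(2)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        ab_iter = ab.copy()
        ab_iter[2] += w
        z = solveh_banded(ab_iter, w * y, lower=False)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def baseline_correct(
    spectra: SpectraSet, smoothness: float = 1e6, asymmetry: float = 0.01
) -> SpectraSet:
    """Subtract a per-spectrum AsLS baseline estimate."""
    corrected = np.empty_like(spectra.absorbance)
    for i, row in enumerate(spectra.absorbance):
        corrected[i] = row - asls_baseline(row, smoothness, asymmetry)
    return spectra.with_absorbance(corrected)


def smooth(spectra: SpectraSet, window: int = 11, polyorder: int = 3) -> SpectraSet:
    """Savitzky-Golay smoothing per spectrum."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > spectra.n_points:
        raise ValueError("window larger than the grid")
    return spectra.with_absorbance(
        savgol_filter(spectra.absorbance, window_length=window, polyorder=polyorder, axis=1)
    )


def subtract_normalize(spectra: SpectraSet, mode: str = "minmax") -> SpectraSet:
    """Subtraction + normalization: minmax maps each spectrum to [0, 1]; vector
    mode subtracts the mean and divides by the Euclidean norm."""
    x = spectra.absorbance
    if mode == "minmax":
        mins = x.min(axis=1, keepdims=True)
        shifted = x - mins
        maxima = shifted.max(axis=1, keepdims=True)
        if np.any(maxima <= 0):
            raise ValueError("constant spectrum cannot be min-max normalized")
        return spectra.with_absorbance(shifted / maxima)
    if mode == "vector":
        centered = x - x.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1, keepdims=True)
        if np.any(norms <= 0):
            raise ValueError("constant spectrum cannot be vector normalized")
        return spectra.with_absorbance(centered / norms)
    raise ValueError("mode must be 'minmax' or 'vector'")


def run_chain(spectra: SpectraSet, config: PreprocessConfig | None = None) -> SpectraSet:
    """Run the full chain in fixed order: ATR -> baseline -> smooth -> normalize."""
    if config is None:
        config = PreprocessConfig()
    out = spectra
    if config.apply_atr:
        out = atr_correct(out, config.atr_reference_wavenumber)
        logger.info("ATR correction applied (reference %.1f cm^-1)", config.atr_reference_wavenumber)
    if config.apply_baseline:
        out = baseline_correct(out, config.baseline_smoothness, config.baseline_asymmetry)
        logger.info("AsLS baseline removed (lambda=%.3g, p=%.3g)",
                    config.baseline_smoothness, config.baseline_asymmetry)
    if config.apply_smooth:
        out = smooth(out, config.smooth_window, config.smooth_polyorder)
        logger.info("Savitzky-Golay smoothing (window=%d, polyorder=%d)",
                    config.smooth_window, config.smooth_polyorder)
    if config.apply_normalize:
        out = subtract_normalize(out, config.normalize_mode)
        logger.info("subtract/normalize (%s)", config.normalize_mode)
    return out
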