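"""Synthetic ATR-FTIR spectra generator for three Ganoderma species.

Real mid-infrared spectra of *G. lucidum* (GL), *G. sinense* (GS) and
*G. tsugae* (GT) fruiting-body powder share nearly identical band positions;
the species differ only through small (1-12 cm^-1) shifts of a handful of
bands, most notably the beta-anomeric saccharide band at 892 cm^-1 (GL/GS)
versus 880 cm^-1 (GT).  The generator emulates exactly that structure: each
spectrum is a sum of Gaussian bands with per-sample amplitude variation and
center jitter, a smooth random polynomial baseline, and additive white noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import SpectraSet, WavenumberGrid

__all__ = [
    "BandTemplate",
    "ClassProfile",
    "default_band_library",
    "generate_dataset",
]

#: cm^-1 FWHM per band of the default library, broad O-H/C-H stretches down to
#: narrow fingerprint bands.
_DEFAULT_WIDTHS = (220.0, 70.0, 55.0, 30.0, 25.0, 25.0, 25.0, 25.0, 30.0, 40.0, 35.0, 20.0)

#: band centers per species (cm^-1), one tuple per class, twelve bands each.
_BAND_CENTERS = {
    "GL": (3310, 2920, 1637, 1420, 1370, 1313, 1249, 1202, 1152, 1067, 1039, 892),
    "GS": (3312, 2923, 1638, 1412, 1371, 1312, 1250, 1202, 1153, 1066, 1037, 892),
    "GT": (3307, 2923, 1634, 1418, 1372, 1311, 1249, 1201, 1154, 1068, 1041, 880),
}

#: indices of the strong bands (O-H stretch, C-H stretch, two C-O saccharide
#: bands); all other bands get a weaker default amplitude.
_STRONG_BAND_IDX = (0, 1, 9, 10)

_DEFAULT_N_SAMPLES = {"GL": 78, "GS": 20, "GT": 20}


@dataclass(frozen=True)
class BandTemplate:
    """One Gaussian absorption band.

    ``width`` is the full width at half maximum in cm^-1; ``amplitude_cv`` is
    the relative standard deviation of the per-sample amplitude and
    ``center_jitter_sd`` the standard deviation of the per-sample center
    shift (cm^-1).
    """

    center: float
    width: float
    base_amplitude: float
    amplitude_cv: float = 0.15
    center_jitter_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.base_amplitude < 0 or self.amplitude_cv < 0:
            raise ValueError("amplitude and amplitude_cv must be non-negative")


@dataclass(frozen=True)
class ClassProfile:
    """Band recipe and sample count for one species."""

    name: str
    bands: tuple[BandTemplate, ...]
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.bands:
            raise ValueError("profile needs at least one band")


def gaussian_band(wavenumbers: np.ndarray, center: float, fwhm: float, amplitude: float) -> np.ndarray:
    """Gaussian profile A*exp(-4 ln2 (nu-c)^2 / w^2) on the given axis."""
    return amplitude * np.exp(-4.0 * np.log(2.0) * ((wavenumbers - center) / fwhm) ** 2)


def default_band_library(
    amplitude_cv: float = 0.15,
    center_jitter_sd: float = 1.5,
) -> dict[str, ClassProfile]:
    """Three-species band library with the study's class sizes (78/20/20).

    Strong bands (3310, 2920, 1067, 1039 cm^-1 region) get base amplitude 1.0,
    all others 0.4 absorbance units.
    """
    library: dict[str, ClassProfile] = {}
    for name, centers in _BAND_CENTERS.items():
        bands = tuple(
            BandTemplate(
                center=float(c),
                width=_DEFAULT_WIDTHS[i],
                base_amplitude=1.0 if i in _STRONG_BAND_IDX else 0.4,
                amplitude_cv=amplitude_cv,
                center_jitter_sd=center_jitter_sd,
            )
            for i, c in enumerate(centers)
        )
        library[name] = ClassProfile(name=name, bands=bands, n_samples=_DEFAULT_N_SAMPLES[name])
    return library


def shift_band(profile: ClassProfile, band_index: int, new_center: float) -> ClassProfile:
    """Profile copy with one band moved — used to widen or shrink class contrast."""
    bands = list(profile.bands)
    bands[band_index] = replace(bands[band_index], center=float(new_center))
    return replace(profile, bands=tuple(bands))


def generate_dataset(
    profiles: dict[str, ClassProfile] | None = None,
    grid: WavenumberGrid | None = None,
    baseline_order: int = 2,
    baseline_scale: float = 0.1,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> SpectraSet:
    """Draw a labelled synthetic dataset.

    Each spectrum is ``sum of Gaussian bands + polynomial baseline + noise``:
    band amplitudes are drawn as ``base_amplitude * (1 + cv * z)`` (clipped at
    zero), centers jittered by ``N(0, center_jitter_sd)``, the baseline is a
    random polynomial of ``baseline_order`` whose coefficients are uniform in
    ``+-baseline_scale * max band amplitude``, and the noise is i.i.d.
    ``N(0, noise_sd)`` per grid point.  Identical seeds give bit-identical
    output.
    """
    if profiles is None:
        profiles = default_band_library()
    if not profiles:
        raise ValueError("empty profile list")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if grid is None:
        grid = WavenumberGrid()
    rng = np.random.default_rng(seed)
    wn = grid.values
    # normalized axis in [0, 1] for the baseline polynomial
    x01 = (wn - wn.min()) / (wn.max() - wn.min())

    rows: list[np.ndarray] = []
    labels: list[str] = []
    ids: list[str] = []
    for name, profile in profiles.items():
        max_amp = max(b.base_amplitude for b in profile.bands)
        for j in range(profile.n_samples):
            spectrum = np.zeros_like(wn)
            for band in profile.bands:
                amp = band.base_amplitude * (1.0 + band.amplitude_cv * rng.standard_normal())
                amp = max(amp, 0.0)
                center = band.center + (
                    band.center_jitter_sd * rng.standard_normal() if band.center_jitter_sd > 0 else 0.0
                )
                spectrum += gaussian_band(wn, center, band.width, amp)
            if baseline_scale > 0:
                coeffs = rng.uniform(-baseline_scale * max_amp, baseline_scale * max_amp, baseline_order + 1)
                spectrum += np.polynomial.polynomial.polyval(x01, coeffs)
            if noise_sd > 0:
                spectrum += noise_sd * rng.standard_normal(wn.size)
            rows.append(spectrum)
            labels.append(name)
            ids.append(f"{name}_{j:03d}")

    return SpectraSet(
        wavenumbers=wn,
        absorbance=np.vstack(rows),
        labels=np.asarray(labels, dtype=object),
        sample_ids=ids,
    )
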