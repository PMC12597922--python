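"""Core container for labelled ATR-FTIR absorbance spectra on a shared wavenumber grid."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["WavenumberGrid", "SpectraSet"]


@dataclass(frozen=True)
class WavenumberGrid:
    """Evenly spaced wavenumber axis, stored high-to-low (instrument convention).

    Parameters
    ----------
    start, stop : float
        First and last wavenumber in cm^-1; ``start > stop`` because FTIR
        spectra are plotted from high to low wavenumber.
    step : float
        Grid spacing in cm^-1 (positive).
    """

    start: float = 4000.0
    stop: float = 400.0
    step: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", float(self.start))
        object.__setattr__(self, "stop", float(self.stop))
        object.__setattr__(self, "step", float(self.step))
        if not self.start > self.stop:
            raise ValueError("grid must be descending: start > stop")
        if not self.step > 0:
            raise ValueError("step must be positive")
        span = (self.start - self.stop) / self.step
        if abs(span - round(span)) > 1e-9:
            raise ValueError("(start - stop)/step must be an integer point count")

    @property
    def n_points(self) -> int:
        return int(round((self.start - self.stop) / self.step)) + 1

    @property
    def values(self) -> np.ndarray:
        """Wavenumbers in cm^-1, descending."""
        return self.start - self.step * np.arange(self.n_points)

    @classmethod
    def from_values(cls, wavenumbers: np.ndarray) -> "WavenumberGrid":
        wn = np.asarray(wavenumbers, dtype=float)
        if wn.size < 2:
            raise ValueError("need at least two wavenumbers")
        steps = np.diff(wn)
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6) or steps[0] >= 0:
            raise ValueError("wavenumbers must be evenly spaced and descending")
        return cls(start=float(wn[0]), stop=float(wn[-1]), step=float(-steps[0]))


@dataclass
class SpectraSet:
    """Absorbance matrix with one row per sample plus labels and unique ids.

    ``wavenumbers`` must be strictly monotone (normally descending, 4000 -> 400),
    ``absorbance`` is ``(n_samples, n_points)`` and all-finite.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(self.absorbance.shape[0])]
        diffs = np.diff(self.wavenumbers)
        if self.wavenumbers.size > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("wavenumbers must be strictly monotone")
        n = self.absorbance.shape[0]
        if self.absorbance.shape[1] != self.wavenumbers.size:
            raise ValueError("absorbance columns must match wavenumber count")
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise ValueError("labels/sample_ids length must match sample count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    @property
    def classes(self) -> list[str]:
        """Class labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(str(lab), None)
        return list(seen)

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.classes}

    def select(self, indices: Sequence[int] | np.ndarray) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=self.absorbance[idx].copy(),
            labels=self.labels[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def select_ids(self, ids: Iterable[str]) -> "SpectraSet":
        pos = {sid: i for i, sid in enumerate(self.sample_ids)}
        return self.select([pos[s] for s in ids])

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        """Copy of this set with a replaced (same-shape) absorbance matrix."""
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=np.asarray(absorbance, dtype=float),
            labels=self.labels.copy(),
            sample_ids=list(self.sample_ids),
        )

    def downsample(self, every: int) -> "SpectraSet":
        """Keep every ``every``-th grid point (coarser axis for desk-scale models)."""
        if every < 1:
            raise ValueError("every must be >= 1")
        return SpectraSet(
            wavenumbers=self.wavenumbers[::every].copy(),
            absorbance=self.absorbance[:, ::every].copy(),
            labels=self.labels.copy(),
            sample_ids=list(self.sample_ids),
        )
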