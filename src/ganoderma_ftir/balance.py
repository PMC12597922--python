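"""Group A/B design and SMOTE class balancing.

The deep-learning track halves the dataset into two mutually exclusive,
class-stratified groups (train group A, test group B) and oversamples every
class in both groups independently to a common per-class target with SMOTE
(synthetic minority oversampling): each synthetic sample is drawn on the
segment between a random original and one of its k nearest same-class,
same-group neighbours.  Oversampling the test group mirrors the original
experimental design; ``balance_groups(..., oversample_test=False)`` disables
it.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .dataset import SpectraSet

__all__ = [
    "GroupAssignment",
    "SmoteConfig",
    "split_groups",
    "smote_oversample",
    "balance_groups",
]

#: per-class oversampling target of the original design
DEFAULT_TARGET_PER_CLASS = 500


@dataclass(frozen=True)
class GroupAssignment:
    """Mutually exclusive half-split of sample ids."""

    group_a_ids: tuple[str, ...]
    group_b_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.group_a_ids) & set(self.group_b_ids):
            raise ValueError("groups must be disjoint")


@dataclass(frozen=True)
class SmoteConfig:
    """k nearest neighbours, per-class target count and seed."""

    k_neighbors: int = 5
    target_per_class: int = DEFAULT_TARGET_PER_CLASS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target_per_class < 1:
            raise ValueError("target_per_class must be >= 1")


def split_groups(spectra: SpectraSet, seed: int = 0) -> GroupAssignment:
    """Stratified half-split: per class, |nA - nB| <= 1, no overlap."""
    rng = np.random.default_rng(seed)
    a_ids: list[str] = []
    b_ids: list[str] = []
    for cls in spectra.classes:
        idx = np.flatnonzero(spectra.labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        perm = rng.permutation(idx)
        n_a = (idx.size + 1) // 2
        a_ids.extend(spectra.sample_ids[i] for i in perm[:n_a])
        b_ids.extend(spectra.sample_ids[i] for i in perm[n_a:])
    return GroupAssignment(group_a_ids=tuple(a_ids), group_b_ids=tuple(b_ids))


def smote_oversample(class_matrix: np.ndarray, config: SmoteConfig) -> np.ndarray:
    """Oversample one class to ``target_per_class`` rows.

    The originals are returned first, unchanged.  Each synthetic row is
    ``x_i + lambda * (x_nn - x_i)`` with ``lambda ~ U(0, 1)`` and ``x_nn`` one
    of the k nearest Euclidean neighbours (self excluded) of a uniformly
    chosen original ``x_i``.  k is capped at ``class size - 1``.
    """
    x = np.atleast_2d(np.asarray(class_matrix, dtype=float))
    n = x.shape[0]
    if n < 2 and config.target_per_class > n:
        raise ValueError("cannot oversample a class with a single sample (no neighbour)")
    if config.target_per_class < n:
        raise ValueError("target_per_class must be >= original class size")
    n_new = config.target_per_class - n
    if n_new == 0:
        return x.copy()

    k = min(config.k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    # first neighbour of each point is itself; drop it
    neighbor_idx = nn.kneighbors(x, return_distance=False)[:, 1:]

    rng = np.random.default_rng(config.seed)
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    lam = rng.uniform(0.0, 1.0, size=n_new)
    partners = neighbor_idx[base, pick]
    synthetic = x[base] + lam[:, None] * (x[partners] - x[base])
    return np.vstack([x, synthetic])


def _stage_seed(seed: int, tag: str) -> int:
    """Stable per-(group, class) sub-seed so groups stay independent."""
    return (seed ^ zlib.crc32(tag.encode())) % (2**31)


def _balance_one_group(
    spectra: SpectraSet, ids: tuple[str, ...], config: SmoteConfig, group_tag: str
) -> SpectraSet:
    group = spectra.select_ids(ids)
    rows: list[np.ndarray] = []
    labels: list[str] = []
    out_ids: list[str] = []
    for cls in group.classes:
        mask = group.labels == cls
        sub = group.absorbance[mask]
        sub_ids = [sid for sid, m in zip(group.sample_ids, mask) if m]
        cls_config = SmoteConfig(
            k_neighbors=config.k_neighbors,
            target_per_class=config.target_per_class,
            seed=_stage_seed(config.seed, f"{group_tag}:{cls}"),
        )
        grown = smote_oversample(sub, cls_config)
        rows.append(grown)
        labels.extend([cls] * grown.shape[0])
        out_ids.extend(sub_ids)
        out_ids.extend(
            f"{cls}_syn{group_tag}_{i:04d}" for i in range(grown.shape[0] - len(sub_ids))
        )
    return SpectraSet(
        wavenumbers=group.wavenumbers,
        absorbance=np.vstack(rows),
        labels=np.asarray(labels, dtype=object),
        sample_ids=out_ids,
    )


def balance_groups(
    spectra: SpectraSet,
    assignment: GroupAssignment,
    config: SmoteConfig | None = None,
    oversample_test: bool = True,
) -> tuple[SpectraSet, SpectraSet]:
    """SMOTE both groups to the per-class target, independently.

    Neighbour search and interpolation never cross groups or classes, and the
    sub-seed of each (group, class) cell depends only on the master seed and
    the cell tag, so group B's synthesis is unaffected by group A's content.
    """
    if config is None:
        config = SmoteConfig()
    group_a = _balance_one_group(spectra, assignment.group_a_ids, config, "A")
    if oversample_test:
        group_b = _balance_one_group(spectra, assignment.group_b_ids, config, "B")
    else:
        group_b = spectra.select_ids(assignment.group_b_ids)
    return group_a, group_b
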