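"""Shared fixtures: small synthetic datasets sized for fast unit tests."""

import numpy as np
import pytest

from ganoderma_ftir.dataset import SpectraSet, WavenumberGrid
from ganoderma_ftir.synthetic import BandTemplate, ClassProfile, generate_dataset


@pytest.fixture
def small_grid() -> WavenumberGrid:
    return WavenumberGrid(start=1800.0, stop=800.0, step=4.0)  # 251 points


def make_small_profiles(n_per_class=(12, 8, 8), jitter=1.0, cv=0.1):
    """Three well-separated classes with a handful of fingerprint bands."""
    def band(center, width=30.0, amp=0.8):
        return BandTemplate(center=center, width=width, base_amplitude=amp,
                            amplitude_cv=cv, center_jitter_sd=jitter)

    return {
        "A": ClassProfile("A", (band(1600), band(1200), band(950)), n_per_class[0]),
        "B": ClassProfile("B", (band(1560), band(1250), band(950)), n_per_class[1]),
        "C": ClassProfile("C", (band(1600), band(1200), band(880)), n_per_class[2]),
    }


@pytest.fixture
def small_dataset(small_grid) -> SpectraSet:
    return generate_dataset(
        make_small_profiles(), small_grid, baseline_order=1, baseline_scale=0.05,
        noise_sd=0.005, seed=11,
    )


@pytest.fixture
def toy_labelled_set() -> SpectraSet:
    """118-sample label structure (78/20/20) on a trivially small grid."""
    rng = np.random.default_rng(0)
    labels = ["GL"] * 78 + ["GS"] * 20 + ["GT"] * 20
    return SpectraSet(
        wavenumbers=np.array([1000.0, 999.0, 998.0]),
        absorbance=rng.normal(size=(118, 3)),
        labels=np.asarray(labels, dtype=object),
        sample_ids=[f"s{i}" for i in range(118)],
    )
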