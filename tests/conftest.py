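"""Shared fixtures: small synthetic cohorts and toy spectra."""

from __future__ import annotations

import numpy as np
import pytest

from ramancnn.dataset import SpectralDataset, Spectrum
from ramancnn.simulate import CohortConfig, PeakSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_grid() -> np.ndarray:
    return np.linspace(614.0, 1722.0, 101)


@pytest.fixture(scope="session")
def small_cohort() -> SpectralDataset:
    """12-patient two-layer cohort with a discriminative band; fast to build."""
    cfg = CohortConfig(
        n_positive_patients=6,
        n_control_patients=6,
        spectra_per_patient=(3, 4),
        n_points=201,
        peaks=(
            PeakSpec(830.0, 12.0, 0.8, 1.6, 0.1),
            PeakSpec(1330.0, 15.0, 1.0, 1.0, 0.1),
        ),
        baseline_scale=0.3,
        noise_sd=0.01,
        cosmic_ray_rate=0.0,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def toy_spectrum(tiny_grid) -> Spectrum:
    rng = np.random.default_rng(7)
    y = 1.0 + 0.5 * np.exp(-0.5 * ((tiny_grid - 1000.0) / 30.0) ** 2)
    y += rng.normal(0, 0.005, tiny_grid.size)
    return Spectrum(
        wavenumbers=tiny_grid,
        intensities=y,
        patient_id="P1",
        condition="OA",
        layer="superficial",
        region="A",
        gender="female",
    )
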