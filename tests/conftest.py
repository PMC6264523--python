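"""Shared fixtures: tiny bundles and the session-scoped simulation study."""

from __future__ import annotations

import numpy as np
import pytest

from laftree.model import AlleleCombination, MeasurementBundle, ModelConfig
from laftree.simulate import SimulationConfig, generate_measurements, simulate_tumor
from laftree.study import chance_level, run_study

AB = AlleleCombination(1, 1)


def make_bundle(af, arms=None, snv_af=None, snv_arms=None, names=None):
    """Build a MeasurementBundle from a plain AF array (one arm by default)."""
    af = np.asarray(af, dtype=float)
    n, m = af.shape
    names = names or ["healthy"] + [f"S{i}" for i in range(1, m)]
    arms = arms or [("1", "p")] * n
    positions = [(c, a, 10 * (i + 1)) for i, (c, a) in enumerate(arms)]
    if snv_af is None:
        snv_af = np.zeros((0, m))
        snv_positions = []
    else:
        snv_af = np.asarray(snv_af, dtype=float)
        snv_arms = snv_arms or [("1", "p")] * snv_af.shape[0]
        snv_positions = [(c, a, 5 + 10 * k) for k, (c, a) in enumerate(snv_arms)]
    return MeasurementBundle(
        af=af,
        positions=positions,
        snv_af=snv_af,
        snv_positions=snv_positions,
        sample_names=names,
        normal_index=0,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One seeded simulated tumor with measurements (shared, read-only)."""
    config = SimulationConfig(n_snps=150, seed=42, mu=0.9)
    rng = np.random.default_rng(42)
    truth = simulate_tumor(config, rng)
    bundle = generate_measurements(truth, config, rng)
    return bundle, truth, config


@pytest.fixture(scope="session")
def study_results():
    """The scaled-down simulation study used by the acceptance checks.

    30 datasets at sigma = 0.02 with one uniform-random tumor fraction each.
    """
    return run_study(n_datasets=30, noise_sigma=0.02, n_snps=200, seed=1)


@pytest.fixture(scope="session")
def chance_results():
    """Chance-level reference errors from uniform-random measurements."""
    return chance_level(n_datasets=5, noise_sigma=0.02, n_snps=200, seed=900)


@pytest.fixture()
def config():
    return ModelConfig(rng_seed=0)
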