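"""Clonal-evolution simulator: determinism, noise moments, calibration."""

import numpy as np
import pytest

from laftree.metrics import is_ambiguous
from laftree.model import expected_laf
from laftree.simulate import (
    ARMS,
    SimulationConfig,
    generate_measurements,
    generate_random_dataset,
    mix_contamination,
    simulate_dataset,
    simulate_tumor,
)


class TestSimulateTumor:
    def test_zero_rounds_healthy_only(self):
        cfg = SimulationConfig(rounds=0, seed=1)
        truth = simulate_tumor(cfg, np.random.default_rng(1))
        assert truth.sample_names == ["healthy"]
        assert truth.tree.edges() == frozenset()

    def test_seeded_determinism(self):
        a = simulate_dataset(SimulationConfig(n_snps=80, seed=9))
        b = simulate_dataset(SimulationConfig(n_snps=80, seed=9))
        assert a[1].sample_names == b[1].sample_names
        assert np.array_equal(a[0].af, b[0].af)
        assert np.array_equal(a[0].snv_af, b[0].snv_af)
        assert a[1].tree.edges() == b[1].tree.edges()

    def test_viability_bounds_respected(self):
        for seed in range(5):
            truth = simulate_tumor(
                SimulationConfig(seed=seed), np.random.default_rng(seed)
            )
            for name in truth.sample_names:
                total = truth.arm_a[name] + truth.arm_b[name]
                assert total.min() >= 1 and total.max() <= 6

    def test_mean_sample_count_near_five(self):
        counts = [
            len(
                simulate_tumor(
                    SimulationConfig(seed=s), np.random.default_rng(s)
                ).sample_names
            )
            for s in range(120)
        ]
        assert 4.3 <= np.mean(counts) <= 6.0

    def test_snvs_nested_along_lineage(self):
        truth = simulate_tumor(SimulationConfig(seed=3), np.random.default_rng(3))
        for child, parent in truth.tree.parent.items():
            if parent is None:
                continue
            lost = truth.snv_sets[parent] - truth.snv_sets[child]
            # SNVs are only lost together with their carrying allele (rare)
            assert len(lost) <= 3


class TestGenerateMeasurements:
    def test_noise_free_laf_matches_expectation(self):
        cfg = SimulationConfig(n_snps=120, noise_sigma=0.0, seed=5, mu=0.8)
        rng = np.random.default_rng(5)
        truth = simulate_tumor(cfg, rng)
        bundle = generate_measurements(truth, cfg, rng)
        for j, name in enumerate(truth.sample_names):
            mu = 0.0 if name == truth.healthy else truth.mu
            for i in range(bundle.n_positions):
                want = expected_laf(truth.a_matrix[i][j], mu)
                assert bundle.laf[i, j] == pytest.approx(want, abs=1e-12)

    def test_noise_moment_recovered(self):
        cfg = SimulationConfig(n_snps=400, noise_sigma=0.02, seed=6, mu=0.9)
        rng = np.random.default_rng(6)
        truth = simulate_tumor(cfg, rng)
        bundle = generate_measurements(truth, cfg, rng)
        resid = []
        for j, name in enumerate(truth.sample_names):
            mu = 0.0 if name == truth.healthy else truth.mu
            for i in range(bundle.n_positions):
                want = expected_laf(truth.a_matrix[i][j], mu)
                if 0.05 < want < 0.45:  # away from fold/clip boundaries
                    resid.append(bundle.laf[i, j] - want)
        assert np.std(resid) == pytest.approx(0.02, abs=0.005)

    def test_positions_spread_over_arms(self):
        cfg = SimulationConfig(n_snps=4400, seed=7)
        rng = np.random.default_rng(7)
        truth = simulate_tumor(cfg, rng)
        bundle = generate_measurements(truth, cfg, rng)
        counts = np.bincount(truth.snp_arm_idx, minlength=len(ARMS))
        # multinomial with equal expected mass per arm (100 per arm here)
        assert counts.min() > 50 and counts.max() < 160

    def test_pure_tumor_loh_laf_near_zero(self):
        cfg = SimulationConfig(n_snps=200, seed=11, mu=1.0, noise_sigma=0.0)
        rng = np.random.default_rng(11)
        truth = simulate_tumor(cfg, rng)
        bundle = generate_measurements(truth, cfg, rng)
        for j, name in enumerate(truth.sample_names):
            if name == truth.healthy:
                continue
            for i in range(bundle.n_positions):
                al = truth.a_matrix[i][j]
                if min(al.a_count, al.b_count) == 0:
                    assert bundle.laf[i, j] == pytest.approx(0.0, abs=1e-12)


class TestRandomDataset:
    def test_uniform_tumor_columns(self, small_dataset):
        bundle, truth, _ = small_dataset
        rand = generate_random_dataset(bundle, seed=123)
        tumor = rand.af[:, 1:]
        assert 0.4 < tumor.mean() < 0.6
        assert (rand.laf >= 0).all() and (rand.laf <= 0.5).all()
        # healthy column untouched
        assert np.array_equal(rand.af[:, 0], bundle.af[:, 0])


class TestContamination:
    def test_zero_contamination_matches_clean_measurements(self):
        cfg = SimulationConfig(n_snps=100, seed=21, mu=0.8, noise_sigma=0.0)
        rng = np.random.default_rng(21)
        truth = simulate_tumor(cfg, rng)
        bundle = generate_measurements(truth, cfg, rng)
        mixed = mix_contamination(
            truth, cfg, contamination=0.0, n_minors=2, rng=np.random.default_rng(1)
        )
        assert np.allclose(mixed.af[:, 1:], bundle.af[:, 1:], atol=1e-12)

    def test_fifty_fifty_mixture_is_linear(self):
        cfg = SimulationConfig(n_snps=100, seed=22, mu=0.8, noise_sigma=0.0)
        rng = np.random.default_rng(22)
        truth = simulate_tumor(cfg, rng)
        generate_measurements(truth, cfg, rng)
        if len(truth.tumor_names()) < 2:
            pytest.skip("needs two subclones")
        mixed = mix_contamination(
            truth, cfg, contamination=0.5, n_minors=1, rng=np.random.default_rng(2)
        )
        mu = truth.mu
        arm_idx = truth.snp_arm_idx
        # every tumor column must be a 50/50 blend of two subclones + healthy
        for j, name in enumerate(truth.sample_names):
            if name == truth.healthy:
                continue
            found = False
            for other in truth.tumor_names():
                if other == name:
                    continue
                b = 0.5 * mu * (truth.arm_b[name] + truth.arm_b[other])[arm_idx]
                c = 0.5 * mu * (
                    truth.arm_a[name]
                    + truth.arm_b[name]
                    + truth.arm_a[other]
                    + truth.arm_b[other]
                )[arm_idx]
                want = (b + (1 - mu)) / (c + 2 * (1 - mu))
                if np.allclose(mixed.af[:, j], want, atol=1e-12):
                    found = True
            assert found

    def test_minor_majority_rejected(self, small_dataset):
        _, truth, cfg = small_dataset
        with pytest.raises(ValueError):
            mix_contamination(
                truth, cfg, contamination=0.6, n_minors=1, rng=np.random.default_rng(0)
            )


class TestAmbiguityCalibration:
    def test_three_quarters_of_positions_ambiguous(self):
        """Across tumors with uniform-random tumor fractions, ~75% of
        ground-truth positions admit more than one allele explanation."""
        fracs = []
        for s in range(40):
            cfg = SimulationConfig(n_snps=100, seed=1000 + s)
            rng = np.random.default_rng(1000 + s)
            truth = simulate_tumor(cfg, rng)
            bundle = generate_measurements(truth, cfg, rng)
            col = {n: j for j, n in enumerate(truth.sample_names)}
            flags = [
                is_ambiguous(truth.a_matrix[i][col[n]], truth.mu)
                for n in truth.tumor_names()
                for i in range(bundle.n_positions)
            ]
            fracs.append(np.mean(flags))
        assert 0.65 <= np.mean(fracs) <= 0.85
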