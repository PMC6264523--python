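"""The scaled-down simulation study: simulate, infer, score, aggregate.

One helper drives the closed loop used by the benchmark command and the
reproducibility script: for each replicate a tumor is simulated with its own
uniform-random tumor fraction, the full iterative inference is run, and the
four error metrics plus the ambiguity report are collected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import ErrorReport, ambiguity_report, evaluate_run
from .model import ModelConfig
from .simulate import (
    SimulationConfig,
    SimulationTruth,
    generate_measurements,
    generate_random_dataset,
    simulate_tumor,
)
from .tstep import InferenceResult, run_inference


@dataclass
class StudyRecord:
    """One replicate's truth, inference result and scores."""

    seed: int
    truth: SimulationTruth
    result: InferenceResult
    report: ErrorReport
    n_ambiguous: int
    n_resolved: int
    n_positions: int


def run_replicate(
    seed: int,
    noise_sigma: float = 0.02,
    n_snps: int = 200,
    n_snvs: int = 50,
    mu: float | None = None,
    model_config: ModelConfig | None = None,
) -> StudyRecord:
    sim_config = SimulationConfig(
        n_snps=n_snps, n_snvs=n_snvs, noise_sigma=noise_sigma, mu=mu, seed=seed
    )
    rng = np.random.default_rng(seed % 2**31)
    truth = simulate_tumor(sim_config, rng)
    bundle = generate_measurements(truth, sim_config, rng)
    config = model_config or ModelConfig(rng_seed=seed % 2**31)
    result = run_inference(bundle, config)
    report = evaluate_run(truth, result.estimates, result.tree)
    frac_amb, frac_res, n_amb, n_total = ambiguity_report(
        truth, result.estimates, config.kmin, config.kmax
    )
    n_resolved = 0 if n_amb == 0 else int(round(frac_res * n_amb))
    return StudyRecord(
        seed=seed,
        truth=truth,
        result=result,
        report=report,
        n_ambiguous=n_amb,
        n_resolved=n_resolved,
        n_positions=n_total,
    )


def run_study(
    n_datasets: int = 20,
    noise_sigma: float = 0.02,
    n_snps: int = 200,
    n_snvs: int = 50,
    seed: int = 1,
    model_config: ModelConfig | None = None,
) -> dict:
    """Aggregate metrics over replicates with per-dataset random tumor fractions."""
    records = [
        run_replicate(
            seed=(seed * 100_003 + k) % 2**31,
            noise_sigma=noise_sigma,
            n_snps=n_snps,
            n_snvs=n_snvs,
            model_config=model_config,
        )
        for k in range(n_datasets)
    ]
    n_amb = sum(r.n_ambiguous for r in records)
    n_res = sum(r.n_resolved for r in records)
    n_tot = sum(r.n_positions for r in records)
    return {
        "n_datasets": n_datasets,
        "e_c": float(np.mean([r.report.e_c for r in records])),
        "e_a": float(np.mean([r.report.e_a for r in records])),
        "e_mu": float(np.mean([r.report.e_mu for r in records])),
        "e_t": float(np.mean([r.report.e_t for r in records])),
        "frac_ambiguous": float(
            np.mean([r.n_ambiguous / r.n_positions for r in records])
        ),
        "frac_resolved": n_res / n_amb if n_amb else float("nan"),
        "n_ambiguous": n_amb,
        "n_positions": n_tot,
        "records": records,
    }


def chance_level(
    n_datasets: int = 5,
    noise_sigma: float = 0.02,
    n_snps: int = 200,
    n_snvs: int = 50,
    seed: int = 900,
    model_config: ModelConfig | None = None,
) -> dict:
    """Mean errors when tumor measurements are replaced by uniform noise."""
    reports = []
    for k in range(n_datasets):
        rep_seed = (seed * 100_003 + k) % 2**31
        sim_config = SimulationConfig(
            n_snps=n_snps, n_snvs=n_snvs, noise_sigma=noise_sigma, seed=rep_seed
        )
        rng = np.random.default_rng(rep_seed)
        truth = simulate_tumor(sim_config, rng)
        bundle = generate_measurements(truth, sim_config, rng)
        random_bundle = generate_random_dataset(bundle, rep_seed + 7)
        config = model_config or ModelConfig(rng_seed=rep_seed)
        result = run_inference(random_bundle, config)
        reports.append(evaluate_run(truth, result.estimates, result.tree))
    return {
        "e_c": float(np.mean([r.e_c for r in reports])),
        "e_a": float(np.mean([r.e_a for r in reports])),
        "e_mu": float(np.mean([r.e_mu for r in reports])),
        "e_t": float(np.mean([r.e_t for r in reports])),
    }
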