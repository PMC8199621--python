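"""Shared fixtures: synthetic datasets and the expensive pipeline run."""

import numpy as np
import pytest

from xenopsc import SimConfig, generate_xenograft_samples
from xenopsc.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_run():
    """Default-condition synthetic experiment (seed 1)."""
    cfg = SimConfig(seed=1)
    samples, truth = generate_xenograft_samples(cfg)
    return cfg, samples, truth


@pytest.fixture(scope="session")
def clean_run():
    """Noise-free experiment: no ambient contamination, no doublets."""
    cfg = SimConfig(seed=1, alpha=0.0, delta=0.0)
    samples, truth = generate_xenograft_samples(cfg)
    return cfg, samples, truth


@pytest.fixture(scope="session")
def pipeline_result(default_run):
    """Full three-approach classification on the default synthetic run."""
    from xenopsc.classify import run_rarecell_pipeline

    _, samples, truth = default_run
    truth_i = truth.set_index("barcode")
    ref = truth_i.loc[samples["Cult"].barcodes, "true_type"]
    res = run_rarecell_pipeline(samples, ref, seed=0)
    return res, truth_i


@pytest.fixture(scope="session")
def default_cohort():
    cfg = CohortConfig(seed=1)
    records, series, truth = generate_cohort(cfg)
    return cfg, records, series, truth


def y_manifold(rng: np.random.Generator, n: int = 600, noise: float = 0.05):
    """Planted Y-shaped 2-D manifold: a trunk and two diverging arms.

    Returns (coords, arm_label in {0 trunk, 1 arm A, 2 arm B}, latent time).
    """
    n1 = n // 3
    t1 = rng.uniform(0, 1, n1)
    t2 = rng.uniform(0, 1, n1)
    t3 = rng.uniform(0, 1, n - 2 * n1)
    trunk = np.column_stack([t1, np.zeros(n1)])
    arm_a = np.column_stack([1 + 0.8 * t2, 0.8 * t2])
    arm_b = np.column_stack([1 + 0.8 * t3, -0.8 * t3])
    coords = np.vstack([trunk, arm_a, arm_b]) + rng.normal(0, noise, (n, 2))
    labels = np.r_[np.zeros(n1), np.ones(n1), 2 * np.ones(n - 2 * n1)].astype(int)
    latent = np.r_[t1, 1 + t2, 1 + t3]
    return coords, labels, latent
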