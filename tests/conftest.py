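"""Shared fixtures: small synthetic cohorts and a trained toy network."""

from __future__ import annotations

import numpy as np
import pytest

from strainpheno.io_preprocess import normalize_time
from strainpheno.synthetic import CovariateModel, CurveTemplateParams, simulate_subject
from strainpheno.tcn import DilatedCausalNet, NetworkConfig, train_network


@pytest.fixture(scope="session")
def covariates() -> CovariateModel:
    return CovariateModel()


@pytest.fixture(scope="session")
def noise_free_params() -> CurveTemplateParams:
    return CurveTemplateParams(noise_sd_pct=0.0)


@pytest.fixture(scope="session")
def separable_cohort(covariates, noise_free_params):
    """Noise-free phenotype-D carriers vs controls: linearly separable."""
    records = []
    for i in range(50):
        records.append(
            simulate_subject(
                "carrier", "D", covariates, seed=1000 + i, params=noise_free_params,
                subject_id=f"CAR{i:03d}",
            )
        )
        records.append(
            simulate_subject(
                "control", "CONTROL", covariates, seed=2000 + i, params=noise_free_params,
                subject_id=f"CON{i:03d}",
            )
        )
    X = np.stack([normalize_time(r).matrix for r in records])
    y = np.array([1.0, 0.0] * 50)
    return records, X, y


@pytest.fixture(scope="session")
def toy_network(separable_cohort):
    """A small network trained to separate the toy cohort."""
    _, X, y = separable_cohort
    cfg = NetworkConfig(
        n_feature_maps=8, n_levels=3, kernel_size=3, dropout=0.1,
        max_epochs=30, patience=10, seed=0,
    )
    net = DilatedCausalNet(cfg)
    train_network(net, X[:80], y[:80], X[80:], y[80:], seed=5)
    return net, X, y
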