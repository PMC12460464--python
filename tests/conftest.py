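"""Shared fixtures: toy-scale simulations and trained models.

The expensive end-to-end experiments (strong-signal accuracy, the
beta/KL grid, importance recovery with a permutation null) are
session-scoped so both the unit suite and the acceptance suite reuse a
single computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fcadapt.evaluate import gaussian_kl
from fcadapt.importance import feature_scores, permutation_null
from fcadapt.synthetic import SimulationConfig, SiteSpec, simulate_cohort
from fcadapt.vae_mmd import VAEMMDClassifier

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# reduced architecture used throughout the toy experiments
TOY_NET = dict(enc1_dim=128, enc2_dim=64, z1_dim=32, z2_dim=16)
TINY_NET = dict(enc1_dim=32, enc2_dim=16, z1_dim=8, z2_dim=4)


def strong_signal_config(seed: int = 0) -> SimulationConfig:
    """Strong class signal, no site effects: 30 ROIs, 0.6 z-units, 60/class."""
    return SimulationConfig(
        n_rois=30,
        class_effect=0.6,
        site_additive_sd=0.0,
        site_scale_range=(1.0, 1.0),
        seed=seed,
    )


def site_shifted_config(seed: int = 1) -> SimulationConfig:
    """Moderate class signal with the default site location/scale shifts."""
    return SimulationConfig(n_rois=30, class_effect=0.3, seed=seed)


def split_target(manifest, rng_seed=0, n_test=60):
    """Deterministically split target-domain rows into held-out test/train."""
    dom = np.array([r.domain for r in manifest.records], dtype=object)
    tgt = np.flatnonzero(dom == "target")
    rng = np.random.default_rng(rng_seed)
    rng.shuffle(tgt)
    return tgt[:n_test], np.concatenate([np.flatnonzero(dom != "target"), tgt[n_test:]])


@pytest.fixture(scope="session")
def strong_signal_run():
    """Train on the strong-signal cohort with target labels hidden."""
    X, manifest, truth = simulate_cohort(strong_signal_config())
    dom = np.array([r.domain for r in manifest.records], dtype=object)
    y = np.array([r.diagnosis for r in manifest.records], dtype=object)
    test_rows, fit_rows = split_target(manifest)
    y_fit = y.copy()
    y_fit[dom == "target"] = "unknown"
    clf = VAEMMDClassifier(**TOY_NET, alpha=500.0, beta=1.0, epochs=50, seed=0)
    clf.fit(X[fit_rows], y_fit[fit_rows], domain=dom[fit_rows])
    pred = clf.predict(X[test_rows], domain=dom[test_rows])
    return {
        "clf": clf,
        "X": X,
        "y": y,
        "domain": dom,
        "truth": truth,
        "test_rows": test_rows,
        "target_test_accuracy": float(np.mean(pred == y[test_rows])),
    }


@pytest.fixture(scope="session")
def beta_kl_grid():
    """Residual source-target latent KL for beta in {0, 1, 10}, 5 seeds."""
    X, manifest, _ = simulate_cohort(site_shifted_config())
    dom = np.array([r.domain for r in manifest.records], dtype=object)
    y = np.array([r.diagnosis for r in manifest.records], dtype=object)
    y_fit = y.copy()
    y_fit[dom == "target"] = "unknown"
    grid: dict[float, list[float]] = {0.0: [], 1.0: [], 10.0: []}
    for seed in range(5):
        for beta in grid:
            clf = VAEMMDClassifier(
                **TOY_NET, alpha=500.0, beta=beta, epochs=20, seed=seed
            )
            clf.fit(X, y_fit, domain=dom)
            z = clf.encode(X, domain=dom)
            grid[beta].append(gaussian_kl(z[dom != "target"], z[dom == "target"]))
    return grid


def importance_training_factory():
    """Reduced-dims importance experiment: data, labels, and a train_fn."""
    sites = [SiteSpec("s0", "source", {c: 40 for c in ("control", "autism", "asperger")})]
    config = SimulationConfig(
        n_rois=15,
        sites=sites,
        class_effect=0.6,
        n_affected=10,
        site_additive_sd=0.0,
        site_scale_range=(1.0, 1.0),
        seed=0,
    )
    X, manifest, truth = simulate_cohort(config)
    y = np.array([r.diagnosis for r in manifest.records], dtype=object)

    def train_fn(X_in, seed):
        clf = VAEMMDClassifier(
            **TINY_NET, alpha=500.0, beta=0.0, epochs=30,
            learning_rate=3e-3, seed=seed,
        ).fit(X_in, y)
        return feature_scores(clf.w1_checkpoints_, input_dim=X_in.shape[1])

    return X, y, truth, train_fn


@pytest.fixture(scope="session")
def importance_recovery():
    """Observed scores plus a 100-permutation null on the reduced problem."""
    X, y, truth, train_fn = importance_training_factory()
    observed = train_fn(X, 0)
    null = permutation_null(train_fn, X, n_perm=100, seed=1)
    k = len(truth.affected_features)
    top_k = np.argsort(-observed)[:k]
    precision_at_k = len(set(top_k) & set(truth.affected_features.tolist())) / k
    return {
        "observed": observed,
        "null": null,
        "truth": truth,
        "precision_at_k": precision_at_k,
    }
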