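"""Shared fixtures: scaled-down study conditions for fast simulation tests.

The biologically plausible network is exercised at a reduced scale (K=3
clusters in 8 input dimensions, a handful of granule cells) so that whole
pretraining/maturation protocols run in seconds; the simplified network and
all closed-form checks run at the full published conditions.
"""

import logging

import numpy as np
import pytest

from neurogen import (ClusterSpec, ExperimentPlan, NetworkConfig,
                      PlasticityConfig, build_dataset, run_neurogenesis)

logging.getLogger("neurogen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_similar():
    """K=3 similar clusters (xi=0.2) at reduced size, with train/test."""
    spec = ClusterSpec(K=3, xi=0.2, kappa=1e4, n_train=60, n_test=15, seed=2)
    train, test = build_dataset(spec)
    return spec, train, test


@pytest.fixture(scope="session")
def tiny_distinct():
    """K=3 distinct clusters (xi=0.8) at reduced size, with train/test."""
    spec = ClusterSpec(K=3, xi=0.8, kappa=1e4, n_train=60, n_test=15, seed=2)
    train, test = build_dataset(spec)
    return spec, train, test


@pytest.fixture
def small_net_cfg():
    """Four granule cells, four interneurons, 8 input cells, 1 ms steps."""
    return NetworkConfig(n_ec=8, n_dgc=4, n_inh=4, dt=1.0, tol=1e-6)


@pytest.fixture
def bio_plast():
    return PlasticityConfig(eta=0.02)


@pytest.fixture(scope="session")
def similar_run(tiny_similar):
    """One full neurogenesis run on the similar tiny task (shared)."""
    spec, train, _ = tiny_similar
    cfg = NetworkConfig(n_ec=8, n_dgc=4, n_inh=4, dt=1.0, tol=1e-6)
    plast = PlasticityConfig(eta=0.02)
    plan = ExperimentPlan(pretrain_classes=(0, 1), novel_classes=(2,),
                          pretrain_epochs=15, late_epochs=4, seed=5)
    result = run_neurogenesis(plan, train, cfg, plast, log_every=20)
    return spec, cfg, result


@pytest.fixture(scope="session")
def toy_train():
    """Seven-cluster similar dataset at reduced size for the toy network."""
    spec = ClusterSpec(K=7, xi=0.2, kappa=1e4, n_train=500, n_test=100,
                       seed=11)
    train, test = build_dataset(spec)
    return spec, train, test


@pytest.fixture(scope="session")
def toy_train_distinct():
    spec = ClusterSpec(K=7, xi=0.8, kappa=1e4, n_train=500, n_test=100,
                       seed=11)
    train, test = build_dataset(spec)
    return spec, train, test
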