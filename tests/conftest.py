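"""Shared fixtures: small networks and synthetic spike records."""

import numpy as np
import pandas as pd
import pytest

from v1micro import build_network
from v1micro.lif import SpikeRecord
from v1micro.network import NetworkGraph, PopulationSpec


@pytest.fixture(scope="session")
def small_column():
    """Single column at 5% scale — fast smoke-test network."""
    return build_network(n_columns=1, scale=0.05, seed=42)


@pytest.fixture(scope="session")
def small_ring():
    """13-column ring at 2% scale — structure checks only."""
    return build_network(n_columns=13, scale=0.02, seed=42)


@pytest.fixture()
def single_neuron_graph():
    """One isolated neuron, no synapses."""
    return NetworkGraph(
        populations=[PopulationSpec("L23_Pyr", 1, 0)],
        offsets=np.array([0, 1]),
        pre=np.empty(0, np.int32), post=np.empty(0, np.int32),
        weight=np.empty(0), delay=np.empty(0),
        channel=np.empty(0, np.uint8), rule_id=np.empty(0, np.int32),
        rule_names=[])


def chain_graph(weights, taus, delays):
    """Neuron 0 -> neurons 1..n via single synapses (test scaffold)."""
    from v1micro.network import CHANNEL_TAUS
    n = len(weights) + 1
    ch = [CHANNEL_TAUS.index(t) for t in taus]
    return NetworkGraph(
        populations=[PopulationSpec("L23_Pyr", n, 0)],
        offsets=np.array([0, n]),
        pre=np.zeros(len(weights), np.int32),
        post=np.arange(1, n, dtype=np.int32),
        weight=np.asarray(weights, float),
        delay=np.asarray(delays, float),
        channel=np.asarray(ch, np.uint8),
        rule_id=np.zeros(len(weights), np.int32),
        rule_names=["test"])


def synthetic_record(column_rates, n_per_column=50, duration=1000.0,
                     seed=0, population="L23_Pyr"):
    """Poisson spike record over n columns with given per-neuron rates."""
    rng = np.random.default_rng(seed)
    n_cols = len(column_rates)
    neurons, times = [], []
    rows = []
    for c, rate in enumerate(column_rates):
        start = c * n_per_column
        rows.append({"name": population, "column": c,
                     "count": n_per_column, "start": start,
                     "stop": start + n_per_column})
        for j in range(n_per_column):
            k = rng.poisson(rate * duration * 1e-3)
            t = np.sort(rng.uniform(0, duration, k))
            neurons.append(np.full(k, start + j, dtype=np.int64))
            times.append(t)
    neurons = np.concatenate(neurons)
    times = np.concatenate(times)
    order = np.argsort(times, kind="stable")
    return SpikeRecord(neurons[order], times[order],
                       n_cols * n_per_column, duration,
                       manifest=pd.DataFrame(rows))
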