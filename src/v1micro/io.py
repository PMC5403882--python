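"""Configuration files, artifact export/import, and run manifests.

Configs are YAML with three optional sections — ``rate_model`` (keys exactly
S_ee..S_vs, I_e..I_v, theta, tau_m, gain_coeff_*), ``network`` (scale,
n_columns, compensation, intercolumnar probability overrides) and
``experiment`` (a serialised ExperimentSpec).  Unknown keys raise
immediately; there are no silent defaults for misspellings.

Artifacts are plain delimited text: spike records as ``neuron_id<TAB>
time_ms``, network graphs as a synapse table plus a population manifest
(bit-exact round trip via 17-significant-digit floats), branch scans and
column profiles as CSV.  A RunManifest records the resolved config, seeds,
package version, output paths with checksums, and wall time.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lif import SpikeRecord
from .network import NetworkGraph, PopulationSpec
from .protocols import ExperimentSpec
from .rate_model import RateModelParams

_CONFIG_SECTIONS = {"rate_model", "network", "experiment"}
_NETWORK_KEYS = {"n_columns", "scale", "seed", "compensation",
                 "prob_overrides"}


def load_config(path) -> dict:
    """Parse a YAML config; unknown sections or keys are hard errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _CONFIG_SECTIONS
    if unknown:
        raise KeyError(f"unknown config sections: {sorted(unknown)}")
    out: dict = {}
    if "rate_model" in raw:
        out["rate_model"] = RateModelParams.from_dict(raw["rate_model"])
    if "network" in raw:
        net = dict(raw["network"])
        bad = set(net) - _NETWORK_KEYS
        if bad:
            raise KeyError(f"unknown network keys: {sorted(bad)}")
        out["network"] = net
    if "experiment" in raw:
        out["experiment"] = ExperimentSpec.from_dict(raw["experiment"])
    return out


def dump_config(cfg: dict, path) -> None:
    """Write a config so that ``load_config`` restores it exactly."""
    raw: dict = {}
    if "rate_model" in cfg:
        raw["rate_model"] = cfg["rate_model"].to_dict()
    if "network" in cfg:
        raw["network"] = cfg["network"]
    if "experiment" in cfg:
        raw["experiment"] = cfg["experiment"].to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Spike records
# ---------------------------------------------------------------------------


def save_spikes(rec: SpikeRecord, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# n_neurons={rec.n_neurons} "
                 f"duration_ms={float(rec.duration)!r}\n")
        for n, t in zip(rec.neurons, rec.times):
            fh.write(f"{n}\t{float(t)!r}\n")
    if rec.manifest is not None:
        rec.manifest.to_csv(path.with_suffix(".manifest.csv"), index=False)


def load_spikes(path) -> SpikeRecord:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        body = pd.read_csv(fh, sep="\t", names=["neuron_id", "time_ms"],
                           float_precision="round_trip")
    manifest_path = path.with_suffix(".manifest.csv")
    manifest = (pd.read_csv(manifest_path)
                if manifest_path.exists() else None)
    return SpikeRecord(body["neuron_id"].to_numpy(np.int64),
                       body["time_ms"].to_numpy(float),
                       int(meta["n_neurons"]), float(meta["duration_ms"]),
                       manifest=manifest)


# ---------------------------------------------------------------------------
# Network graphs
# ---------------------------------------------------------------------------


def save_graph(graph: NetworkGraph, prefix) -> None:
    """Write ``<prefix>.synapses.tsv`` and ``<prefix>.manifest.csv``."""
    prefix = Path(prefix)
    df = graph.synapse_frame()
    with open(prefix.with_suffix(".synapses.tsv"), "w") as fh:
        fh.write(f"# seed={graph.seed} n_columns={graph.n_columns} "
                 f"scale={graph.scale!r} compensation={graph.compensation}\n")
        df.to_csv(fh, sep="\t", index=False,
                  float_format="%.17g")
    graph.manifest_frame().to_csv(prefix.with_suffix(".manifest.csv"),
                                  index=False)
    with open(prefix.with_suffix(".rules.json"), "w") as fh:
        json.dump(graph.rule_names, fh)


def load_graph(prefix) -> NetworkGraph:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".synapses.tsv")) as fh:
        header = fh.readline().strip().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    man = pd.read_csv(prefix.with_suffix(".manifest.csv"))
    rules_path = prefix.with_suffix(".rules.json")
    rule_names = json.loads(rules_path.read_text()) if rules_path.exists() \
        else []
    pops = [PopulationSpec(r["name"], int(r["count"]), int(r["column"]))
            for _, r in man.iterrows()]
    offsets = np.concatenate([man["start"].to_numpy(np.int64),
                              [int(man["stop"].iloc[-1])]])
    return NetworkGraph(
        populations=pops, offsets=offsets,
        pre=df["pre"].to_numpy(np.int32), post=df["post"].to_numpy(np.int32),
        weight=df["weight"].to_numpy(float),
        delay=df["delay"].to_numpy(float),
        channel=df["channel"].to_numpy(np.uint8),
        rule_id=df["rule_id"].to_numpy(np.int32), rule_names=rule_names,
        seed=int(meta["seed"]), n_columns=int(meta["n_columns"]),
        scale=float(meta["scale"]), compensation=meta["compensation"])


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


def checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one run: config, seeds, outputs, checksums."""

    experiment: str
    config: dict
    seeds: list
    outputs: dict = field(default_factory=dict)  # path -> sha256
    version: str = __version__
    wall_time_s: float = 0.0

    def add_output(self, path) -> None:
        self.outputs[str(path)] = checksum(path)

    def verify(self) -> list:
        """Paths whose checksum no longer matches (or that are missing)."""
        bad = []
        for p, digest in self.outputs.items():
            if not Path(p).exists() or checksum(p) != digest:
                bad.append(p)
        return bad

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"experiment": self.experiment, "config": self.config,
                       "seeds": self.seeds, "outputs": self.outputs,
                       "version": self.version,
                       "wall_time_s": self.wall_time_s}, fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(d["experiment"], d["config"], d["seeds"], d["outputs"],
                   d["version"], d["wall_time_s"])


class Stopwatch:
    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.elapsed = time.perf_counter() - self.t0
        return False
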