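"""Run configuration, zone files, and trajectory writers.

All randomness flows through explicit seeds stored in the configuration;
a run directory (config + outputs) is sufficient to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .dynamics import NetworkTrajectory, STATE_NAMES
from .experiments import ZoneAssignment
from .hemo import HemodynamicParameters
from .metrics import MetricConfig
from .params import IntegrationConfig

log = logging.getLogger("epileptornet")


# --------------------------------------------------------------------------
# zones

def read_zones(path: str | Path) -> ZoneAssignment:
    """CSV with columns ``region,zone`` (zones EZ_IZ1 / PZ_IZ2 / NIZ)."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    if "region" not in cols or "zone" not in cols:
        raise ValueError("zones file needs 'region' and 'zone' columns")
    return ZoneAssignment(dict(zip(df[cols["region"]], df[cols["zone"]])))


def write_zones(zones: ZoneAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {"region": list(zones.zones), "zone": list(zones.zones.values())}
    ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Serializable description of one simulation/fitting run."""

    connectome_path: str | None = None
    zones_path: str | None = None
    reference_bold_path: str | None = None
    output_dir: str = "."
    scenario: str = "spike_free"
    a: float = 1.7402
    K_s: float = 0.1
    K_rs: float = 10.0
    a_grid: list[float] = field(default_factory=list)
    krs_grid: list[float] = field(default_factory=list)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    metrics: MetricConfig = field(default_factory=MetricConfig)
    hemo: HemodynamicParameters = field(default_factory=HemodynamicParameters)
    TR: float = 3.6
    bold_discard_s: float = 36.0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["metrics"]["mse_scales"] = list(d["metrics"]["mse_scales"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for name, typ in (("integration", IntegrationConfig),
                          ("metrics", MetricConfig),
                          ("hemo", HemodynamicParameters)):
            if name in d and isinstance(d[name], dict):
                sub = d[name]
                if name == "metrics" and "mse_scales" in sub:
                    sub["mse_scales"] = tuple(sub["mse_scales"])
                d[name] = typ(**sub)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def log_resolved(self) -> None:
        """Log the fully resolved configuration (reproducibility contract)."""
        log.info("resolved run configuration: %s", asdict(self))


# --------------------------------------------------------------------------
# trajectory writers

def write_trajectory_hdf5(traj: NetworkTrajectory, path: str | Path) -> None:
    """Hierarchical container: /t, /states (node x time x variable), /output."""
    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=traj.t)
        ds = f.create_dataset("states", data=traj.states, compression="gzip")
        ds.attrs["variables"] = list(STATE_NAMES)
        f.create_dataset("output", data=traj.output, compression="gzip")
        f.create_dataset("p", data=traj.p)
        f.attrs["labels"] = [str(lab) for lab in traj.labels]
        f.attrs["dt_store_ms"] = traj.dt_store


def read_trajectory_hdf5(path: str | Path) -> NetworkTrajectory:
    with h5py.File(path, "r") as f:
        return NetworkTrajectory(
            labels=[lab if isinstance(lab, str) else lab.decode()
                    for lab in f.attrs["labels"]],
            t=f["t"][:],
            states=f["states"][:],
            p=f["p"][:],
            dt_store=float(f.attrs["dt_store_ms"]),
        )


def write_trajectory_csv(traj: NetworkTrajectory, path: str | Path) -> None:
    """Long-format CSV: time, node, the 8 state variables and the output."""
    frames = []
    out = traj.output
    for i, lab in enumerate(traj.labels):
        df = pd.DataFrame(traj.states[i], columns=list(STATE_NAMES))
        df.insert(0, "time_s", traj.t)
        df.insert(1, "node", lab)
        df["p"] = traj.p[i]
        df["output"] = out[i]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> NetworkTrajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    labels = list(dict.fromkeys(df["node"]))
    t = np.asarray(sorted(df["time_s"].unique()), dtype=float)
    n, T = len(labels), len(t)
    states = np.empty((n, T, 8))
    p = np.zeros(n)
    for i, lab in enumerate(labels):
        sub = df[df["node"] == lab].sort_values("time_s")
        states[i] = sub[list(STATE_NAMES)].to_numpy()
        if "p" in sub:
            p[i] = sub["p"].iloc[0]
    dt_store = float(np.round((t[1] - t[0]) * 1000.0, 9)) if T > 1 else 1.0
    return NetworkTrajectory(labels=labels, t=t, states=states, p=p,
                             dt_store=dt_store)
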