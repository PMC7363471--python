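"""Epileptogenicity maps and the three in-silico resting-state experiments.

Scenarios assign per-region (x0, a, p) from the clinical zone semantics:
EZ_IZ1 (seizure-generating / primary irritative), PZ_IZ2 (secondarily
involved, spiking) and NIZ (non-involved).  The experiments are (1) the
working-point sweep of the homogeneous Hopf excitability ``a`` and global
coupling ``K_rs`` against reference BOLD, (2) the interictal-spike sweep of
a single spiking region's spike-frequency parameter ``b2``, and (3) the
hyperexcitability sweep of a single region's ``a`` above the Hopf critical
point, both compared with a seed-matched spike-free control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from .connectome import Connectome
from .dynamics import BlowUpError, simulate
from .hemo import BoldSeries, HemodynamicParameters, balloon_windkessel, bold_postprocess
from .metrics import (
    FitSummary,
    MetricConfig,
    bold_observables,
    fit_summary,
    global_similarity,
)
from .params import A_CRITIC, CouplingParameters, IntegrationConfig, NodeParameters
from .traces import classify_trace

ZONES = ("EZ_IZ1", "PZ_IZ2", "NIZ")

#: Per-zone scenario defaults: mixing ratio p and epileptogenicity x0 for the
#: spiking resting state (x0 offsets 0.0/0.2/0.5 below the seizure threshold).
SPIKING_P = {"EZ_IZ1": 0.9, "PZ_IZ2": 0.7, "NIZ": 0.1}
SPIKING_X0 = {"EZ_IZ1": -2.07, "PZ_IZ2": -2.25, "NIZ": -2.55}
SPIKE_FREE_P = 0.1
SPIKE_FREE_X0 = -2.5


@dataclass
class ZoneAssignment:
    """Per-region zone labels (every region exactly one zone)."""

    zones: dict[str, str]

    def __post_init__(self) -> None:
        bad = {z for z in self.zones.values() if z not in ZONES}
        if bad:
            raise ValueError(f"unknown zone labels: {sorted(bad)}; use {ZONES}")

    def zone_of(self, label: str) -> str:
        return self.zones.get(label, "NIZ")

    def regions(self, zone: str) -> list[str]:
        return [lab for lab, z in self.zones.items() if z == zone]

    @classmethod
    def all_niz(cls, labels: list[str]) -> "ZoneAssignment":
        return cls({lab: "NIZ" for lab in labels})

    def validate_against(self, labels: list[str]) -> None:
        unknown = set(self.zones) - set(labels)
        if unknown:
            raise ValueError(
                f"zone assignment names regions absent from the connectome: "
                f"{sorted(unknown)}"
            )


@dataclass
class EpileptogenicityMap:
    """Per-region (x0, a, p, b2) spatial excitability map."""

    labels: list[str]
    x0: np.ndarray
    a: np.ndarray
    p: np.ndarray
    b2: np.ndarray
    scenario: str = "custom"

    def __post_init__(self) -> None:
        n = len(self.labels)
        for name in ("x0", "a", "p", "b2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per region")
            setattr(self, name, arr)
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("mixing ratios p must lie in [0, 1]")

    def node_parameters(self) -> list[NodeParameters]:
        return [
            NodeParameters(x0=float(self.x0[i]), a=float(self.a[i]),
                           p=float(self.p[i]), b2=float(self.b2[i]))
            for i in range(len(self.labels))
        ]

    def with_roi(self, roi: str, **changes: float) -> "EpileptogenicityMap":
        """Copy of the map with one region's parameters overridden."""
        if roi not in self.labels:
            raise KeyError(f"region {roi!r} not in map")
        i = self.labels.index(roi)
        new = EpileptogenicityMap(
            labels=list(self.labels), x0=self.x0.copy(), a=self.a.copy(),
            p=self.p.copy(), b2=self.b2.copy(), scenario=self.scenario,
        )
        for name, val in changes.items():
            getattr(new, name)[i] = val
        return new


def build_map(
    labels: list[str],
    zones: ZoneAssignment,
    scenario: str,
    a: float = A_CRITIC,
    a_hyper: float = 2.2,
    b2: float = 4.0,
    overrides: dict | None = None,
) -> EpileptogenicityMap:
    """Construct the per-region excitability map for a scenario.

    ``spike_free``: p = 0.1 and x0 = -2.5 everywhere, homogeneous a.
    ``spiking``: p = 0.9 / 0.7 / 0.1 and x0 = -2.07 / -2.25 / -2.55 for
    EZ_IZ1 / PZ_IZ2 / NIZ, homogeneous a (default the critical value).
    ``hyperexcitable``: spike-free p and x0 with a = ``a_hyper`` in
    EZ_IZ1 and PZ_IZ2 and a at the critical value in NIZ.

    ``overrides`` maps a parameter name to either a scalar or a
    {zone: value} dictionary applied after the scenario rules.
    """
    zones.validate_against(labels)
    n = len(labels)
    zvec = [zones.zone_of(lab) for lab in labels]
    if scenario == "spike_free":
        x0 = np.full(n, SPIKE_FREE_X0)
        p = np.full(n, SPIKE_FREE_P)
        avec = np.full(n, a)
    elif scenario == "spiking":
        x0 = np.array([SPIKING_X0[z] for z in zvec])
        p = np.array([SPIKING_P[z] for z in zvec])
        avec = np.full(n, a)
    elif scenario == "hyperexcitable":
        x0 = np.full(n, SPIKE_FREE_X0)
        p = np.full(n, SPIKE_FREE_P)
        avec = np.array([a_hyper if z != "NIZ" else A_CRITIC for z in zvec])
    else:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected spike_free, spiking "
            "or hyperexcitable"
        )
    arrays = {"x0": x0, "a": avec, "p": p, "b2": np.full(n, b2)}
    for name, spec in (overrides or {}).items():
        if name not in arrays:
            raise KeyError(f"unknown parameter {name!r} in overrides")
        if isinstance(spec, dict):
            for zone, val in spec.items():
                arrays[name][[i for i, z in enumerate(zvec) if z == zone]] = val
        else:
            arrays[name][:] = spec
    return EpileptogenicityMap(labels=list(labels), scenario=scenario, **arrays)


# --------------------------------------------------------------------------
# forward chain

@dataclass
class SweepConfig:
    """Shared settings for one experiment sweep."""

    integration: IntegrationConfig = field(
        default_factory=lambda: IntegrationConfig(duration=440.0))
    metrics: MetricConfig = field(
        default_factory=lambda: MetricConfig(mse_scales=tuple(range(1, 6))))
    hemo: HemodynamicParameters = field(default_factory=HemodynamicParameters)
    K_s: float = 0.1
    K_rs: float = 10.0  # used where the sweep does not scan K_rs itself
    TR: float = 3.6
    bold_discard_s: float = 36.0  # hemodynamic transient dropped from raw BOLD
    seed: int = 42
    #: Global-mean regression of the simulated BOLD.  The full printed
    #: pipeline regresses; in small synthetic networks the regression removes
    #: the network-wide component through which a single perturbed region
    #: expresses its influence, so the perturbation experiments typically run
    #: with the flag off.
    global_mean_regression: bool = True


def forward_bold(
    connectome: Connectome,
    emap: EpileptogenicityMap,
    K_rs: float,
    cfg: SweepConfig,
    seed_sequences: list[np.random.SeedSequence] | None = None,
) -> BoldSeries:
    """Simulate -> Balloon-Windkessel -> post-processed BOLD."""
    coupling = CouplingParameters(K_s=cfg.K_s, K_rs=K_rs)
    traj = simulate(connectome, emap.node_parameters(), coupling,
                    cfg.integration, seed_sequences=seed_sequences)
    raw = balloon_windkessel(traj.output, traj.dt_store, cfg.hemo)
    n_drop = int(round(cfg.bold_discard_s * traj.fs))
    if n_drop >= raw.shape[1]:
        raise ValueError("bold_discard_s leaves no BOLD samples")
    bold = bold_postprocess(raw[:, n_drop:], traj.dt_store,
                            labels=traj.labels, TR=cfg.TR,
                            global_mean_regression=cfg.global_mean_regression)
    bold.meta.update({"scenario": emap.scenario, "K_rs": K_rs})
    return bold


def _cell_seed_sequences(cfg: SweepConfig, cell: int, n: int):
    return np.random.SeedSequence(entropy=cfg.seed, spawn_key=(cell,)).spawn(n)


@dataclass
class SweepResult:
    """Tidy per-cell results of one experiment sweep."""

    table: pd.DataFrame
    optimum: dict | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# --------------------------------------------------------------------------
# experiment 1: working point

def working_point_sweep(
    connectome: Connectome,
    a_values: np.ndarray,
    krs_values: np.ndarray,
    reference: BoldSeries,
    cfg: SweepConfig | None = None,
    common_noise: bool = True,
) -> SweepResult:
    """Fit landscape over (a, K_rs) against a reference BOLD series.

    Each cell simulates the spike-free scenario with homogeneous a, forwards
    to BOLD, and computes the five comparison metrics; GS is normalized over
    the completed cells and the optimum is its argmin.  A diverging cell is
    recorded as failed and the sweep continues.

    With ``common_noise`` (default) every cell reuses the same per-node
    noise streams, so differences between cells reflect the parameters
    rather than the noise realization (common-random-numbers variance
    reduction); the streams still differ from any reference generated with
    its own seed.  Set it to False for independent per-cell seeds.
    """
    cfg = cfg or SweepConfig()
    zones = ZoneAssignment.all_niz(connectome.labels)
    ref_obs = bold_observables(reference, cfg.metrics)
    common = _cell_seed_sequences(cfg, 1, connectome.n) if common_noise else None
    rows = []
    summaries: list[FitSummary | None] = []
    cell = 0
    for a in np.asarray(a_values, dtype=float):
        for krs in np.asarray(krs_values, dtype=float):
            emap = build_map(connectome.labels, zones, "spike_free", a=a)
            row = {"a": a, "K_rs": krs, "seed": cfg.seed, "cell": cell,
                   "status": "ok"}
            try:
                seeds = common if common_noise else _cell_seed_sequences(
                    cfg, cell, connectome.n)
                bold = forward_bold(connectome, emap, krs, cfg, seeds)
                fs = fit_summary(bold_observables(bold, cfg.metrics), ref_obs,
                                 cfg.metrics)
            except (BlowUpError, RuntimeError, ValueError) as exc:
                row["status"] = f"failed: {exc}"
                fs = None
            summaries.append(fs)
            if fs is not None:
                row.update(corr=fs.corr, ks=fs.ks, dcoh=fs.dcoh,
                           dmeta=fs.dmeta, rmsd=fs.rmsd)
            rows.append(row)
            cell += 1
    ok = [s for s in summaries if s is not None]
    if len(ok) >= 2:
        normed = iter(global_similarity(ok))
        for row, s in zip(rows, summaries):
            row["gs"] = next(normed).gs if s is not None else np.nan
    elif len(ok) == 1:
        rows[summaries.index(ok[0])]["gs"] = 1.0
    table = pd.DataFrame(rows)
    optimum = None
    if "gs" in table and table["gs"].notna().any():
        best = table.loc[table["gs"].idxmin()]
        optimum = {"a": float(best["a"]), "K_rs": float(best["K_rs"]),
                   "gs": float(best["gs"])}
    return SweepResult(table=table, optimum=optimum)


# --------------------------------------------------------------------------
# experiments 2 & 3: single-region perturbations vs seed-matched control

def roi_order(connectome: Connectome) -> list[str]:
    """Region labels sorted by ascending structural node strength."""
    s = connectome.node_strength()
    return [connectome.labels[i] for i in np.argsort(s, kind="stable")]


def _roi_mean_spcc(spcc: np.ndarray, idx: int) -> float:
    row = np.delete(spcc[idx], idx)
    return float(row.mean())


def _perturbation_sweep(
    connectome: Connectome,
    rois: list[str],
    values: np.ndarray,
    param_name: str,
    make_condition,
    cfg: SweepConfig,
    control_a: float = A_CRITIC,
) -> SweepResult:
    zones = ZoneAssignment.all_niz(connectome.labels)
    control_map = build_map(connectome.labels, zones, "spike_free", a=control_a)
    seeds = _cell_seed_sequences(cfg, 0, connectome.n)
    control_bold = forward_bold(connectome, control_map, cfg.K_rs, cfg, seeds)
    control_obs = bold_observables(control_bold, cfg.metrics)
    rows = []
    for roi in rois:
        idx = connectome.labels.index(roi)
        for val in np.asarray(values, dtype=float):
            emap = make_condition(control_map, roi, val)
            row = {"roi": roi, param_name: val, "seed": cfg.seed,
                   "status": "ok"}
            try:
                # condition shares the control's noise streams so changes
                # reflect the manipulation, not the noise realization
                coupling = CouplingParameters(K_s=cfg.K_s, K_rs=cfg.K_rs)
                traj = simulate(connectome, emap.node_parameters(), coupling,
                                cfg.integration, seed_sequences=seeds)
                raw = balloon_windkessel(traj.output, traj.dt_store, cfg.hemo)
                n_drop = int(round(cfg.bold_discard_s * traj.fs))
                bold = bold_postprocess(
                    raw[:, n_drop:], traj.dt_store, labels=traj.labels,
                    TR=cfg.TR,
                    global_mean_regression=cfg.global_mean_regression)
                obs = bold_observables(bold, cfg.metrics)
                fs = fit_summary(obs, control_obs, cfg.metrics)
                cls = classify_trace(traj.output[idx], traj.dt_store)
                row.update(
                    corr=fs.corr, ks=fs.ks, dcoh=fs.dcoh, dmeta=fs.dmeta,
                    rmsd=fs.rmsd, spike_rate=cls.spike_rate, label=cls.label,
                    roi_mean_spcc=_roi_mean_spcc(obs["spcc"], idx),
                    roi_mean_spcc_control=_roi_mean_spcc(control_obs["spcc"], idx),
                )
                if connectome.n >= 3:
                    z, p, direction = compare_connectivity(
                        np.delete(obs["spcc"][idx], idx),
                        np.delete(control_obs["spcc"][idx], idx),
                    )
                    row.update(z=z, p=p, direction=direction)
            except (BlowUpError, RuntimeError, ValueError) as exc:
                row["status"] = f"failed: {exc}"
            rows.append(row)
    return SweepResult(table=pd.DataFrame(rows))


def spiking_sweep(
    connectome: Connectome,
    rois: list[str],
    b2_values: np.ndarray,
    cfg: SweepConfig | None = None,
    roi_x0: float = SPIKING_X0["EZ_IZ1"],
    roi_p: float = SPIKING_P["EZ_IZ1"],
) -> SweepResult:
    """Single spiking region: change vs spike-free control across b2.

    The selected region becomes epileptogenic-but-subcritical (spiking) with
    spike frequency set by b2; all metrics are computed against the
    seed-matched spike-free control.
    """
    cfg = cfg or SweepConfig()

    def condition(control_map: EpileptogenicityMap, roi: str, b2: float):
        return control_map.with_roi(roi, x0=roi_x0, p=roi_p, b2=b2)

    return _perturbation_sweep(connectome, rois, b2_values, "b2", condition, cfg)


def hyperexcitability_sweep(
    connectome: Connectome,
    rois: list[str],
    a_values: np.ndarray,
    cfg: SweepConfig | None = None,
) -> SweepResult:
    """Single hyperexcitable region: change vs control across a > a_critic."""
    cfg = cfg or SweepConfig()

    def condition(control_map: EpileptogenicityMap, roi: str, a: float):
        return control_map.with_roi(roi, a=a)

    return _perturbation_sweep(connectome, rois, a_values, "a", condition, cfg)


# --------------------------------------------------------------------------
# statistics

def compare_connectivity(
    condition: np.ndarray,
    control: np.ndarray,
) -> tuple[float, float, int]:
    """Two-tailed Wilcoxon rank-sum comparison of connectivity samples.

    Returns (z score, two-sided p value, direction), direction being the
    sign of the median difference.  Significance at p < 0.05 corresponds to
    |z| > 1.96.  Samples of fewer than 2 values cannot be compared (e.g. a
    two-region irritative zone) and raise.
    """
    condition = np.asarray(condition, dtype=float).ravel()
    control = np.asarray(control, dtype=float).ravel()
    if len(condition) < 2 or len(control) < 2:
        raise ValueError(
            "statistical comparison needs at least 2 values per sample"
        )
    res = ranksums(condition, control)
    direction = int(np.sign(np.median(condition) - np.median(control)))
    return float(res.statistic), float(res.pvalue), direction
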