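"""Balloon-Windkessel hemodynamics and BOLD post-processing.

The four-state Friston model transduces regional neural activity into a
vasodilatory signal s, inflow f, venous volume v and deoxyhemoglobin content
q; the percent BOLD change is a static nonlinear readout of (q, v).  The
post-processing chain reproduces typical resting-state fMRI conditions:
downsampling to the scanner TR (anti-aliased), global-mean regression, and a
zero-phase third-order Butterworth band-pass at 0.01-0.1 Hz.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy.signal import butter, sosfiltfilt

from .params import HemodynamicParameters


@dataclass
class BoldSeries:
    """Region-by-time BOLD matrix sampled at a fixed repetition time."""

    labels: list[str]
    data: np.ndarray  # (n_regions, n_samples)
    TR: float = 3.6  # s
    global_mean_regressed: bool = False
    bandpassed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count does not match BOLD rows")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@njit(cache=True)
def _balloon_loop(u, dt, kappa, gamma, tau, alpha, rho, V0):
    n, T = u.shape
    k1 = 7.0 * rho
    k2 = 2.0
    k3 = 2.0 * rho - 0.2
    bold = np.empty((n, T))
    ialpha = 1.0 / alpha
    for i in range(n):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for t in range(T):
            x = u[i, t]
            # Heun predictor-corrector on the 4 hemodynamic states
            ds1 = x - kappa * s - gamma * (f - 1.0)
            df1 = s
            fv = v ** ialpha
            dv1 = (f - fv) / tau
            E = 1.0 - (1.0 - rho) ** (1.0 / f)
            dq1 = (f * E / rho - fv * q / v) / tau
            s_p = s + dt * ds1
            f_p = f + dt * df1
            v_p = v + dt * dv1
            q_p = q + dt * dq1
            if f_p <= 0.0 or v_p <= 0.0 or q_p <= 0.0:
                return bold, i, t
            ds2 = x - kappa * s_p - gamma * (f_p - 1.0)
            df2 = s_p
            fv_p = v_p ** ialpha
            dv2 = (f_p - fv_p) / tau
            E_p = 1.0 - (1.0 - rho) ** (1.0 / f_p)
            dq2 = (f_p * E_p / rho - fv_p * q_p / v_p) / tau
            s += 0.5 * dt * (ds1 + ds2)
            f += 0.5 * dt * (df1 + df2)
            v += 0.5 * dt * (dv1 + dv2)
            q += 0.5 * dt * (dq1 + dq2)
            if f <= 0.0 or v <= 0.0 or q <= 0.0:
                return bold, i, t
            bold[i, t] = 100.0 * V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v)
                                       + k3 * (1.0 - v))
    return bold, -1, -1


def balloon_windkessel(
    neural: np.ndarray,
    dt_ms: float,
    params: HemodynamicParameters | None = None,
    demean: bool = True,
) -> np.ndarray:
    """Percent-signal BOLD from regional neural drive via the Balloon model.

    ``neural`` is (n_regions, n_samples) at sampling interval ``dt_ms``
    (milliseconds).  The drive is demeaned per region (the model is driven by
    deviations from baseline activity) and scaled by the neuronal efficacy.
    Raises on non-finite input or on hemodynamic state collapse
    (non-positive inflow/volume/deoxyhemoglobin).
    """
    params = params or HemodynamicParameters()
    u = np.atleast_2d(np.asarray(neural, dtype=float))
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite neural input to the hemodynamic model")
    if demean:
        u = u - u.mean(axis=1, keepdims=True)
    u = params.epsilon * u
    dt_s = dt_ms / 1000.0
    bold, bad_i, bad_t = _balloon_loop(
        u, dt_s, params.kappa, params.gamma, params.tau,
        params.alpha, params.rho, params.V0,
    )
    if bad_i >= 0:
        raise RuntimeError(
            f"hemodynamic state became non-positive at region {bad_i}, "
            f"t = {bad_t * dt_s:.2f} s (input too strong?)"
        )
    return bold


def downsample_to_tr(raw: np.ndarray, dt_ms: float, TR: float = 3.6) -> np.ndarray:
    """Anti-aliased decimation of high-rate BOLD to the scanner TR.

    Low-pass (4th-order Butterworth at the TR Nyquist frequency, zero phase)
    then sample picking; the output has floor(T_total / TR) samples.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    fs = 1000.0 / dt_ms
    n_out = int(np.floor(raw.shape[1] / fs / TR))
    if n_out < 1:
        raise ValueError("series shorter than one TR")
    nyq_tr = 0.5 / TR
    sos = butter(4, nyq_tr, "lowpass", fs=fs, output="sos")
    smooth = sosfiltfilt(sos, raw, axis=1)
    idx = np.round(np.arange(n_out) * TR * fs).astype(int)
    return smooth[:, idx]


def regress_global_mean(data: np.ndarray) -> np.ndarray:
    """Regress the global mean signal (with intercept) out of each region."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    g = data.mean(axis=0)
    X = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(X, data.T, rcond=None)
    return data - (X @ beta).T


def bandpass(data: np.ndarray, TR: float, low: float = 0.01,
             high: float = 0.1, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass along time (rows = regions)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    fs = 1.0 / TR
    if high >= fs / 2:
        raise ValueError("band-pass upper edge at or above Nyquist")
    sos = butter(order, [low, high], "bandpass", fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if data.shape[1] <= padlen:
        raise ValueError(
            f"series too short for stable band-pass filtering "
            f"({data.shape[1]} samples <= {padlen})"
        )
    return sosfiltfilt(sos, data, axis=1)


def bold_postprocess(
    raw: np.ndarray,
    dt_ms: float,
    labels: list[str] | None = None,
    TR: float = 3.6,
    global_mean_regression: bool = True,
    band: tuple[float, float] = (0.01, 0.1),
) -> BoldSeries:
    """Full simulated-fMRI post-processing chain.

    Downsample to the TR, regress out the global mean (in that order), then
    band-pass 0.01-0.1 Hz with a zero-phase third-order Butterworth filter.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    ds = downsample_to_tr(raw, dt_ms, TR)
    if global_mean_regression:
        ds = regress_global_mean(ds)
    filt = bandpass(ds, TR, *band)
    if labels is None:
        labels = [f"node{i:02d}" for i in range(raw.shape[0])]
    return BoldSeries(labels=labels, data=filt, TR=TR,
                      global_mean_regressed=global_mean_regression,
                      bandpassed=True)


def write_bold(bold: BoldSeries, path: str | Path) -> None:
    """Region-by-time CSV (header = labels, one column per region) + JSON sidecar."""
    path = Path(path)
    pd.DataFrame(bold.data.T, columns=bold.labels).to_csv(
        path, index=False, float_format="%.17g")
    sidecar = {
        "TR": bold.TR,
        "global_mean_regressed": bold.global_mean_regressed,
        "bandpassed": bold.bandpassed,
        "meta": bold.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_bold(path: str | Path) -> BoldSeries:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    side = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return BoldSeries(
        labels=list(df.columns),
        data=df.to_numpy().T,
        TR=float(side.get("TR", 3.6)),
        global_mean_regressed=bool(side.get("global_mean_regressed", False)),
        bandpassed=bool(side.get("bandpassed", False)),
        meta=side.get("meta", {}),
    )
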