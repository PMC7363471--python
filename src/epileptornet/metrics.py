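"""Resting-state functional-connectivity observables and the fitting score.

Five observables characterize a region-by-time BOLD matrix: the static
Pearson correlation matrix (sPCC), the functional connectivity dynamics
matrix (FCD; window-by-window correlation of sliding-window sPCC upper
triangles), coherence and metastability (mean and SD of the Kuramoto order
parameter of the regional Hilbert phases), and the multiscale-entropy (MSE)
profile per region.  Simulated and reference data are compared through the
sPCC upper-triangle correlation, the Kolmogorov-Smirnov distance of FCD
value distributions, absolute coherence/metastability differences, and the
root-mean-square distance of MSE profiles; the composite Global Similarity
score combines the five (quadratic in the MSE distance, linear in the rest)
and is min-max normalized to [1, 2] over a parameter sweep, its minimum
marking the optimal working point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import hilbert

from .hemo import BoldSeries
from .params import MetricConfig


# --------------------------------------------------------------------------
# static and dynamic functional connectivity

def static_pcc(bold: BoldSeries | np.ndarray) -> np.ndarray:
    """Pearson correlation matrix over the whole time window.

    Zero-variance regions yield NaN rows/columns and a warning (flagged, not
    silent).
    """
    data = bold.data if isinstance(bold, BoldSeries) else np.atleast_2d(bold)
    if data.shape[1] < 3:
        raise ValueError("need at least 3 time points for correlation")
    sd = data.std(axis=1)
    if np.any(sd == 0):
        warnings.warn(
            f"zero-variance regions {list(np.flatnonzero(sd == 0))}: "
            "correlation undefined (NaN)"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0, out=r)


def upper_triangle(mat: np.ndarray, k: int = 1) -> np.ndarray:
    mat = np.asarray(mat)
    return mat[np.triu_indices_from(mat, k=k)]


def compare_spcc(sim: np.ndarray, emp: np.ndarray) -> float:
    """Pearson correlation of the strictly-upper-triangle entries."""
    sim, emp = np.asarray(sim), np.asarray(emp)
    if sim.shape != emp.shape:
        raise ValueError(f"sPCC shapes differ: {sim.shape} vs {emp.shape}")
    a, b = upper_triangle(sim), upper_triangle(emp)
    return float(np.corrcoef(a, b)[0, 1])


def window_samples(window_s: float, TR: float) -> int:
    """Sliding-window length in samples: ceil(window_s / TR)."""
    return int(np.ceil(window_s / TR))


def sliding_window_fcd(
    bold: BoldSeries,
    window_s: float = 60.0,
    step_tr: int = 1,
) -> np.ndarray:
    """Functional-connectivity-dynamics matrix.

    Windowed sPCC matrices (fully contained windows of ceil(window_s/TR)
    samples advancing by ``step_tr`` TRs) are compared pairwise through the
    Pearson correlation of their upper triangles; a 344-sample series at
    TR 3.6 s yields 328 windows of 60 s.
    """
    w = window_samples(window_s, bold.TR)
    T = bold.n_samples
    if T < w:
        raise ValueError(f"series ({T} samples) shorter than one window ({w})")
    starts = range(0, T - w + 1, step_tr)
    tri = []
    for s in starts:
        seg = bold.data[:, s:s + w]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(seg)
        tri.append(upper_triangle(r))
    tri = np.asarray(tri)
    fcd = np.corrcoef(tri)
    np.fill_diagonal(fcd, 1.0)
    return np.clip(fcd, -1.0, 1.0, out=fcd)


def fcd_values(fcd: np.ndarray, exclude_band: int = 0) -> np.ndarray:
    """Strictly-upper-triangle FCD entries, optionally excluding a diagonal
    band of width ``exclude_band`` (pairs of overlapping windows)."""
    return upper_triangle(fcd, k=1 + exclude_band)


def ks_distance(sample1: np.ndarray, sample2: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov distance (sup-norm of empirical CDFs)."""
    x1 = np.sort(np.asarray(sample1, dtype=float).ravel())
    x2 = np.sort(np.asarray(sample2, dtype=float).ravel())
    if len(x1) == 0 or len(x2) == 0:
        raise ValueError("empty sample in KS distance")
    xs = np.concatenate([x1, x2])
    cdf1 = np.searchsorted(x1, xs, side="right") / len(x1)
    cdf2 = np.searchsorted(x2, xs, side="right") / len(x2)
    return float(np.abs(cdf1 - cdf2).max())


# --------------------------------------------------------------------------
# phase synchronization

def instantaneous_phase(bold: BoldSeries | np.ndarray, trim: float = 0.05) -> np.ndarray:
    """Per-region instantaneous phase via the Hilbert analytic signal.

    Each region is demeaned before the transform; a fraction ``trim`` of
    samples is dropped at each edge to suppress transform edge effects.
    Constant regions have no defined phase and raise.
    """
    data = bold.data if isinstance(bold, BoldSeries) else np.atleast_2d(bold)
    if np.any(data.std(axis=1) == 0):
        raise ValueError("constant region signal: instantaneous phase undefined")
    centered = data - data.mean(axis=1, keepdims=True)
    analytic = hilbert(centered, axis=1)
    phase = np.angle(analytic)
    n_trim = int(np.floor(trim * data.shape[1]))
    if n_trim > 0:
        phase = phase[:, n_trim:-n_trim]
    return phase


def kuramoto_order(phases: np.ndarray) -> np.ndarray:
    """Kuramoto order parameter R(t): modulus of the mean unit phasor.

    ``phases`` is (n_regions, n_times); returns R(t) in [0, 1] (1 = full
    synchronization, 0 = incoherence).
    """
    phases = np.atleast_2d(phases)
    if phases.shape[0] < 2:
        raise ValueError("Kuramoto order parameter needs at least 2 regions")
    R = np.abs(np.exp(1j * phases).mean(axis=0))
    return np.clip(R, 0.0, 1.0)


def coherence_metastability(R: np.ndarray) -> tuple[float, float]:
    """Time-mean (coherence) and time-SD (metastability) of R(t)."""
    R = np.asarray(R, dtype=float).ravel()
    if R.size == 0:
        raise ValueError("empty synchronization series")
    return float(R.mean()), float(R.std())


# --------------------------------------------------------------------------
# multiscale entropy

def coarse_grain(series: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping block means of length ``scale`` (scale 1 = original)."""
    series = np.asarray(series, dtype=float).ravel()
    if scale < 1 or int(scale) != scale:
        raise ValueError("scale factor must be a positive integer")
    if scale > len(series):
        raise ValueError(f"scale {scale} exceeds series length {len(series)}")
    n = len(series) // scale
    return series[: n * scale].reshape(n, scale).mean(axis=1)


def sample_entropy(
    series: np.ndarray,
    m: int = 1,
    r: float | None = None,
    r_factor: float = 0.35,
) -> float:
    """Sample entropy: -ln of the conditional template-match probability.

    Templates of length m match when their Chebyshev distance is <= r
    (default ``r_factor`` times the series SD); self-matches are excluded.
    Returns inf (degenerate, no crash) when no template pair matches at
    length m + 1, and NaN for a constant series (zero tolerance).
    """
    x = np.asarray(series, dtype=float).ravel()
    N = len(x)
    if N < m + 2:
        raise ValueError(f"series too short for m={m} (length {N})")
    if r is None:
        sd = x.std()
        if sd == 0:
            warnings.warn("constant series: sample entropy undefined")
            return float("nan")
        r = r_factor * sd
    counts = []
    for mm in (m, m + 1):
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        # templates are the first N - m embedding vectors for both lengths,
        # so that every length-m template has a defined continuation
        emb = emb[: N - m]
        dist = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
        match = (dist <= r).sum() - len(emb)  # exclude self-matches
        counts.append(match)
    B, A = counts  # length-m and length-(m+1) match counts
    if B == 0 or A == 0:
        warnings.warn("no template matches: sample entropy degenerate (infinite)")
        return float("inf")
    return float(-np.log(A / B))


def mse_profile(
    bold: BoldSeries | np.ndarray,
    scales: tuple[int, ...] = tuple(range(1, 14)),
    m: int = 1,
    r_factor: float = 0.35,
) -> np.ndarray:
    """Multiscale entropy: per-region SampEn of coarse-grained series.

    The tolerance r is fixed from the SD of the original (scale-1) series
    and held constant across scales.  Raises if any scale leaves fewer than
    10 points.
    """
    data = bold.data if isinstance(bold, BoldSeries) else np.atleast_2d(bold)
    n, N = data.shape
    out = np.empty((n, len(scales)))
    for si, scale in enumerate(scales):
        if N // scale < 10:
            raise ValueError(
                f"scale {scale} leaves {N // scale} points (< 10): "
                "series too short for reliable sample entropy"
            )
    for i in range(n):
        sd = data[i].std()
        r = r_factor * sd if sd > 0 else None
        for si, scale in enumerate(scales):
            y = coarse_grain(data[i], scale)
            out[i, si] = sample_entropy(y, m=m, r=r, r_factor=r_factor)
    return out


def rmsd(profile1: np.ndarray, profile2: np.ndarray) -> float:
    """Root-mean-square distance between two MSE profiles."""
    p1, p2 = np.asarray(profile1, float), np.asarray(profile2, float)
    if p1.shape != p2.shape:
        raise ValueError(f"profile shapes differ: {p1.shape} vs {p2.shape}")
    return float(np.sqrt(np.mean((p1 - p2) ** 2)))


# --------------------------------------------------------------------------
# fit summary and global similarity

@dataclass
class FitSummary:
    """Comparison of one simulation against the reference data."""

    corr: float  # sPCC upper-triangle correlation
    ks: float  # KS distance of FCD distributions
    dcoh: float  # |coherence difference|
    dmeta: float  # |metastability difference|
    rmsd: float  # MSE-profile distance
    gs: float = float("nan")  # filled by global_similarity over a sweep

    def raw_score(self) -> float:
        """Unnormalized global-similarity score (smaller = better fit)."""
        return self.dcoh + self.dmeta + (1.0 - self.corr) + self.ks + self.rmsd ** 2


def bold_observables(bold: BoldSeries, cfg: MetricConfig | None = None) -> dict:
    """All five observables of one BOLD series."""
    cfg = cfg or MetricConfig()
    spcc = static_pcc(bold)
    fcd = sliding_window_fcd(bold, cfg.window_s, cfg.step_tr)
    w = window_samples(cfg.window_s, bold.TR)
    band = w // cfg.step_tr if cfg.fcd_exclude_overlap else 0
    phases = instantaneous_phase(bold, trim=cfg.phase_trim)
    coh, meta = coherence_metastability(kuramoto_order(phases))
    mse = mse_profile(bold, scales=cfg.mse_scales, m=cfg.mse_m,
                      r_factor=cfg.mse_r_factor)
    return {
        "spcc": spcc,
        "fcd": fcd,
        "fcd_values": fcd_values(fcd, exclude_band=band),
        "coherence": coh,
        "metastability": meta,
        "mse": mse,
    }


def fit_summary(
    sim: BoldSeries | dict,
    ref: BoldSeries | dict,
    cfg: MetricConfig | None = None,
) -> FitSummary:
    """Six-number comparison of a simulated against a reference BOLD series.

    Accepts BoldSeries or precomputed observable dictionaries (so a sweep
    computes the reference observables once).
    """
    cfg = cfg or MetricConfig()
    obs_s = bold_observables(sim, cfg) if isinstance(sim, BoldSeries) else sim
    obs_r = bold_observables(ref, cfg) if isinstance(ref, BoldSeries) else ref
    return FitSummary(
        corr=compare_spcc(obs_s["spcc"], obs_r["spcc"]),
        ks=ks_distance(obs_s["fcd_values"], obs_r["fcd_values"]),
        dcoh=abs(obs_s["coherence"] - obs_r["coherence"]),
        dmeta=abs(obs_s["metastability"] - obs_r["metastability"]),
        rmsd=rmsd(obs_s["mse"], obs_r["mse"]),
    )


def global_similarity(summaries: list[FitSummary]) -> list[FitSummary]:
    """Normalized Global Similarity over a sweep of fit summaries.

    The raw score is min-max normalized to [1, 2] across the sweep (argmin
    preserved); a degenerate sweep (all raw scores equal) maps to all 1 with
    a warning.  Returns new FitSummary objects with ``gs`` filled.
    """
    if len(summaries) < 2:
        raise ValueError("global similarity normalization needs >= 2 sweep points")
    raw = np.array([s.raw_score() for s in summaries])
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn("degenerate sweep: all raw scores equal; GS set to 1")
        gs = np.ones_like(raw)
    else:
        gs = 1.0 + (raw - lo) / (hi - lo)
    return [replace(s, gs=float(g)) for s, g in zip(summaries, gs)]
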