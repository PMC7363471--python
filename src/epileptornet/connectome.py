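"""Structural connectome container, I/O, graph summaries and synthesis.

A connectome is a symmetric, non-negative region-by-region weight matrix with
zero diagonal, normalized to unit maximum (streamline counts rescaled so the
strongest connection equals 1).  No thresholding of weak edges is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Relative tolerance beyond which asymmetry is a hard error rather than noise.
SYMMETRY_RTOL = 1e-8


@dataclass
class Connectome:
    labels: list[str]
    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.labels)
        if self.C.shape != (n, n):
            raise ValueError(
                f"weight matrix shape {self.C.shape} does not match "
                f"{n} region labels"
            )
        if np.any(self.C < 0):
            raise ValueError("connectome weights must be non-negative")
        scale = max(np.abs(self.C).max(), 1.0)
        if np.abs(self.C - self.C.T).max() > SYMMETRY_RTOL * scale:
            raise ValueError("connectome matrix is not symmetric")
        if np.any(np.diag(self.C) != 0):
            warnings.warn("nonzero diagonal entries set to 0 (self-connections)")
            np.fill_diagonal(self.C, 0.0)
        m = self.C.max()
        if m > 0 and not np.isclose(m, 1.0):
            self.C = self.C / m

    @property
    def n(self) -> int:
        return len(self.labels)

    def node_strength(self) -> np.ndarray:
        """Row sums of the weight matrix (structural strength per region)."""
        return self.C.sum(axis=1)

    def total_streamline_weight(self) -> float:
        """Sum of all (undirected) connection weights."""
        return float(self.C.sum()) / 2.0


def node_strength(conn: Connectome) -> np.ndarray:
    return conn.node_strength()


def read_connectome(path: str | Path, labels_path: str | Path | None = None) -> Connectome:
    """Read a connectome from a CSV/TSV square matrix.

    If the file has a header row of region names it is used for labels;
    otherwise ``labels_path`` must point to a one-column label file.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    if labels_path is not None:
        labels = [ln.strip() for ln in Path(labels_path).read_text().splitlines() if ln.strip()]
        mat = pd.read_csv(path, sep=sep, header=None,
                          float_precision="round_trip").to_numpy(dtype=float)
    else:
        df = pd.read_csv(path, sep=sep, index_col=None,
                         float_precision="round_trip")
        labels = list(df.columns)
        mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"connectome matrix is not square: {mat.shape}")
    if len(labels) != mat.shape[0]:
        raise ValueError(
            f"label count {len(labels)} does not match matrix size {mat.shape[0]}"
        )
    return Connectome(labels=labels, C=mat)


def write_connectome(conn: Connectome, path: str | Path) -> None:
    """Write the connectome as CSV with a header row of region labels."""
    df = pd.DataFrame(conn.C, columns=conn.labels)
    df.to_csv(path, index=False, float_format="%.17g")


def synthetic_connectome(
    n_regions: int,
    density: float = 1.0,
    sigma: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    labels: list[str] | None = None,
) -> Connectome:
    """Generate a streamline-count-like synthetic connectome.

    Weights are drawn from a log-normal distribution (heavy-tailed, like DTI
    streamline counts), symmetrized, optionally sparsified to the requested
    edge density, zero-diagonal and max-normalized.

    Parameters
    ----------
    n_regions : number of regions (>= 2).
    density : fraction of off-diagonal pairs with nonzero weight.
    sigma : log-normal shape parameter of the weights.
    seed : RNG seed or SeedSequence (fully reproducible).
    """
    if n_regions < 2:
        raise ValueError("a connectome needs at least 2 regions")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    W = rng.lognormal(mean=0.0, sigma=sigma, size=(n_regions, n_regions))
    W = np.triu(W, k=1)
    if density < 1.0:
        iu = np.triu_indices(n_regions, k=1)
        n_edges = len(iu[0])
        keep = rng.random(n_edges) < density
        # guarantee connectivity of the sampled graph is not required; at
        # least one edge must survive so max-normalization is well defined
        if not keep.any():
            keep[rng.integers(n_edges)] = True
        mask = np.zeros((n_regions, n_regions), dtype=bool)
        mask[iu] = keep
        W = np.where(mask, W, 0.0)
    W = W + W.T
    if labels is None:
        labels = [f"node{i:02d}" for i in range(n_regions)]
    return Connectome(labels=labels, C=W)
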