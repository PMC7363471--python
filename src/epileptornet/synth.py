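"""Synthetic study data: pseudo-empirical BOLD with known ground truth.

The package ships no patient data; parameter-recovery experiments fit the
model to *pseudo-empirical* BOLD generated by the model itself at known
(a, K_rs) through the full forward chain, so that the target has exactly
the empirical format: region-by-time matrix at TR 3.6 s, global-mean
regressed and band-limited to 0.01-0.1 Hz.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .connectome import Connectome, synthetic_connectome  # re-export
from .experiments import SweepConfig, ZoneAssignment, build_map, forward_bold
from .hemo import BoldSeries

__all__ = ["synthetic_connectome", "pseudo_empirical_bold"]


def pseudo_empirical_bold(
    connectome: Connectome,
    a: float,
    K_rs: float,
    seed: int,
    cfg: SweepConfig | None = None,
) -> BoldSeries:
    """Ground-truth BOLD from the spike-free scenario at known (a, K_rs).

    ``seed`` controls the noise realization independently of any fitting
    sweep; the generating parameters are recorded in ``meta['truth']``.
    """
    cfg = cfg or SweepConfig()
    cfg = replace(cfg, seed=seed)
    zones = ZoneAssignment.all_niz(connectome.labels)
    emap = build_map(connectome.labels, zones, "spike_free", a=a)
    seeds = np.random.SeedSequence(entropy=seed, spawn_key=(0,)).spawn(connectome.n)
    bold = forward_bold(connectome, emap, K_rs, cfg, seed_sequences=seeds)
    bold.meta["truth"] = {"a": a, "K_rs": K_rs, "seed": seed}
    return bold
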