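"""Full forward chain: network simulation -> BOLD -> RS-FC observables.

A 6-node synthetic connectome runs in the spike-free resting state (all
regions healthy, p = 0.1) for ~7 minutes; the mixed neural output drives the
Balloon-Windkessel model, the BOLD is downsampled to TR 3.6 s, global-mean
regressed and band-passed 0.01-0.1 Hz, and the five observables are
computed.
"""

import numpy as np

from epileptornet import (
    MetricConfig,
    SweepConfig,
    IntegrationConfig,
    ZoneAssignment,
    build_map,
    forward_bold,
    synthetic_connectome,
)
from epileptornet.metrics import bold_observables

conn = synthetic_connectome(6, seed=3)
cfg = SweepConfig(seed=42,
                  integration=IntegrationConfig(duration=440.0, seed=42),
                  metrics=MetricConfig(mse_scales=(1, 2, 3, 4, 5)))
emap = build_map(conn.labels, ZoneAssignment.all_niz(conn.labels),
                 "spike_free", a=1.74)
bold = forward_bold(conn, emap, K_rs=10.0, cfg=cfg)
print(f"BOLD: {bold.n_regions} regions x {bold.n_samples} samples at "
      f"TR {bold.TR} s")

obs = bold_observables(bold, cfg.metrics)
tri = obs["spcc"][np.triu_indices(conn.n, k=1)]
print(f"sPCC off-diagonal: mean {tri.mean():+.3f}, range "
      f"[{tri.min():+.3f}, {tri.max():+.3f}]")
print(f"FCD matrix: {obs['fcd'].shape[0]} windows of 60 s")
print(f"coherence R-bar = {obs['coherence']:.3f}, "
      f"metastability sigma_R = {obs['metastability']:.3f}")
print(f"MSE profile (region 0, scales 1-5): "
      f"{np.round(obs['mse'][0], 2)}")
print()
print("Coherence/metastability describe how uniformly the regional BOLD "
      "phases align over time; the MSE profile measures signal complexity "
      "per region across temporal scales of 3.6-18 s.")
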