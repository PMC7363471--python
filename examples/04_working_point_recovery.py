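"""Fit the model working point to pseudo-empirical BOLD by Global Similarity.

Ground-truth BOLD is generated at a known working point (a, K_rs); a coarse
3x3 sweep with different noise seeds (common across cells) then relocates it
as the Global-Similarity argmin.  GS combines the five comparison metrics
(quadratic in the MSE distance, linear in the rest) normalized to [1, 2];
smaller is better.
"""

from epileptornet import (
    IntegrationConfig,
    SweepConfig,
    pseudo_empirical_bold,
    synthetic_connectome,
    working_point_sweep,
)

conn = synthetic_connectome(8, seed=2024)
cfg = SweepConfig(seed=11, integration=IntegrationConfig(duration=440.0, seed=11))

truth = {"a": 1.9, "K_rs": 10.0}
ref = pseudo_empirical_bold(conn, a=truth["a"], K_rs=truth["K_rs"],
                            seed=99, cfg=cfg)
print(f"reference generated at {truth}")

res = working_point_sweep(conn, [1.6, 1.9, 2.2], [5.0, 10.0, 20.0], ref, cfg)
print(res.table[["a", "K_rs", "corr", "ks", "dcoh", "dmeta", "rmsd", "gs"]]
      .round(3).to_string(index=False))
print(f"GS argmin at {res.optimum}")
print()
print("The K_rs (coupling) axis is well identified; the excitability axis "
      "is nearly flat at this scale because the correlation-based "
      "observables normalize away the amplitude changes that a produces "
      "(see docs/methods.md).")
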