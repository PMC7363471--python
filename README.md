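# epileptornet

Brain-network-model simulations of the **interictal resting state in
epilepsy**: a hybrid neural mass that mixes an epileptogenic subpopulation
(the Epileptor seizure model) with a healthy subpopulation (a
supercritical-Hopf oscillator) in every brain region, coupled through a
structural connectome; a Balloon–Windkessel BOLD forward model; the
standard resting-state functional-connectivity observables; and a composite
Global Similarity score for fitting the model's working point to reference
fMRI data.

Intended for computational neuroscientists studying how epileptogenic
regions express themselves *between* seizures: which working point
(excitability `a`, global coupling `K_rs`) best reproduces resting-state
BOLD statistics, and how interictal spikes or regional hyperexcitability
reshape whole-brain functional connectivity.

## The model

Each region `i` carries eight state variables. The Epileptor block
(`x1, y1, z, x2, y2, g`) generates seizures and interictal spikes gated by
the epileptogenicity `x0_i` (autonomous seizures above `x0_critic ≈ −2.05`);
the Hopf pair (`x3, y3`)

```
x3' = d (y3 + 3 x3² − x3³ + K_rs Σ_j C_ij (x3_j − x3_i))
y3' = d (a_i − 10 x3 − y3)
```

generates ~10 Hz resting oscillation, damped below `a_critic = 1.7402` and
self-sustained above it (d = 0.02 sets the frequency). Regions couple by
slow permittivity coupling (`−K_s Σ_j C_ij (x1_j − x1_i)` in the
z-equation, `K_s = 0.1`) and fast diffusive coupling (above). The regional
output `p_i (−x1 + x2) + (1 − p_i) x3` mixes epileptiform and healthy
activity; clinical zones (EZ/IZ1, PZ/IZ2, NIZ) map onto per-region
`(x0, a, p)` scenarios. Integration is stochastic Heun at dt = 0.1 ms with
additive noise on x2, y2 (0.00025) and x3 (0.02).

Simulated BOLD (Balloon–Windkessel, TR 3.6 s, global-mean regressed,
0.01–0.1 Hz band) is summarized by five observables — static Pearson
correlation (sPCC), functional connectivity dynamics (FCD) compared by
Kolmogorov–Smirnov distance, Kuramoto coherence and metastability, and
multiscale sample entropy (m = 1, r = 0.35·SD, scales 1..13) compared by
RMSD — combined into the Global Similarity score
`|ΔCoh| + |ΔMeta| + (1 − corr) + KS + RMSD²`, normalized to [1, 2] over a
sweep; its argmin is the optimal working point. See `docs/methods.md`.

## Worked example

```python
from epileptornet import (CouplingParameters, IntegrationConfig,
                          NodeParameters, classify_trace, simulate,
                          single_node_connectome)

cfg = IntegrationConfig(duration=600.0, seed=1)   # 10 min of model time
traj = simulate(single_node_connectome(),
                NodeParameters(x0=-2.07, a=1.74, p=0.7),
                CouplingParameters(), cfg)
cls = classify_trace(traj.output[0], traj.dt_store)
print(cls.label, round(cls.spike_rate, 2))
```

prints

```
spiking 0.1
```

an isolated region just below the seizure threshold (`x0 = −2.07`, with the
epileptiform ensemble dominating the output at `p = 0.7`) produces sparse
interictal spikes (~0.1 events/min at the default spike-frequency parameter
b2 = 4; lowering b2 to 2 yields near-continuous spiking); at `x0 = −1.9` the same region is
classified `seizing` (recurrent ~6.5 s seizures), at `x0 = −2.5` `silent`.

The `examples/` directory has one short script per capability: single-node
phenotypes, bifurcation location, the full BOLD/observables chain,
working-point recovery by Global Similarity, and the spiking/
hyperexcitability perturbation experiments. A thin CLI mirrors the
pipelines (`epileptornet simulate`, `sweep-working-point`, `sweep-spiking`,
`sweep-hyperexcitable`, `compare`).

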