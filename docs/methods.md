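# Methods

## The hybrid node model

Each brain region is a neural mass with two interacting subpopulations.

**Epileptor subpopulation** (`x1, y1, z, x2, y2, g`): a phenomenological
model of seizure dynamics. The fast pair (x1, y1) produces ictal fast
discharges, the second pair (x2, y2) produces spike-wave events, `g` is a
slow low-pass filter of x1 feeding the second pair, and `z` is the slow
permittivity variable (time constant tau0 = 28571 ms) that switches the
region between interictal and ictal states. The epileptogenicity `x0`
controls the z-equilibrium: above x0_critic ≈ −2.05 the fixed point of the
fast subsystem vanishes (the fold of the left branch of the cubic x1
nullcline sits at x1 = −4/3, z ≈ 2.914) and the region cycles through
seizures autonomously. Below threshold, the second population sits close to
its firing threshold when x0 is just subcritical, so noise triggers
interictal spikes whose rate falls as the spike-frequency parameter `b2`
grows (b2 = 2: near-continuous spiking; b2 = 4, the default: ~0.1–0.3
events/min; b2 ≥ 6: silent).

**Hopf subpopulation** (`x3, y3`): an excitable oscillator equivalent to
the normal form of a supercritical Hopf bifurcation, modelling healthy
resting-state activity:

    x3' = d (y3 + 3 x3^2 − x3^3 + coupling)
    y3' = d (a − 10 x3 − y3)

Linear stability at the fixed point (trace −3x² + 6x − 1 = 0 with
a = 10x + x³ − 3x²) gives the critical excitability a_critic = 1.7402 and an
angular frequency of 3d rad/ms at the bifurcation — 9.55 Hz for the default
rate d = 0.02, the dominant resting rhythm. Below a_critic the node shows
noise-driven damped oscillation; above it a stable limit cycle.

**Output mixing.** The regional output is `p·(−x1 + x2) + (1 − p)·x3`: the
mixing ratio p exposes the epileptiform ensemble (p → 1) or the healthy
oscillation (p → 0).

**Network coupling.** Regions are linked by a symmetric, zero-diagonal,
max-normalized structural connectome C. Two pathways, both instantaneous:
slow *permittivity coupling* in the z-equation,
`z' = (4(x1 − x0) − z − K_s Σ_j C_ij (x1_j − x1_i)) / tau0` (excitatory input
from the network lowers z and recruits the region toward seizure; K_s fixed
at 0.1), and fast *diffusive coupling* `+ K_rs Σ_j C_ij (x3_j − x3_i)` inside
the x3-equation (scanned during fitting).

## Integration

Stochastic Heun (predictor–corrector) at dt = 0.1 ms. Additive white
Gaussian noise enters x2 and y2 (strength 0.00025) and x3 (strength 0.02);
a "strength" sigma means per-step increments of SD sqrt(2·sigma·dt), the
same noise realization entering predictor and corrector. Every node owns an
independent `numpy` Generator spawned from the run seed, so a zero-coupling
network is bit-identical to isolated single-node runs and all results are
seed-reproducible. The first 20 s are discarded. Trajectories are stored
every 10th step (1 ms).

Initial conditions are drawn uniformly within per-variable physiological
ranges (x1 ∈ [−2, 1], y1 ∈ [−20, 2], z ∈ [2, 5], x2 ∈ [−2, 0], y2 ∈ [0, 2],
g ∈ [−1, 1], x3 ∈ [−2, 4], y3 ∈ [−6, 6]). Starting z near 0 would place the
fast subsystem in a stiff regime (local growth ~10/ms from the 0.6(z − 4)²
term) where a 0.1 ms step diverges; the discarded transient erases the
choice of IC distribution. Divergence (|state| > 1e6 or non-finite) raises
an error naming the node and time.

## Hemodynamics and BOLD post-processing

The mixed output, demeaned per region, drives the Balloon–Windkessel model
with the standard Friston constants (signal decay kappa = 0.65 s⁻¹,
autoregulation gamma = 0.41 s⁻¹, transit time tau = 0.98 s, stiffness
alpha = 0.32, resting oxygen extraction rho = 0.34, venous volume
V0 = 0.02); the readout is percent signal change. Integration is Heun at
the stored neural rate; non-positive inflow/volume/deoxyhemoglobin states
are an error. Post-processing mirrors resting-state fMRI conditions:
anti-aliased decimation (4th-order zero-phase Butterworth at the TR Nyquist,
then sample picking) to TR 3.6 s, global-mean regression (with intercept),
then a zero-phase 3rd-order Butterworth band-pass 0.01–0.1 Hz — in that
order; the regression is a flag since small networks behave differently
under it (below). Pipelines drop the first 36 s of raw BOLD for the
hemodynamic transient.

## Observables and fitting

* **sPCC**: full-window Pearson correlation matrix; two series are compared
  by correlating strictly-upper-triangle entries.
* **FCD**: sliding-window sPCC (window = ceil(60 s / TR) = 17 samples,
  advancing 1 TR; a 344-sample series yields 328 windows), then
  window-by-window correlation of upper triangles. Distributions of FCD
  values are compared by the two-sample Kolmogorov–Smirnov distance.
* **Coherence / metastability**: mean and SD over time of the Kuramoto
  order parameter of the regional Hilbert phases. Regions are demeaned
  before the transform and 5% of phase samples are trimmed at each edge
  against transform edge effects.
* **MSE**: sample entropy (m = 1, Chebyshev norm, tolerance r = 0.35 × SD
  of the original series, held fixed across scales, self-matches excluded)
  of coarse-grained series at scales 1..13 (3.6–46.8 s at TR 3.6 s).
  Degenerate cases are flagged (constant series → NaN; no template matches
  → inf), never silent. Profiles are compared by RMSD. Short desk-scale
  runs use scales 1..5 — 13 scales need ≥ 130 BOLD samples (~8 min).
* **Global Similarity**: raw score |ΔCoh| + |ΔMeta| + (1 − corr) + KS +
  RMSD² (quadratic weight on the complexity distance, linear on the rest),
  min–max normalized to [1, 2] over a sweep; the optimum is the argmin.

Statistical comparisons of connectivity samples use the two-tailed Wilcoxon
rank-sum test (significance p < 0.05 ⇔ |z| > 1.96); samples of fewer than
two values (e.g. a two-region irritative zone) are a documented error.

## Scenarios

Zone semantics: EZ_IZ1 (seizure-generating), PZ_IZ2 (secondarily involved,
spiking), NIZ (uninvolved). Scenario defaults: *spike-free* — p = 0.1,
x0 = −2.5 everywhere, homogeneous a; *spiking* — p = 0.9/0.7/0.1 and
x0 = −2.07/−2.25/−2.55 for EZ/PZ/NIZ (offsets 0, 0.2, 0.5 below threshold),
homogeneous a = 1.74; *hyperexcitable* — spike-free p and x0 with
a > a_critic in EZ ∪ PZ and a = a_critic in NIZ. The NIZ mixing ratio in
the spiking scenario is not separately specified anywhere; the spike-free
value 0.1 is used (overridable). All zone values are override-able per
scenario.

## Trace classification

Spike detection: the output is high-passed above 15 Hz — well above the
~9.5 Hz healthy rhythm, so only the fast edges of epileptiform transients
survive — and events are excursions beyond 5 robust SDs (1.4826·MAD) with a
200 ms refractory period. On silent traces this detector produced zero
false events per 600 s across seeds; a 3-SD threshold on the broadband
signal would instead false-alarm on the near-Gaussian healthy oscillation
at ~6/min. Seizure detection exploits the ictal baseline shift: the
epileptiform ensemble moves to its ictal branch, shifting the low-passed
(0.2 Hz) output by ≈ 0.9·p model units; episodes are sustained (≥ 3 s)
deviations beyond 0.25 from the median. The 3 s minimum reflects the
model's seizure duration at these time constants (≈ 6.5 s at x0 = −1.9,
set by tau0 and the z excursion); an absolute threshold is appropriate
because the output scale is fixed by the equations, not by any gain. A
trace is *seizing* if an episode is found, else *spiking* if any event
fired, else *silent*.

## Bifurcation location

Both critical values are deterministic properties located by bisection on
noise-free runs from fixed initial conditions near the subcritical
equilibrium (found by root-finding on the drift). For `a`: a 0.3 kick on
x3, 300 s horizon, sustained oscillation = tail (last 50 s) peak-to-peak
> 0.02 — at 0.005 from the critical point the two outcomes differ by two
orders of magnitude, so the threshold is uncritical. For `x0`: 600 s
horizon, seizure = x1 crossing −1.0 (past the fold at x1 = −4/3). The
measured dynamical threshold is ≈ −2.06, slightly below the printed −2.05,
consistent with the fold analysis of the transcribed equations
(equilibrium existence ends at x0 ≈ −2.062).

## Experiment design at desk scale

The shipped experiments run on synthetic connectomes (log-normal,
heavy-tailed weights, symmetrized, max-normalized — streamline-count-like)
of 8–10 regions for 440 s of model time, a deliberate stand-in for
84-region, 20-minute runs; pseudo-empirical reference BOLD is generated by
the model itself at known (a, K_rs) so that recovery has a ground truth.

Two design choices matter and were fixed after an explicit sensitivity
analysis:

* **Common random numbers.** Sweep cells share per-node noise streams
  (while still differing from the reference seed). With independent
  per-cell seeds the seed-to-seed scatter of the comparison metrics
  (SD ≈ 0.1 in the sPCC correlation at 440 s) dominates the landscape;
  with common noise the landscape is smooth and differences between cells
  reflect the parameters.
* **Identifiability.** At the printed x3 noise strength the Hopf envelope
  decorrelates within ~25–100 ms whatever `a` is, so all BOLD-band
  (0.01–0.1 Hz) signal content is a flat noise floor and the
  correlation-based observables are insensitive to `a` (raw-score changes
  ~1e-3 across a ∈ [1.3, 2.5]); `a` mainly rescales amplitudes, which
  correlation, phase and SD-normalized entropy metrics remove. The
  coupling K_rs, in contrast, shapes the correlation structure directly
  and is recovered to within one grid step (with a reproducible one-step
  bias toward stronger coupling: higher-coupling simulations have higher
  deterministic SNR and correlate better with any reference). The recovery
  grid therefore spans the full sub- to supercritical range
  (a ∈ [1.3, 2.5] × K_rs ∈ [0, 40]) as a coarse search; on the `a` axis
  the argmin position within the grid should be read as unconstrained.
* **Global-mean regression in perturbation experiments.** A single
  perturbed region expresses its influence as a network-wide coherent
  change; in an 8-node network global-mean regression removes exactly that
  component (hyperexcitability effect +0.002…+0.003 in mean sPCC without
  regression, −1e-5 and sign-unstable with it). The perturbation
  experiments therefore default to the unregressed series; the
  working-point fitting keeps the full pipeline.

Control/condition pairs always share noise streams, so differences reflect
the manipulation. Failed (diverging) sweep cells are recorded and skipped,
never aborting a sweep.

## What the synthetic data do and do not show

The synthetic connectome reproduces the weight statistics (heavy tail,
symmetry, normalization) but not the topology, hemispheric structure or
subject specificity of tractography; pseudo-empirical BOLD shares the
model's own dynamics, so recovery experiments validate the fitting
machinery, not the model's fit to real brains. Passing tests demonstrate
internal consistency of the chain (dynamics → hemodynamics → observables →
score) and the printed intrinsic properties of the node model; they say
nothing about empirical working points of patients or controls, which
require data this package does not ship.

## Known limitations

* No transmission delays (coupling is instantaneous by design).
* The `a` axis of the fitting landscape is unidentifiable at desk scale
  (above); distinguishing sub- from supercritical working points likely
  requires amplitude-sensitive observables or far longer recordings.
* Sample entropy is the O(N²) definition — fine for BOLD-length series,
  not meant for raw neural traces.
* The Desikan–Killiany label/abbreviation mapping is best-effort: the 84
  regions are counted as 35 "cortical" labels per hemisphere (34 cortical
  parcels plus the cerebellar cortex) and 7 subcortical structures per
  hemisphere.
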