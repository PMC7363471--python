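"""Parameter containers for the hybrid Epileptor/Hopf node and its integration.

Each brain region couples an Epileptor subpopulation (six state variables
``x1, y1, z, x2, y2, g``) generating epileptiform discharges with a
supercritical-Hopf pair (``x3, y3``) generating physiological resting-state
oscillation near 10 Hz.  Time is measured in milliseconds throughout the
neural model; durations exposed to users are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Critical value of the Hopf bifurcation parameter ``a``.  Closed form: the
#: (x3, y3) fixed point satisfies a = 10*x + x**3 - 3*x**2 and loses stability
#: where the Jacobian trace -3*x**2 + 6*x - 1 vanishes, i.e. x = 1 - sqrt(6)/3.
A_CRITIC = 1.7402

#: Epileptogenicity above which an isolated node seizes autonomously.
X0_CRITIC = -2.05


@dataclass(frozen=True)
class NodeParameters:
    """Per-region parameters of the hybrid node.

    ``x0`` (epileptogenicity), ``a`` (Hopf excitability) and ``p`` (mixing
    ratio of epileptiform vs healthy output) define a region's role; all
    remaining parameters are fixed model constants.
    """

    x0: float = -2.5
    a: float = A_CRITIC
    p: float = 0.1
    b2: float = 4.0
    m: float = 0.0
    I_ext1: float = 3.1
    I_ext2: float = 0.45
    tau0: float = 28571.0
    tau2: float = 25.0
    gamma: float = 0.01
    d: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"mixing ratio p must lie in [0, 1], got {self.p}")
        for name in ("tau0", "tau2", "gamma", "d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CouplingParameters:
    """Global scaling of the two coupling pathways.

    ``K_s`` scales the slow permittivity coupling between Epileptor
    subpopulations (enters the z-equation through weighted x1 differences);
    ``K_rs`` scales the fast diffusive coupling between Hopf subpopulations.
    """

    K_s: float = 0.1
    K_rs: float = 0.0

    def __post_init__(self) -> None:
        if self.K_s < 0 or self.K_rs < 0:
            raise ValueError("coupling strengths must be non-negative")


@dataclass(frozen=True)
class IntegrationConfig:
    """Stochastic Heun integration settings.

    Noise strengths are additive diffusion coefficients sigma: each step adds
    Gaussian increments of standard deviation sqrt(2*sigma*dt) to x2, y2
    (``noise_x2y2``) and x3 (``noise_x3``).  ``store_every`` thins the stored
    trajectory (default every 10th step, i.e. 1 ms at dt = 0.1 ms).
    """

    dt: float = 0.1  # ms
    duration: float = 1200.0  # s
    discard: float = 20.0  # s
    seed: int = 42
    noise_x2y2: float = 0.00025
    noise_x3: float = 0.02
    store_every: int = 10

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.discard < self.duration:
            raise ValueError("discard must be smaller than duration")
        if self.noise_x2y2 < 0 or self.noise_x3 < 0:
            raise ValueError("noise strengths must be non-negative")
        if self.store_every < 1:
            raise ValueError("store_every must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * 1000.0 / self.dt))

    @property
    def dt_store(self) -> float:
        """Sampling interval of the stored trajectory in ms."""
        return self.dt * self.store_every


@dataclass(frozen=True)
class HemodynamicParameters:
    """Balloon-Windkessel constants (Friston et al. 2003 values).

    Units: rate constants in 1/s, transit time in s.  ``epsilon`` is the
    neuronal efficacy scaling the (demeaned) neural drive; ``V0`` the resting
    venous volume fraction.
    """

    kappa: float = 0.65  # signal decay rate (1/s)
    gamma: float = 0.41  # autoregulatory feedback rate (1/s)
    tau: float = 0.98  # mean transit time (s)
    alpha: float = 0.32  # vessel stiffness exponent
    rho: float = 0.34  # resting oxygen extraction fraction
    V0: float = 0.02  # resting venous volume fraction
    epsilon: float = 1.0  # neuronal efficacy

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "alpha", "rho", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class MetricConfig:
    """Settings for the resting-state functional-connectivity observables."""

    window_s: float = 60.0  # FCD sliding-window length (s)
    step_tr: int = 1  # FCD window increment in TRs
    mse_scales: tuple[int, ...] = tuple(range(1, 14))
    mse_m: int = 1
    mse_r_factor: float = 0.35
    phase_trim: float = 0.05  # fraction of phase samples trimmed at each edge
    fcd_exclude_overlap: bool = False

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.mse_scales):
            raise ValueError("MSE scale factors must be positive integers")
        if not 0 <= self.phase_trim < 0.5:
            raise ValueError("phase_trim must lie in [0, 0.5)")


def node_parameter_arrays(
    params: "NodeParameters | list[NodeParameters]", n: int
) -> dict[str, np.ndarray]:
    """Broadcast node parameters to per-region arrays (x0, a, p, b2)."""
    if isinstance(params, NodeParameters):
        params = [params] * n
    if len(params) != n:
        raise ValueError(f"expected {n} node parameter sets, got {len(params)}")
    return {
        name: np.array([getattr(q, name) for q in params], dtype=float)
        for name in ("x0", "a", "p", "b2")
    }
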