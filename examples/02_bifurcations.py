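"""Locate the two critical points of the isolated node by bisection.

The Hopf pair switches from damped to self-sustained ~10 Hz oscillation at
a_critic; the Epileptor subsystem starts seizing autonomously above
x0_critic.  Both are deterministic properties found from noise-free runs.
"""

from epileptornet import find_bifurcation, spectral_peak_hz

a_c = find_bifurcation("a", (1.0, 2.5), tol=0.01)
print(f"Hopf critical excitability  a_critic ~ {a_c:.3f}   (expected ~1.74)")

x0_c = find_bifurcation("x0", (-2.5, -1.5), tol=0.01)
print(f"Seizure threshold          x0_critic ~ {x0_c:.3f}  (expected ~-2.05)")

f = spectral_peak_hz(a=1.8)
print(f"Supercritical spectral peak          ~ {f:.2f} Hz (expected ~10 Hz)")
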