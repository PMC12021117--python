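"""Perfect tracking with the exact actionable target.

A first-order system dy/dt = b0 (f - y) cannot follow a moving optimum when
it adapts toward the optimum itself (it lags and shrinks), but it tracks
perfectly when it adapts toward f = y_o + (1/b0) dy_o/dt.  This script
integrates both strategies on a 24-h sinusoidal optimum and prints the
post-transient tracking error of each.
"""

import numpy as np

from adaptrack import integrate_exact

B0 = 1.0 / 3.0  # adaptation rate, 1/h

t = np.arange(0.0, 96.0, 0.005)  # four days, fine grid (hours)
omega = 2 * np.pi / 24.0
y_opt = np.sin(omega * t)

naive = integrate_exact(B0, y_opt, t, y0=0.0)
actionable = integrate_exact(B0, y_opt + (omega / B0) * np.cos(omega * t), t, y0=0.0)

post = t > 10.0 / B0  # discard the exp(-b0 t) transient
print(f"max |y - y_o| adapting to the optimum itself : {np.max(np.abs(naive[post] - y_opt[post])):.4f}")
print(f"max |y - y_o| adapting to the actionable target: {np.max(np.abs(actionable[post] - y_opt[post])):.2e}")
print()
print("The first number is the irreducible lag-and-attenuation error of naive")
print("adaptation (~omega/b0 in phase); the second shows the actionable target")
print("restores tracking to integrator precision without using future values.")
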