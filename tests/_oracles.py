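"""Independent fixed-step RK4 oracle for the supply-demand ODEs.

Re-implements the dynamics from the model definition with its own demand
evaluation and a classical Runge-Kutta stepper, sharing no code path with
the package's adaptive integrator.
"""

from __future__ import annotations

import math

import numpy as np


def rk4_reference(params, demand_fn, t_end=288.0, h=0.001, sample=0.1,
                  initial_state=(0.0, 0.0)):
    """Fixed-step RK4 integration; returns (times, x_m, x_c) sampled every
    ``sample`` T-units.  ``demand_fn`` is an independent evaluator of E(t)."""
    lam, D = params.synthesis_rate, params.transport_rate
    nm, nc = params.degradation_organelle, params.degradation_cytosol
    p, alpha = params.wildtype_fraction, int(params.encoding)

    def deriv(t, xm, xc):
        fb = max(0.0, demand_fn(t) - xm)
        dxm = (1 - alpha) * lam * p * fb + D * xc - nm * xm
        dxc = alpha * lam * fb - (D + nc) * xc
        return dxm, dxc

    n = int(round(t_end / h))
    per = int(round(sample / h))
    xm, xc = initial_state
    out_t, out_m, out_c = [0.0], [xm], [xc]
    for i in range(n):
        t = i * h
        k1 = deriv(t, xm, xc)
        k2 = deriv(t + h / 2, xm + h / 2 * k1[0], xc + h / 2 * k1[1])
        k3 = deriv(t + h / 2, xm + h / 2 * k2[0], xc + h / 2 * k2[1])
        k4 = deriv(t + h, xm + h * k3[0], xc + h * k3[1])
        xm += h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        xc += h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        if (i + 1) % per == 0:
            out_t.append((i + 1) * h)
            out_m.append(xm)
            out_c.append(xc)
    return np.array(out_t), np.array(out_m), np.array(out_c)


def sinusoid(a, b, k, tau=144.0):
    """Independent periodic demand evaluator for the oracle."""
    omega = 2.0 * math.pi * k / tau
    return lambda t: a * (1.0 + b * math.sin(omega * t))
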