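"""Two-compartment supply-and-demand dynamics for one organelle gene.

The cell tries to match the amount of functional gene product in the
organelle, x_m(t), to an environmental demand E(t).  Expression is driven
by a deficit-sensing feedback f(E, x_m) = max(0, E - x_m).  The gene may be
encoded in the organelle itself (alpha = 0), where a mutational load reduces
the functional fraction of organelle DNA to p, or in the nucleus
(alpha = 1), where the product is made in the cytosol (amount x_c) and must
be imported at rate D while being degraded at rate nu_c before import:

    dx_m/dt = (1 - alpha) * lambda * p * f(E, x_m) + D * x_c - nu_m * x_m
    dx_c/dt = alpha * lambda * f(E, x_m) - D * x_c - nu_c * x_c

All rates are per T-unit (T = 10 min).  The system is linear within each
branch of f; the kink at x_m = E makes the right-hand side non-smooth but
Lipschitz, which the adaptive LSODA integrator handles without event
detection.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .environments import Environment

__all__ = [
    "Encoding",
    "ModelParameters",
    "Trajectory",
    "SimulationError",
    "feedback",
    "rhs",
    "simulate",
]


class Encoding(IntEnum):
    """Compartment in which the gene is encoded.

    Exactly two strategies exist: ORGANELLE (alpha = 0, the gene sits on
    organelle DNA and expression is scaled by the wild-type fraction p) and
    NUCLEUS (alpha = 1, the product is synthesized in the cytosol and
    imported).  Intermediate values are not part of the model.
    """

    ORGANELLE = 0
    NUCLEUS = 1


@dataclass(frozen=True)
class ModelParameters:
    """Cell-biological rate constants for one gene/species scenario.

    Parameters
    ----------
    synthesis_rate : lambda, gene-product synthesis rate (per T).  The yeast
        reference estimate is ~0.1/min, i.e. 1 per T-unit.
    transport_rate : D, cytosol-to-organelle import rate (per T); plausible
        range ~0.1-10.  Low D models hard-to-import (e.g. hydrophobic)
        products.
    degradation_organelle : nu_m, degradation rate inside the organelle
        (per T); protein half-lives of hours-days suggest ~0.01-0.1.
    degradation_cytosol : nu_c, degradation rate in the cytosol (per T);
        a ~43 min cytosolic half-life gives ~0.1.
    wildtype_fraction : p, proportion of undamaged (wild-type) organelle DNA
        in [0, 1]; 1 - p is the coarse-grained mutational load.
    encoding : which compartment carries the gene (alpha tag).
    """

    synthesis_rate: float = 1.0
    transport_rate: float = 1.0
    degradation_organelle: float = 0.1
    degradation_cytosol: float = 0.1
    wildtype_fraction: float = 1.0
    encoding: Encoding = Encoding.ORGANELLE

    def __post_init__(self):
        for name in ("synthesis_rate", "transport_rate",
                     "degradation_organelle", "degradation_cytosol"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative "
                                 f"number, got {v!r}")
        p = self.wildtype_fraction
        if not (isinstance(p, (int, float)) and math.isfinite(p)) or not 0 <= p <= 1:
            raise ValueError(f"wildtype_fraction must lie in [0, 1], got {p!r}")
        if self.encoding not in (0, 1):
            raise ValueError(f"encoding must be 0 (organelle) or 1 (nucleus), "
                             f"got {self.encoding!r}")
        object.__setattr__(self, "encoding", Encoding(self.encoding))

    def with_encoding(self, encoding: Encoding) -> "ModelParameters":
        """Copy of these parameters under the other encoding strategy."""
        return dataclasses.replace(self, encoding=Encoding(encoding))

    # convenient short aliases matching the field's usual symbols
    @property
    def lam(self) -> float:
        return self.synthesis_rate

    @property
    def D(self) -> float:
        return self.transport_rate

    @property
    def nu_m(self) -> float:
        return self.degradation_organelle

    @property
    def nu_c(self) -> float:
        return self.degradation_cytosol

    @property
    def p(self) -> float:
        return self.wildtype_fraction

    @property
    def alpha(self) -> int:
        return int(self.encoding)


class SimulationError(RuntimeError):
    """Integrator failure; carries the parameter set that failed."""

    def __init__(self, message: str, params: ModelParameters,
                 environment: Environment):
        super().__init__(message)
        self.params = params
        self.environment = environment


def feedback(demand: float, x_m: float) -> float:
    """Deficit-sensing signalling function f(E, x_m) = max(0, E - x_m).

    Expression is switched on in proportion to the shortfall of organelle
    supply below demand and off entirely once supply meets demand.
    Continuous, piecewise linear, non-negative.
    """
    if demand < 0 or x_m < 0:
        raise ValueError(
            f"feedback requires non-negative inputs, got E={demand}, x_m={x_m}"
        )
    return max(0.0, demand - x_m)


def rhs(t: float, state, params: ModelParameters,
        environment: Environment) -> tuple[float, float]:
    """Instantaneous rates (dx_m/dt, dx_c/dt) at time ``t``."""
    x_m, x_c = state
    if x_m < 0 or x_c < 0:
        raise ValueError(f"state must be non-negative, got {tuple(state)}")
    E = float(environment.evaluate(t))
    f = max(0.0, E - x_m)
    alpha = params.alpha
    dxm = (1 - alpha) * params.lam * params.p * f + params.D * x_c \
        - params.nu_m * x_m
    dxc = alpha * params.lam * f - (params.D + params.nu_c) * x_c
    return dxm, dxc


@dataclass(frozen=True)
class Trajectory:
    """Simulated time course of supply and demand for one scenario.

    ``time`` is a strictly increasing uniform grid (T-units); ``x_m`` and
    ``x_c`` are the organelle and cytosol amounts; ``demand`` is E(t) on the
    same grid.  ``clip_magnitude`` records the largest negative undershoot
    the solver produced before post-hoc clipping at zero (should be at the
    level of the integration tolerance).
    """

    time: np.ndarray
    x_m: np.ndarray
    x_c: np.ndarray
    demand: np.ndarray
    params: ModelParameters
    environment: Environment
    clip_magnitude: float = 0.0

    def __post_init__(self):
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.time,
            "x_m": self.x_m,
            "x_c": self.x_c,
            "E": self.demand,
            "alpha": self.params.alpha,
        })

    def to_csv(self, path) -> None:
        """Write columns time, x_m, x_c, E, alpha (times in T-units)."""
        self.to_frame().to_csv(path, index=False)

    def slice(self, t_start: float, t_end: float) -> "Trajectory":
        """Restrict to grid points with t_start <= t <= t_end."""
        mask = (self.time >= t_start - 1e-9) & (self.time <= t_end + 1e-9)
        if not mask.any():
            raise ValueError("window outside the trajectory time span")
        return Trajectory(self.time[mask], self.x_m[mask], self.x_c[mask],
                          self.demand[mask], self.params, self.environment,
                          self.clip_magnitude)


#: default solver tolerances (both relative and absolute)
SOLVER_TOL = 1e-8
#: default output grid spacing, T-units (1 minute)
DEFAULT_SAMPLING_STEP = 0.1


def simulate(params: ModelParameters, environment: Environment,
             window: tuple[float, float] = (0.0, 288.0),
             sampling_step: float = DEFAULT_SAMPLING_STEP,
             initial_state: tuple[float, float] = (0.0, 0.0)) -> Trajectory:
    """Integrate the dynamics over a time window.

    Uses LSODA (adaptive, stiff/non-stiff switching) with rtol = atol = 1e-8.
    For piecewise-constant (noisy) environments every level change is passed
    to the solver as a critical time, so integration never steps across a
    demand discontinuity.  Output is sampled on a uniform grid of spacing
    ``sampling_step`` covering the window; negative numerical undershoot is
    clipped at zero and its magnitude recorded on the trajectory.

    Default initial conditions are (x_m, x_c) = (0, 0): the cell starts with
    no gene product and the first simulated day is normally discarded as
    equilibration.
    """
    t_start, t_end = window
    if not t_start < t_end:
        raise ValueError(f"window must satisfy t_start < t_end, got {window}")
    if sampling_step <= 0:
        raise ValueError(f"sampling_step must be > 0, got {sampling_step}")
    x0, c0 = initial_state
    if x0 < 0 or c0 < 0:
        raise ValueError(f"initial state must be non-negative, got {initial_state}")

    n = max(2, int(round((t_end - t_start) / sampling_step)))
    grid = np.linspace(t_start, t_end, n + 1)

    lam, D, nu_m, nu_c, p = (params.lam, params.D, params.nu_m,
                             params.nu_c, params.p)
    alpha = params.alpha
    ev = environment._scalar_evaluator()
    loss_c = D + nu_c

    if alpha == 0:
        lp = lam * p

        def func(y, t):
            f = ev(t) - y[0]
            if f < 0.0:
                f = 0.0
            return (lp * f + D * y[1] - nu_m * y[0], -loss_c * y[1])
    else:
        def func(y, t):
            f = ev(t) - y[0]
            if f < 0.0:
                f = 0.0
            return (D * y[1] - nu_m * y[0], lam * f - loss_c * y[1])

    tcrit = environment.breakpoints(t_start, t_end)
    if len(tcrit):
        # append the window end so LSODA never probes beyond the realized
        # horizon of a piecewise-constant signal
        tcrit = np.append(tcrit, t_end)
    sol, info = odeint(func, [x0, c0], grid,
                       tcrit=tcrit if len(tcrit) else None,
                       rtol=SOLVER_TOL, atol=SOLVER_TOL,
                       mxstep=100_000, full_output=True,
                       printmessg=False)
    if info["message"] != "Integration successful.":
        raise SimulationError(
            f"LSODA failed: {info['message']} (params={params})",
            params, environment)

    undershoot = float(max(0.0, -sol.min()))
    sol = np.clip(sol, 0.0, None)
    demand = np.asarray(environment.evaluate(grid), dtype=float)
    return Trajectory(time=grid, x_m=sol[:, 0], x_c=sol[:, 1], demand=demand,
                      params=params, environment=environment,
                      clip_magnitude=undershoot)
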