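"""Closed-form equilibria and the favourability condition (static demand).

With constant demand E(t) = a and positive organelle turnover the system
settles in the deficit branch of the feedback (x_m* < a), where the
dynamics are linear and solvable by hand:

    organelle encoding (alpha = 0):
        x_m* = lambda p a / (lambda p + nu_m),          x_c* = 0
    nuclear encoding (alpha = 1):
        x_m* = lambda D a / (lambda D + (D + nu_c) nu_m),
        x_c* = nu_m x_m* / D                            (D > 0)

The instantaneous cost of strategy alpha is C_alpha = a - x_m*, and their
ratio is independent of the demand scale a:

    C_0 / C_1 = (lambda D + (D + nu_c) nu_m) / ((lambda p + nu_m)(D + nu_c))

Nuclear encoding is favoured (C_0/C_1 > 1) exactly when D > p (D + nu_c):
fast import, little cytosolic loss, heavy organelle-DNA damage.  The
nu_m = 0 case is the perfect-adaptation limit in which either strategy
matches demand exactly and both instantaneous costs vanish.

These formulas double as oracles for the numerical integrator: simulated
static-environment costs must reproduce them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model_core import Encoding, ModelParameters

__all__ = [
    "EquilibriumSolution",
    "equilibrium",
    "cost_ratio",
    "favourability_condition",
]


@dataclass(frozen=True)
class EquilibriumSolution:
    """Steady state of one encoding strategy under static demand ``a``."""

    x_m_star: float
    x_c_star: float
    instantaneous_cost: float
    encoding: Encoding
    params: ModelParameters
    mean_demand: float


def equilibrium(params: ModelParameters, a: float = 1.0) -> EquilibriumSolution:
    """Closed-form steady state under static demand E(t) = a.

    Raises ``ValueError`` for degenerate parameter sets with no finite
    equilibrium (all synthesis and loss pathways switched off).
    """
    if a <= 0:
        raise ValueError(f"static demand a must be > 0, got {a}")
    lam, D, nu_m, nu_c, p = (params.lam, params.D, params.nu_m,
                             params.nu_c, params.p)
    if params.encoding == Encoding.ORGANELLE:
        denom = lam * p + nu_m
        if denom <= 0:
            raise ValueError(
                "no organelle-encoded equilibrium: lambda*p + nu_m must be > 0")
        x_m = lam * p * a / denom
        x_c = 0.0
    else:
        denom = lam * D + (D + nu_c) * nu_m
        if denom <= 0:
            raise ValueError(
                "no nuclear-encoded equilibrium: lambda*D + (D + nu_c)*nu_m "
                "must be > 0")
        x_m = lam * D * a / denom
        if D > 0:
            x_c = nu_m * x_m / D
        elif nu_c > 0:
            # no import at all: the organelle pool decays to zero and the
            # cytosol balances synthesis against its own degradation
            x_c = lam * a / nu_c
        else:
            raise ValueError("no nuclear-encoded equilibrium with D = 0 and "
                             "nu_c = 0: the cytosolic pool grows unboundedly")
    return EquilibriumSolution(x_m_star=x_m, x_c_star=x_c,
                               instantaneous_cost=a - x_m,
                               encoding=params.encoding, params=params,
                               mean_demand=a)


def cost_ratio(params: ModelParameters) -> float:
    """Equilibrium instantaneous cost ratio C_0 / C_1 under static demand.

    Independent of the demand level a (it cancels) and of the ``encoding``
    tag on ``params``.  > 1 favours nuclear encoding, < 1 organelle.
    """
    lam, D, nu_m, nu_c, p = (params.lam, params.D, params.nu_m,
                             params.nu_c, params.p)
    denom = (lam * p + nu_m) * (D + nu_c)
    if denom == 0:
        raise ValueError(
            "cost ratio undefined: (lambda*p + nu_m)*(D + nu_c) must be > 0")
    return (lam * D + (D + nu_c) * nu_m) / denom


def favourability_condition(params: ModelParameters) -> tuple[str, float]:
    """Which compartment a static environment favours, with its margin.

    Returns ``(favoured, margin)`` where margin = D - p (D + nu_c).
    A positive margin means C_0/C_1 > 1 (nucleus favoured), negative means
    organelle favoured, zero is the exact neutrality locus.  Agrees with
    :func:`cost_ratio` versus 1 for every valid parameter set.
    """
    margin = params.D - params.p * (params.D + params.nu_c)
    if margin > 0:
        return "nucleus", margin
    if margin < 0:
        return "organelle", margin
    return "neutral", margin
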