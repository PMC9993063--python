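"""Environmental demand signals E(t).

The model is forced by a time-varying "demand" placed on the organelle by
the environment (light, oxygenation, temperature, activity...).  Four demand
classes are supported, all sharing the same time-averaged level ``a`` so that
costs are comparable across classes:

* static        -- E(t) = a
* periodic      -- E(t) = a (1 + b sin(2 pi k t / tau)), b in [0, 1]
* white noise   -- piecewise-constant, independent uniform draws on [0, 2a]
* red noise     -- piecewise-constant bounded random walk on [0, 2a]

Times are measured in T-units (T = 10 min); ``tau`` defaults to 144 T, i.e.
one 24 h day, so ``k`` counts oscillations per day (k = 1 diurnal, k = 2
semidiurnal).

The noisy classes are the stochastic generators of the package: a partition
0 = s_0 < s_1 < ... < s_n = horizon into subintervals d_i = [s_i, s_{i+1})
carries one constant level per subinterval.  White noise draws each level
u_i ~ U(0, 2a) independently; red noise accumulates a clamped random walk

    w_i = max(0, min(2a, w_{i-1} + |d_i| (u_i - a))),   u_i ~ U(0, 2a),

which produces temporally correlated fluctuations while remaining bounded
in [0, 2a].  Realizations are deterministic for a fixed seed and can be
exported/imported as (s_i, level) CSV so a run is exactly replayable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Environment",
    "EnvironmentSpec",
    "StaticEnvironment",
    "PeriodicEnvironment",
    "PiecewiseConstantEnvironment",
    "generate_white",
    "generate_red",
    "red_levels_from_draws",
    "DAY",
]

#: One day in T-units (T = 10 minutes).
DAY = 144.0


class Environment:
    """Base class: a demand signal evaluable at any time point.

    Subclasses carry a ``kind`` tag and implement :meth:`evaluate`.
    """

    kind: str = "abstract"
    #: time-averaged demand level
    a: float

    def evaluate(self, t):
        """Demand at time ``t`` (scalar or array)."""
        raise NotImplementedError

    def breakpoints(self, t_start: float, t_end: float) -> np.ndarray:
        """Interior discontinuity times within (t_start, t_end).

        The simulator restarts the ODE solver at each of these so it never
        smooths across a jump.  Smooth signals return an empty array.
        """
        return np.empty(0)

    def __call__(self, t):
        return self.evaluate(t)

    def _scalar_evaluator(self):
        """Fast float -> float evaluator for the ODE right-hand side.

        The default delegates to :meth:`evaluate`; subclasses override with
        closure-based versions to avoid array overhead in the inner loop.
        """
        return lambda t: float(self.evaluate(t))


# the spec-facing name for "a tagged description of one demand signal"
EnvironmentSpec = Environment


@dataclass(frozen=True)
class StaticEnvironment(Environment):
    """Constant demand E(t) = a."""

    a: float = 1.0
    kind = "static"

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError(f"mean demand a must be > 0, got {self.a}")

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.a)
        return float(out) if out.ndim == 0 else out

    def _scalar_evaluator(self):
        a = self.a
        return lambda t: a


@dataclass(frozen=True)
class PeriodicEnvironment(Environment):
    """Sinusoidal demand E(t) = a (1 + b sin(2 pi k t / tau)).

    ``a`` is the time-averaged demand, ``a*b`` the oscillation amplitude
    (``b`` the relative amplitude, in [0, 1] so demand stays non-negative),
    ``k`` the number of oscillations per characteristic time ``tau``.
    """

    a: float = 1.0
    b: float = 1.0
    k: float = 1.0
    tau: float = DAY
    kind = "periodic"

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError(f"mean demand a must be > 0, got {self.a}")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError(f"relative amplitude b must lie in [0, 1], got {self.b}")
        if self.k < 0:
            raise ValueError(f"frequency k must be >= 0, got {self.k}")
        if self.tau <= 0:
            raise ValueError(f"timescale tau must be > 0, got {self.tau}")

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        out = self.a * (1.0 + self.b * np.sin(2.0 * np.pi * self.k * t / self.tau))
        return float(out) if out.ndim == 0 else out

    def _scalar_evaluator(self):
        a, b = self.a, self.b
        omega = 2.0 * math.pi * self.k / self.tau
        return lambda t: a * (1.0 + b * math.sin(omega * t))


@dataclass(frozen=True)
class PiecewiseConstantEnvironment(Environment):
    """Piecewise-constant demand over a uniform partition of [0, horizon].

    Subinterval d_i = [s_i, s_{i+1}) carries level ``levels[i]``; evaluation
    is right-continuous at breakpoints (t = s_i maps to d_i).  The terminal
    point t = horizon maps to the last subinterval so closed windows can be
    evaluated.  Used for both white- and red-noise realizations; ``kind``
    records which recursion produced the levels.
    """

    a: float
    step: float
    horizon: float
    levels: np.ndarray
    kind: str = "white"
    seed: int | None = None
    w0: float | None = None

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError(f"mean demand a must be > 0, got {self.a}")
        if self.step <= 0:
            raise ValueError(f"noise step must be > 0, got {self.step}")
        if self.horizon < self.step:
            raise ValueError("horizon must be at least one step")
        levels = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "levels", levels)
        n = math.ceil(self.horizon / self.step - 1e-12)
        if len(levels) != n:
            raise ValueError(
                f"expected {n} levels for horizon {self.horizon} at step "
                f"{self.step}, got {len(levels)}"
            )
        if np.any(levels < 0) or np.any(levels > 2 * self.a):
            raise ValueError("noise levels must lie in [0, 2a]")

    @property
    def starts(self) -> np.ndarray:
        """Left endpoints s_i of the subintervals."""
        return self.step * np.arange(len(self.levels))

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-12) or np.any(t > self.horizon + 1e-9):
            raise ValueError(
                f"time outside the realized horizon [0, {self.horizon}]"
            )
        idx = np.clip((t / self.step).astype(int), 0, len(self.levels) - 1)
        out = self.levels[idx]
        return float(out) if out.ndim == 0 else out

    def breakpoints(self, t_start: float, t_end: float) -> np.ndarray:
        s = self.starts
        return s[(s > t_start + 1e-12) & (s < t_end - 1e-12)]

    def _scalar_evaluator(self):
        levels = self.levels
        step = self.step
        last = len(levels) - 1
        def ev(t):
            i = int(t / step)
            return levels[i] if i < last else levels[last]
        return ev

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"s_i": self.starts, "level": self.levels})

    def to_csv(self, path) -> None:
        """Export the realization as (s_i, level) rows for exact replay."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, a: float, horizon: float | None = None,
                 kind: str = "white") -> "PiecewiseConstantEnvironment":
        """Rebuild a realization exported by :meth:`to_csv`."""
        df = pd.read_csv(path, float_precision="round_trip")
        s = df["s_i"].to_numpy(dtype=float)
        if len(s) < 1:
            raise ValueError("empty realization file")
        step = s[1] - s[0] if len(s) > 1 else (horizon if horizon else 1.0)
        if horizon is None:
            horizon = s[-1] + step
        return cls(a=a, step=float(step), horizon=float(horizon),
                   levels=df["level"].to_numpy(dtype=float), kind=kind)


def generate_white(a: float, step: float = 1.0, horizon: float = 2 * DAY,
                   seed: int | None = None) -> PiecewiseConstantEnvironment:
    """Uncorrelated (white) noisy demand: independent levels u_i ~ U(0, 2a).

    Parameters
    ----------
    a : mean demand; the uniform range is [0, 2a] so the average is ``a``.
    step : subinterval width |d_i| in T-units (default 1 T = 10 min).
    horizon : total realized span in T-units.
    seed : RNG seed; identical seeds give bit-identical realizations.
    """
    _check_noise_args(a, step, horizon)
    n = math.ceil(horizon / step - 1e-12)
    rng = np.random.default_rng(seed)
    levels = rng.uniform(0.0, 2.0 * a, size=n)
    return PiecewiseConstantEnvironment(a=a, step=step, horizon=horizon,
                                        levels=levels, kind="white", seed=seed)


def red_levels_from_draws(draws: np.ndarray, a: float, step: float,
                          w0: float) -> np.ndarray:
    """Apply the bounded random-walk recursion to given uniform draws.

    w_i = max(0, min(2a, w_{i-1} + step * (u_i - a))), starting from w0.
    Split out from :func:`generate_red` so the recursion can be exercised
    with controlled draws (e.g. u_i = a giving a constant walk).
    """
    w = float(w0)
    out = np.empty(len(draws))
    for i, u in enumerate(draws):
        w = max(0.0, min(2.0 * a, w + step * (u - a)))
        out[i] = w
    return out


def generate_red(a: float, step: float = 1.0, horizon: float = 2 * DAY,
                 seed: int | None = None,
                 w0: float | None = None) -> PiecewiseConstantEnvironment:
    """Correlated (red) noisy demand: bounded random walk on [0, 2a].

    Successive levels differ by at most ``step * a``, producing positive
    temporal autocorrelation -- the defining contrast with white noise.
    ``w0`` is the walk's starting level (default: the mean ``a``, which
    avoids an initial transient toward the mean).
    """
    _check_noise_args(a, step, horizon)
    if w0 is None:
        w0 = a
    if not 0.0 <= w0 <= 2.0 * a:
        raise ValueError(f"w0 must lie in [0, 2a], got {w0}")
    n = math.ceil(horizon / step - 1e-12)
    rng = np.random.default_rng(seed)
    draws = rng.uniform(0.0, 2.0 * a, size=n)
    levels = red_levels_from_draws(draws, a, step, w0)
    return PiecewiseConstantEnvironment(a=a, step=step, horizon=horizon,
                                        levels=levels, kind="red", seed=seed,
                                        w0=w0)


def _check_noise_args(a: float, step: float, horizon: float) -> None:
    if a <= 0:
        raise ValueError(f"mean demand a must be > 0, got {a}")
    if step <= 0:
        raise ValueError(f"noise step must be > 0, got {step}")
    if horizon < step:
        raise ValueError(
            f"horizon ({horizon}) must cover at least one step ({step})"
        )
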