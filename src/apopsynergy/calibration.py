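"""Parameter estimation against observation tables.

Fitting happens on the fold-change scale (all the model's experimental
readouts are relative), in log-parameter space, with multi-start
Latin-hypercube initialisation and derivative-free local refinement
(Nelder–Mead): timed dose events make the loss surface piecewise and
degrade finite-difference gradients.  The loss is a weighted sum of
squared residuals, weighted by replicate standard errors with a floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .models import build_variant
from .network import default_grid, integrate
from .ros_cflip import build_ros_cflip_network, cflip_fold_change, simulate_ros_cflip

__all__ = [
    "CalibrationProblem",
    "CalibrationResult",
    "fit",
    "residuals",
    "profile",
    "ros_cflip_problem",
    "ly30_flip_decay_problem",
]

#: floor on the replicate standard error used as residual weight, in
#: fold-change units; prevents zero-noise data from producing infinite
#: weights
SE_FLOOR = 0.05


@dataclass
class CalibrationProblem:
    """Bounded least-squares problem on fold-change observations.

    ``predict`` maps a parameter dict to predicted values for every
    observation row (aligned with ``observations``).  Observations are
    tidy rows of (readout, time, replicate, value).
    """

    free_parameters: dict[str, tuple[float, float]]
    observations: pd.DataFrame
    predict: Callable[[dict[str, float]], np.ndarray]

    def __post_init__(self):
        for name, (lo, hi) in self.free_parameters.items():
            if not (0 < lo < hi < np.inf):
                raise ValueError(
                    f"bounds for {name!r} must be positive and finite")
        if len(self.observations) == 0:
            raise ValueError("need at least one observation")
        obs = self.observations
        se = obs.groupby(["readout", "time"])["value"].transform(
            lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        self._weights = 1.0 / np.maximum(se.to_numpy(), SE_FLOOR)

    def params_from_log(self, x: np.ndarray) -> dict[str, float]:
        return {n: float(np.exp(v))
                for n, v in zip(self.free_parameters, x)}

    @property
    def log_bounds(self) -> list[tuple[float, float]]:
        return [(np.log(lo), np.log(hi))
                for lo, hi in self.free_parameters.values()]


@dataclass
class CalibrationResult:
    best_parameters: dict[str, float]
    loss: float
    converged: bool
    at_bounds: list[str] = field(default_factory=list)
    per_start: list[dict] = field(default_factory=list)


def residuals(parameters: dict[str, float],
              problem: CalibrationProblem) -> np.ndarray:
    """Weighted (simulated − observed) on the fold-change scale."""
    pred = problem.predict(parameters)
    obs = problem.observations["value"].to_numpy()
    if len(pred) != len(obs):
        raise ValueError("predict() must return one value per observation")
    return (pred - obs) * problem._weights


def loss(parameters, problem) -> float:
    r = residuals(parameters, problem)
    return float(r @ r)


def fit(problem: CalibrationProblem, n_starts: int = 10, seed: int = 0,
        x0: dict[str, float] | None = None) -> CalibrationResult:
    """Best of ``n_starts`` bounded local fits in log-parameter space.

    Starts are Latin-hypercube samples of the log-bounded box (plus the
    optional explicit ``x0``); deterministic given the seed.
    """
    names = list(problem.free_parameters)
    bounds = problem.log_bounds
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = []
    if x0 is not None:
        starts.append(np.log([x0[n] for n in names]))
    n_lhs = max(0, n_starts - len(starts))
    if n_lhs:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        starts.extend(lo + sampler.random(n_lhs) * (hi - lo))

    def objective(x):
        try:
            return loss(problem.params_from_log(x), problem)
        except Exception:
            return 1e12  # integration failure far from plausible values

    best = None
    trace = []
    n_converged = 0
    for x_start in starts:
        res = minimize(objective, x_start, method="Nelder-Mead",
                       bounds=bounds,
                       options={"xatol": 1e-4, "fatol": 1e-10,
                                "maxiter": 400 * len(names)})
        trace.append({"x0": problem.params_from_log(x_start),
                      "x": problem.params_from_log(res.x),
                      "loss": float(res.fun), "converged": bool(res.success)})
        n_converged += bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if n_converged == 0:
        raise RuntimeError(
            f"no start converged in {len(starts)} attempts; "
            f"best loss {best.fun:.3g}")
    params = problem.params_from_log(best.x)
    tol = 1e-3
    at_bounds = [n for n, xv, l, h in zip(names, best.x, lo, hi)
                 if xv - l < tol or h - xv < tol]
    return CalibrationResult(params, float(best.fun), bool(best.success),
                             at_bounds, trace)


def profile(parameter_name: str, problem: CalibrationProblem, grid,
            n_starts: int = 3, seed: int = 0) -> pd.DataFrame:
    """Profile loss: minimum over the other parameters at each grid value."""
    if parameter_name not in problem.free_parameters:
        raise KeyError(parameter_name)
    others = {n: b for n, b in problem.free_parameters.items()
              if n != parameter_name}
    rows = []
    for value in grid:
        if others:
            sub = CalibrationProblem(
                others, problem.observations,
                lambda p, v=value: problem.predict(
                    {**p, parameter_name: v}))
            res = fit(sub, n_starts=n_starts, seed=seed)
            rows.append({"value": value, "loss": res.loss,
                         **res.best_parameters})
        else:
            rows.append({"value": value,
                         "loss": loss({parameter_name: value}, problem)})
    return pd.DataFrame(rows)


# -- concrete problem factories --------------------------------------

def ros_cflip_problem(observations: pd.DataFrame,
                      free_parameters: dict[str, tuple[float, float]],
                      ly30_dose_um: float = 25.0,
                      fixed: dict[str, float] | None = None,
                      ) -> CalibrationProblem:
    """Fit ROS–cFLIP kinetic constants to cFLIP fold-change data.

    Observation rows must have readout ``cflip_fold``; predictions are
    deterministic cFLIP fold-changes of the ROS–cFLIP network.
    """
    times = observations["time"].to_numpy(dtype=float)
    t_end = max(1.0, float(times.max()))

    def predict(params: dict[str, float]) -> np.ndarray:
        overrides = dict(fixed or {})
        overrides.update(params)
        net = build_ros_cflip_network(overrides)
        traj = simulate_ros_cflip(net, ly30_dose_um, t_end=t_end, step=0.02)
        return cflip_fold_change(traj, times)

    return CalibrationProblem(free_parameters, observations, predict)


def ly30_flip_decay_problem(observations: pd.DataFrame,
                            free_parameters: dict[str, tuple[float, float]],
                            ly30_dose_um: float = 25.0,
                            ) -> CalibrationProblem:
    """Fit the constant-rate LY30-driven cFLIP degradation constant.

    Uses the deterministic mean cell of the LY30-only variant (cFLIP
    decay does not depend on the sampled initial conditions); rows must
    have readout ``cflip_fold``.
    """
    times = observations["time"].to_numpy(dtype=float)
    grid = default_grid(max(1.0, float(times.max())), step=0.05)

    def predict(params: dict[str, float]) -> np.ndarray:
        variant = build_variant("ly30_only", ly30_dose=ly30_dose_um,
                                ly30_overrides=params)
        traj = integrate(variant.network, variant.events, grid)
        flip = traj.get("flip")
        return np.interp(times, grid, flip / flip[0])

    return CalibrationProblem(free_parameters, observations, predict)
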