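"""Profile-likelihood identifiability analysis.

For each parameter the objective is re-minimized over all remaining
parameters while the parameter of interest is stepped away from its
best-fit value; the resulting one-dimensional profile defines a
confidence interval where it crosses the best objective plus a
threshold (default 1.0, the pointwise 1-sigma level for a chi-square
objective).  A profile that stays below the threshold all the way to a
box bound marks the parameter as practically non-identifiable on that
side: the lower bound "includes zero", the upper bound is "infinite".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .fitting import EnsembleObjective, EnsembleSpec, FitResult, _refine

__all__ = ["Profile", "profile", "profile_scalar", "profile_all", "relative_ci_table"]


@dataclass
class Profile:
    """One-parameter profile likelihood with its confidence interval."""

    parameter: tuple | str
    values: list          # parameter values visited (natural scale)
    objectives: list      # re-optimized objective at each value
    best_value: float
    best_objective: float
    threshold: float
    ci_lower: float       # natural scale; meaningful unless lower_open
    ci_upper: float
    lower_open: bool      # profile never crossed before the lower box bound
    upper_open: bool

    @property
    def identifiable(self) -> bool:
        return not (self.lower_open or self.upper_open)

    @property
    def relative_ci(self) -> float:
        """(upper - lower) / best-fit value; inf if either side is open."""
        if not self.identifiable:
            return np.inf
        return (self.ci_upper - self.ci_lower) / self.best_value

    def covers(self, value: float) -> bool:
        """Whether *value* lies inside the (possibly one-sided) interval."""
        lo = -np.inf if self.lower_open else self.ci_lower
        hi = np.inf if self.upper_open else self.ci_upper
        return lo <= value <= hi

    def to_dict(self) -> dict:
        return {
            "parameter": list(self.parameter) if isinstance(self.parameter, tuple) else self.parameter,
            "values": [float(v) for v in self.values],
            "objectives": [float(o) for o in self.objectives],
            "best_value": float(self.best_value),
            "best_objective": float(self.best_objective),
            "threshold": float(self.threshold),
            "ci_lower": float(self.ci_lower),
            "ci_upper": float(self.ci_upper),
            "lower_open": self.lower_open,
            "upper_open": self.upper_open,
        }


def profile_scalar(
    objective: Callable[[float], float],
    best: float,
    lower: float,
    upper: float,
    threshold: float = 1.0,
    step0: float = 0.05,
    step_target: float = 0.1,
    max_steps: int = 50,
    refine: bool = True,
) -> tuple[list, list, float, bool, float, bool]:
    """Profile a one-dimensional objective in both directions.

    *objective* maps the profiled coordinate (in the stepping scale) to
    the re-optimized objective.  The step size adapts so each step gains
    about ``step_target`` objective units; crossings are refined by root
    finding when *refine* is set.  Returns (values, objectives,
    ci_lower, lower_open, ci_upper, upper_open) in the stepping scale.
    """
    f_best = objective(best)
    level = f_best + threshold
    values, objectives = [best], [f_best]
    bounds: dict[int, tuple[float, bool]] = {}
    for direction in (-1, +1):
        step = step0
        x_prev, f_prev = best, f_best
        bound = upper if direction > 0 else lower
        open_flag = True
        ci = bound
        for _ in range(max_steps):
            x = x_prev + direction * step
            at_bound = (x >= bound) if direction > 0 else (x <= bound)
            if at_bound:
                x = bound
            f = objective(x)
            values.append(x)
            objectives.append(f)
            if f >= level:
                if refine and f > level and abs(x - x_prev) > 1e-12:
                    try:
                        ci = brentq(lambda z: objective(z) - level, *sorted((x_prev, x)),
                                    xtol=1e-4 * max(1.0, abs(best)))
                    except ValueError:
                        ci = x
                else:
                    # linear interpolation of the crossing
                    w = (level - f_prev) / (f - f_prev) if f > f_prev else 1.0
                    ci = x_prev + w * (x - x_prev)
                open_flag = False
                break
            gain = f - f_prev
            if gain > 1e-12:
                step = float(np.clip(step * step_target / gain, step * 0.5, step * 2.0))
            else:
                step *= 2.0
            x_prev, f_prev = x, f
            if at_bound:
                break
        bounds[direction] = (ci, open_flag)
    (lo, lo_open), (hi, hi_open) = bounds[-1], bounds[+1]
    return values, objectives, lo, lo_open, hi, hi_open


def profile(
    spec: EnsembleSpec,
    fit_result: FitResult,
    parameter: tuple,
    threshold: float = 1.0,
    step0: float = 0.05,
    step_target: float = 0.1,
    max_steps: int = 50,
    reopt_nfev: int | None = 60,
    others: str = "auto",
) -> Profile:
    """Profile one packed parameter of an ensemble fit.

    *parameter* is a packing key such as ``("cell", "epo_01", "k_ItoM")``
    (see :class:`~eportraffic.fitting.EnsembleObjective`).  Stepping is
    in log10 space; nuisance parameters are re-optimized at each grid
    point, warm-started from the neighbouring solution.  A failed
    re-optimization at a grid point is recorded with the previous
    objective and profiling continues.

    ``others`` controls which nuisance parameters move for a per-cell
    parameter: ``"reoptimize"`` re-optimizes every other parameter in
    the ensemble (the textbook profile; expensive for coupled
    ensembles), ``"conditional"`` re-optimizes only the profiled cell's
    own parameters with the remaining cells fixed at their best fit
    (the distribution-constraint penalty is still evaluated, so added
    condition groups contribute curvature).  ``"auto"`` picks the exact
    separable profile when the ensemble decouples and the conditional
    profile otherwise.
    """
    obj = EnsembleObjective(spec)
    parameter = tuple(parameter)
    if parameter not in obj.index:
        raise KeyError(f"unknown parameter {parameter}")
    if others not in ("auto", "reoptimize", "conditional"):
        raise ValueError(f"unknown others mode {others!r}")
    x_full = np.asarray(fit_result.best_x, dtype=float)

    decoupled = (
        spec.constraint_weight == 0
        and not spec.fit_globals
        and not spec.shared_types
    )
    per_cell = parameter[0] == "cell"
    conditional = per_cell and (
        others == "conditional" or (others == "auto" and not decoupled)
    )
    separable = per_cell and decoupled and others in ("auto", "conditional")

    if separable or conditional:
        # only the profiled cell's parameters move; the other cells'
        # data residuals are constant and contribute an offset, while
        # the constraint penalty (if any) is re-evaluated as this
        # cell's parameters vary
        i_cell = next(
            i for i, k in enumerate(obj.kernels) if k.cell.cell_id == parameter[1]
        )
        kernel = obj.kernels[i_cell]
        cols = [obj.index[key] for key in obj.cell_slices[i_cell]]
        x_cell = x_full[cols]
        x_work = x_full.copy()

        def cell_penalty(x_cell_vals: np.ndarray) -> float:
            if not obj._constraint_idx:
                return 0.0
            x_work[cols] = x_cell_vals
            w = spec.constraint_weight
            total = 0.0
            import itertools as _it

            for ptype, groups, per_group in obj._constraint_idx:
                stats_g = [(x_work[ix].mean(), x_work[ix].var()) for ix in per_group]
                for (m1, v1), (m2, v2) in _it.combinations(stats_g, 2):
                    total += w * ((m1 - m2) ** 2 + (v1 - v2) ** 2)
            return total

        cell_obj_best = float(
            np.sum(kernel.residuals(x_cell, spec.k_on, spec.k_off) ** 2)
        ) + cell_penalty(x_cell)
        offset = float(fit_result.objective) - cell_obj_best
        idx = kernel.free_names.index(parameter[2])
        free = [i for i in range(len(kernel.free_names)) if i != idx]
        lo = obj.lower[cols]
        hi = obj.upper[cols]
        x_best = x_cell
        n_dim = len(kernel.free_names)

        def base_residuals(x: np.ndarray) -> np.ndarray:
            res = kernel.residuals(x, spec.k_on, spec.k_off)
            if obj._constraint_idx:
                res = np.append(res, np.sqrt(cell_penalty(x)))
            return res

    else:
        idx = obj.index[parameter]
        free = [i for i in range(obj.n_params) if i != idx]
        lo, hi = obj.lower, obj.upper
        x_best = x_full
        offset = 0.0
        n_dim = obj.n_params
        base_residuals = obj.residuals
    sparsity = None

    # cache of warm-start solutions along the profile
    warm = {round(float(x_best[idx]), 12): x_best[free]}

    def reopt(value: float) -> float:
        x0_free = min(
            warm.items(), key=lambda kv: abs(kv[0] - value)
        )[1]
        def residual_free(xf: np.ndarray) -> np.ndarray:
            return base_residuals(_embed(xf, free, idx, value, n_dim))
        try:
            sol = _refine(residual_free, np.clip(x0_free, lo[free], hi[free]),
                          lo[free], hi[free], sparsity=sparsity,
                          max_nfev=reopt_nfev)
            warm[round(float(value), 12)] = sol.x
            return offset + float(2 * sol.cost)
        except Exception:  # noqa: BLE001 - flagged point, profiling continues
            x = _embed(x0_free, free, idx, value, n_dim)
            return offset + float(np.sum(base_residuals(x) ** 2))

    values, objectives, ci_lo, lo_open, ci_hi, hi_open = profile_scalar(
        reopt, float(x_best[idx]), lo[idx], hi[idx],
        threshold=threshold, step0=step0, step_target=step_target,
        max_steps=max_steps,
    )
    return Profile(
        parameter=parameter,
        values=[10.0 ** v for v in values],
        objectives=objectives,
        best_value=10.0 ** float(x_best[idx]),
        best_objective=float(fit_result.objective),
        threshold=threshold,
        ci_lower=10.0 ** ci_lo,
        ci_upper=10.0 ** ci_hi,
        lower_open=lo_open,
        upper_open=hi_open,
    )


def _embed(xf: np.ndarray, free: list, idx: int, value: float, n: int) -> np.ndarray:
    x = np.empty(n)
    x[free] = xf
    x[idx] = value
    return x


def profile_all(
    spec: EnsembleSpec,
    fit_result: FitResult,
    parameters: Sequence[tuple] | None = None,
    **kwargs,
) -> list[Profile]:
    """Profiles for several parameters (default: all per-cell kinetics)."""
    if parameters is None:
        parameters = [
            key for key in fit_result.param_names
            if key[0] == "cell" and not key[2].endswith("(t0)")
        ]
    return [profile(spec, fit_result, p, **kwargs) for p in parameters]


def relative_ci_table(profiles: Sequence[Profile]):
    """Tidy table of relative confidence-interval sizes per cell and parameter."""
    import pandas as pd

    rows = []
    for p in profiles:
        cell = p.parameter[1] if isinstance(p.parameter, tuple) and len(p.parameter) == 3 else ""
        name = p.parameter[-1] if isinstance(p.parameter, tuple) else p.parameter
        rows.append(
            (cell, name, p.best_value, p.ci_lower, p.ci_upper,
             p.lower_open, p.upper_open, p.relative_ci)
        )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "parameter", "best", "ci_lower", "ci_upper",
                 "lower_open", "upper_open", "relative_ci"],
    )
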