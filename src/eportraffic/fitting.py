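"""Cell-ensemble parameter estimation and AICc model selection.

An ensemble model describes every cell of a heterogeneous population with
the same ODE structure while letting trafficking parameters and initial
receptor concentrations differ between cells; only the ligand binding and
unbinding rates are global (they are biophysical constants of the
receptor-ligand pair, not of the cell).  The objective is a weighted
least-squares chi-square over all cells and conditions plus optional
distribution-constraint penalties that keep the mean and variance of each
log10 kinetic parameter consistent across the experimental condition
groups (Epo-stimulated, photobleached, cycloheximide-treated) — the cells
are drawn from one population, so their parameters should follow one
distribution regardless of treatment.

Optimization runs in log10 parameter space with box bounds, from
Latin-hypercube multi-starts refined by bounded trust-region least
squares.  When the constraint weight is zero and the global binding rates
and scaling factors are held fixed, the joint optimum separates exactly
across cells and each cell is fitted independently (much cheaper, same
optimum); otherwise the full coupled problem is solved with a sparse
finite-difference Jacobian.

Model comparison uses the small-sample corrected Akaike information
criterion with chi-square standing in for -2 log-likelihood up to a
data-dependent constant that cancels in differences.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import least_squares
from scipy.sparse import lil_matrix
from scipy.stats import qmc

from .model import (
    ModelVariant,
    StimulusProtocol,
    reduced_model,
)
from .observation import Observable, OBSERVABLE_WEIGHTS, observable_names

__all__ = [
    "CellFitSpec",
    "EnsembleSpec",
    "FitResult",
    "build_ensemble",
    "objective",
    "fit",
    "aicc",
    "select_variant",
    "fixing_ladder",
    "n_retained",
]

LOG_BOUNDS_RATES = (-6.0, 3.0)
LOG_BOUNDS_INITS = (-3.0, 3.0)

# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class CellFitSpec:
    """Data and model of one cell in the ensemble."""

    cell_id: str
    condition: str
    protocol: StimulusProtocol
    #: per observable: (Observable, indices into protocol.sample_times, values)
    observations: tuple[tuple[Observable, np.ndarray, np.ndarray], ...]

    @property
    def n_data(self) -> int:
        return sum(len(v) for _, _, v in self.observations)


@dataclass
class EnsembleSpec:
    """Joint fitting problem over a set of cells."""

    variant: ModelVariant
    cells: list[CellFitSpec]
    k_on: float = 0.1
    k_off: float = 0.1
    fit_globals: bool = False
    constraint_weight: float = 1.0
    shared_types: frozenset[str] = frozenset()  # parameter types fixed across cells
    rate_bounds: tuple[float, float] = LOG_BOUNDS_RATES
    init_bounds: tuple[float, float] = LOG_BOUNDS_INITS

    def cell_param_names(self, condition: str) -> tuple[str, ...]:
        if condition == "epo":
            return self.variant.cell_param_names
        return reduced_model(condition).kinetic_param_names

    @property
    def n_data(self) -> int:
        return sum(c.n_data for c in self.cells)

    @property
    def groups(self) -> list[str]:
        return sorted({c.condition for c in self.cells})

    def constraint_types(self) -> list[tuple[str, list[str]]]:
        """(parameter type, condition groups sharing it) for the penalty."""
        groups = self.groups
        out = []
        all_types = sorted(
            set().union(*(set(self.cell_param_names(g)) for g in groups))
        )
        for ptype in all_types:
            if ptype in self.shared_types:
                continue
            sharing = [g for g in groups if ptype in self.cell_param_names(g)]
            if len(sharing) >= 2:
                out.append((ptype, sharing))
        return out


def _cell_seed(seed: int, cell_id: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), zlib.crc32(cell_id.encode())])


def build_ensemble(
    table: pd.DataFrame,
    variant: ModelVariant | str,
    combo: str = "epo+bleach+chx",
    epo_conc: float = 4.2,
    k_on: float = 0.1,
    k_off: float = 0.1,
    sigma_rel: float = 0.1,
    sigma_abs_frac: float = 0.0,
    floor_frac: float = 0.01,
    constraint_weight: float = 1.0,
    fit_globals: bool = False,
    cell_ids: Iterable[str] | None = None,
) -> EnsembleSpec:
    """Assemble an :class:`EnsembleSpec` from a long-format trajectory table.

    ``combo`` selects the condition groups ("epo", "epo+bleach" or
    "epo+bleach+chx").  The default error model is purely multiplicative
    with a prediction floor of ``floor_frac`` times the observable's data
    maximum (guards against vanishing predictions); for data with an
    additive background set ``sigma_abs_frac`` > 0 to add an absolute
    error term of that fraction of the data maximum.
    """
    if isinstance(variant, str):
        variant = ModelVariant.from_name(variant)
    conditions = combo.split("+")
    unknown = set(conditions) - {"epo", "bleach", "chx"}
    if unknown:
        raise ValueError(f"unknown conditions in combo: {sorted(unknown)}")
    sub = table[table["condition"].isin(conditions)]
    if cell_ids is not None:
        sub = sub[sub["cell_id"].isin(set(cell_ids))]
    missing = set(conditions) - set(sub["condition"].unique())
    if missing:
        raise ValueError(f"data combo {combo!r} requires conditions {sorted(missing)}")
    obs_max = {name: grp["value_au"].max() for name, grp in sub.groupby("observable")}
    cells = []
    for cell_id, cdf in sub.groupby("cell_id", sort=True):
        condition = cdf["condition"].iloc[0]
        times = np.sort(cdf["time_min"].unique())
        protocol = _default_protocol(condition, times, epo_conc)
        observations = []
        for obs_name in observable_names(condition):
            odf = cdf[cdf["observable"] == obs_name].sort_values("time_min")
            if odf.empty:
                continue
            idx = np.searchsorted(times, odf["time_min"].to_numpy())
            # an observable whose data are identically zero carries no
            # signal; a unit absolute error keeps its residuals defined
            sigma_abs = sigma_abs_frac * obs_max[obs_name]
            floor = floor_frac * obs_max[obs_name]
            if sigma_abs + floor <= 0:
                sigma_abs = 1.0
            obs = Observable(
                obs_name, scale=1.0, sigma_rel=sigma_rel,
                sigma_abs=sigma_abs, floor=floor,
            )
            observations.append((obs, idx, odf["value_au"].to_numpy(dtype=float)))
        cells.append(CellFitSpec(str(cell_id), condition, protocol, tuple(observations)))
    return EnsembleSpec(
        variant=variant,
        cells=cells,
        k_on=k_on,
        k_off=k_off,
        fit_globals=fit_globals,
        constraint_weight=constraint_weight,
    )


def _default_protocol(condition: str, times: np.ndarray, epo_conc: float) -> StimulusProtocol:
    times = tuple(float(t) for t in times)
    if condition == "epo":
        return StimulusProtocol("epo", times, epo_conc=epo_conc, epo_add_time=times[0])
    if condition == "bleach":
        return StimulusProtocol("bleach", times, bleach_start=5.0, bleach_duration=0.5)
    return StimulusProtocol("chx", times, chx_time=times[0])


# ---------------------------------------------------------------------------
# fast per-cell simulation kernels (log10 parameter vectors in, predictions out)


class _CellKernel:
    """Precompiled residual machinery for one cell.

    Parameter layout: cell kinetic rates (variant order) followed by the
    two initial concentrations (EpoR_i, EpoR_m), all log10.  The time
    grid and event boundaries are fixed per cell, so the propagation
    schedule — which piecewise-constant segment is active for each step
    and where samples are recorded — is compiled once; a residual
    evaluation then only rebuilds the segment matrices, exponentiates
    each distinct (segment, step) pair once and runs the matrix-vector
    recursion.
    """

    def __init__(self, spec: EnsembleSpec, cell: CellFitSpec):
        self.cell = cell
        self.condition = cell.condition
        self.param_names = list(spec.cell_param_names(cell.condition))
        self.free_names = self.param_names + ["EpoR_i(t0)", "EpoR_m(t0)"]
        self.variant = spec.variant
        times = np.asarray(cell.protocol.sample_times)
        self.times = times
        self.protocol = cell.protocol
        self.n = 6 if cell.condition == "epo" else 3
        weights = OBSERVABLE_WEIGHTS[cell.condition]
        self.obs = [
            (obs, w_idx, values, weights[obs.name])
            for obs, w_idx, values in cell.observations
        ]
        self.n_res = cell.n_data
        # flattened observation arrays for vectorized residuals
        self._W = np.column_stack([w for _, _, _, w in self.obs])
        self._t_idx = np.concatenate([t_idx for _, t_idx, _, _ in self.obs])
        self._o_idx = np.concatenate(
            [np.full(len(t_idx), j) for j, (_, t_idx, _, _) in enumerate(self.obs)]
        )
        self._values = np.concatenate([v for _, _, v, _ in self.obs])
        self._sig_rel = np.concatenate(
            [np.full(len(v), obs.sigma_rel) for obs, _, v, _ in self.obs]
        )
        self._sig_abs = np.concatenate(
            [np.full(len(v), obs.sigma_abs) for obs, _, v, _ in self.obs]
        )
        self._floor = np.concatenate(
            [np.full(len(v), obs.floor) for obs, _, v, _ in self.obs]
        )
        self._obs_names = [obs.name for obs, _, _, _ in self.obs]
        # segment start times (piecewise-constant coefficients)
        if cell.condition == "epo":
            starts = [times[0]]
            if cell.protocol.epo_add_time > times[0] + 1e-12:
                starts.append(cell.protocol.epo_add_time)
        elif cell.condition == "bleach":
            t_b = cell.protocol.bleach_start
            starts = [times[0], max(times[0], t_b),
                      max(times[0], t_b + cell.protocol.bleach_duration)]
        else:
            starts = [times[0]]
        self.n_segments = len(starts)
        # compiled schedule: (segment index, dt, sample slot or -1)
        plan: list[tuple[int, float, int]] = []
        t = times[0]
        for i in range(1, len(times)):
            target = times[i]
            while True:
                seg = max(j for j, s in enumerate(starts) if s <= t + 1e-12)
                cuts = [s for s in starts if t + 1e-12 < s < target - 1e-12]
                stop = min(cuts) if cuts else target
                if stop - t > 1e-12:
                    plan.append((seg, round(stop - t, 10), -1 if cuts else i))
                t = stop
                if not cuts:
                    break
        self.plan = plan

    def _assemble_epo(self, r: np.ndarray, k_on: float, k_off: float,
                      epo: float) -> tuple[np.ndarray, np.ndarray]:
        """Direct six-state system assembly from the rate vector.

        Equivalent to :func:`eportraffic.model.system_matrices`; variant
        consistency is guaranteed by construction of the rate layout.
        """
        v = self.variant
        k_syn, k_deg, k_itom, k_mtoi, k_mtore = r[:5]
        A = np.zeros((6, 6))
        A[0, 0] = -(k_deg + k_itom)
        A[0, 1] = k_mtoi
        A[1, 0] = k_itom
        A[1, 1] = -(k_mtoi + k_on * epo)
        A[1, 2] = k_off
        A[2, 1] = k_on * epo
        A[2, 2] = -(k_off + k_mtore)
        A[3, 2] = k_mtore
        i = 5
        exit_rate = 0.0
        if v.has_A:
            A[1, 3] += r[i]; exit_rate += r[i]; i += 1
        if v.has_B:
            A[0, 3] += r[i]; A[4, 3] += r[i]; exit_rate += r[i]; i += 1
        if v.has_C:
            A[5, 3] += r[i]; exit_rate += r[i]; i += 1
        if v.has_D:
            A[4, 3] += r[i]; exit_rate += r[i]; i += 1
        A[3, 3] = -exit_rate
        b = np.zeros(6)
        b[0] = k_syn
        return A, b

    def _segment_matrices(self, rates: np.ndarray, k_on: float,
                          k_off: float) -> list[tuple[np.ndarray, np.ndarray]]:
        if self.condition == "epo":
            post = self._assemble_epo(rates, k_on, k_off, self.protocol.epo_conc)
            if self.n_segments == 2:
                return [self._assemble_epo(rates, k_on, k_off, 0.0), post]
            return [post]
        kin = dict(zip(self.param_names, rates))
        if self.condition == "bleach":
            model = reduced_model("bleach")
            off = model.matrices(kin, False)
            return [off, model.matrices(kin, True), off]
        return [reduced_model("chx").matrices(kin, False)]

    def states(self, x_cell: np.ndarray, k_on: float, k_off: float) -> np.ndarray:
        """State trajectory at the cell's sample times."""
        vals = 10.0 ** np.asarray(x_cell, dtype=float)
        segmats = self._segment_matrices(vals[: len(self.param_names)], k_on, k_off)
        n = self.n
        y = np.zeros(n + 1)
        y[0], y[1], y[n] = vals[len(self.param_names)], vals[len(self.param_names) + 1], 1.0
        out = np.empty((len(self.times), n))
        out[0] = y[:n]
        cache: dict[tuple[int, float], np.ndarray] = {}
        for seg, dt, rec in self.plan:
            key = (seg, dt)
            M = cache.get(key)
            if M is None:
                M = _expm_aug(*segmats[seg], dt, n)
                cache[key] = M
            y = M @ y
            if rec >= 0:
                out[rec] = y[:n]
        return out

    def residuals(self, x_cell: np.ndarray, k_on: float, k_off: float,
                  scales: Mapping[str, float] | None = None) -> np.ndarray:
        states = self.states(x_cell, k_on, k_off)
        pred = (states @ self._W)[self._t_idx, self._o_idx]
        if scales is not None:
            pred = pred * np.array([scales.get(n, 1.0) for n in self._obs_names])[self._o_idx]
        sigma = self._sig_rel * np.maximum(pred, self._floor) + self._sig_abs
        return (self._values - pred) / sigma


def _expm_aug(A: np.ndarray, b: np.ndarray, dt: float, n: int) -> np.ndarray:
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = A
    aug[:n, n] = b
    return expm(aug * dt)


# ---------------------------------------------------------------------------
# objective


class EnsembleObjective:
    """Residual vector and chi-square of the full ensemble problem."""

    def __init__(self, spec: EnsembleSpec):
        self.spec = spec
        self.kernels = [_CellKernel(spec, c) for c in spec.cells]
        # parameter packing: [globals?] + [shared types] + per-cell free
        names: list[tuple] = []
        lo, hi = [], []
        rb, ib = spec.rate_bounds, spec.init_bounds
        if spec.fit_globals:
            for g in ("k_on", "k_off"):
                names.append(("global", g))
                lo.append(rb[0]); hi.append(rb[1])
        self.shared = sorted(spec.shared_types)
        for s in self.shared:
            names.append(("shared", s))
            lo.append(rb[0]); hi.append(rb[1])
        self.cell_slices: list[tuple[np.ndarray, list[int]]] = []
        for k in self.kernels:
            order = []       # index into x for each entry of the kernel vector
            free_idx = []
            for pname in k.free_names:
                if pname in spec.shared_types:
                    order.append(("shared", pname))
                else:
                    key = ("cell", k.cell.cell_id, pname)
                    names.append(key)
                    bounds = ib if pname.endswith("(t0)") else rb
                    lo.append(bounds[0]); hi.append(bounds[1])
                    order.append(key)
            self.cell_slices.append(order)
        self.names = names
        self.index = {n: i for i, n in enumerate(names)}
        self.lower = np.array(lo)
        self.upper = np.array(hi)
        self.n_params = len(names)
        self.n_data = spec.n_data
        self.constraints = spec.constraint_types() if spec.constraint_weight > 0 else []
        # per (ptype, group): indices of the cells' entries
        self._constraint_idx = []
        for ptype, groups in self.constraints:
            per_group = []
            for g in groups:
                idx = [
                    self.index[("cell", k.cell.cell_id, ptype)]
                    for k in self.kernels
                    if k.cell.condition == g and ("cell", k.cell.cell_id, ptype) in self.index
                ]
                per_group.append(np.array(idx, dtype=int))
            self._constraint_idx.append((ptype, groups, per_group))
        self.n_penalty = sum(
            2 * len(list(itertools.combinations(groups, 2)))
            for _, groups, _ in self._constraint_idx
        )

    # -- packing helpers ----------------------------------------------------
    def x0_from(self, values: Mapping[tuple, float]) -> np.ndarray:
        x = np.empty(self.n_params)
        for key, i in self.index.items():
            x[i] = values[key]
        return x

    def cell_vector(self, x: np.ndarray, i_cell: int) -> np.ndarray:
        order = self.cell_slices[i_cell]
        return np.array([x[self.index[key]] for key in order])

    def globals_of(self, x: np.ndarray) -> tuple[float, float]:
        if self.spec.fit_globals:
            return 10.0 ** x[self.index[("global", "k_on")]], 10.0 ** x[
                self.index[("global", "k_off")]
            ]
        return self.spec.k_on, self.spec.k_off

    # -- residuals ----------------------------------------------------------
    def residuals(self, x: np.ndarray) -> np.ndarray:
        k_on, k_off = self.globals_of(x)
        parts = [
            k.residuals(self.cell_vector(x, i), k_on, k_off)
            for i, k in enumerate(self.kernels)
        ]
        if self._constraint_idx:
            w = np.sqrt(self.spec.constraint_weight)
            pen = []
            for ptype, groups, per_group in self._constraint_idx:
                stats = [(x[idx].mean(), x[idx].var()) for idx in per_group]
                for (m1, v1), (m2, v2) in itertools.combinations(stats, 2):
                    pen.append(w * (m1 - m2))
                    pen.append(w * (v1 - v2))
            parts.append(np.array(pen))
        return np.concatenate(parts)

    def chi2(self, x: np.ndarray) -> float:
        """Data part of the objective (no penalty)."""
        k_on, k_off = self.globals_of(x)
        return float(
            sum(
                np.sum(k.residuals(self.cell_vector(x, i), k_on, k_off) ** 2)
                for i, k in enumerate(self.kernels)
            )
        )

    def value(self, x: np.ndarray) -> float:
        return float(np.sum(self.residuals(x) ** 2))

    def jac_sparsity(self) -> lil_matrix:
        n_res = self.n_data + self.n_penalty
        S = lil_matrix((n_res, self.n_params), dtype=bool)
        row = 0
        glob_idx = [
            self.index[("global", g)]
            for g in ("k_on", "k_off")
            if ("global", g) in self.index
        ]
        shared_idx = [self.index[("shared", s)] for s in self.shared]
        for i, k in enumerate(self.kernels):
            cols = [self.index[key] for key in self.cell_slices[i]]
            if k.cell.condition == "epo":
                cols = cols + glob_idx
            for r in range(row, row + k.n_res):
                S[r, cols] = True
            row += k.n_res
        for ptype, groups, per_group in self._constraint_idx:
            all_idx = np.concatenate(per_group) if per_group else []
            n_pairs = len(list(itertools.combinations(groups, 2)))
            for r in range(row, row + 2 * n_pairs):
                S[r, all_idx] = True
            row += 2 * n_pairs
        return S

    # -- nested dict representation -----------------------------------------
    def params_dict(self, x: np.ndarray) -> dict:
        k_on, k_off = self.globals_of(x)
        out = {"global": {"k_on": k_on, "k_off": k_off}, "cells": {}}
        for i, k in enumerate(self.kernels):
            vec = 10.0 ** self.cell_vector(x, i)
            out["cells"][k.cell.cell_id] = dict(zip(k.free_names, map(float, vec)))
        if self.shared:
            out["shared"] = {
                s: float(10.0 ** x[self.index[("shared", s)]]) for s in self.shared
            }
        return out


def objective(spec: EnsembleSpec, x: np.ndarray) -> float:
    """Penalized least-squares objective at log10 parameter vector *x*."""
    return EnsembleObjective(spec).value(x)


# ---------------------------------------------------------------------------
# AICc


def aicc(chi2: float, n_params: int, n_data: int) -> float:
    """Corrected Akaike information criterion.

    ``chi2`` plays the role of -2 log-likelihood up to a constant that
    depends only on the data and cancels when comparing models on the
    same dataset.
    """
    if n_data <= n_params + 1:
        raise ValueError(
            f"AICc undefined: n_data={n_data} must exceed n_params+1={n_params + 1}"
        )
    return chi2 + 2 * n_params + 2 * n_params * (n_params + 1) / (n_data - n_params - 1)


def n_retained(n_starts: int, frac: float = 0.005) -> int:
    """Number of multi-start fits retained as the top *frac* fraction."""
    return max(1, int(round(n_starts * frac)))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Outcome of a multi-start ensemble fit."""

    variant: str
    param_names: list
    best_x: np.ndarray
    best_params: dict
    chi2: float
    objective: float
    n_data: int
    n_params: int
    aicc: float
    starts: list  # [(objective, x array)] sorted ascending
    seed: int | None = None

    def top(self, frac: float = 0.005) -> list:
        """The best ``frac`` fraction of starts (at least one)."""
        return self.starts[: n_retained(len(self.starts), frac)]

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "param_names": [list(n) for n in self.param_names],
            "best_x": [float(v) for v in self.best_x],
            "best_params": self.best_params,
            "chi2": self.chi2,
            "objective": self.objective,
            "n_data": self.n_data,
            "n_params": self.n_params,
            "aicc": self.aicc,
            "start_objectives": [float(o) for o, _ in self.starts],
            "seed": self.seed,
        }


def _lhs(n: int, dim: int, lower: np.ndarray, upper: np.ndarray,
         seed_seq: np.random.SeedSequence) -> np.ndarray:
    sampler = qmc.LatinHypercube(d=dim, seed=np.random.default_rng(seed_seq))
    return qmc.scale(sampler.random(n), lower, upper)


def _refine(fun, x0, lower, upper, sparsity=None, **ls_kwargs):
    defaults = dict(method="trf", ftol=1e-6, xtol=1e-8, gtol=1e-8)
    defaults.update(ls_kwargs)
    return least_squares(
        fun, x0, bounds=(lower, upper), jac_sparsity=sparsity, **defaults
    )


def fit(
    spec: EnsembleSpec,
    n_starts: int = 100,
    seed: int = 0,
    x0: np.ndarray | None = None,
    cap_nfev: int | None = 100,
    polish_top: int = 5,
    joint_nfev: int | None = 60,
    **ls_kwargs,
) -> FitResult:
    """Multi-start bounded least-squares fit of the ensemble.

    Latin-hypercube starts in the log10 box are each refined by
    trust-region least squares; refinement of every start is capped at
    ``cap_nfev`` residual evaluations and the best ``polish_top`` starts
    are then polished to full convergence (set ``cap_nfev=None`` to
    refine every start fully).  Deterministic given *seed*.

    Strategy by problem structure: when the constraint weight is zero
    and the global binding rates are fixed, the joint optimum separates
    exactly and each cell is optimized independently.  With a positive
    constraint weight (but fixed globals) the fit is hierarchical: the
    unconstrained separable optimum seeds a joint refinement of the
    coupled penalized problem (sparse Jacobian, ``joint_nfev`` budget
    per refined start).  Fully coupled problems (free globals or shared
    parameter types) are solved jointly from Latin-hypercube starts.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    obj = EnsembleObjective(spec)
    separable = not spec.fit_globals and not spec.shared_types
    if separable and spec.constraint_weight == 0:
        starts = _separable_starts(obj, spec, n_starts, seed, cap_nfev, polish_top,
                                   **ls_kwargs)
    elif separable and x0 is None:
        base = replace(spec, constraint_weight=0.0)
        base_obj = EnsembleObjective(base)
        starts = _separable_starts(base_obj, base, n_starts, seed, cap_nfev,
                                   polish_top, **ls_kwargs)
        # re-evaluate with the penalty, then jointly refine the leaders
        starts = sorted(
            ((obj.value(x), x) for _, x in starts), key=lambda t: t[0]
        )
        sparsity = obj.jac_sparsity()
        n_refine = max(1, polish_top)
        refined = []
        for o, x in starts[:n_refine]:
            try:
                sol = _refine(obj.residuals, x, obj.lower, obj.upper,
                              sparsity=sparsity, max_nfev=joint_nfev, **ls_kwargs)
                refined.append((float(2 * sol.cost), sol.x))
            except Exception:  # noqa: BLE001
                refined.append((o, x))
        starts = sorted(refined + starts[n_refine:], key=lambda t: t[0])
    else:
        sparsity = obj.jac_sparsity() if obj.n_params > 40 else None
        rng_seq = np.random.SeedSequence([int(seed), 0xE5])
        X0 = _lhs(n_starts, obj.n_params, obj.lower, obj.upper, rng_seq)
        if x0 is not None:
            X0[0] = np.clip(x0, obj.lower, obj.upper)
        starts = _multistart(
            obj.residuals, X0, obj.lower, obj.upper,
            cap_nfev=cap_nfev, polish_top=polish_top, sparsity=sparsity, **ls_kwargs
        )
        if not starts:
            raise RuntimeError("all optimization starts failed")
    best_obj, best_x = starts[0]
    chi2 = obj.chi2(best_x)
    return FitResult(
        variant=spec.variant.name,
        param_names=obj.names,
        best_x=best_x,
        best_params=obj.params_dict(best_x),
        chi2=chi2,
        objective=best_obj,
        n_data=obj.n_data,
        n_params=obj.n_params,
        aicc=aicc(best_obj, obj.n_params, obj.n_data),
        starts=starts,
        seed=seed,
    )


def _separable_starts(
    obj: EnsembleObjective,
    spec: EnsembleSpec,
    n_starts: int,
    seed: int,
    cap_nfev: int | None,
    polish_top: int,
    aux_cache: dict | None = None,
    n_refine: int | None = None,
    **ls_kwargs,
) -> list[tuple[float, np.ndarray]]:
    """Combine independent per-cell multistarts into ensemble starts.

    Start *s* of the ensemble combines every cell's *s*-th best refined
    start, so the leading combined start is the exact separable joint
    optimum; bleach/chx cell results are shared across variants through
    *aux_cache* (their reduced models are variant independent).
    """
    starts_x = np.empty((n_starts, obj.n_params))
    starts_obj = np.zeros(n_starts)
    for i, kernel in enumerate(obj.kernels):
        cid = kernel.cell.cell_id
        if aux_cache is not None and kernel.cell.condition != "epo" and cid in aux_cache:
            res = aux_cache[cid]
        else:
            res = _fit_cell(kernel, spec, n_starts, _cell_seed(seed, cid),
                            cap_nfev=cap_nfev, polish_top=polish_top,
                            n_refine=n_refine, **ls_kwargs)
            if aux_cache is not None and kernel.cell.condition != "epo":
                aux_cache[cid] = res
        cols = [obj.index[key] for key in obj.cell_slices[i]]
        for s, (fval, x_cell) in enumerate(res):
            starts_x[s, cols] = x_cell
            starts_obj[s] += fval
    return sorted(
        ((float(o), np.array(x)) for o, x in zip(starts_obj, starts_x)),
        key=lambda t: t[0],
    )


def _multistart(
    fun,
    X0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    cap_nfev: int | None,
    polish_top: int,
    sparsity=None,
    n_refine: int | None = None,
    **ls_kwargs,
) -> list[tuple[float, np.ndarray]]:
    """Multi-start local refinement.

    All starts are evaluated; the most promising ``n_refine`` (all, by
    default) are refined by bounded least squares with an evaluation
    budget of ``cap_nfev``, and the best ``polish_top`` refined starts
    are then polished to full convergence.  Returns (objective, x)
    sorted ascending.
    """
    n = X0.shape[0]
    if n_refine is None or n_refine >= n:
        refine_idx = range(n)
        results = [(np.inf, X0[s].copy()) for s in range(n)]
    else:
        f0 = np.empty(n)
        for s in range(n):
            try:
                f0[s] = float(np.sum(np.asarray(fun(X0[s])) ** 2))
            except Exception:  # noqa: BLE001
                f0[s] = np.inf
        refine_idx = np.argsort(f0)[: max(1, n_refine)]
        results = [(f0[s], X0[s].copy()) for s in range(n)]
    for s in refine_idx:
        try:
            sol = _refine(fun, X0[s], lower, upper, sparsity=sparsity,
                          max_nfev=cap_nfev, **ls_kwargs)
            results[s] = (float(2 * sol.cost), sol.x)
        except Exception:  # noqa: BLE001 - a failed start is recorded as is
            pass
    if all(not np.isfinite(o) for o, _ in results):
        return []
    if cap_nfev is not None and polish_top > 0:
        order = np.argsort([o for o, _ in results])[:polish_top]
        for idx in order:
            o, x = results[idx]
            if not np.isfinite(o):
                continue
            try:
                sol = _refine(fun, x, lower, upper, sparsity=sparsity, **ls_kwargs)
                if 2 * sol.cost < o:
                    results[idx] = (float(2 * sol.cost), sol.x)
            except Exception:  # noqa: BLE001
                pass
    return sorted(results, key=lambda t: t[0])


def _fit_cell(
    kernel: _CellKernel,
    spec: EnsembleSpec,
    n_starts: int,
    seed_seq: np.random.SeedSequence,
    cap_nfev: int | None = 100,
    polish_top: int = 5,
    n_refine: int | None = None,
    **ls_kwargs,
) -> list[tuple[float, np.ndarray]]:
    """Independent multi-start fit of a single cell (globals fixed).

    Results come back sorted by objective, so when cells are combined
    into ensemble starts, the leading combined start is the sum of the
    per-cell optima — the exact separable joint optimum.
    """
    dim = len(kernel.free_names)
    rb, ib = spec.rate_bounds, spec.init_bounds
    lower = np.array([ib[0] if n.endswith("(t0)") else rb[0] for n in kernel.free_names])
    upper = np.array([ib[1] if n.endswith("(t0)") else rb[1] for n in kernel.free_names])
    X0 = _lhs(n_starts, dim, lower, upper, seed_seq)
    fun = lambda x: kernel.residuals(x, spec.k_on, spec.k_off)  # noqa: E731
    out = _multistart(fun, X0, lower, upper, cap_nfev=cap_nfev,
                      polish_top=polish_top, n_refine=n_refine, **ls_kwargs)
    if not out:
        raise RuntimeError(f"all starts failed for cell {kernel.cell.cell_id}")
    return out


# ---------------------------------------------------------------------------
# model selection


def select_variant(
    table: pd.DataFrame,
    variants: Sequence[ModelVariant | str] | None = None,
    mode: str = "ensemble",
    combo: str = "epo+bleach+chx",
    n_starts: int = 25,
    seed: int = 0,
    constraint_weight: float = 1.0,
    return_fits: bool = False,
    cap_nfev: int | None = 40,
    polish_top: int = 3,
    joint_nfev: int | None = 40,
    screen_top: int = 6,
    n_refine: int | None = 8,
    **build_kwargs,
):
    """Fit every variant and rank by AICc difference to the best.

    ``mode='ensemble'`` fits each variant to all cells of the data
    combination; with a positive constraint weight the fit is the
    two-stage procedure of :func:`fit` (separable multistart seeding a
    joint constrained refinement).  The joint refinement is spent only
    on the ``screen_top`` variants leading after the separable stage —
    AICc gaps beyond that are far larger than what the refinement can
    move.  ``mode='single_cell'`` fits each Epo-treated cell
    independently and reports per-cell AICc differences with medians.
    Returns a DataFrame (and the fits, if requested); variants whose fit
    fails are reported with NaN and excluded from the ranking.
    """
    if variants is None:
        from .model import enumerate_variants

        variants = enumerate_variants()
    variants = [ModelVariant.from_name(v) if isinstance(v, str) else v for v in variants]

    if mode == "ensemble":
        stage1, fits, failed = {}, {}, []
        aux_cache: dict[str, list] = {}
        for variant in variants:
            try:
                spec = build_ensemble(
                    table, variant, combo=combo,
                    constraint_weight=constraint_weight, **build_kwargs
                )
                base = (replace(spec, constraint_weight=0.0)
                        if constraint_weight > 0 else spec)
                obj = EnsembleObjective(spec)
                starts = _separable_starts(
                    EnsembleObjective(base), base, n_starts, seed,
                    cap_nfev, polish_top, aux_cache=aux_cache, n_refine=n_refine,
                )
                if constraint_weight > 0:
                    starts = sorted(((obj.value(x), x) for _, x in starts),
                                    key=lambda t: t[0])
                stage1[variant.name] = (spec, obj, starts)
            except Exception as exc:  # noqa: BLE001
                import warnings

                warnings.warn(f"variant {variant.name or 'basic'} failed: {exc}")
                failed.append(variant.name or "basic")
        ranked = sorted(
            stage1,
            key=lambda v: aicc(
                stage1[v][2][0][0], stage1[v][1].n_params, stage1[v][1].n_data
            ),
        )
        refine_set = set(ranked[:screen_top]) if constraint_weight > 0 else set()
        rows = []
        for vname, (spec, obj, starts) in stage1.items():
            if vname in refine_set:
                sparsity = obj.jac_sparsity()
                refined = []
                for o, x in starts[: max(1, polish_top)]:
                    try:
                        sol = _refine(obj.residuals, x, obj.lower, obj.upper,
                                      sparsity=sparsity, max_nfev=joint_nfev)
                        refined.append((float(2 * sol.cost), sol.x))
                    except Exception:  # noqa: BLE001
                        refined.append((o, x))
                starts = sorted(refined + starts[max(1, polish_top):],
                                key=lambda t: t[0])
            best_obj, best_x = starts[0]
            result = FitResult(
                variant=vname,
                param_names=obj.names,
                best_x=best_x,
                best_params=obj.params_dict(best_x),
                chi2=obj.chi2(best_x),
                objective=best_obj,
                n_data=obj.n_data,
                n_params=obj.n_params,
                aicc=aicc(best_obj, obj.n_params, obj.n_data),
                starts=starts,
                seed=seed,
            )
            fits[vname] = result
            rows.append((vname or "basic", result.chi2, result.n_params,
                         result.n_data, result.aicc))
        rows += [(v, np.nan, np.nan, np.nan, np.nan) for v in failed]
        df = pd.DataFrame(rows, columns=["variant", "chi2", "n_params", "n_data", "aicc"])
        df["delta_aicc"] = df["aicc"] - df["aicc"].min()
        df = df.sort_values("delta_aicc").reset_index(drop=True)
        return (df, fits) if return_fits else df

    if mode == "single_cell":
        epo_ids = sorted(table.loc[table["condition"] == "epo", "cell_id"].unique())
        records = []
        for cell_id in epo_ids:
            for variant in variants:
                spec = build_ensemble(
                    table, variant, combo="epo", cell_ids=[cell_id],
                    constraint_weight=0.0, **build_kwargs
                )
                result = fit(spec, n_starts=n_starts, seed=seed,
                             cap_nfev=cap_nfev, polish_top=polish_top)
                records.append((cell_id, variant.name or "basic", result.aicc))
        df = pd.DataFrame(records, columns=["cell_id", "variant", "aicc"])
        df["delta_aicc"] = df["aicc"] - df.groupby("cell_id")["aicc"].transform("min")
        medians = (
            df.groupby("variant")["delta_aicc"].median().rename("median_delta_aicc")
        )
        return df.merge(medians, on="variant")

    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# sequential parameter-fixing ladder


def fixing_ladder(
    spec: EnsembleSpec,
    direction: str = "min",
    n_starts: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Greedy ladder of cell-specific parameters fixed to global values.

    At every step the not-yet-shared parameter type whose sharing causes
    the smallest ("min") or largest ("max") AICc increase relative to the
    unrestricted fit is fixed for all cells, refitting after each fixing.
    ``k_syn`` always stays cell specific (it carries the cell-to-cell
    differences in receptor abundance).  Ties break lexicographically.
    """
    if direction not in ("min", "max"):
        raise ValueError("direction must be 'min' or 'max'")
    base = fit(spec, n_starts=n_starts, seed=seed)
    candidate_types = sorted(
        set().union(*(set(spec.cell_param_names(c.condition)) for c in spec.cells))
        - {"k_syn"}
    )
    fixed: list[str] = []
    rows = []
    current = base
    while len(fixed) < len(candidate_types):
        trials = []
        for ptype in candidate_types:
            if ptype in fixed:
                continue
            shared = frozenset(fixed + [ptype])
            trial_spec = replace(spec, shared_types=shared)
            x0 = _warm_start(trial_spec, current)
            result = fit(trial_spec, n_starts=1, seed=seed, x0=x0)
            trials.append((result.aicc - base.aicc, ptype, result))
        trials.sort(key=lambda t: (t[0], t[1]) if direction == "min" else (-t[0], t[1]))
        delta, ptype, result = trials[0]
        fixed.append(ptype)
        current = result
        rows.append((len(fixed), ptype, float(delta)))
    return pd.DataFrame(rows, columns=["step", "fixed_type", "delta_aicc"])


def _warm_start(spec: EnsembleSpec, previous: FitResult) -> np.ndarray:
    """Initial vector for a restricted spec from an earlier fit."""
    obj = EnsembleObjective(spec)
    prev = dict(zip(map(tuple, previous.param_names), previous.best_x))
    x0 = np.empty(obj.n_params)
    for key, i in obj.index.items():
        kind = key[0]
        if kind == "shared":
            ptype = key[1]
            vals = [v for k, v in prev.items() if k[0] in ("cell", "shared") and k[-1] == ptype]
            x0[i] = float(np.mean(vals)) if vals else 0.0
        elif key in prev:
            x0[i] = prev[key]
        else:
            x0[i] = 0.5 * (obj.lower[i] + obj.upper[i])
    return np.clip(x0, obj.lower, obj.upper)
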