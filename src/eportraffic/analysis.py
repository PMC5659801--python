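"""Post-fit biology: fluxes, control coefficients, variability and correlations.

Quantifies what the fitted (or generated) single-cell parameters imply:

* reaction fluxes (rate constant times source concentration) along each
  cell's trajectory, the currency in which transport processes compare;
* concentration control coefficients — normalized sensitivities
  ``r = (k/y) dy/dk`` of the membrane or endosomal complex concentration
  to each kinetic parameter;
* cell-to-cell variability (CVs) of parameters and predicted
  concentrations;
* Pearson correlations between single-cell parameters (on log10 values,
  the parameters being log-normally distributed) with t-test p-values;
* the covariance-removal experiment: sampling parameter vectors from a
  multivariate log-normal with the full estimated covariance versus one
  in which the covariances between the ligand-bound-receptor transport
  parameters and everything else are zeroed — quantifying how much the
  correlation of opposing transport processes buffers output variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import expm

from .model import (
    ModelVariant,
    CellParameters,
    StimulusProtocol,
    receptor_steady_state,
    simulate,
    system_matrices,
    EPOR_I, EPOR_M, EPOR_STAR_M, EPOR_STAR_RE,
)

__all__ = [
    "FluxSet",
    "ParameterEnsembleStats",
    "fluxes",
    "control_coefficients",
    "correlation_analysis",
    "pearson_with_pvalue",
    "covariance_experiment",
    "data_level_correlations",
    "STAR_TRANSPORT_PARAMS",
]

#: parameters describing reactions of the ligand-bound receptor; the
#: covariance-removal experiment zeroes their covariances with all others
STAR_TRANSPORT_PARAMS = ("k_MtoRE", "k_REtoM", "k_deg_REtoEx", "k_deg_REtoI")

#: flux name -> (rate constant, source state index); binding flux handled apart
_FLUX_DEFS = {
    "F_deg": ("k_deg", EPOR_I),
    "F_ItoM": ("k_ItoM", EPOR_I),
    "F_MtoI": ("k_MtoI", EPOR_M),
    "F_Epo_off": ("k_off", EPOR_STAR_M),
    "F_EpoRstar_MtoRE": ("k_MtoRE", EPOR_STAR_M),
    "F_EpoRstar_REtoM": ("k_REtoM", EPOR_STAR_RE),
    "F_EpoRstar_REtoI": ("k_REtoI", EPOR_STAR_RE),
    "F_EpoRstar_deg_REtoEx": ("k_deg_REtoEx", EPOR_STAR_RE),
    "F_EpoRstar_deg_REtoI": ("k_deg_REtoI", EPOR_STAR_RE),
}


@dataclass
class FluxSet:
    """Reaction fluxes (nM/min) of one cell at its sample times."""

    times: np.ndarray
    table: pd.DataFrame  # columns: flux names; rows aligned with times

    def at(self, t: float) -> pd.Series:
        i = int(np.argmin(np.abs(self.times - t)))
        return self.table.iloc[i]


def fluxes(
    variant: ModelVariant,
    params: CellParameters,
    trajectory: np.ndarray,
    protocol: StimulusProtocol,
) -> FluxSet:
    """Fluxes along a simulated trajectory (each rate x source species)."""
    params.require(variant)
    times = np.asarray(protocol.sample_times)
    traj = np.asarray(trajectory, dtype=float)
    if traj.shape != (times.size, 6):
        raise ValueError("trajectory shape does not match protocol sample times")
    epo = np.where(times > protocol.epo_add_time, protocol.epo_conc, 0.0)
    cols = {"F_Epo_on": params.k_on * epo * traj[:, EPOR_M]}
    for name, (rate_name, src) in _FLUX_DEFS.items():
        rate = getattr(params, rate_name, None)
        if rate is None:
            continue
        cols[name] = rate * traj[:, src]
    return FluxSet(times=times, table=pd.DataFrame(cols, index=times))


def control_coefficients(
    variant: ModelVariant,
    params: CellParameters,
    target: str = "EpoRstar_m",
    t: float | None = 300.0,
    epo: float = 4.2,
    rel_step: float = 0.01,
    init: Sequence[float] | None = None,
) -> dict[str, float]:
    """Concentration control coefficients ``r = (k/y) dy/dk``.

    Central finite differences with a relative parameter step.  With
    ``t=None`` the target is evaluated at the stimulated steady state
    (direct linear solve); otherwise at time *t* minutes after ligand
    addition, starting from the cell's pre-stimulus steady state (or
    *init*).
    """
    target_idx = {"EpoRstar_m": EPOR_STAR_M, "EpoRstar_RE": EPOR_STAR_RE}.get(target)
    if target_idx is None:
        raise ValueError(f"unknown target {target!r}")

    def evaluate(p: CellParameters) -> float:
        if t is None:
            return float(receptor_steady_state(variant, p, epo)[target_idx])
        protocol = StimulusProtocol("epo", (0.0, float(t)), epo_conc=epo, epo_add_time=0.0)
        return float(simulate(variant, p, protocol, init=init)[-1, target_idx])

    y0 = evaluate(params)
    if y0 == 0:
        raise ZeroDivisionError(f"target {target} is zero; control coefficients undefined")
    out: dict[str, float] = {}
    values = params.as_dict(variant)
    for name, k in values.items():
        if k == 0.0:
            out[name] = 0.0
            continue
        up = CellParameters(**{**values, name: k * (1 + rel_step)})
        dn = CellParameters(**{**values, name: k * (1 - rel_step)})
        out[name] = (evaluate(up) - evaluate(dn)) / (2 * rel_step * y0)
    return out


# ---------------------------------------------------------------------------
# correlations


def pearson_with_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson rho with the two-sided p-value from t = rho*sqrt(n-2)/sqrt(1-rho^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    rho = float(np.corrcoef(x, y)[0, 1])
    if abs(rho) >= 1.0:
        return rho, 0.0
    tstat = rho * np.sqrt(n - 2) / np.sqrt(1 - rho**2)
    p = 2 * sps.t.sf(abs(tstat), df=n - 2)
    return rho, float(p)


def correlation_analysis(
    values: pd.DataFrame, log: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of per-cell values with p-values.

    *values*: rows are cells, columns are parameter types.  Kinetic
    parameters are correlated on log10 values (they are log-normally
    distributed); pass ``log=False`` for linear-scale quantities such as
    concentrations or amounts.
    """
    if len(values) < 3:
        raise ValueError("need at least 3 cells")
    data = np.log10(values) if log else values
    cols = list(values.columns)
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, p = pearson_with_pvalue(data.iloc[:, i], data.iloc[:, j])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
    )


# ---------------------------------------------------------------------------
# multivariate log-normal ensemble statistics and the covariance experiment


@dataclass
class ParameterEnsembleStats:
    """Multivariate log-normal summary of single-cell parameters.

    ``log_mean``/``log_cov`` are in natural-log space.  ``repaired``
    flags a nearest-positive-semidefinite repair of the covariance
    (eigenvalue clipping), applied when estimation or covariance surgery
    produces an indefinite matrix.
    """

    param_names: list
    log_mean: np.ndarray
    log_cov: np.ndarray
    repaired: bool = False

    @classmethod
    def from_samples(cls, values: pd.DataFrame) -> "ParameterEnsembleStats":
        """Estimate from per-cell parameter values (rows = cells)."""
        if len(values) < 2:
            raise ValueError("need at least 2 cells to estimate a covariance")
        logs = np.log(values.to_numpy(dtype=float))
        mean = logs.mean(axis=0)
        cov = np.cov(logs, rowvar=False)
        stats = cls(list(values.columns), mean, np.atleast_2d(cov))
        return stats._ensure_psd()

    def _ensure_psd(self) -> "ParameterEnsembleStats":
        w, V = np.linalg.eigh(self.log_cov)
        if w.min() < 0:
            w_clipped = np.clip(w, 0.0, None)
            self.log_cov = (V * w_clipped) @ V.T
            self.repaired = True
        return self

    def summary(self) -> pd.DataFrame:
        """Per-parameter mean, SD and CV implied by the log-normal fit."""
        sigma2 = np.diag(self.log_cov)
        mean = np.exp(self.log_mean + sigma2 / 2)
        cv = np.sqrt(np.expm1(sigma2))
        return pd.DataFrame(
            {"mean": mean, "sd": mean * cv, "cv": cv}, index=self.param_names
        )

    def reduced(self, star_params: Sequence[str] = STAR_TRANSPORT_PARAMS) -> "ParameterEnsembleStats":
        """Copy with covariances between *star_params* and all others zeroed."""
        cov = self.log_cov.copy()
        star = [i for i, n in enumerate(self.param_names) if n in star_params]
        other = [i for i in range(len(self.param_names)) if i not in star]
        for i in star:
            for j in other:
                cov[i, j] = cov[j, i] = 0.0
        out = ParameterEnsembleStats(
            list(self.param_names), self.log_mean.copy(), cov
        )
        return out._ensure_psd()

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        draws = rng.multivariate_normal(self.log_mean, self.log_cov, size=n,
                                        method="svd")
        return pd.DataFrame(np.exp(draws), columns=self.param_names)


def _concentration_at(
    variant: ModelVariant,
    row: Mapping[str, float],
    k_on: float,
    k_off: float,
    epo: float,
    t: float,
) -> tuple[float, float]:
    """([EpoR*_m](t), [EpoR*_RE](t)) from the pre-stimulus steady state."""
    values = {"k_on": k_on, "k_off": k_off}
    values.update({p: float(row[p]) for p in variant.cell_param_names})
    params = CellParameters.for_variant(variant, values)
    A, b = system_matrices(variant, params, epo)
    epor_i = values["k_syn"] / values["k_deg"]
    epor_m = values["k_ItoM"] / values["k_MtoI"] * epor_i
    aug = np.zeros((7, 7))
    aug[:6, :6] = A
    aug[:6, 6] = b
    y = expm(aug * t) @ np.array([epor_i, epor_m, 0, 0, 0, 0, 1.0])
    return float(y[EPOR_STAR_M]), float(y[EPOR_STAR_RE])


def covariance_experiment(
    stats: ParameterEnsembleStats,
    variant: ModelVariant | str = "ACD",
    n_samples: int = 1000,
    seed: int = 0,
    reduced: bool = False,
    k_on: float = 0.1,
    k_off: float = 0.1,
    epo: float = 4.2,
    t: float = 300.0,
) -> dict[str, float]:
    """CVs of the complex concentrations after 5 h of stimulation.

    Samples *n_samples* parameter vectors from the multivariate
    log-normal (full covariance, or with the ligand-bound-transport
    covariances zeroed when *reduced*), simulates each synthetic cell
    from its pre-stimulus steady state and reports the CV of
    ``[EpoR*_m](t)`` and ``[EpoR*_RE](t)`` with bootstrap Monte-Carlo
    standard errors.  Deterministic given *seed*.
    """
    if isinstance(variant, str):
        variant = ModelVariant.from_name(variant)
    use = stats.reduced() if reduced else stats
    rng = np.random.default_rng(seed)
    draws = use.sample(n_samples, rng)
    out = np.array(
        [
            _concentration_at(variant, draws.iloc[i], k_on, k_off, epo, t)
            for i in range(n_samples)
        ]
    )
    result: dict[str, float] = {}
    boot = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB0]))
    for j, name in enumerate(("EpoRstar_m", "EpoRstar_RE")):
        vals = out[:, j]
        cv = float(vals.std() / vals.mean())
        idx = boot.integers(0, n_samples, size=(200, n_samples))
        cvs = vals[idx].std(axis=1) / vals[idx].mean(axis=1)
        result[f"cv_{name}"] = cv
        result[f"cv_{name}_se"] = float(cvs.std())
    result["repaired"] = bool(use.repaired)
    return result


# ---------------------------------------------------------------------------
# data-level correlations (fold changes relative to the population mean)


def data_level_correlations(
    table: pd.DataFrame,
    t0: float = 0.0,
    t_late: float = 300.0,
    volumes: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Fold-change correlations across Epo-treated cells.

    For each cell, concentrations are reduced to fold changes relative
    to the population mean (scale free), and three associations are
    tested: membrane vs vesicular receptor concentration before
    stimulation; total receptor concentration before stimulation vs
    membrane-bound ligand at ``t_late``; and — when per-cell *volumes*
    are supplied — the corresponding absolute amounts.  Cells with zero
    population variance are flagged with NaN correlations.
    """
    sub = table[table["condition"] == "epo"]
    if sub.empty:
        raise ValueError("no epo-condition cells in table")
    wide_t0 = _values_at(sub, t0)
    wide_late = _values_at(sub, t_late)
    mem0 = wide_t0["EpoR_GFP_mem"]
    ves0 = wide_t0["EpoR_GFP_ves"]
    tot0 = wide_t0.get("EpoR_GFP_mem", 0) + wide_t0.get("EpoR_GFP_ves", 0) + wide_t0.get(
        "EpoR_GFP_Cy55ves", 0
    )
    epo_mem_late = wide_late["Epo_Cy55_mem"]
    pairs = [
        ("conc_mem0_vs_ves0", mem0, ves0),
        ("conc_tot0_vs_epomem_late", tot0, epo_mem_late),
    ]
    if volumes is not None:
        vol = pd.Series(volumes).reindex(mem0.index)
        pairs.append(("amount_tot0_vs_epomem_late", tot0 * vol, epo_mem_late * vol))
    rows = []
    for name, a, b in pairs:
        fa = a / a.mean()
        fb = b / b.mean()
        try:
            rho, p = pearson_with_pvalue(fa.to_numpy(), fb.to_numpy())
        except ValueError:
            rho, p = np.nan, np.nan
        rows.append((name, rho, p, len(fa)))
    return pd.DataFrame(rows, columns=["pair", "rho", "p_value", "n_cells"])


def _values_at(sub: pd.DataFrame, t: float) -> pd.DataFrame:
    times = sub["time_min"].unique()
    nearest = times[np.argmin(np.abs(times - t))]
    if abs(nearest - t) > 1e-6:
        raise ValueError(f"no samples at t = {t} min (nearest: {nearest})")
    at = sub[sub["time_min"] == nearest]
    return at.pivot_table(index="cell_id", columns="observable", values="value_au")
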