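"""Mapping from model states to fluorescence observables.

Microscopy reports compartment fluorescence per cell volume in arbitrary
units (a.u.).  Each observable is a linear combination of model states
multiplied by a shared scaling factor (a.u. per nM):

* ``EpoR_GFP_mem``    — GFP in the membrane region: free plus Epo-bound
  membrane receptor,
* ``EpoR_GFP_ves``    — GFP in vesicles without ligand: intracellular
  free receptor,
* ``EpoR_GFP_Cy55ves``— GFP colocalised with labelled Epo: the
  recycling-endosome complex pool,
* ``Epo_Cy55_mem``    — labelled Epo at the membrane: the membrane
  complex,
* ``Epo_Cy55_cpl``    — cytoplasmic labelled Epo: endosomal complexes
  plus intracellularly accumulated degraded ligand (the dye survives
  proteolysis).

The bleach/chx conditions expose only the two GFP observables of the
three-state reduced models; dark or degraded receptor pools carry no
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Observable",
    "observable_names",
    "observe",
    "chi2_contribution",
    "OBSERVABLE_WEIGHTS",
]

# weights over the six epo-condition states
# (EpoR_i, EpoR_m, EpoRstar_m, EpoRstar_RE, Epo_deg_i, Epo_deg_ext)
_EPO_WEIGHTS = {
    "EpoR_GFP_mem": np.array([0.0, 1.0, 1.0, 0.0, 0.0, 0.0]),
    "EpoR_GFP_ves": np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
    "EpoR_GFP_Cy55ves": np.array([0.0, 0.0, 0.0, 1.0, 0.0, 0.0]),
    "Epo_Cy55_mem": np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0]),
    "Epo_Cy55_cpl": np.array([0.0, 0.0, 0.0, 1.0, 1.0, 0.0]),
}

# weights over the three reduced-model states (EpoR_i, EpoR_m, bookkeeping)
_AUX_WEIGHTS = {
    "EpoR_GFP_mem": np.array([0.0, 1.0, 0.0]),
    "EpoR_GFP_ves": np.array([1.0, 0.0, 0.0]),
}

OBSERVABLE_WEIGHTS = {
    "epo": _EPO_WEIGHTS,
    "bleach": _AUX_WEIGHTS,
    "chx": _AUX_WEIGHTS,
}


def observable_names(condition: str) -> tuple[str, ...]:
    try:
        return tuple(OBSERVABLE_WEIGHTS[condition])
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}") from None


@dataclass(frozen=True)
class Observable:
    """An observable with its scaling factor and error model.

    sigma(predicted) = sigma_rel * max(predicted, floor) + sigma_abs
    """

    name: str
    scale: float = 1.0
    sigma_rel: float = 0.1
    sigma_abs: float = 0.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.sigma_rel < 0 or self.sigma_abs < 0:
            raise ValueError("sigmas must be >= 0")
        if self.sigma_rel == 0 and self.sigma_abs == 0:
            raise ValueError("at least one of sigma_rel, sigma_abs must be positive")

    def sigma(self, predicted: np.ndarray | float) -> np.ndarray | float:
        return self.sigma_rel * np.maximum(predicted, self.floor) + self.sigma_abs


def observe(
    states: np.ndarray,
    name: str,
    condition: str = "epo",
    scale: float = 1.0,
) -> np.ndarray:
    """Observable value(s) in a.u. for state vector(s) *states*.

    *states* has shape (n_states,) or (n_times, n_states).
    """
    weights = OBSERVABLE_WEIGHTS.get(condition)
    if weights is None:
        raise ValueError(f"unknown condition {condition!r}")
    w = weights.get(name)
    if w is None:
        raise KeyError(f"unknown observable {name!r} for condition {condition!r}")
    states = np.asarray(states, dtype=float)
    return scale * (states @ w)


def chi2_contribution(
    observed: np.ndarray | float,
    predicted: np.ndarray | float,
    observable: Observable,
) -> np.ndarray | float:
    """Squared weighted residual ``((observed - predicted) / sigma)**2``."""
    sigma = observable.sigma(predicted)
    if np.any(np.asarray(sigma) <= 0):
        raise ZeroDivisionError(f"sigma is zero for observable {observable.name}")
    return ((np.asarray(observed) - np.asarray(predicted)) / sigma) ** 2
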