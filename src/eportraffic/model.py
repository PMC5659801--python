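"""ODE models of erythropoietin receptor (EpoR) trafficking.

The basic network describes synthesis and degradation of intracellular
receptor (EpoR_i), exchange with the plasma-membrane pool (EpoR_m),
pseudo-first-order binding of extracellular Epo to membrane receptor
(forming the active complex EpoR*_m) and endocytosis of the complex into a
recycling-endosome pool (EpoR*_RE).  Four optional parts extend the basic
network with different exit routes from the endosomal pool:

* part A — direct recycling of the receptor to the plasma membrane with
  release of intact ligand,
* part B — recycling into the intracellular receptor pool with
  intracellular accumulation of degraded ligand,
* part C — receptor degradation with export of degraded ligand,
* part D — receptor degradation with intracellular accumulation of
  degraded ligand.

All reactions are first order; extracellular Epo is held constant (ligand
depletion in the medium is negligible, see
:func:`eportraffic.synth.fraction_ligand_internalized`), so for a fixed
stimulus the system is linear and is propagated exactly with matrix
exponentials.  Two reduced three-state models describe the auxiliary
experiments: photobleaching (receptor replenishment after a laser pulse)
and cycloheximide treatment (degradation with synthesis switched off).

Units: time in minutes, concentrations in nM, rate constants per minute
(the binding rate ``k_on`` per nM per minute).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.integrate import solve_ivp

__all__ = [
    "ModelVariant",
    "CellParameters",
    "StimulusProtocol",
    "enumerate_variants",
    "rhs",
    "system_matrices",
    "prestimulus_steady_state",
    "receptor_steady_state",
    "simulate",
    "reduced_model",
    "BleachModel",
    "ChxModel",
    "STATE_NAMES",
]

# state vector layout (epo condition)
EPOR_I, EPOR_M, EPOR_STAR_M, EPOR_STAR_RE, EPO_DEG_I, EPO_DEG_EXT = range(6)
STATE_NAMES = (
    "EpoR_i",
    "EpoR_m",
    "EpoRstar_m",
    "EpoRstar_RE",
    "Epo_deg_i",
    "Epo_deg_ext",
)

#: kinetic parameter introduced by each optional part
PART_PARAMS = {
    "A": "k_REtoM",
    "B": "k_REtoI",
    "C": "k_deg_REtoEx",
    "D": "k_deg_REtoI",
}

GLOBAL_PARAMS = ("k_on", "k_off")
BASE_CELL_PARAMS = ("k_syn", "k_deg", "k_ItoM", "k_MtoI", "k_MtoRE")


@dataclass(frozen=True)
class ModelVariant:
    """One of the 16 structural variants of the trafficking network."""

    has_A: bool = False
    has_B: bool = False
    has_C: bool = False
    has_D: bool = False

    @property
    def name(self) -> str:
        return "".join(
            letter
            for letter, flag in zip("ABCD", (self.has_A, self.has_B, self.has_C, self.has_D))
            if flag
        )

    @classmethod
    def from_name(cls, name: str) -> "ModelVariant":
        name = name.strip().upper()
        if sorted(name) != sorted(set(name)) or any(c not in "ABCD" for c in name):
            raise ValueError(f"invalid variant name {name!r}")
        return cls(*(letter in name for letter in "ABCD"))

    @property
    def parts(self) -> tuple[str, ...]:
        return tuple(letter for letter in "ABCD" if getattr(self, f"has_{letter}"))

    @property
    def cell_param_names(self) -> tuple[str, ...]:
        """Cell-specific kinetic rate constants of this variant."""
        return BASE_CELL_PARAMS + tuple(PART_PARAMS[p] for p in self.parts)

    @property
    def kinetic_param_names(self) -> tuple[str, ...]:
        """All kinetic parameters including the global binding rates."""
        return GLOBAL_PARAMS + self.cell_param_names

    @property
    def n_kinetic(self) -> int:
        return len(self.kinetic_param_names)

    @property
    def n_states(self) -> int:
        # bookkeeping states for degraded ligand are retained (identically
        # zero when the corresponding parts are absent) so every variant
        # has six state equations
        return 6

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name or "basic"


def enumerate_variants() -> list[ModelVariant]:
    """All 16 subsets of parts {A, B, C, D}, ordered by canonical name."""
    variants = [
        ModelVariant(*(letter in combo for letter in "ABCD"))
        for r in range(5)
        for combo in itertools.combinations("ABCD", r)
    ]
    return sorted(variants, key=lambda v: v.name)


@dataclass(frozen=True)
class CellParameters:
    """Kinetic rate constants of a single cell.

    ``k_on``/``k_off`` are global (shared across cells); the remaining
    rates are cell specific.  Parameters belonging to absent parts must be
    ``None`` — they are structurally excluded, not silently zero.
    """

    k_on: float
    k_off: float
    k_syn: float
    k_deg: float
    k_ItoM: float
    k_MtoI: float
    k_MtoRE: float
    k_REtoM: float | None = None
    k_REtoI: float | None = None
    k_deg_REtoEx: float | None = None
    k_deg_REtoI: float | None = None

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"rate constant {name} must be >= 0, got {value}")

    @classmethod
    def for_variant(cls, variant: ModelVariant, values: Mapping[str, float]) -> "CellParameters":
        expected = set(variant.kinetic_param_names)
        given = set(values)
        if given != expected:
            missing = expected - given
            extra = given - expected
            raise ValueError(
                f"parameters for variant {variant.name or 'basic'} mismatch: "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        return cls(**{k: float(v) for k, v in values.items()})

    def require(self, variant: ModelVariant) -> None:
        """Raise unless the present/absent parameters match *variant*."""
        for letter, pname in PART_PARAMS.items():
            present = getattr(self, pname) is not None
            wanted = getattr(variant, f"has_{letter}")
            if present and not wanted:
                raise ValueError(
                    f"parameter {pname} set but part {letter} absent from "
                    f"variant {variant.name or 'basic'}"
                )
            if wanted and not present:
                raise ValueError(
                    f"variant {variant.name or 'basic'} requires {pname}"
                )

    def as_dict(self, variant: ModelVariant | None = None) -> dict[str, float]:
        names = (
            variant.kinetic_param_names
            if variant is not None
            else [n for n in self.__dataclass_fields__ if getattr(self, n) is not None]
        )
        return {n: float(getattr(self, n)) for n in names}

    @property
    def n_kinetic(self) -> int:
        return sum(getattr(self, n) is not None for n in self.__dataclass_fields__)


@dataclass(frozen=True)
class StimulusProtocol:
    """Experimental protocol of one cell.

    ``epo_add_time`` marks ligand addition (the stimulus applies for
    t > epo_add_time, so a sample taken exactly at the addition time is
    pre-stimulus).  The bleach pulse is a window during which a
    first-order loss moves fluorescent receptor into a dark pool.  From
    ``chx_time`` on, receptor synthesis is off.
    """

    condition: str
    sample_times: tuple[float, ...]
    epo_conc: float = 0.0
    epo_add_time: float = 0.0
    bleach_start: float = 5.0
    bleach_duration: float = 0.5
    chx_time: float = 0.0

    def __post_init__(self) -> None:
        if self.condition not in ("epo", "bleach", "chx"):
            raise ValueError(f"unknown condition {self.condition!r}")
        times = tuple(float(t) for t in self.sample_times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample_times must be strictly increasing")
        if self.epo_conc < 0:
            raise ValueError("epo_conc must be >= 0")
        if self.epo_conc > 0 and self.condition != "epo":
            raise ValueError("epo_conc > 0 only allowed for condition 'epo'")
        object.__setattr__(self, "sample_times", times)


def system_matrices(
    variant: ModelVariant, params: CellParameters, epo: float
) -> tuple[np.ndarray, np.ndarray]:
    """Linear system ``dx/dt = A x + b`` of the six-state model."""
    if epo < 0:
        raise ValueError("epo must be >= 0")
    params.require(variant)
    p = params
    A = np.zeros((6, 6))
    b = np.zeros(6)

    A[EPOR_I, EPOR_I] = -(p.k_deg + p.k_ItoM)
    A[EPOR_I, EPOR_M] = p.k_MtoI
    A[EPOR_M, EPOR_I] = p.k_ItoM
    A[EPOR_M, EPOR_M] = -(p.k_MtoI + p.k_on * epo)
    A[EPOR_M, EPOR_STAR_M] = p.k_off
    A[EPOR_STAR_M, EPOR_M] = p.k_on * epo
    A[EPOR_STAR_M, EPOR_STAR_M] = -(p.k_off + p.k_MtoRE)
    A[EPOR_STAR_RE, EPOR_STAR_M] = p.k_MtoRE

    exit_rate = 0.0
    if variant.has_A:
        A[EPOR_M, EPOR_STAR_RE] += p.k_REtoM
        exit_rate += p.k_REtoM
    if variant.has_B:
        A[EPOR_I, EPOR_STAR_RE] += p.k_REtoI
        A[EPO_DEG_I, EPOR_STAR_RE] += p.k_REtoI
        exit_rate += p.k_REtoI
    if variant.has_C:
        A[EPO_DEG_EXT, EPOR_STAR_RE] += p.k_deg_REtoEx
        exit_rate += p.k_deg_REtoEx
    if variant.has_D:
        A[EPO_DEG_I, EPOR_STAR_RE] += p.k_deg_REtoI
        exit_rate += p.k_deg_REtoI
    A[EPOR_STAR_RE, EPOR_STAR_RE] = -exit_rate

    b[EPOR_I] = p.k_syn
    return A, b


def rhs(
    variant: ModelVariant,
    params: CellParameters,
    state: Sequence[float],
    epo: float,
) -> np.ndarray:
    """Time derivative of the six-state vector at constant ligand *epo*."""
    A, b = system_matrices(variant, params, epo)
    return A @ np.asarray(state, dtype=float) + b


def prestimulus_steady_state(params: CellParameters) -> tuple[float, float]:
    """Steady state (EpoR_i, EpoR_m) of the ligand-free turnover cycle.

    Without ligand the complex states are empty and the receptor pools
    settle at ``EpoR_i = k_syn/k_deg`` and
    ``EpoR_m = (k_ItoM/k_MtoI) * EpoR_i``.
    """
    if params.k_deg <= 0 or params.k_MtoI <= 0:
        raise ZeroDivisionError("prestimulus steady state requires k_deg > 0 and k_MtoI > 0")
    epor_i = params.k_syn / params.k_deg
    epor_m = params.k_ItoM / params.k_MtoI * epor_i
    return epor_i, epor_m


def receptor_steady_state(
    variant: ModelVariant, params: CellParameters, epo: float
) -> np.ndarray:
    """Steady state of the four receptor species by direct linear solve.

    The cumulative ligand-bookkeeping states grow without bound under
    stimulation and are excluded.
    """
    A, b = system_matrices(variant, params, epo)
    return np.linalg.solve(A[:4, :4], -b[:4])


def _segments(
    protocol: StimulusProtocol,
    variant: ModelVariant,
    params: CellParameters,
) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Piecewise-constant (start_time, A, b) segments covering the protocol."""
    t0 = protocol.sample_times[0]
    if protocol.condition == "epo":
        before = system_matrices(variant, params, 0.0)
        after = system_matrices(variant, params, protocol.epo_conc)
        return [(t0, *before), (max(t0, protocol.epo_add_time), *after)]
    raise ValueError(f"condition {protocol.condition!r} uses a reduced model")


def _propagate(
    segments: list[tuple[float, np.ndarray, np.ndarray]],
    init: np.ndarray,
    times: Sequence[float],
) -> np.ndarray:
    """Exact propagation of a piecewise-affine linear ODE.

    Uses the augmented-matrix exponential; transition matrices are cached
    per (segment, step) so regular sampling grids cost one or two ``expm``
    evaluations per segment.
    """
    n = init.size
    times = np.asarray(times, dtype=float)
    out = np.empty((times.size, n))
    y = np.append(init, 1.0)
    # breakpoints: starts of segments after the first
    starts = [s[0] for s in segments]
    cache: dict[tuple[int, float], np.ndarray] = {}

    def step(seg_idx: int, y: np.ndarray, dt: float) -> np.ndarray:
        if dt <= 0:
            return y
        key = (seg_idx, round(dt, 12))
        M = cache.get(key)
        if M is None:
            A, b = segments[seg_idx][1], segments[seg_idx][2]
            aug = np.zeros((n + 1, n + 1))
            aug[:n, :n] = A
            aug[:n, n] = b
            M = expm(aug * dt)
            cache[key] = M
        return M @ y

    t = times[0]
    out[0] = y[:n]
    for i, target in enumerate(times[1:], start=1):
        while True:
            # active segment at current time t: last segment with start <= t
            seg_idx = max(j for j, s in enumerate(starts) if s <= t or np.isclose(s, t))
            # next breakpoint strictly inside (t, target)
            nxt = [s for s in starts if s > t + 1e-12 and s < target - 1e-12]
            t_stop = min(nxt) if nxt else target
            y = step(seg_idx, y, t_stop - t)
            t = t_stop
            if not nxt or t >= target - 1e-12:
                break
        out[i] = y[:n]
        t = target
    return out


def simulate(
    variant: ModelVariant,
    params: CellParameters,
    protocol: StimulusProtocol,
    init: Sequence[float] | None = None,
    method: str = "expm",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Six-state trajectory sampled at ``protocol.sample_times``.

    ``method='expm'`` (default) propagates the piecewise-linear system
    exactly; ``method='lsoda'`` integrates numerically with a
    stiff-capable solver (used as an independent cross-check).
    Events (ligand addition) are handled by restarting at segment
    boundaries, never by discontinuous forcing inside the right-hand side.
    """
    if protocol.condition != "epo":
        raise ValueError("simulate() handles the epo condition; use reduced_model() otherwise")
    if init is None:
        epor_i, epor_m = prestimulus_steady_state(params)
        init = np.array([epor_i, epor_m, 0.0, 0.0, 0.0, 0.0])
    init = np.asarray(init, dtype=float)
    if init.shape != (6,) or np.any(init < 0):
        raise ValueError("init must be a nonnegative vector of length 6")
    segs = _segments(protocol, variant, params)
    if method == "expm":
        try:
            return _propagate(segs, init, protocol.sample_times)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"integration failed for variant {variant.name or 'basic'}: {exc}"
            ) from exc
    if method == "lsoda":
        return _integrate_segments(segs, init, protocol.sample_times, rtol, atol)
    raise ValueError(f"unknown method {method!r}")


def _integrate_segments(
    segments: list[tuple[float, np.ndarray, np.ndarray]],
    init: np.ndarray,
    times: Sequence[float],
    rtol: float,
    atol: float,
) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    starts = [s[0] for s in segments]
    bounds = sorted({t for t in starts if times[0] < t < times[-1]} | {times[0], times[-1]})
    out = np.empty((times.size, init.size))
    y = init.copy()
    out[np.isclose(times, times[0])] = y
    for a, b_ in zip(bounds, bounds[1:]):
        seg_idx = max(j for j, s in enumerate(starts) if s <= a + 1e-12)
        A, b = segments[seg_idx][1], segments[seg_idx][2]
        sol = solve_ivp(
            lambda t, y: A @ y + b,
            (a, b_),
            y,
            method="LSODA",
            dense_output=True,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"LSODA failed on segment [{a}, {b_}]: {sol.message}")
        mask = (times > a + 1e-12) & (times <= b_ + 1e-12)
        if mask.any():
            out[mask] = sol.sol(times[mask]).T
        y = sol.y[:, -1]
    return out


# ---------------------------------------------------------------------------
# reduced models for the auxiliary experiments


class BleachModel:
    """Three-state model of photobleached cells.

    States (EpoR_i, EpoR_m, EpoR_dark): receptor turnover and
    membrane exchange, with a first-order bleaching reaction moving
    fluorescent receptor from both pools into a cumulative dark pool
    during the pulse window.  Kinetic parameters: k_syn, k_deg, k_ItoM,
    k_MtoI, k_bleach.
    """

    condition = "bleach"
    n_states = 3
    state_names = ("EpoR_i", "EpoR_m", "EpoR_dark")
    kinetic_param_names = ("k_syn", "k_deg", "k_ItoM", "k_MtoI", "k_bleach")

    @staticmethod
    def matrices(params: Mapping[str, float], bleaching: bool) -> tuple[np.ndarray, np.ndarray]:
        k_syn = params["k_syn"]
        k_deg = params["k_deg"]
        k_itom = params["k_ItoM"]
        k_mtoi = params["k_MtoI"]
        k_bl = params["k_bleach"] if bleaching else 0.0
        A = np.array(
            [
                [-(k_deg + k_itom + k_bl), k_mtoi, 0.0],
                [k_itom, -(k_mtoi + k_bl), 0.0],
                [k_bl, k_bl, 0.0],
            ]
        )
        b = np.array([k_syn, 0.0, 0.0])
        return A, b

    def simulate(
        self,
        params: Mapping[str, float],
        protocol: StimulusProtocol,
        init: Sequence[float],
    ) -> np.ndarray:
        init = np.asarray(init, dtype=float)
        t0 = protocol.sample_times[0]
        pulse_end = protocol.bleach_start + protocol.bleach_duration
        segs = [
            (t0, *self.matrices(params, False)),
            (max(t0, protocol.bleach_start), *self.matrices(params, True)),
            (max(t0, pulse_end), *self.matrices(params, False)),
        ]
        return _propagate(segs, init, protocol.sample_times)


class ChxModel:
    """Three-state model of cycloheximide-treated cells.

    States (EpoR_i, EpoR_m, EpoR_deg_cum): degradation and membrane
    exchange with synthesis switched off from ``chx_time``.  Kinetic
    parameters: k_deg, k_ItoM, k_MtoI.
    """

    condition = "chx"
    n_states = 3
    state_names = ("EpoR_i", "EpoR_m", "EpoR_deg_cum")
    kinetic_param_names = ("k_deg", "k_ItoM", "k_MtoI")

    @staticmethod
    def matrices(params: Mapping[str, float], synthesizing: bool, k_syn: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        k_deg = params["k_deg"]
        k_itom = params["k_ItoM"]
        k_mtoi = params["k_MtoI"]
        A = np.array(
            [
                [-(k_deg + k_itom), k_mtoi, 0.0],
                [k_itom, -k_mtoi, 0.0],
                [k_deg, 0.0, 0.0],
            ]
        )
        b = np.array([k_syn if synthesizing else 0.0, 0.0, 0.0])
        return A, b

    def simulate(
        self,
        params: Mapping[str, float],
        protocol: StimulusProtocol,
        init: Sequence[float],
        k_syn_before: float = 0.0,
    ) -> np.ndarray:
        init = np.asarray(init, dtype=float)
        t0 = protocol.sample_times[0]
        segs = [
            (t0, *self.matrices(params, True, k_syn_before)),
            (max(t0, protocol.chx_time), *self.matrices(params, False)),
        ]
        return _propagate(segs, init, protocol.sample_times)


_REDUCED = {"bleach": BleachModel(), "chx": ChxModel()}


def reduced_model(condition: str) -> BleachModel | ChxModel:
    """Variant-independent reduced model for the bleach or chx condition."""
    try:
        return _REDUCED[condition]
    except KeyError:
        raise ValueError(f"no reduced model for condition {condition!r}") from None
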