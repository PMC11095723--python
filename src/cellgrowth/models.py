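"""Candidate ODE models for substrate-modulated cell-population growth.

The state of a culture well is ``(n, cg, cl, co)``: cell population
(cells/well), glucose, lactate and dissolved-oxygen concentration
(mol m^-3).  Population growth is logistic with a multiplicative
environmental factor ``F_env = f1(co) * f2(cg) * f3(cl)`` built from
per-substrate modulating effects (zero-order, first-order, or
Michaelis-Menten).  Glucose is consumed by Michaelis-Menten kinetics,
lactate is produced by glycolysis (2 lactate per glucose) and removed by
oxidative respiration, and oxygen is clamped at the incubator level.

Units: rate constants are per second (as published); all public
interfaces take and return time in **hours**.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import odeint, solve_ivp

HOUR_S = 3600.0

#: canonical observable order used across the package
OBSERVABLES = ("n", "cg", "cl")

SUBSTRATES = ("oxygen", "glucose", "lactate")


class EffectKind(str, enum.Enum):
    """Functional form of a substrate's modulating effect on proliferation."""

    ZERO_ORDER = "zero_order"
    FIRST_ORDER = "first_order"
    MMK_POSITIVE = "mmk_positive"
    MMK_NEGATIVE = "mmk_negative"

    @property
    def is_mmk(self) -> bool:
        return self in (EffectKind.MMK_POSITIVE, EffectKind.MMK_NEGATIVE)


@dataclass(frozen=True)
class ModulatingEffect:
    """A modulating-effect kind together with its half-saturation constant.

    ``K`` (mol m^-3) is required (and must be positive) for the two
    Michaelis-Menten kinds and must be absent otherwise.
    """

    kind: EffectKind
    K: float | None = None

    def __post_init__(self) -> None:
        kind = EffectKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind.is_mmk:
            if self.K is None or not np.isfinite(self.K) or self.K <= 0:
                raise ValueError(
                    f"effect kind {kind.value} requires a positive K, got {self.K!r}"
                )
        elif self.K is not None:
            raise ValueError(f"effect kind {kind.value} carries no K")


def modulating_factor(effect: ModulatingEffect, c: float | np.ndarray) -> float | np.ndarray:
    """Evaluate a modulating effect at concentration ``c`` (mol m^-3).

    zero-order -> 1; first-order -> c; MMK positive -> c/(c+K);
    MMK negative -> K/(c+K).  MMK outputs lie in [0, 1].
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    kind = effect.kind
    if kind is EffectKind.ZERO_ORDER:
        out = np.ones_like(c)
    elif kind is EffectKind.FIRST_ORDER:
        out = c.copy()
    elif kind is EffectKind.MMK_POSITIVE:
        out = c / (c + effect.K)
    elif kind is EffectKind.MMK_NEGATIVE:
        out = effect.K / (c + effect.K)
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown effect kind {kind!r}")
    return out if out.ndim else float(out)


class Kinetics(str, enum.Enum):
    ZERO = "zero"
    FIRST = "first"
    MICHAELIS_MENTEN = "michaelis_menten"
    COMPETITIVE_INHIBITION = "competitive_inhibition"


def reaction_rate(
    kinetics: Kinetics | str,
    V: float,
    c: float = 0.0,
    cbar: float = 1.0,
    c_inhibitor: float = 0.0,
    cbar_inhibition: float = 1.0,
) -> float:
    """Per-cell reaction term R for a substrate (volumetric rate is n*R)."""
    kinetics = Kinetics(kinetics)
    if c < 0 or c_inhibitor < 0:
        raise ValueError("concentrations must be non-negative")
    if kinetics is Kinetics.ZERO:
        return V
    if kinetics is Kinetics.FIRST:
        return V * c
    if cbar <= 0:
        raise ValueError("cbar must be positive for saturating kinetics")
    if kinetics is Kinetics.MICHAELIS_MENTEN:
        return V * c / (c + cbar)
    if cbar_inhibition <= 0:
        raise ValueError("cbar_inhibition must be positive")
    return V * (c / (c + cbar)) * (cbar_inhibition / (c_inhibitor + cbar_inhibition))


# effect kinds permitted per substrate, in enumeration order
_OXYGEN_KINDS = (EffectKind.ZERO_ORDER, EffectKind.FIRST_ORDER, EffectKind.MMK_POSITIVE)
_GLUCOSE_KINDS = _OXYGEN_KINDS
_LACTATE_KINDS = (EffectKind.ZERO_ORDER, EffectKind.FIRST_ORDER, EffectKind.MMK_NEGATIVE)


@dataclass(frozen=True)
class CandidateModel:
    """One candidate structure: which effect kind each substrate carries."""

    f_oxygen: EffectKind = EffectKind.MMK_POSITIVE
    f_glucose: EffectKind = EffectKind.MMK_POSITIVE
    f_lactate: EffectKind = EffectKind.MMK_NEGATIVE

    def __post_init__(self) -> None:
        object.__setattr__(self, "f_oxygen", EffectKind(self.f_oxygen))
        object.__setattr__(self, "f_glucose", EffectKind(self.f_glucose))
        object.__setattr__(self, "f_lactate", EffectKind(self.f_lactate))
        if self.f_oxygen not in _OXYGEN_KINDS:
            raise ValueError(f"oxygen effect may not be {self.f_oxygen.value}")
        if self.f_glucose not in _GLUCOSE_KINDS:
            raise ValueError(f"glucose effect may not be {self.f_glucose.value}")
        if self.f_lactate not in _LACTATE_KINDS:
            raise ValueError(f"lactate effect may not be {self.f_lactate.value}")

    @property
    def kinds(self) -> tuple[EffectKind, EffectKind, EffectKind]:
        return (self.f_oxygen, self.f_glucose, self.f_lactate)

    @property
    def name(self) -> str:
        """Name by which substrates carry an MMK effect (e.g. ``OxyGluLac``).

        Models without any MMK effect are named ``Const``; substrates with a
        first-order effect are appended as a ``+`` suffix so that all 27
        structures have distinct names.
        """
        tags = ("Oxy", "Glu", "Lac")
        letters = ("o", "g", "l")
        mmk = "".join(t for t, k in zip(tags, self.kinds) if k.is_mmk)
        first = "".join(
            c for c, k in zip(letters, self.kinds) if k is EffectKind.FIRST_ORDER
        )
        base = mmk or "Const"
        return base + (f"+{first}" if first else "")

    @property
    def n_mmk(self) -> int:
        return sum(k.is_mmk for k in self.kinds)

    @property
    def n_first_order(self) -> int:
        return sum(k is EffectKind.FIRST_ORDER for k in self.kinds)

    def free_parameter_names(self) -> tuple[str, ...]:
        """Parameters inferred for this structure.

        beta, delta, V_g and cbar_g are always free; each MMK effect adds
        its half-saturation constant.
        """
        names = ["beta", "delta", "V_g", "cbar_g"]
        if self.f_oxygen.is_mmk:
            names.append("K_o")
        if self.f_glucose.is_mmk:
            names.append("K_g")
        if self.f_lactate.is_mmk:
            names.append("K_l")
        return tuple(names)

    def effects(self, params: "ParameterSet") -> tuple[ModulatingEffect, ...]:
        """Bind effect kinds to the K values carried by ``params``."""
        ks = (params.K_o, params.K_g, params.K_l)
        return tuple(
            ModulatingEffect(kind, K if kind.is_mmk else None)
            for kind, K in zip(self.kinds, ks)
        )


def enumerate_candidates(
    oxygen_kinds: Sequence[EffectKind] = _OXYGEN_KINDS,
    glucose_kinds: Sequence[EffectKind] = _GLUCOSE_KINDS,
    lactate_kinds: Sequence[EffectKind] = _LACTATE_KINDS,
) -> list[CandidateModel]:
    """All candidate structures in deterministic (oxygen, glucose, lactate)
    lexicographic order; the full family has 3 x 3 x 3 = 27 members."""
    return [
        CandidateModel(fo, fg, fl)
        for fo, fg, fl in itertools.product(oxygen_kinds, glucose_kinds, lactate_kinds)
    ]


def model_by_name(name: str) -> CandidateModel:
    for m in enumerate_candidates():
        if m.name == name:
            return m
    raise KeyError(f"no candidate model named {name!r}")


@dataclass(frozen=True)
class ParameterSet:
    """Free parameters of a candidate model (rate constants per second).

    ``V_g`` is the glucose consumption rate constant per cell, in
    mol m^-3 s^-1 per cell/well: the volumetric consumption rate is
    ``V_g * n * cg / (cg + cbar_g)``.  K entries are only meaningful for
    models whose corresponding effect is Michaelis-Menten.
    """

    beta: float
    delta: float
    V_g: float
    cbar_g: float
    K_o: float | None = None
    K_g: float | None = None
    K_l: float | None = None

    def __post_init__(self) -> None:
        if self.beta <= 0 or not np.isfinite(self.beta):
            raise ValueError("beta must be a positive finite real")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.V_g < 0:
            raise ValueError("V_g must be non-negative")
        if self.cbar_g <= 0:
            raise ValueError("cbar_g must be positive")
        for nm in ("K_o", "K_g", "K_l"):
            v = getattr(self, nm)
            if v is not None and v <= 0:
                raise ValueError(f"{nm} must be positive when present")

    def to_array(self, names: Sequence[str]) -> np.ndarray:
        vals = []
        for nm in names:
            v = getattr(self, nm)
            if v is None:
                raise ValueError(f"parameter {nm} is not set")
            vals.append(v)
        return np.asarray(vals, dtype=float)

    def updated(self, names: Sequence[str], values: Sequence[float]) -> "ParameterSet":
        return replace(self, **dict(zip(names, map(float, values))))


@dataclass(frozen=True)
class FixedConstants:
    """Constants held fixed during inference (published defaults)."""

    V_o: float = 2.00e-19
    cbar_o: float = 6.66e-9
    n_max: float = 3.0e6
    #: +1: glycolysis produces lactate (2 per glucose) and respiration
    #: consumes it; -1 flips the whole lactate balance (exposed because
    #: the published equation is typographically ambiguous)
    lactate_sign: int = 1

    def __post_init__(self) -> None:
        if self.V_o < 0:
            raise ValueError("V_o must be non-negative")
        if self.cbar_o <= 0:
            raise ValueError("cbar_o must be positive")
        if self.n_max <= 0:
            raise ValueError("n_max must be positive")
        if self.lactate_sign not in (1, -1):
            raise ValueError("lactate_sign must be +1 or -1")


def published_parameters() -> ParameterSet:
    """The published calibrated values for the OxyGluLac structure.

    Note the published half-saturation constants for glucose and lactate
    lie far outside the concentrations realised in a 114 h culture, so
    with these values the substrate effects are nearly flat.
    """
    return ParameterSet(
        beta=3.83e-5, delta=3.12e-5, V_g=8.78e-19, cbar_g=1.66,
        K_o=1.88e-5, K_g=6.86e-7, K_l=8602.0,
    )


def default_synthetic_parameters() -> ParameterSet:
    """Synthetic-fixture parameter set for the OxyGluLac structure.

    beta, delta (scaled down) and cbar_g follow the published values; the
    half-saturation constants are placed inside the experimental
    concentration ranges so every substrate has a measurable effect, and
    V_g is expressed per cell/well at a magnitude that depletes glucose
    over a multi-week horizon.  A fixture choice, not a published value.
    """
    return ParameterSet(
        beta=3.83e-5, delta=5.0e-6, V_g=2.0e-12, cbar_g=1.66,
        K_o=0.08, K_g=2.0, K_l=8.0,
    )


def default_synthetic_constants() -> FixedConstants:
    return FixedConstants(V_o=1.0e-13, cbar_o=6.66e-9, n_max=3.0e6)


def oxygen_percent_to_concentration(percent: float) -> float:
    """Map incubator oxygen percent to dissolved mol m^-3 (18.6% -> 0.18)."""
    return 0.18 * percent / 18.6


@dataclass(frozen=True)
class CultureCondition:
    """Initial state and horizon of one culture well."""

    n0: float
    cg0: float
    cl0: float
    co: float
    horizon_h: float = 114.0

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if self.cg0 <= 0:
            raise ValueError("cg0 must be positive")
        if self.cl0 < 0:
            raise ValueError("cl0 must be non-negative")
        if self.co <= 0:
            raise ValueError("co must be positive")
        if self.horizon_h <= 0:
            raise ValueError("horizon_h must be positive")


@dataclass
class Trajectory:
    """Simulated state sequences on a shared time grid (hours)."""

    times: np.ndarray
    n: np.ndarray
    cg: np.ndarray
    cl: np.ndarray
    co: np.ndarray
    meta: dict = field(default_factory=dict)

    def observable(self, name: str) -> np.ndarray:
        if name not in OBSERVABLES:
            raise KeyError(f"unknown observable {name!r}")
        return getattr(self, name)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_h": self.times, "n": self.n, "cg": self.cg, "cl": self.cl,
             "co": self.co}
        )


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the time (hours) where it failed."""

    def __init__(self, message: str, t_fail_h: float | None = None):
        super().__init__(message)
        self.t_fail_h = t_fail_h


def _factor_table(model: CandidateModel, params: ParameterSet):
    """Per-substrate (kind, K) pairs with K validated once up front."""
    effs = model.effects(params)
    return [(e.kind, e.K) for e in effs]


def _apply_effect(kind: EffectKind, K: float | None, c: np.ndarray) -> np.ndarray:
    if kind is EffectKind.ZERO_ORDER:
        return np.ones_like(c)
    if kind is EffectKind.FIRST_ORDER:
        return c
    if kind is EffectKind.MMK_POSITIVE:
        return c / (c + K)
    return K / (c + K)


def ode_rhs(
    model: CandidateModel,
    params: ParameterSet,
    consts: FixedConstants,
    state: Sequence[float],
) -> np.ndarray:
    """Time derivative of ``(n, cg, cl, co)`` in per-second units.

    dn/dt  = f1(co) f2(cg) f3(cl) * beta * n * (1 - n/n_max) - delta * n
    dcg/dt = -V_g n cg/(cg + cbar_g)
    dcl/dt = +2 V_g n cg/(cg + cbar_g) - (1/3) V_o n co/(co + cbar_o)
    dco/dt = 0   (oxygen clamp)
    """
    n, cg, cl, co = (float(s) for s in state)
    if not all(np.isfinite([n, cg, cl, co])):
        raise ValueError("state must be finite")
    d = _rhs_core(
        np.array([n]), np.array([cg]), np.array([cl]), np.array([co]),
        model, params, consts,
    )
    return np.array([d[0][0], d[1][0], d[2][0], 0.0])


def _rhs_core(n, cg, cl, co, model, params, consts):
    """Vectorised RHS over stacked conditions; clips negatives to 0."""
    n = np.maximum(n, 0.0)
    cg = np.maximum(cg, 0.0)
    cl = np.maximum(cl, 0.0)
    table = _factor_table(model, params)
    with np.errstate(over="ignore", invalid="ignore"):
        f1 = _apply_effect(table[0][0], table[0][1], co)
        f2 = _apply_effect(table[1][0], table[1][1], cg)
        f3 = _apply_effect(table[2][0], table[2][1], cl)
        rg = params.V_g * n * cg / (cg + params.cbar_g)
        ro = consts.V_o * n * co / (co + consts.cbar_o)
        dn = (
            f1 * f2 * f3 * params.beta * n * (1.0 - n / consts.n_max)
            - params.delta * n
        )
        dcg = -rg
        dcl = consts.lactate_sign * (2.0 * rg - ro / 3.0)
    return dn, dcg, dcl


DEFAULT_SOLVER_OPTIONS = {"method": "LSODA", "rtol": 1e-8, "atol": 1e-10}


def _integrate(
    model: CandidateModel,
    params: ParameterSet,
    consts: FixedConstants,
    y0: np.ndarray,
    co: np.ndarray,
    times_h: np.ndarray,
    solver_options: dict | None,
) -> np.ndarray:
    """Integrate stacked conditions; returns array (3, C, T)."""
    opts = dict(DEFAULT_SOLVER_OPTIONS)
    if solver_options:
        opts.update(solver_options)
    method = opts.pop("method")
    C = co.size

    def rhs(t, y):
        n, cg, cl = y[:C], y[C : 2 * C], y[2 * C :]
        dn, dcg, dcl = _rhs_core(n, cg, cl, co, model, params, consts)
        return np.concatenate([dn, dcg, dcl]) * HOUR_S

    t_end = float(times_h[-1])
    if t_end == 0.0:
        sol_y = np.repeat(y0[:, None], times_h.size, axis=1)
    elif method == "LSODA":
        # fast path: odeint has much lower per-call overhead than solve_ivp
        lead = 1 if times_h[0] > 0 else 0
        t_grid = np.concatenate([[0.0], times_h]) if lead else times_h
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # failures surface as errors below
            res, info = odeint(
                lambda y, t: rhs(t, y), y0, t_grid,
                rtol=opts.get("rtol"), atol=opts.get("atol"),
                mxstep=int(opts.get("mxstep", 0)), full_output=True,
            )
        if info["message"] != "Integration successful.":
            raise IntegrationError(
                f"ODE integration failed: {info['message']}",
                t_fail_h=float(info["tcur"][-1]) if len(info["tcur"]) else 0.0,
            )
        sol_y = res[lead:].T
    else:
        opts.pop("mxstep", None)
        sol = solve_ivp(rhs, (0.0, t_end), y0, method=method, t_eval=times_h, **opts)
        if not sol.success:
            raise IntegrationError(
                f"ODE integration failed: {sol.message}",
                t_fail_h=float(sol.t[-1]) if sol.t.size else 0.0,
            )
        sol_y = sol.y
    out = sol_y.reshape(3, C, times_h.size)
    return out


def simulate(
    model: CandidateModel,
    params: ParameterSet,
    consts: FixedConstants,
    condition: CultureCondition,
    times_h: Sequence[float],
    solver_options: dict | None = None,
) -> Trajectory:
    """Integrate the model for one culture condition at the given output
    times (hours).

    The initial condition is applied at seeding time t = 0 regardless of
    the first requested output time.  States are floored at 0; the number
    of floored values is recorded in ``Trajectory.meta['n_clipped']``.
    """
    times = np.asarray(times_h, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be strictly increasing and non-negative")
    y0 = np.array([condition.n0, condition.cg0, condition.cl0])
    out = _integrate(
        model, params, consts, y0, np.array([condition.co]), times, solver_options
    )
    raw = out[:, 0, :]
    n_clipped = int(np.sum(raw < 0))
    clipped = np.maximum(raw, 0.0)
    return Trajectory(
        times=times,
        n=clipped[0],
        cg=clipped[1],
        cl=clipped[2],
        co=np.full_like(times, condition.co),
        meta={"n_clipped": n_clipped},
    )


def simulate_conditions(
    model: CandidateModel,
    params: ParameterSet,
    consts: FixedConstants,
    conditions: Sequence[CultureCondition],
    times_h: Sequence[float],
    solver_options: dict | None = None,
) -> np.ndarray:
    """Integrate many conditions as one stacked system on a shared grid.

    Returns an array of shape ``(n_conditions, 3, n_times)`` ordered as
    ``OBSERVABLES``.  This is the calibration work-horse: one solver call
    covers the whole experimental design.
    """
    times = np.asarray(times_h, dtype=float)
    y0 = np.concatenate(
        [
            [c.n0 for c in conditions],
            [c.cg0 for c in conditions],
            [c.cl0 for c in conditions],
        ]
    ).astype(float)
    co = np.array([c.co for c in conditions], dtype=float)
    out = _integrate(model, params, consts, y0, co, times, solver_options)
    return np.maximum(out, 0.0).transpose(1, 0, 2)


def substrate_dependence(
    model: CandidateModel, consts: FixedConstants, V_g_positive: bool = True
) -> tuple[bool, bool]:
    """Whether the population dynamics depend on oxygen / on glucose.

    Dependence is direct (a non-zero-order modulating term) or routed
    through lactate: glucose consumption produces lactate and oxygen
    consumption removes it, so a lactate effect couples both substrates
    to the population whenever the corresponding rate constant is
    positive.
    """
    lactate_active = model.f_lactate is not EffectKind.ZERO_ORDER
    dep_o = model.f_oxygen is not EffectKind.ZERO_ORDER or (
        lactate_active and consts.V_o > 0
    )
    dep_g = model.f_glucose is not EffectKind.ZERO_ORDER or (
        lactate_active and V_g_positive
    )
    return dep_o, dep_g


def filter_candidates(
    models: Iterable[CandidateModel],
    required: Iterable[str],
    consts: FixedConstants | None = None,
) -> list[CandidateModel]:
    """Retain models whose population depends on every required substrate.

    ``required`` is a subset of {"oxygen", "glucose"}.  With both
    required, the full 27-member family reduces to 22.
    """
    required = set(required)
    unknown = required - {"oxygen", "glucose"}
    if unknown:
        raise ValueError(f"unknown required substrates: {sorted(unknown)}")
    consts = consts or FixedConstants()
    kept = []
    for m in models:
        dep_o, dep_g = substrate_dependence(m, consts)
        if "oxygen" in required and not dep_o:
            continue
        if "glucose" in required and not dep_g:
            continue
        kept.append(m)
    return kept
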