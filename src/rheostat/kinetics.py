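"""Mass-action kinetics of the sphingolipid rheostat.

Two model variants are defined:

* the *core* rheostat — ceramide (x1) ⇌ sphingosine (x2) ⇌ S1P (x3) with a
  zero-order ceramide input and irreversible S1P degradation; this is the
  scheme subjected to metabolic control analysis, and
* the *extended* rheostat — sphinganine → ceramide ⇌ sphingosine ⇌ S1P with
  condition-dependent apparent rates: the SphK step k3 is attenuated in wild
  type (``alpha_hai1a``) and de novo sphinganine synthesis k00 is attenuated
  by a ceramide-driven negative feedback (``alpha_cer``), both gated by a
  Boolean condition switch ``s_on`` (1 in wild type, 0 in the mutant).

All rate laws are mass action: interconversions first order, synthesis zero
order.  The system is therefore affine-linear, dx/dt = A x + b, which gives
closed-form steady states (a linear solve) and an exact matrix-exponential
propagator alongside the numeric integrator.

Units: concentrations in arbitrary model units (a.u.), time in days with
t = 0 at 2 days post fertilization (dpf), rate constants in day⁻¹ (first
order) or a.u.·day⁻¹ (zero order).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "CORE_SPECIES",
    "EXTENDED_SPECIES",
    "CoreParameters",
    "ExtendedParameters",
    "ConditionSpec",
    "Trajectory",
    "ValidationError",
    "NoSteadyStateError",
    "IntegrationError",
    "apparent_rates",
    "core_rhs",
    "extended_rhs",
    "core_system_matrices",
    "extended_system_matrices",
    "steady_state",
    "simulate",
    "propagate_linear",
]

CORE_SPECIES = ("ceramide", "sphingosine", "s1p")
EXTENDED_SPECIES = ("sphinganine", "ceramide", "sphingosine", "s1p")

#: tolerance below which small negative solver excursions are clipped to 0
_NEG_CLIP = 1e-7


class ValidationError(ValueError):
    """A parameter or state violates its declared invariant."""


class NoSteadyStateError(RuntimeError):
    """The balance equations are singular; no unique steady state exists."""


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce a valid trajectory."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class CoreParameters:
    """Rate constants of the 3-species core rheostat.

    ``k0`` is the zero-order ceramide input (a.u.·day⁻¹); ``k1r`` the
    first-order reverse of that boundary exchange; ``k2f``/``k2r`` the
    ceramide⇌sphingosine interconversion; ``k3``/``k3r`` the
    sphingosine⇌S1P step (k3 is the SphK rate); ``k4`` irreversible S1P
    degradation.  Forward rates must be positive, reverse rates nonnegative.
    """

    k0: float
    k1r: float
    k2f: float
    k2r: float
    k3: float
    k3r: float
    k4: float

    def __post_init__(self) -> None:
        for name in ("k0", "k2f", "k3", "k4"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        for name in ("k1r", "k2r", "k3r"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        for f in fields(self):
            _require(np.isfinite(getattr(self, f.name)), f"{f.name} must be finite")


@dataclass(frozen=True)
class ExtendedParameters:
    """Rate constants of the 4-species extended rheostat.

    ``k00`` is the de novo (serine-palmitoyltransferase) sphinganine input,
    ``k01`` sphinganine→ceramide; the rheostat steps k2f/k2r, k3/k3r, k4 are
    as in :class:`CoreParameters`.  ``alpha_hai1a`` ∈ [0.5, 1) attenuates
    SphK in wild type (the mutant's SphK is at least twice the wild-type
    rate); ``alpha_cer`` ∈ [−1, 0] attenuates de novo synthesis when the
    ceramide feedback is engaged (−1 shuts synthesis off completely).
    """

    k00: float
    k01: float
    k2f: float
    k2r: float
    k3: float
    k3r: float
    k4: float
    alpha_hai1a: float = 0.5
    alpha_cer: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k00", "k01", "k2f", "k3", "k4"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        for name in ("k2r", "k3r"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(
            0.5 <= self.alpha_hai1a < 1.0,
            f"alpha_hai1a must lie in [0.5, 1), got {self.alpha_hai1a}",
        )
        _require(
            -1.0 <= self.alpha_cer <= 0.0,
            f"alpha_cer must lie in [-1, 0], got {self.alpha_cer}",
        )
        for f in fields(self):
            _require(np.isfinite(getattr(self, f.name)), f"{f.name} must be finite")


@dataclass(frozen=True)
class ConditionSpec:
    """Experimental condition: a label and the Boolean switch ``s_on``.

    The switch is ON (1) in wild type — SphK attenuated, feedback engaged —
    and OFF (0) in the hai1a-amorphic mutant.
    """

    condition_id: str
    s_on: int

    def __post_init__(self) -> None:
        _require(self.s_on in (0, 1), f"s_on must be 0 or 1, got {self.s_on}")


@dataclass(frozen=True)
class Trajectory:
    """Simulated time course: times (days from 2 dpf) × state rows."""

    times: np.ndarray
    states: np.ndarray
    model_tag: str
    condition_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        _require(t.ndim == 1 and np.all(np.diff(t) > 0) if t.size > 1 else t.ndim == 1,
                 "times must be strictly increasing")
        _require(self.states.shape[0] == t.size, "states/times length mismatch")

    def species(self) -> Sequence[str]:
        return CORE_SPECIES if self.model_tag == "core" else EXTENDED_SPECIES


def apparent_rates(params: ExtendedParameters, s_on: int) -> tuple[float, float]:
    """Condition-dependent apparent rates of the extended model.

    Returns ``(k3_app, k00_app)`` with

        k3_app  = k3  · (1 − s_on · alpha_hai1a)
        k00_app = k00 · (1 + s_on · alpha_cer)

    so that with ``s_on = 0`` (mutant) both equal the raw rates, while in
    wild type SphK is reduced by at least half and de novo synthesis is
    scaled down by the feedback factor.
    """
    _require(s_on in (0, 1), f"s_on must be 0 or 1, got {s_on}")
    k3_app = params.k3 * (1.0 - s_on * params.alpha_hai1a)
    k00_app = params.k00 * (1.0 + s_on * params.alpha_cer)
    return k3_app, k00_app


def core_rhs(state: np.ndarray, params: CoreParameters) -> np.ndarray:
    """Time derivative of the core model at ``state`` (a.u.·day⁻¹)."""
    x1, x2, x3 = _check_state(state, 3)
    p = params
    dx1 = p.k0 - p.k1r * x1 - p.k2f * x1 + p.k2r * x2
    dx2 = p.k2f * x1 - p.k2r * x2 - p.k3 * x2 + p.k3r * x3
    dx3 = p.k3 * x2 - p.k3r * x3 - p.k4 * x3
    return np.array([dx1, dx2, dx3])


def extended_rhs(state: np.ndarray, params: ExtendedParameters, s_on: int) -> np.ndarray:
    """Time derivative of the extended model under condition ``s_on``."""
    x_sa, x_cer, x_sph, x_s1p = _check_state(state, 4)
    k3a, k00a = apparent_rates(params, s_on)
    p = params
    dx_sa = k00a - p.k01 * x_sa
    dx_cer = p.k01 * x_sa - p.k2f * x_cer + p.k2r * x_sph
    dx_sph = p.k2f * x_cer - p.k2r * x_sph - k3a * x_sph + p.k3r * x_s1p
    dx_s1p = k3a * x_sph - p.k3r * x_s1p - p.k4 * x_s1p
    return np.array([dx_sa, dx_cer, dx_sph, dx_s1p])


def _check_state(state: np.ndarray, n: int) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    _require(x.shape == (n,), f"state must have shape ({n},), got {x.shape}")
    _require(bool(np.all(np.isfinite(x))), "state must be finite")
    return x


def core_system_matrices(params: CoreParameters) -> tuple[np.ndarray, np.ndarray]:
    """Affine form dx/dt = A x + b of the core model."""
    p = params
    A = np.array(
        [
            [-(p.k1r + p.k2f), p.k2r, 0.0],
            [p.k2f, -(p.k2r + p.k3), p.k3r],
            [0.0, p.k3, -(p.k3r + p.k4)],
        ]
    )
    b = np.array([p.k0, 0.0, 0.0])
    return A, b


def extended_system_matrices(
    params: ExtendedParameters, s_on: int
) -> tuple[np.ndarray, np.ndarray]:
    """Affine form dx/dt = A x + b of the extended model under ``s_on``."""
    k3a, k00a = apparent_rates(params, s_on)
    p = params
    A = np.array(
        [
            [-p.k01, 0.0, 0.0, 0.0],
            [p.k01, -p.k2f, p.k2r, 0.0],
            [0.0, p.k2f, -(p.k2r + k3a), p.k3r],
            [0.0, 0.0, k3a, -(p.k3r + p.k4)],
        ]
    )
    b = np.array([k00a, 0.0, 0.0, 0.0])
    return A, b


def _system_matrices(params, s_on: int) -> tuple[np.ndarray, np.ndarray, str]:
    if isinstance(params, CoreParameters):
        A, b = core_system_matrices(params)
        return A, b, "core"
    if isinstance(params, ExtendedParameters):
        A, b = extended_system_matrices(params, s_on)
        return A, b, "extended"
    raise ValidationError(f"unknown parameter type {type(params).__name__}")


def steady_state(params, s_on: int = 0) -> np.ndarray:
    """Unique nonnegative steady state, by linear solve of A x = −b.

    The model variant is inferred from the parameter type.  Raises
    :class:`NoSteadyStateError` when the balance matrix is singular (e.g.
    the core model with ``k4 = 0`` and ``k1r = 0``, which has no outflow).
    """
    A, b, _ = _system_matrices(params, s_on)
    try:
        x = np.linalg.solve(A, -b)
    except np.linalg.LinAlgError as exc:
        raise NoSteadyStateError(f"singular balance matrix: {exc}") from exc
    if not np.all(np.isfinite(x)) or np.linalg.cond(A) > 1e12:
        raise NoSteadyStateError("balance matrix numerically singular")
    # compartmental A with outflow is a nonsingular M-matrix: x >= 0 holds
    # exactly; clip roundoff only
    return np.where((x < 0) & (x > -_NEG_CLIP), 0.0, x)


def propagate_linear(A: np.ndarray, b: np.ndarray, x0: np.ndarray, t: float) -> np.ndarray:
    """Exact solution of dx/dt = A x + b at time ``t`` via the augmented
    matrix exponential (valid for singular A as well)."""
    n = A.shape[0]
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A
    M[:n, n] = b
    z = np.append(np.asarray(x0, dtype=float), 1.0)
    return (expm(M * t) @ z)[:n]


def simulate(
    params,
    x0: np.ndarray,
    times: np.ndarray,
    s_on: int = 0,
    condition_id: str = "",
    method: str = "lsoda",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model from ``x0`` over ``times`` (days from 2 dpf).

    ``method`` is either a stiff-capable ``scipy.integrate.solve_ivp``
    method name (default ``"lsoda"``) or ``"expm"`` for the exact
    matrix-exponential propagator of the affine-linear system.
    """
    A, b, tag = _system_matrices(params, s_on)
    t = np.asarray(times, dtype=float)
    x0 = _check_state(x0, A.shape[0])
    _require(bool(np.all(x0 >= 0)), "initial state must be nonnegative")
    _require(t.size >= 1 and bool(np.all(np.diff(t) > 0)), "times must be strictly increasing")

    if method == "expm":
        states = np.array([propagate_linear(A, b, x0, ti) for ti in t])
    else:
        if t[0] == 0.0:
            t_eval = t
        else:
            t_eval = np.concatenate([[0.0], t])
        sol = solve_ivp(
            lambda _t, x: A @ x + b,
            (0.0, float(t_eval[-1])) if t_eval[-1] > 0 else (0.0, 1e-12),
            x0,
            method=method.upper() if method in ("lsoda", "bdf") else method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"solver failed: {sol.message}")
        states = sol.y.T
        if t[0] != 0.0:
            states = states[1:]
    states = np.where((states < 0) & (states > -_NEG_CLIP), 0.0, states)
    return Trajectory(times=t, states=states, model_tag=tag, condition_id=condition_id)


def scale_reaction(params: CoreParameters, reaction: int, factor: float) -> CoreParameters:
    """Return core parameters with reaction ``reaction`` (1..4) scaled by
    ``factor`` — forward and reverse constants together, the proportional
    perturbation used for control coefficients."""
    _require(reaction in (1, 2, 3, 4), f"reaction must be 1..4, got {reaction}")
    _require(factor > 0, "factor must be > 0")
    if reaction == 1:
        return replace(params, k0=params.k0 * factor, k1r=params.k1r * factor)
    if reaction == 2:
        return replace(params, k2f=params.k2f * factor, k2r=params.k2r * factor)
    if reaction == 3:
        return replace(params, k3=params.k3 * factor, k3r=params.k3r * factor)
    return replace(params, k4=params.k4 * factor)
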