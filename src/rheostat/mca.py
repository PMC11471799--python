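"""Metabolic control analysis of the core sphingolipid rheostat.

Control coefficients quantify how the steady state responds to small
proportional perturbations of whole reactions.  With each reaction j scaled
by a factor p_j (forward and reverse constants together), the scaled
concentration control coefficient is

    C^xi_j = d ln x_i* / d ln p_j |_{p=1}

and the flux control coefficient C^J_j is the same logarithmic derivative
of the steady-state downstream flux J = v4.  For this compartmental
mass-action network the balance equations are affine-linear, so the
coefficients follow from one linear solve per reaction (implicit
differentiation of A(p)·x + b(p) = 0).  The classical summation theorems —
Σ_j C^J_j = 1 and Σ_j C^xi_j = 0 per species — hold by construction and are
used as invariants.

The biological question the analysis answers: the hai1a mutant's elevated
SphK activity enters solely through the sphingosine→S1P rate k3 (reaction
v3).  A negative ceramide control coefficient with respect to v3 means the
rheostat alone drives ceramide *down* in the mutant and therefore cannot
explain ceramide over-production.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import (
    CORE_SPECIES,
    CoreParameters,
    ValidationError,
    core_system_matrices,
    scale_reaction,
    steady_state,
)

__all__ = [
    "REACTIONS",
    "ControlCoefficients",
    "net_rates",
    "elasticities",
    "control_coefficients",
    "control_coefficients_fd",
    "k3_perturbation_report",
]

REACTIONS = ("v1", "v2", "v3", "v4")


@dataclass(frozen=True)
class ControlCoefficients:
    """Flux and concentration control coefficients at a reference state.

    ``c_flux`` has one entry per reaction (v1..v4); ``c_conc`` is species
    (ceramide, sphingosine, S1P) × reaction.  Scaled coefficients obey the
    summation theorems Σ c_flux = 1 and Σ_j c_conc[i, j] = 0.
    """

    c_flux: np.ndarray
    c_conc: np.ndarray
    reference_state: np.ndarray
    reference_params: CoreParameters
    scaled: bool = True

    def flux_series(self) -> pd.Series:
        return pd.Series(self.c_flux, index=list(REACTIONS), name="c_flux")

    def conc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.c_conc, index=list(CORE_SPECIES), columns=list(REACTIONS))

    def summation_residuals(self) -> tuple[float, np.ndarray]:
        """(|Σ c_flux − 1|, per-species |Σ_j c_conc|) — both ≈ 0 when scaled."""
        return abs(float(self.c_flux.sum()) - 1.0), np.abs(self.c_conc.sum(axis=1))


def net_rates(params: CoreParameters, state: np.ndarray) -> np.ndarray:
    """Net rates (v1, v2, v3, v4) at ``state``: v1 = k0 − k1r·x1,
    v2 = k2f·x1 − k2r·x2, v3 = k3·x2 − k3r·x3, v4 = k4·x3."""
    x1, x2, x3 = np.asarray(state, dtype=float)
    p = params
    return np.array(
        [
            p.k0 - p.k1r * x1,
            p.k2f * x1 - p.k2r * x2,
            p.k3 * x2 - p.k3r * x3,
            p.k4 * x3,
        ]
    )


def elasticities(params: CoreParameters, state: np.ndarray) -> np.ndarray:
    """Scaled elasticity matrix ε[j, k] = (∂v_j/∂x_k)·(x_k/v_j).

    Requires a strictly positive state and nonzero net rates; a zero net
    rate makes the scaled elasticity of that reaction undefined.
    """
    x = np.asarray(state, dtype=float)
    if not np.all(x > 0):
        raise ValidationError("elasticities require a strictly positive state")
    v = net_rates(params, x)
    p = params
    gross = np.array(
        [
            p.k0 + p.k1r * x[0],
            p.k2f * x[0] + p.k2r * x[1],
            p.k3 * x[1] + p.k3r * x[2],
            p.k4 * x[2],
        ]
    )
    zero = np.abs(v) <= 1e-12 * gross
    if np.any(zero):
        bad = [REACTIONS[j] for j in np.flatnonzero(zero)]
        raise ValidationError(
            f"zero net rate for {', '.join(bad)}: scaled elasticity undefined"
        )
    dvdx = np.array(
        [
            [-p.k1r, 0.0, 0.0],
            [p.k2f, -p.k2r, 0.0],
            [0.0, p.k3, -p.k3r],
            [0.0, 0.0, p.k4],
        ]
    )
    return dvdx * x[np.newaxis, :] / v[:, np.newaxis]


def _reaction_derivatives(params: CoreParameters):
    """∂A/∂p_j and ∂b/∂p_j of the affine system at p = 1, for each reaction
    scaling p_j (forward and reverse constants scaled together)."""
    p = params
    dA = [
        np.array([[-p.k1r, 0, 0], [0, 0, 0], [0, 0, 0]], dtype=float),
        np.array([[-p.k2f, p.k2r, 0], [p.k2f, -p.k2r, 0], [0, 0, 0]], dtype=float),
        np.array([[0, 0, 0], [0, -p.k3, p.k3r], [0, p.k3, -p.k3r]], dtype=float),
        np.array([[0, 0, 0], [0, 0, 0], [0, 0, -p.k4]], dtype=float),
    ]
    db = [
        np.array([p.k0, 0, 0], dtype=float),
        np.zeros(3),
        np.zeros(3),
        np.zeros(3),
    ]
    return dA, db


def control_coefficients(params: CoreParameters, scaled: bool = True) -> ControlCoefficients:
    """Analytic control coefficients at the positive steady state.

    Implicit differentiation of A(p)·x + b(p) = 0 gives, per reaction j,
    dx/dp_j = −A⁻¹(∂A/∂p_j·x* + ∂b/∂p_j); scaling by x* (and the flux
    J = k4·x3*) yields the logarithmic coefficients.  With ``scaled=False``
    the raw sensitivities dx/dp_j and dJ/dp_j are returned instead.
    """
    xs = steady_state(params)
    if not np.all(xs > 0):
        raise ValidationError("control coefficients require a positive steady state")
    A, _ = core_system_matrices(params)
    dA, db = _reaction_derivatives(params)
    dxdp = np.column_stack(
        [np.linalg.solve(A, -(dA[j] @ xs + db[j])) for j in range(4)]
    )
    J = params.k4 * xs[2]
    dJdp = params.k4 * dxdp[2, :].copy()
    dJdp[3] += J  # explicit dependence of v4 on its own scaling
    if scaled:
        c_conc = dxdp / xs[:, np.newaxis]
        c_flux = dJdp / J
    else:
        c_conc = dxdp
        c_flux = dJdp
    return ControlCoefficients(
        c_flux=c_flux, c_conc=c_conc, reference_state=xs,
        reference_params=params, scaled=scaled,
    )


def control_coefficients_fd(
    params: CoreParameters, rel_step: float = 1e-4
) -> ControlCoefficients:
    """Finite-difference control coefficients (independent check).

    Central differences of ln x* and ln J with respect to ln p_j, each
    reaction scaled by (1 ± rel_step).
    """
    if not 0 < rel_step <= 0.1:
        raise ValidationError(f"rel_step must lie in (0, 0.1], got {rel_step}")
    xs = steady_state(params)
    if not np.all(xs > 0):
        raise ValidationError("control coefficients require a positive steady state")
    c_conc = np.empty((3, 4))
    c_flux = np.empty(4)
    dlnp = np.log1p(rel_step) - np.log1p(-rel_step)
    for j in range(4):
        try:
            xp = steady_state(scale_reaction(params, j + 1, 1.0 + rel_step))
            xm = steady_state(scale_reaction(params, j + 1, 1.0 - rel_step))
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise ValidationError(
                f"steady state failed under perturbation of {REACTIONS[j]}: {exc}"
            ) from exc
        c_conc[:, j] = (np.log(xp) - np.log(xm)) / dlnp
        Jp = params.k4 * (1.0 + rel_step if j == 3 else 1.0) * xp[2]
        Jm = params.k4 * (1.0 - rel_step if j == 3 else 1.0) * xm[2]
        c_flux[j] = (np.log(Jp) - np.log(Jm)) / dlnp
    return ControlCoefficients(
        c_flux=c_flux, c_conc=c_conc, reference_state=xs, reference_params=params,
    )


def k3_perturbation_report(params: CoreParameters, fold_change: float) -> pd.DataFrame:
    """Steady-state ratios (mutant / wild type) under a k3 fold increase.

    Models the hai1a mutant's elevated SphK as ``k3 → k3·fold_change``
    (forward rate only — SphK catalyses only the forward step) and reports
    the per-species steady-state ratio plus a flag marking ceramide
    depletion (ratio < 1), the sign conclusion of the control analysis.
    """
    if not fold_change >= 1:
        raise ValidationError(f"fold_change must be >= 1, got {fold_change}")
    base = steady_state(params)
    from dataclasses import replace

    pert = steady_state(replace(params, k3=params.k3 * fold_change))
    ratio = pert / base
    return pd.DataFrame(
        {
            "species": list(CORE_SPECIES),
            "wild_type": base,
            "mutant": pert,
            "ratio": ratio,
            "depleted": ratio < 1.0,
        }
    ).set_index("species")
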