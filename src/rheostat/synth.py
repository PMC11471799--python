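"""Synthetic lipidomics-style data with known ground truth.

Emulates the study design the calibration assumes: two genotype conditions
(wild-type sibling with the condition switch ON, hai1a-amorphic mutant with
it OFF), measurements at 2 and 4 dpf, four biological replicates, observed
species sphinganine, C16 ceramide and sphingosine (S1P stays latent).
Replicate values are s_i·x_i(t) plus additive Gaussian noise of per-species
standard deviation σ_i, truncated at zero (abundances are nonnegative;
truncation events are logged and are negligible at the preset σ).

The ``study_like_feedback`` preset is constructed so that its noise-free
trajectories show the qualitative mutant-vs-wild-type pattern the feedback
hypothesis explains: mutant ceramide below wild type at 2 dpf but above it
at 4 dpf, and mutant sphinganine above wild type at 4 dpf.  The no-feedback
preset (α_cer = 0) shows no such crossing.  These orderings are asserted at
preset construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import (
    DEFAULT_CONDITIONS,
    DEFAULT_OBSERVABLES,
    MEASUREMENT_COLUMNS,
    CalibrationProblem,
    make_problem,  # noqa: F401  (re-exported: problems are built from synthetic tables)
)
from .kinetics import (
    EXTENDED_SPECIES,
    ConditionSpec,
    ExtendedParameters,
    ValidationError,
    extended_system_matrices,
    propagate_linear,
)

__all__ = [
    "SyntheticDesign",
    "TruthScenario",
    "study_like_truth",
    "generate_measurements",
    "make_problem",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticDesign:
    """Study layout: conditions × times × replicates × observables."""

    conditions: tuple[ConditionSpec, ...] = DEFAULT_CONDITIONS
    times_dpf: tuple[float, ...] = (2.0, 4.0)
    n_replicates: int = 4
    observables: tuple[str, ...] = DEFAULT_OBSERVABLES

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if 2.0 not in self.times_dpf:
            raise ValidationError(
                "2 dpf must be included (initial-condition convention)"
            )


@dataclass(frozen=True)
class TruthScenario:
    """Ground truth: extended-model parameters, per-condition 2-dpf states,
    per-species scalings (measured units per model unit) and noise σ."""

    variant: str
    params: ExtendedParameters
    x0: dict[str, np.ndarray]
    scalings: dict[str, float] = field(
        default_factory=lambda: dict(sphinganine=10.0, ceramide=200.0, sphingosine=8.0)
    )
    sigmas: dict[str, float] = field(
        default_factory=lambda: dict(sphinganine=0.5, ceramide=6.0, sphingosine=0.35)
    )

    def __post_init__(self) -> None:
        if self.variant not in ("feedback", "no_feedback"):
            raise ValidationError(f"unknown variant {self.variant!r}")
        for cid, x in self.x0.items():
            if np.asarray(x).shape != (len(EXTENDED_SPECIES),) or np.any(np.asarray(x) < 0):
                raise ValidationError(f"x0[{cid!r}] must be a nonnegative 4-vector")
        for d in (self.scalings, self.sigmas):
            if any(v <= 0 for v in d.values()):
                raise ValidationError("scalings and sigmas must be positive")

    def states(self, condition: ConditionSpec, times_dpf) -> np.ndarray:
        """Noise-free model states at the given dpf times (rows × species)."""
        A, b = extended_system_matrices(self.params, condition.s_on)
        x0 = self.x0[condition.condition_id]
        return np.array(
            [x0 if t == 2.0 else propagate_linear(A, b, x0, float(t) - 2.0)
             for t in times_dpf]
        )


# Preset ground truth.  Rate constants (day⁻¹ / a.u.·day⁻¹) are set so the
# mutant relaxes appreciably but not completely over the 2-day window; the
# wild type, whose de novo input is fully repressed by the engaged feedback
# (α_cer = −1), decays only moderately.  2-dpf states encode the
# experimentally motivated starting point: mutant ceramide depleted and S1P
# elevated relative to wild type, sphinganine slightly below, sphingosine
# equal.
_PRESET_PARAMS = dict(
    k00=0.9, k01=0.5, k2f=0.45, k2r=0.3, k3=1.1, k3r=0.15, k4=1.0,
    alpha_hai1a=0.6,
)
_PRESET_X0 = {
    "wild_type": np.array([0.70, 1.10, 0.50, 0.30]),
    "mutant": np.array([0.60, 0.75, 0.50, 0.55]),
}


def study_like_truth(variant: str = "feedback") -> TruthScenario:
    """Documented preset truth scenario for the given variant.

    The feedback preset uses α_cer = −1 (the fully engaged feedback, the
    setting under which the negative-feedback simulations were run); the
    no-feedback preset sets α_cer = 0.  The feedback preset's 2→4 dpf
    mutant ceramide crossing and sphinganine excess are asserted here, as
    is the absence of the crossing without feedback.
    """
    if variant not in ("feedback", "no_feedback"):
        raise ValidationError(f"unknown variant {variant!r}")
    alpha_cer = -1.0 if variant == "feedback" else 0.0
    truth = TruthScenario(
        variant=variant,
        params=ExtendedParameters(**_PRESET_PARAMS, alpha_cer=alpha_cer),
        x0={k: v.copy() for k, v in _PRESET_X0.items()},
    )
    wt, mut = truth.x0["wild_type"], truth.x0["mutant"]
    cer = EXTENDED_SPECIES.index("ceramide")
    sa = EXTENDED_SPECIES.index("sphinganine")
    wt4 = truth.states(DEFAULT_CONDITIONS[0], [4.0])[0]
    mut4 = truth.states(DEFAULT_CONDITIONS[1], [4.0])[0]
    assert mut[cer] < wt[cer], "preset must deplete mutant ceramide at 2 dpf"
    if variant == "feedback":
        assert mut4[cer] > wt4[cer], "feedback preset must cross: mutant ceramide up at 4 dpf"
        assert mut4[sa] > wt4[sa], "feedback preset must raise mutant sphinganine at 4 dpf"
    else:
        assert mut4[cer] < wt4[cer], "no-feedback preset must not cross"
    return truth


def generate_measurements(
    truth: TruthScenario,
    design: SyntheticDesign = SyntheticDesign(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicate-level measurement table from a truth scenario.

    One row per (observable, condition, time, replicate); values are
    s_i·x_i(t) + ε with ε ~ N(0, σ_i²), truncated at zero.  Byte-identical
    output for identical (truth, design, seed).
    """
    for o in design.observables:
        if o not in truth.scalings or o not in truth.sigmas:
            raise ValidationError(f"truth lacks scaling/sigma for observable {o!r}")
    rng = np.random.default_rng(seed)
    rows = []
    n_trunc = 0
    for cond in design.conditions:
        states = truth.states(cond, design.times_dpf)
        for t_dpf, x in zip(design.times_dpf, states):
            for obs in design.observables:
                i = EXTENDED_SPECIES.index(obs)
                mu = truth.scalings[obs] * x[i]
                draws = mu + truth.sigmas[obs] * rng.standard_normal(design.n_replicates)
                n_trunc += int(np.sum(draws < 0))
                draws = np.maximum(draws, 0.0)
                for r, v in enumerate(draws):
                    rows.append((obs, cond.condition_id, float(t_dpf), r, float(v)))
    if n_trunc:
        logger.warning("truncated %d negative measurement draw(s) at 0", n_trunc)
    df = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
    df.attrs["n_truncated"] = n_trunc
    return df


def no_feedback_counterpart(truth: TruthScenario) -> TruthScenario:
    """Same rates/initials with the feedback switched off (α_cer = 0)."""
    return replace(truth, variant="no_feedback",
                   params=replace(truth.params, alpha_cer=0.0))
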