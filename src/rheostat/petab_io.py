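"""PEtab-style problem serialization and results I/O.

The on-disk layout is a strict, documented subset of the PEtab parameter
estimation format: four TSV tables bound together by a YAML file.

``conditions.tsv``    conditionId, s_on
``observables.tsv``   observableId, observableFormula, noiseFormula
                      (formula is ``<scaling> * <species>``, noise a σ id)
``parameters.tsv``    parameterId, nominalValue, lowerBound, upperBound,
                      estimate, parameterScale
``measurements.tsv``  observableId, simulationConditionId, time,
                      replicateId, measurement   (time in dpf)
``problem.yaml``      file bindings plus the model variant

Serialization is deterministic: IDs sorted, floats written with 17
significant digits (lossless for doubles), UTF-8, Unix newlines — repeated
writes are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import (
    CalibrationProblem,
    ModelComparisonReport,
    ObservableSpec,
)
from .kinetics import ConditionSpec, ValidationError

__all__ = [
    "ProblemBundle",
    "RunConfig",
    "read_problem",
    "write_problem",
    "write_report",
    "read_report",
    "write_provenance",
]

logger = logging.getLogger(__name__)

_YAML_NAME = "problem.yaml"
_TABLES = {
    "conditions": "conditions.tsv",
    "observables": "observables.tsv",
    "parameters": "parameters.tsv",
    "measurements": "measurements.tsv",
}

_REQUIRED_COLUMNS = {
    "conditions": ["conditionId", "s_on"],
    "observables": ["observableId", "observableFormula", "noiseFormula"],
    "parameters": ["parameterId", "nominalValue", "lowerBound", "upperBound",
                   "estimate", "parameterScale"],
    "measurements": ["observableId", "simulationConditionId", "time",
                     "replicateId", "measurement"],
}


@dataclass
class ProblemBundle:
    """Paths of a problem directory plus the parsed problem."""

    directory: Path
    paths: dict[str, Path]
    problem: CalibrationProblem


@dataclass(frozen=True)
class RunConfig:
    """Run settings shared by the CLI subcommands."""

    seed: int = 0
    n_starts: int = 100
    rtol: float = 1e-8
    atol: float = 1e-10
    ci_method: str = "t"
    sigma_mode: str = "profile"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ValidationError("seed must be a nonnegative integer")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValidationError("solver tolerances must be positive")
        if self.n_starts < 1:
            raise ValidationError("n_starts must be >= 1")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.__dict__, sort_keys=True).encode()
        ).hexdigest()[:12]


def _fmt(x) -> str:
    if isinstance(x, bool):
        return "1" if x else "0"
    if isinstance(x, float):
        return format(x, ".17g")
    return str(x)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    lines = ["\t".join(df.columns)]
    for row in df.itertuples(index=False):
        lines.append("\t".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def write_problem(problem: CalibrationProblem, directory) -> ProblemBundle:
    """Serialize a problem to a PEtab-style directory (deterministic)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in _TABLES.items()}

    cond = pd.DataFrame(
        sorted((c.condition_id, c.s_on) for c in problem.conditions),
        columns=["conditionId", "s_on"],
    )
    obs = pd.DataFrame(
        sorted(
            (o.observable_id, f"{o.scaling_id} * {o.species}", o.sigma_id)
            for o in problem.observables
        ),
        columns=["observableId", "observableFormula", "noiseFormula"],
    )
    par = problem.parameters.reset_index().rename(
        columns={
            "parameterId": "parameterId", "value": "nominalValue",
            "lower": "lowerBound", "upper": "upperBound", "scale": "parameterScale",
        }
    )[["parameterId", "nominalValue", "lowerBound", "upperBound", "estimate",
       "parameterScale"]].sort_values("parameterId").reset_index(drop=True)
    par["nominalValue"] = par["nominalValue"].astype(float)
    par["lowerBound"] = par["lowerBound"].astype(float)
    par["upperBound"] = par["upperBound"].astype(float)
    par["estimate"] = par["estimate"].astype(bool)
    meas = problem.measurements.rename(
        columns={
            "observable_id": "observableId", "condition_id": "simulationConditionId",
            "time_dpf": "time", "replicate": "replicateId", "value": "measurement",
        }
    )[["observableId", "simulationConditionId", "time", "replicateId", "measurement"]]
    meas = meas.sort_values(
        ["observableId", "simulationConditionId", "time", "replicateId"]
    ).reset_index(drop=True)
    meas["time"] = meas["time"].astype(float)
    meas["measurement"] = meas["measurement"].astype(float)

    _write_tsv(cond, paths["conditions"])
    _write_tsv(obs, paths["observables"])
    _write_tsv(par, paths["parameters"])
    _write_tsv(meas, paths["measurements"])

    yaml_path = directory / _YAML_NAME
    doc = {
        "format_version": 1,
        "variant": problem.variant,
        "condition_files": [_TABLES["conditions"]],
        "observable_files": [_TABLES["observables"]],
        "parameter_file": _TABLES["parameters"],
        "measurement_files": [_TABLES["measurements"]],
    }
    yaml_path.write_text(
        yaml.safe_dump(doc, sort_keys=True), encoding="utf-8", newline="\n"
    )
    paths["yaml"] = yaml_path
    return ProblemBundle(directory=directory, paths=paths, problem=problem)


def _read_tsv(path: Path, kind: str, errors: list[str]) -> pd.DataFrame | None:
    if not path.exists():
        errors.append(f"missing file: {path.name}")
        return None
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = _REQUIRED_COLUMNS[kind]
    unknown = [c for c in df.columns if c not in required]
    missing = [c for c in required if c not in df.columns]
    if unknown:
        errors.append(f"{path.name}: unknown column(s) {unknown}")
    if missing:
        errors.append(f"{path.name}: missing column(s) {missing}")
        return None
    return df


def _numeric(df: pd.DataFrame, col: str, fname: str, errors: list[str]) -> pd.Series:
    # parse via float() for exact IEEE round-trip of the 17-digit format
    values = []
    for i, raw in df[col].items():
        try:
            values.append(float(raw))
        except (TypeError, ValueError):
            errors.append(f"{fname} line {i + 2}: non-numeric {col} value {raw!r}")
            values.append(np.nan)
    return pd.Series(values, index=df.index, dtype=float)


def read_problem(directory) -> ProblemBundle:
    """Parse and fully validate a PEtab-style problem directory.

    All violations are collected and reported together, with file/line
    context, rather than failing at the first.
    """
    directory = Path(directory)
    errors: list[str] = []
    yaml_path = directory / _YAML_NAME
    if not yaml_path.exists():
        raise ValidationError(f"missing file: {_YAML_NAME} in {directory}")
    doc = yaml.safe_load(yaml_path.read_text(encoding="utf-8"))
    variant = doc.get("variant", "feedback")

    paths = {k: directory / v for k, v in _TABLES.items()}
    cond = _read_tsv(paths["conditions"], "conditions", errors)
    obs = _read_tsv(paths["observables"], "observables", errors)
    par = _read_tsv(paths["parameters"], "parameters", errors)
    meas = _read_tsv(paths["measurements"], "measurements", errors)
    if errors:
        raise ValidationError("; ".join(errors))

    conditions = []
    for i, row in cond.iterrows():
        s_on = pd.to_numeric(pd.Series([row["s_on"]]), errors="coerce")[0]
        if pd.isna(s_on) or int(s_on) not in (0, 1):
            errors.append(f"conditions.tsv line {i + 2}: s_on must be 0 or 1")
        else:
            conditions.append(ConditionSpec(row["conditionId"], int(s_on)))

    observables = []
    for i, row in obs.iterrows():
        formula = row["observableFormula"]
        parts = [p.strip() for p in str(formula).split("*")]
        if len(parts) != 2:
            errors.append(
                f"observables.tsv line {i + 2}: formula {formula!r} is not "
                "'<scaling> * <species>'"
            )
            continue
        scaling_id, species = parts
        try:
            observables.append(
                ObservableSpec(row["observableId"], species, scaling_id,
                               str(row["noiseFormula"]).strip())
            )
        except ValidationError as exc:
            errors.append(f"observables.tsv line {i + 2}: {exc}")

    par = par.assign(
        nominalValue=_numeric(par, "nominalValue", "parameters.tsv", errors),
        lowerBound=_numeric(par, "lowerBound", "parameters.tsv", errors),
        upperBound=_numeric(par, "upperBound", "parameters.tsv", errors),
    )
    bad_scale = ~par["parameterScale"].isin(["log10", "lin"])
    for i in par.index[bad_scale]:
        errors.append(
            f"parameters.tsv line {i + 2}: parameterScale must be log10 or lin"
        )
    parameters = pd.DataFrame(
        {
            "value": par["nominalValue"].to_numpy(dtype=float),
            "lower": par["lowerBound"].to_numpy(dtype=float),
            "upper": par["upperBound"].to_numpy(dtype=float),
            "estimate": par["estimate"].astype(str).isin(["1", "True", "true"]).to_numpy(),
            "scale": par["parameterScale"].to_numpy(),
        },
        index=pd.Index(par["parameterId"], name="parameterId"),
    )

    meas = meas.assign(
        time=_numeric(meas, "time", "measurements.tsv", errors),
        measurement=_numeric(meas, "measurement", "measurements.tsv", errors),
    )
    cond_ids = {c.condition_id for c in conditions}
    obs_ids = {o.observable_id for o in observables}
    for i, row in meas.iterrows():
        if row["observableId"] not in obs_ids:
            errors.append(
                f"measurements.tsv line {i + 2}: dangling observableId "
                f"{row['observableId']!r}"
            )
        if row["simulationConditionId"] not in cond_ids:
            errors.append(
                f"measurements.tsv line {i + 2}: dangling simulationConditionId "
                f"{row['simulationConditionId']!r}"
            )
    if errors:
        raise ValidationError("; ".join(errors))

    measurements = pd.DataFrame(
        {
            "observable_id": meas["observableId"],
            "condition_id": meas["simulationConditionId"],
            "time_dpf": meas["time"].astype(float),
            "replicate": pd.to_numeric(meas["replicateId"]).astype(int),
            "value": meas["measurement"].astype(float),
        }
    )
    problem = CalibrationProblem(
        variant=variant,
        conditions=tuple(conditions),
        observables=tuple(observables),
        measurements=measurements,
        parameters=parameters,
    )
    paths["yaml"] = yaml_path
    return ProblemBundle(directory=directory, paths=paths, problem=problem)


# ---------------------------------------------------------------------------
# results


def write_report(report: ModelComparisonReport, path) -> None:
    """Serialize a comparison report to JSON (deterministic key order)."""
    Path(path).write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8", newline="\n",
    )


def read_report(path) -> ModelComparisonReport:
    return ModelComparisonReport.from_dict(
        json.loads(Path(path).read_text(encoding="utf-8"))
    )


def write_provenance(directory, config: RunConfig, extra: dict | None = None) -> Path:
    """Record version, seed and config hash next to a run's outputs."""
    from . import __version__

    record = {
        "version": __version__,
        "seed": config.seed,
        "config": dict(config.__dict__),
        "config_hash": config.digest(),
    }
    if extra:
        record.update(extra)
    path = Path(directory) / "provenance.json"
    path.write_text(
        json.dumps(record, indent=2, sort_keys=True) + "\n",
        encoding="utf-8", newline="\n",
    )
    return path
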