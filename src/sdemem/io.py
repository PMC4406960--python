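"""Dataset and configuration readers/writers.

Data files are long-format CSV with columns ID, TIME, DV (one row per
observation).  Dosing and infusion schedules live in the run configuration,
not in the data file: a bolus is part of the model's initial condition and
infusions are (rate, duration, start) records, so both study designs are
expressible without a dosing-row dialect.  Run configurations are YAML (or
JSON, a YAML subset).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import PiecewiseConstantInput, get_model
from .simulate import Dataset, StudyDesign, SubjectData

__all__ = [
    "RunConfig",
    "read_dataset",
    "dataset_from_frame",
    "write_dataset",
    "write_estimates",
    "read_estimates",
    "write_study_result",
]


class DatasetFormatError(ValueError):
    """Malformed dataset file."""


def dataset_from_frame(df: pd.DataFrame, inputs=None) -> Dataset:
    """Validate and group a long-format (ID, TIME, DV) frame into a Dataset.

    Rows may arrive in any order; they are grouped by subject and sorted by
    time.  Non-numeric DV values and duplicate (ID, TIME) pairs are rejected
    with the offending row numbers.
    """
    missing = [c for c in ("ID", "TIME", "DV") if c not in df.columns]
    if missing:
        raise DatasetFormatError(
            f"dataset is missing required column(s): {', '.join(missing)}")
    bad_rows = []
    for col in ("TIME", "DV"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()].tolist()
        bad_rows.extend((int(i), col) for i in bad)
    if bad_rows:
        desc = ", ".join(f"row {i} ({c})" for i, c in bad_rows[:10])
        raise DatasetFormatError(f"non-numeric values: {desc}")
    work = df.copy()
    work["TIME"] = pd.to_numeric(work["TIME"])
    work["DV"] = pd.to_numeric(work["DV"])
    work = work.dropna(subset=["DV"])

    dup = work.duplicated(subset=["ID", "TIME"], keep=False)
    if dup.any():
        offenders = work.index[dup].tolist()[:10]
        raise DatasetFormatError(
            f"duplicate (ID, TIME) pairs at rows {offenders}")

    subjects = []
    input_map = inputs or {}
    for i, (sid, grp) in enumerate(work.groupby("ID", sort=True)):
        grp = grp.sort_values("TIME")
        u = input_map.get(sid) if isinstance(input_map, dict) else None
        if u is None and isinstance(input_map, (list, tuple)) and input_map:
            u = input_map[i] if len(input_map) > 1 else input_map[0]
        subjects.append(SubjectData(id=sid,
                                    times=grp["TIME"].to_numpy(float),
                                    y=grp["DV"].to_numpy(float)[:, None],
                                    input=u))
    return Dataset(subjects)


def read_dataset(path, inputs=None) -> Dataset:
    """Read a CSV dataset (columns ID, TIME, DV)."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        import warnings

        warnings.warn(f"dataset {path} has no data rows")
        return Dataset([])
    return dataset_from_frame(df, inputs=inputs)


def write_dataset(dataset: Dataset, path, truth_path=None):
    """Write a Dataset as CSV; optionally a companion truth file with the
    simulated random effects and individual parameters."""
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    if truth_path is not None:
        dataset.truth_frame().to_csv(Path(truth_path), index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Declarative description of a simulation/estimation run."""

    model: str = "one_compartment_abs_mm"
    model_config: dict = field(default_factory=dict)
    method: str = None
    start: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    true_values: dict = field(default_factory=dict)
    n_subjects: int = 20
    observation_times: list = None
    infusions: list = None          # [{rate, duration, start, subjects}]
    seed: int = 0
    step: float = 0.01
    n_replicates: int = 20
    gtol: float = 1e-4
    output_dir: str = "."

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.observation_times is not None and np.any(
            np.asarray(cfg.observation_times, float) < 0
        ):
            raise ValueError("observation times must be nonnegative")
        return cfg

    def population_model(self):
        return get_model(self.model, **self.model_config)

    def design(self) -> StudyDesign:
        pm = self.population_model()
        times = self.observation_times
        if times is None:
            times = np.arange(1.0, 98.0, 8.0)
        inputs = None
        if self.infusions:
            inputs = []
            for rec in self.infusions:
                n = int(rec.get("subjects", 1))
                u = PiecewiseConstantInput.infusion(
                    float(rec["rate"]), float(rec["duration"]),
                    float(rec.get("start", 0.0)))
                inputs.extend([u] * n)
            if len(inputs) != self.n_subjects:
                raise ValueError(
                    "infusion subject counts must sum to n_subjects")
        return StudyDesign(n_subjects=self.n_subjects,
                           observation_times=np.asarray(times, float),
                           seed=self.seed, step=self.step, inputs=inputs)

    def theta(self, values: dict, pm=None):
        pm = pm or self.population_model()
        base = pm.default_start.copy()
        for name, val in (values or {}).items():
            base[pm.theta_names.index(name)] = float(val)
        return base

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# estimate tables
# ---------------------------------------------------------------------------

def write_estimates(result, path, metadata=None):
    """Write an estimate table (CSV) plus a JSON metadata sidecar.

    ``result`` is a PopulationEstimate or ReplicateStudyResult; fixed
    parameters are marked and reported without an RSE (the reporting
    convention uses a dash for a pinned system-noise factor).  The pair of
    files round-trips through :func:`read_estimates`.
    """
    from .estimation import PopulationEstimate, ReplicateStudyResult

    path = Path(path)
    meta = dict(metadata or {})
    if isinstance(result, PopulationEstimate):
        df = result.summary().reset_index(names="parameter")
        meta.update(kind="population_estimate", objective=result.objective,
                    converged=bool(result.converged), method=result.method,
                    fixed=result.fixed, model=result.model_name,
                    n_iterations=result.n_iter)
    elif isinstance(result, ReplicateStudyResult):
        df = result.table().reset_index(names="parameter")
        meta.update(kind="replicate_study", n_replicates=result.n_replicates,
                    excluded=result.excluded, valid=bool(result.valid),
                    master_seed=result.master_seed, **result.config)
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    df.to_csv(path, index=False)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return path


def read_estimates(path):
    """Read back an estimate table and its metadata."""
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(".json")
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    return df, meta


def write_study_result(result, out_dir, stem="replicate_study"):
    """Write the full replicate-study output set (summary + per-replicate)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_estimates(result, out_dir / f"{stem}_summary.csv")
    result.estimates.to_csv(out_dir / f"{stem}_replicates.csv", index=False)
    return out_dir
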