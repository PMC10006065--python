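"""Reading and writing survival tables, configs and run artifacts.

Tables are comma-separated with a header row, UTF-8, "." decimal; times
are in whatever unit the study uses (the package is unit-agnostic).
Configuration is a flat YAML document so a run is reproducible from its
config file and seed alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data import DesignPair, SurvivalData
from .exceptions import ConfigError, SchemaError

__all__ = ["RunConfig", "read_survival_table", "write_survival_table",
           "train_test_split"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    ``assignment`` is mandatory when two covariate blocks are declared:
    "clinical_drift" maps the clinical block to the drift mu and the
    molecular block to the initial level y0; "clinical_level" swaps them.
    With a single undifferentiated covariate set, use
    ``clinical_columns`` only and ``assignment: shared``.
    """

    input_path: str | None = None
    time_column: str = "time"
    status_column: str = "status"
    clinical_columns: list = field(default_factory=list)
    molecular_columns: list = field(default_factory=list)
    assignment: str = "shared"
    variant: str = "cyclical"
    nu: float = 0.1
    max_mstop: int = 200
    cv_folds: int = 10
    grid_points: int = 20
    cv_repeats: int = 1
    test_fraction: float = 0.0
    test_size: int = 0
    eval_bins: int = 10
    seed: int = 0
    output_dir: str = "fhtboost_run"
    simulate: dict | None = None

    def __post_init__(self):
        if self.assignment not in ("shared", "clinical_drift", "clinical_level"):
            raise ConfigError(f"unknown assignment {self.assignment!r}")
        if self.assignment != "shared" and not (self.clinical_columns and
                                                self.molecular_columns):
            raise ConfigError("block assignment requires both clinical_columns "
                              "and molecular_columns")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def _numeric(frame: pd.DataFrame, columns, path) -> pd.DataFrame:
    sub = frame[columns]
    out = sub.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & ~sub.isna()
    if bad.any().any():
        col = bad.any()[bad.any()].index[0]
        row = int(bad[col].idxmax())
        raise SchemaError(f"{path}: non-numeric value in column {col!r}, row {row}")
    if out.isna().any().any():
        col = out.isna().any()
        col = col[col].index[0]
        raise SchemaError(f"{path}: missing values in column {col!r}")
    return out


def read_survival_table(path, config: RunConfig):
    """Parse a delimited survival table into ``(SurvivalData, DesignPair)``.

    Covariate blocks are assigned to the model parameters according to
    ``config.assignment``; with "shared", all declared covariate columns
    (or every non-outcome column if none are declared) feed both
    parameters.
    """
    frame = pd.read_csv(path)
    for col in (config.time_column, config.status_column):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if frame.columns.duplicated().any():
        dupes = frame.columns[frame.columns.duplicated()].tolist()
        raise SchemaError(f"{path}: duplicate column(s) {dupes}")

    outcome = _numeric(frame, [config.time_column, config.status_column], path)
    time = outcome[config.time_column].to_numpy(float)
    status = outcome[config.status_column].to_numpy(float)
    if np.any((status != 0) & (status != 1)):
        bad = int(np.flatnonzero((status != 0) & (status != 1))[0])
        raise SchemaError(f"{path}: status must be 0/1 (row {bad})")
    if np.any(time <= 0):
        bad = int(np.flatnonzero(time <= 0)[0])
        raise SchemaError(f"{path}: nonpositive time at row {bad}")
    data = SurvivalData(time, status.astype(int))

    declared = list(config.clinical_columns) + list(config.molecular_columns)
    if declared:
        missing = [c for c in declared if c not in frame.columns]
        if missing:
            raise SchemaError(f"{path}: declared covariate(s) not found: {missing}")
        covars = declared
    else:
        covars = [c for c in frame.columns
                  if c not in (config.time_column, config.status_column)]
    X = _numeric(frame, covars, path) if covars else pd.DataFrame(index=frame.index)

    if config.assignment == "clinical_drift":
        designs = DesignPair(X[config.clinical_columns], X[config.molecular_columns])
    elif config.assignment == "clinical_level":
        designs = DesignPair(X[config.molecular_columns], X[config.clinical_columns])
    else:
        designs = DesignPair(X[covars], X[covars])
    return data, designs


def write_survival_table(path, data: SurvivalData, designs: DesignPair,
                         config: RunConfig | None = None) -> None:
    """Inverse of :func:`read_survival_table` (shared-assignment layout
    writes each covariate column once even if used by both parameters)."""
    time_col = config.time_column if config else "time"
    status_col = config.status_column if config else "status"
    frame = pd.DataFrame({time_col: data.time, status_col: data.event})
    seen = {}
    for name, col in zip(designs.mu_names, designs.X_mu.T):
        seen[name] = col
    for name, col in zip(designs.y0_names, designs.X_y0.T):
        seen.setdefault(name, col)
    for name, col in seen.items():
        frame[name] = col
    frame.to_csv(path, index=False)


def train_test_split(n: int, seed: int, *, test_size: int = 0,
                     test_fraction: float = 0.0):
    """Seeded index split. Give either an absolute test size (e.g. 95 of
    295) or a fraction (e.g. 1/3); returns (train_idx, test_idx)."""
    if (test_size > 0) == (test_fraction > 0):
        raise ConfigError("specify exactly one of test_size, test_fraction")
    k = test_size if test_size > 0 else int(round(n * test_fraction))
    if not 0 < k < n:
        raise ConfigError("test set must be non-empty and smaller than n")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[k:]), np.sort(perm[:k])
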