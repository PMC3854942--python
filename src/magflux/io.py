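"""Readers, writers and configuration for every pipeline artifact.

Trace tables are long-format UTF-8 delimited text (comma by default,
tab accepted; the dialect is sniffed from the header line).  Schedules,
run configurations, manifests and results are YAML with a mandatory
``schema_version`` field and strict (unknown-key-rejecting) schemas.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import TRACE_COLUMNS
from .errors import ConfigError, DataError, ScheduleError
from .presets import PLATEAU_K, TITRATION_LEVELS, V0_WINDOW_S
from .protocols import BufferSegment, Ionophore, ProtocolSchedule

logger = logging.getLogger("magflux")

SCHEMA_VERSION = 1

#: condition labels with defined semantics; others are accepted with a warning
KNOWN_CONDITIONS = {"WT", "mock", "S200Y", "L324P"}

_KEY_COLUMNS = ["experiment_id", "cell_id", "probe", "time_s", "channel"]


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_traces(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a tidy trace table (CSV or TSV)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"trace table not found: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path))
    return validate_traces(df, source=str(path))


def validate_traces(df: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{source}: missing column(s) {', '.join(missing)}")
    bad_time = df.index[df["time_s"] < 0]
    if len(bad_time):
        raise DataError(f"{source}: negative time_s at row {bad_time[0]}")
    bad_value = df.index[~(df["value"] > 0)]
    if len(bad_value):
        raise DataError(f"{source}: nonpositive value at row {bad_value[0]} "
                        f"(field 'value')")
    bad_channel = df.index[~df["channel"].isin(["F", "F1", "F2"])]
    if len(bad_channel):
        raise DataError(f"{source}: unknown channel at row {bad_channel[0]}")
    dup = df.duplicated(subset=_KEY_COLUMNS)
    if dup.any():
        raise DataError(
            f"{source}: duplicate (experiment_id, cell_id, probe, time_s, "
            f"channel) key at row {df.index[dup][0]}"
        )
    # per cell+probe, the channel set must be consistent across time
    sets = df.groupby(["experiment_id", "cell_id", "probe"])["channel"].agg(
        lambda s: frozenset(s)
    )
    if not sets.map(lambda s: s in ({"F"}, {"F1", "F2"},
                                    frozenset({"F"}), frozenset({"F1", "F2"}))).all():
        bad = sets[~sets.isin([frozenset({"F"}), frozenset({"F1", "F2"})])]
        raise DataError(f"{source}: inconsistent channel set for {bad.index[0]}")
    unknown = set(df["condition"].unique()) - KNOWN_CONDITIONS
    if unknown:
        logger.warning("free-form condition label(s): %s", sorted(unknown))
    return df


def write_traces(df: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a validated trace table; ``.tsv`` extension selects tabs.

    Rows are sorted by (experiment_id, cell_id, time_s, channel) and
    values carry 12 significant digits so a write/read round trip is
    lossless.
    """
    path = Path(path)
    df = validate_traces(df[TRACE_COLUMNS].copy())
    df = df.sort_values(["experiment_id", "cell_id", "probe", "time_s", "channel"],
                        kind="mergesort").reset_index(drop=True)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")
    return path


# ---------------------------------------------------------------------------
# schedules

def write_schedule(schedule: ProtocolSchedule, path: Union[str, Path]) -> Path:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": schedule.name,
        "segments": [
            {"t_start": s.t_start, "t_end": s.t_end, "mg_out": s.mg_out,
             "na_out": s.na_out, "nmdg_out": s.nmdg_out, "cohex_mm": s.cohex_mm,
             "ionophore": s.ionophore.value}
            for s in schedule.segments
        ],
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    return path


def read_schedule(path: Union[str, Path]) -> ProtocolSchedule:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"schedule file not found: {path}")
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(doc, dict) or "segments" not in doc:
        raise ScheduleError(f"{path}: not a schedule document")
    segs = []
    for i, raw in enumerate(doc["segments"]):
        extra = set(raw) - {"t_start", "t_end", "mg_out", "na_out", "nmdg_out",
                            "cohex_mm", "ionophore"}
        if extra:
            raise ScheduleError(f"{path}: unknown segment key(s) {sorted(extra)} "
                                f"in segment {i}")
        kw = dict(raw)
        if "ionophore" in kw:
            kw["ionophore"] = Ionophore(kw["ionophore"])
        segs.append(BufferSegment(**kw))
    return ProtocolSchedule(tuple(segs), name=doc.get("name", ""))


# ---------------------------------------------------------------------------
# dataset QC

@dataclass
class QCReport:
    """Validation outcome for a dataset against its schedule."""

    warnings: list[str] = field(default_factory=list)
    n_cells: int = 0
    n_cells_usable: int = 0

    @property
    def ok(self) -> bool:
        return not self.warnings

    @property
    def fatal(self) -> bool:
        return self.n_cells_usable == 0


def validate_dataset(df: pd.DataFrame, schedule: ProtocolSchedule) -> QCReport:
    """Check trace coverage and sampling against a schedule.

    Per-cell problems (gaps, nonuniform sampling, samples outside the
    schedule span) are warnings; the report is fatal only when no cell
    is usable.  Overlapping schedules raise at construction, before this
    check.
    """
    report = QCReport()
    groups = df.groupby(["experiment_id", "cell_id", "probe"])
    report.n_cells = len(groups)
    for key, grp in groups:
        label = "/".join(str(k) for k in key)
        times = np.sort(grp["time_s"].unique())
        usable = True
        steps = np.diff(times)
        if len(steps) and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-6):
            report.warnings.append(f"{label}: nonuniform sampling")
            usable = False
        if times.min() < schedule.t_start - 1e-9 or times.max() > schedule.t_end + 1e-9:
            report.warnings.append(f"{label}: samples outside schedule coverage")
            usable = False
        if usable:
            report.n_cells_usable += 1
    return report


# ---------------------------------------------------------------------------
# run configuration

_PRESETS = ("stoichiometry", "titration", "phases", "extrusion", "loading")


@dataclass
class RunConfig:
    """Resolved configuration of one simulate/analyze run."""

    seed: int
    preset: str = "stoichiometry"
    conditions: tuple[str, ...] = ("WT", "mock")
    n_experiments: Optional[int] = None   # preset-dependent default
    n_cells: int = 10
    noise_sigma: Optional[float] = None   # None -> observation-model default
    jitter_cv: Optional[float] = None
    gain_cv: Optional[float] = None
    window_s: float = V0_WINDOW_S
    plateau_k: int = PLATEAU_K
    titration_levels: tuple[float, ...] = TITRATION_LEVELS
    aggregation: str = "ratio_of_means"
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.preset not in _PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}; "
                              f"expected one of {_PRESETS}")
        if self.aggregation not in ("ratio_of_means", "mean_of_ratios"):
            raise ConfigError("aggregation must be ratio_of_means or mean_of_ratios")
        if self.seed is None:
            raise ConfigError("seed is mandatory for any stochastic step")
        self.conditions = tuple(self.conditions)
        self.titration_levels = tuple(float(x) for x in self.titration_levels)

    def effective(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["conditions"] = list(self.conditions)
        doc["titration_levels"] = list(self.titration_levels)
        doc["software_version"] = __version__
        return doc


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a YAML run configuration with a strict schema.

    Unknown keys are rejected with the offending name; missing keys fall
    back to documented defaults; ``seed`` is mandatory.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    doc = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    doc.pop("schema_version", None)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config key {sorted(unknown)[0]!r}")
    if "seed" not in doc:
        raise ConfigError(f"{path}: 'seed' is required")
    return RunConfig(**doc)


# ---------------------------------------------------------------------------
# generic YAML documents (manifests, results)

def write_yaml(doc: dict, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_plain(doc), sort_keys=False), encoding="utf-8")
    return path


def read_yaml(path: Union[str, Path]) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    return yaml.safe_load(path.read_text(encoding="utf-8"))


def _plain(obj):
    """Recursively convert numpy scalars/arrays and enums to plain python."""
    if isinstance(obj, dict):
        return {_plain(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, enum.Enum):
        return obj.value
    return obj
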