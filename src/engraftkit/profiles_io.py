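"""Abundance-table and cohort-metadata I/O, validation, and time-window vocabulary.

Abundance tables are plain :class:`pandas.DataFrame` objects with samples as
rows and species as columns, holding relative abundances (unitless fractions).
Metadata tables map each sample to a subject, a role (donor or recipient), the
assigned donor, the study week, and the treatment arm.

The trial layout this package targets delivers four weekly FMT infusions
starting at week 3; recipient samples at weeks 0 and 3 (the week-3 sample is
taken before the first infusion) are pre-FMT, and engraftment is assessed in
an *acute* window (weeks 4-7, one week after each infusion), a *durable*
window (weeks 8-14, two or more weeks after the last infusion), and the
*overall* window spanning both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: Detection limit used throughout: species below 0.1% relative abundance are
#: treated as absent.
DEFAULT_TAU = 0.001

#: First post-FMT study week; samples strictly earlier are the pre-FMT baseline.
FIRST_POST_FMT_WEEK = 4

REQUIRED_METADATA_COLUMNS = ("sample_id", "subject_id", "role", "donor_id", "week", "arm")

_SEPARATORS = {"tsv": "\t", "csv": ","}


@dataclass(frozen=True)
class WindowSpec:
    """A named inclusive range of study weeks."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"window {self.name!r}: end {self.end} < start {self.start}")

    def contains(self, week: int) -> bool:
        return self.start <= week <= self.end


def default_windows() -> list[WindowSpec]:
    """Acute (weeks 4-7), durable (weeks 8-14) and overall (weeks 4-14) windows."""
    return [WindowSpec("acute", 4, 7), WindowSpec("durable", 8, 14), WindowSpec("overall", 4, 14)]


@dataclass(frozen=True)
class ThresholdConfig:
    """Detection-limit configuration.

    tau
        Relative-abundance detection limit; entries below it are zeroed.
    renormalize
        If True, rows are re-closed to sum 1 after thresholding.  Off by
        default: sub-threshold mass is discarded, so row sums report the
        retained cumulative abundance per sample.
    """

    tau: float = DEFAULT_TAU
    renormalize: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau < 1.0:
            raise ValueError(f"tau must be in [0, 1), got {self.tau}")


def read_abundance_table(
    path: str | Path,
    dialect: str = "tsv",
    species_as_rows: bool = False,
) -> pd.DataFrame:
    """Read a wide-format abundance table (samples x species).

    The first column holds sample identifiers (or species identifiers when
    ``species_as_rows``); all remaining cells must parse as nonnegative reals.
    Duplicate sample or species identifiers are rejected.
    """
    sep = _separator(dialect)
    with open(path) as fh:  # pandas mangles duplicate header names; check the raw header
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dups = sorted({h for h in header if header.count(h) > 1})
    if dups:
        kind = "sample" if species_as_rows else "species"
        raise ValueError(f"{path}: duplicated {kind} id(s) {dups}")
    table = pd.read_csv(path, sep=sep, index_col=0)
    if species_as_rows:
        table = table.T
    return validate_abundance_table(table, source=str(path))


def write_abundance_table(table: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    table.to_csv(path, sep=_separator(dialect), index_label="sample_id")


def validate_abundance_table(table: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Check identifiers are unique and values are nonnegative finite reals."""
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"{source}: duplicated sample id(s) {dups}")
    if table.columns.has_duplicates:
        dups = table.columns[table.columns.duplicated()].unique().tolist()
        raise ValueError(f"{source}: duplicated species id(s) {dups}")
    try:
        values = table.astype(float)
    except (TypeError, ValueError) as exc:
        bad = _first_non_numeric(table)
        raise ValueError(f"{source}: malformed numeric cell at {bad}") from exc
    if not np.isfinite(values.to_numpy()).all():
        bad = _first_bad(values, lambda a: ~np.isfinite(a))
        raise ValueError(f"{source}: non-finite value at {bad}")
    if (values.to_numpy() < 0).any():
        bad = _first_bad(values, lambda a: a < 0)
        raise ValueError(f"{source}: negative abundance at {bad}")
    return values


def _first_non_numeric(table: pd.DataFrame) -> tuple:
    for col in table.columns:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            return (table.index[bad.to_numpy()][0], col)
    return ("?", "?")


def _first_bad(values: pd.DataFrame, predicate) -> tuple:
    mask = predicate(values.to_numpy())
    i, j = np.argwhere(mask)[0]
    return (values.index[i], values.columns[j])


def to_relative(table: pd.DataFrame) -> pd.DataFrame:
    """Close each row to sum 1, preserving proportions.

    Raises on all-zero rows, naming the offending sample.
    """
    sums = table.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        raise ValueError(f"cannot normalize all-zero sample(s): {table.index[zero].tolist()}")
    return table.div(sums, axis=0)


def apply_detection_threshold(table: pd.DataFrame, cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Zero out entries below the detection limit ``cfg.tau``.

    Entries at or above tau are unchanged unless ``cfg.renormalize`` re-closes
    the rows.  With renormalization off, ``table.sum(axis=1)`` of the result is
    the retained cumulative abundance per sample (1 minus the discarded mass).
    """
    cfg = cfg or ThresholdConfig()
    out = table.where(table >= cfg.tau, 0.0)
    if cfg.renormalize:
        out = to_relative(out)
    return out


def retained_fraction(thresholded: pd.DataFrame) -> pd.Series:
    """Per-sample cumulative abundance retained after thresholding."""
    return thresholded.sum(axis=1)


def assign_window(week: int, windows: Sequence[WindowSpec] | None = None) -> set[str]:
    """Names of every window whose inclusive week range contains ``week``."""
    windows = default_windows() if windows is None else windows
    return {w.name for w in windows if w.contains(week)}


def read_metadata(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read the sample-metadata table and check its required columns."""
    meta = pd.read_csv(path, sep=_separator(dialect), dtype={"donor_id": "string"})
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing required column(s) {missing}")
    meta["week"] = meta["week"].astype(int)
    return meta.set_index("sample_id", drop=False)


def validate_cohort(
    profiles: pd.DataFrame,
    metadata: pd.DataFrame,
    first_post_fmt_week: int = FIRST_POST_FMT_WEEK,
) -> None:
    """Cross-check profiles against metadata and enforce cohort invariants.

    Every profiled sample must be described in the metadata; every recipient
    needs at least one pre-FMT sample and a donor with at least one sample;
    weeks must be unique per subject.
    """
    unknown = profiles.index.difference(metadata.index)
    if len(unknown):
        raise ValueError(f"samples missing from metadata: {unknown.tolist()}")
    bad_roles = set(metadata["role"]) - {"donor", "recipient"}
    if bad_roles:
        raise ValueError(f"unknown role value(s): {sorted(bad_roles)}")
    dup = metadata.groupby("subject_id")["week"].apply(lambda w: w.duplicated().any())
    if dup.any():
        raise ValueError(f"duplicate weeks for subject(s): {dup.index[dup].tolist()}")
    donors_with_samples = set(metadata.loc[metadata["role"] == "donor", "donor_id"])
    recipients = metadata[metadata["role"] == "recipient"]
    for subject, rows in recipients.groupby("subject_id"):
        if not (rows["week"] < first_post_fmt_week).any():
            raise ValueError(f"recipient {subject} has no pre-FMT sample")
        donor_ids = set(rows["donor_id"].dropna())
        if len(donor_ids) != 1:
            raise ValueError(f"recipient {subject} must have exactly one donor, got {sorted(donor_ids)}")
        (donor_id,) = donor_ids
        if donor_id not in donors_with_samples:
            raise ValueError(f"recipient {subject}: donor {donor_id} has no samples")


@dataclass
class AnalysisConfig:
    """Bundle of thresholding and window settings, loadable from YAML."""

    tau: float = DEFAULT_TAU
    renormalize: bool = False
    windows: list[WindowSpec] = field(default_factory=default_windows)
    min_core_samples: int = 6

    @property
    def threshold(self) -> ThresholdConfig:
        return ThresholdConfig(tau=self.tau, renormalize=self.renormalize)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file.

    Recognized keys: ``tau``, ``renormalize``, ``min_core_samples`` and
    ``windows`` (mapping of name to [start, end]).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = AnalysisConfig()
    if "tau" in raw:
        cfg.tau = float(raw["tau"])
    if "renormalize" in raw:
        cfg.renormalize = bool(raw["renormalize"])
    if "min_core_samples" in raw:
        cfg.min_core_samples = int(raw["min_core_samples"])
    if "windows" in raw:
        cfg.windows = [WindowSpec(name, int(lo), int(hi)) for name, (lo, hi) in raw["windows"].items()]
    ThresholdConfig(tau=cfg.tau)  # re-validate
    return cfg


def _separator(dialect: str) -> str:
    try:
        return _SEPARATORS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'") from None
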