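"""Domain model for hearing-aid datalog snapshots.

A *snapshot* is one row of a manufacturer-style datalog export: the state of a
single device as recorded at one fitting visit.  Each snapshot carries the
audiogram entered into the fitting software (8 frequencies, dB HL, missing
values allowed), the device's logged acoustic-environment statistics (a
12-bin histogram of time proportions over input-SPL ranges, acoustic-class
time proportions, environmental gain reductions, fraction of time in
directional mode, mean input SPL), the device style, and bookkeeping fields
(device serial, global session sequence number, days since the last visit).

This module defines the canonical column schema, light-weight record types,
delimited-text readers/writers, and the audiogram missing-value pattern
tabulation.  Missing values are represented as NaN in numeric columns and as
NaN/empty in string columns; on disk a missing value is an empty cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("aidlog")

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class SchemaError(ValueError):
    """A file or frame does not carry the mandatory datalog columns."""


class IntegrityError(ValueError):
    """A dataset violates a structural invariant (e.g. duplicate keys)."""


class ConfigError(ValueError):
    """An infeasible or inconsistent configuration."""


class DegenerateDataError(ValueError):
    """Input data carry no usable variation for the requested operation."""


# ---------------------------------------------------------------------------
# Canonical schema
# ---------------------------------------------------------------------------

#: The fixed audiometric frequency panel (Hz), ascending.  This is the only
#: panel supported; it matches the standard 8-frequency clinical audiogram.
AUDIOGRAM_FREQUENCIES: tuple[int, ...] = (250, 500, 1000, 2000, 3000, 4000, 6000, 8000)

AUDIOGRAM_COLUMNS: tuple[str, ...] = tuple(f"ac{f}" for f in AUDIOGRAM_FREQUENCIES)

#: Labels of the 12 ordered input-SPL bins: "<40 dB SPL", then 5-dB ranges,
#: up to ">90 dB SPL".
SPL_BIN_LABELS: tuple[str, ...] = (
    "lt40",
    "40_45",
    "45_50",
    "50_55",
    "55_60",
    "60_65",
    "65_70",
    "70_75",
    "75_80",
    "80_85",
    "85_90",
    "gt90",
)

SPL_COLUMNS: tuple[str, ...] = tuple(f"spl_{b}" for b in SPL_BIN_LABELS)

#: Representative level (dB SPL) of each bin: midpoints for the closed 5-dB
#: bins, and 2.5 dB beyond the edge for the two open-ended bins, mirroring
#: the closed bins' midpoints.
SPL_BIN_REPRESENTATIVES: np.ndarray = np.array(
    [37.5, 42.5, 47.5, 52.5, 57.5, 62.5, 67.5, 72.5, 77.5, 82.5, 87.5, 92.5]
)

ACOUSTIC_CLASSES: tuple[str, ...] = ("quiet", "noise", "speech")
ACOUSTIC_COLUMNS: tuple[str, ...] = tuple(f"prop_{c}" for c in ACOUSTIC_CLASSES)

#: The closed set of device styles.  CIC, HalfShell, ITE and ITC are
#: custom-molded in-ear styles; BTEa and BTEb are behind-the-ear variants.
STYLES: tuple[str, ...] = ("CIC", "HalfShell", "ITE", "ITC", "BTEa", "BTEb")
CUSTOM_STYLES: tuple[str, ...] = ("CIC", "HalfShell", "ITE", "ITC")
BTE_STYLES: tuple[str, ...] = ("BTEa", "BTEb")

#: Canonical column order of a datalog file.
COLUMNS: tuple[str, ...] = (
    ("device_id", "session_seq", "days_since_last_visit", "style")
    + AUDIOGRAM_COLUMNS
    + SPL_COLUMNS
    + ACOUSTIC_COLUMNS
    + (
        "gain_reduction_noise",
        "gain_reduction_quiet",
        "fraction_directional",
        "mean_input_spl",
    )
)

_INT_COLUMNS = ("session_seq", "days_since_last_visit")
_STR_COLUMNS = ("device_id", "style")
_FLOAT_COLUMNS = tuple(c for c in COLUMNS if c not in _INT_COLUMNS + _STR_COLUMNS)

#: Quantization slack on proportion sums: half an ULP at two significant
#: figures (0.005) per bin.
SPL_SUM_SLACK = 0.06  # 12 bins
ACOUSTIC_SUM_SLACK = 0.015  # 3 bins


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Audiogram:
    """Hearing thresholds (dB HL) on the fixed 8-frequency panel.

    ``thresholds`` is ordered as :data:`AUDIOGRAM_FREQUENCIES`; a missing
    entry is NaN.  Present values must lie in [-10, 120] dB HL.
    """

    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(AUDIOGRAM_FREQUENCIES):
            raise ValueError("audiogram must have exactly 8 thresholds")
        vals = np.asarray(self.thresholds, dtype=float)
        present = vals[~np.isnan(vals)]
        if present.size and (present.min() < -10 or present.max() > 120):
            raise ValueError("audiogram thresholds must lie in [-10, 120] dB HL")

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.thresholds, dtype=float)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def __getitem__(self, frequency: int) -> float:
        return self.thresholds[AUDIOGRAM_FREQUENCIES.index(frequency)]


@dataclass(frozen=True)
class InputSPLHistogram:
    """Proportions of time spent in each of the 12 ordered input-SPL bins.

    Each proportion lies in [0, 1]; the sum may fall short of 1 for lightly
    used devices (the datalog stores values to two significant figures) and
    may exceed 1 by at most the quantization slack.
    """

    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.proportions) != len(SPL_BIN_LABELS):
            raise ValueError("input-SPL histogram must have exactly 12 bins")
        vals = np.asarray(self.proportions, dtype=float)
        present = vals[~np.isnan(vals)]
        if present.size and (present.min() < 0 or present.max() > 1):
            raise ValueError("proportions must lie in [0, 1]")
        if present.size == vals.size and vals.sum() > 1 + SPL_SUM_SLACK:
            raise ValueError("proportion sum exceeds 1 + quantization slack")

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.proportions, dtype=float)


@dataclass(frozen=True)
class DeviceSnapshot:
    """One device-at-one-visit record with all logged modalities."""

    device_id: str
    session_seq: int
    days_since_last_visit: int | None
    style: str | None
    audiogram: Audiogram
    input_spl: InputSPLHistogram
    acoustic_class_props: tuple[float, float, float]
    gain_reduction_noise: float
    gain_reduction_quiet: float
    fraction_directional: float
    mean_input_spl: float

    def __post_init__(self) -> None:
        if self.session_seq <= 0:
            raise ValueError("session_seq must be a positive integer")
        if self.style is not None and self.style not in STYLES:
            raise ValueError(f"unknown device style {self.style!r}")
        if self.days_since_last_visit is not None and self.days_since_last_visit < 0:
            raise ValueError("days_since_last_visit must be non-negative")


@dataclass
class Dataset:
    """An ordered collection of device snapshots, stored as a DataFrame.

    The frame uses the canonical :data:`COLUMNS`; integer columns use
    pandas' nullable ``Int64`` dtype so that missing entries round-trip as
    empty cells.  ``(device_id, session_seq)`` pairs are unique.
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"dataset frame lacks mandatory columns: {missing}")
        self.frame = self.frame.loc[:, list(COLUMNS)]
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_snapshots(
        cls, snapshots: Iterable[DeviceSnapshot], provenance: str = ""
    ) -> "Dataset":
        rows = []
        for s in snapshots:
            row: dict[str, object] = {
                "device_id": s.device_id,
                "session_seq": s.session_seq,
                "days_since_last_visit": s.days_since_last_visit,
                "style": s.style,
                "gain_reduction_noise": s.gain_reduction_noise,
                "gain_reduction_quiet": s.gain_reduction_quiet,
                "fraction_directional": s.fraction_directional,
                "mean_input_spl": s.mean_input_spl,
            }
            row.update(zip(AUDIOGRAM_COLUMNS, s.audiogram.thresholds))
            row.update(zip(SPL_COLUMNS, s.input_spl.proportions))
            row.update(zip(ACOUSTIC_COLUMNS, s.acoustic_class_props))
            rows.append(row)
        frame = pd.DataFrame(rows, columns=list(COLUMNS))
        frame = _coerce_dtypes(frame)
        return cls(frame, provenance=provenance)

    def to_snapshots(self) -> list[DeviceSnapshot]:
        out = []
        for _, r in self.frame.iterrows():
            days = r["days_since_last_visit"]
            out.append(
                DeviceSnapshot(
                    device_id=str(r["device_id"]),
                    session_seq=int(r["session_seq"]),
                    days_since_last_visit=None if pd.isna(days) else int(days),
                    style=None if pd.isna(r["style"]) else str(r["style"]),
                    audiogram=Audiogram(tuple(float(r[c]) for c in AUDIOGRAM_COLUMNS)),
                    input_spl=InputSPLHistogram(
                        tuple(float(r[c]) for c in SPL_COLUMNS)
                    ),
                    acoustic_class_props=tuple(
                        float(r[c]) for c in ACOUSTIC_COLUMNS
                    ),
                    gain_reduction_noise=float(r["gain_reduction_noise"]),
                    gain_reduction_quiet=float(r["gain_reduction_quiet"]),
                    fraction_directional=float(r["fraction_directional"]),
                    mean_input_spl=float(r["mean_input_spl"]),
                )
            )
        return out

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        f = self.frame
        if f["device_id"].isna().any():
            raise IntegrityError("device_id may not be missing")
        if f["session_seq"].isna().any():
            raise IntegrityError("session_seq may not be missing")
        if f.duplicated(subset=["device_id", "session_seq"]).any():
            raise IntegrityError("duplicate (device_id, session_seq) pairs")
        styles = f["style"].dropna()
        bad = set(styles.unique()) - set(STYLES)
        if bad:
            raise IntegrityError(f"unknown device styles: {sorted(bad)}")
        aud = f[list(AUDIOGRAM_COLUMNS)].to_numpy(dtype=float)
        present = aud[~np.isnan(aud)]
        if present.size and (present.min() < -10 or present.max() > 120):
            raise IntegrityError("audiogram thresholds outside [-10, 120] dB HL")
        for cols, slack, name in (
            (SPL_COLUMNS, SPL_SUM_SLACK, "input-SPL"),
            (ACOUSTIC_COLUMNS, ACOUSTIC_SUM_SLACK, "acoustic-class"),
        ):
            props = f[list(cols)].to_numpy(dtype=float)
            pv = props[~np.isnan(props)]
            if pv.size and (pv.min() < -1e-12 or pv.max() > 1 + 1e-12):
                raise IntegrityError(f"{name} proportions outside [0, 1]")
            sums = np.nansum(props, axis=1)
            if (sums > 1 + slack + 1e-12).any():
                raise IntegrityError(f"{name} proportion sum exceeds 1 + slack")

    # -- conveniences ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def missing_masks(self) -> pd.DataFrame:
        """Per-column boolean masks marking missing entries."""
        return self.frame.isna()

    def subset(self, mask: np.ndarray | pd.Series, provenance: str = "") -> "Dataset":
        """Row subset preserving order; no mutation of retained rows."""
        sub = self.frame.loc[np.asarray(mask, dtype=bool)].copy()
        return Dataset(sub.reset_index(drop=True), provenance or self.provenance)

    def equals(self, other: "Dataset", rtol: float = 1e-9, atol: float = 1e-9) -> bool:
        """Field-by-field equality with NaN == NaN and float tolerance."""
        a, b = self.frame, other.frame
        if len(a) != len(b):
            return False
        for c in _STR_COLUMNS:
            ca, cb = a[c].astype(object), b[c].astype(object)
            if not ((ca.isna() & cb.isna()) | (ca == cb)).all():
                return False
        for c in _INT_COLUMNS + _FLOAT_COLUMNS:
            va = a[c].to_numpy(dtype=float)
            vb = b[c].to_numpy(dtype=float)
            if not np.allclose(va, vb, rtol=rtol, atol=atol, equal_nan=True):
                return False
        return True


def _coerce_dtypes(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    for c in _INT_COLUMNS:
        frame[c] = pd.array(
            pd.to_numeric(frame[c], errors="raise"), dtype="Int64"
        )
    for c in _FLOAT_COLUMNS:
        frame[c] = pd.to_numeric(frame[c], errors="raise").astype(float)
    for c in _STR_COLUMNS:
        frame[c] = frame[c].astype(object).where(~pd.isna(frame[c]), np.nan)
    return frame


# ---------------------------------------------------------------------------
# Delimited-text IO
# ---------------------------------------------------------------------------


def read_snapshots(path, dialect: Mapping | None = None) -> Dataset:
    """Read a delimited-text datalog file into a :class:`Dataset`.

    Parameters
    ----------
    path
        CSV file with a header row.  Empty cells denote missing values.
    dialect
        Optional mapping with keys ``"delimiter"`` (default ``","``) and
        ``"column_map"`` (file-column -> canonical-column renames), allowing
        exports with non-canonical headers to be read.

    Rows containing non-empty but unparseable numeric cells are rejected and
    counted in the log.  Missing mandatory columns raise :class:`SchemaError`;
    duplicate ``(device_id, session_seq)`` pairs raise :class:`IntegrityError`.
    """
    dialect = dict(dialect or {})
    sep = dialect.get("delimiter", ",")
    column_map = dict(dialect.get("column_map", {}))

    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns=column_map)
    missing_cols = [c for c in COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {missing_cols}")
    raw = raw.loc[:, list(COLUMNS)]
    raw = raw.apply(lambda s: s.str.strip())

    numeric_cols = list(_INT_COLUMNS + _FLOAT_COLUMNS)
    parsed = {}
    bad = np.zeros(len(raw), dtype=bool)
    for c in numeric_cols:
        col = raw[c].replace("", np.nan)
        num = pd.to_numeric(col, errors="coerce")
        bad |= num.isna().to_numpy() & col.notna().to_numpy()
        parsed[c] = num
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("read_snapshots: rejected %d rows with unparseable numerics", n_bad)

    frame = pd.DataFrame({c: raw[c].replace("", np.nan) for c in _STR_COLUMNS})
    for c in numeric_cols:
        frame[c] = parsed[c]
    frame = frame.loc[~bad, :]
    frame = _coerce_dtypes(frame.reindex(columns=list(COLUMNS)))
    return Dataset(frame.reset_index(drop=True), provenance=str(path))


def write_snapshots(dataset: Dataset, path) -> object:
    """Write a :class:`Dataset` as delimited text; missing values as empty cells.

    Returns the path written.  Column order is the canonical order, so
    ``read_snapshots(write_snapshots(d, p))`` reproduces ``d`` field by field.
    """
    dataset.frame.to_csv(path, index=False, na_rep="")
    return path


# ---------------------------------------------------------------------------
# Missing-value pattern tabulation
# ---------------------------------------------------------------------------


def missing_pattern_table(dataset: Dataset) -> pd.DataFrame:
    """Tabulate audiogram missing-value patterns, ranked by frequency.

    Each record's pattern is the 8-bit mask of which audiogram frequencies
    are missing.  Returns a DataFrame with columns ``pattern`` (one character
    per frequency, ``x`` = missing, ``-`` = present), ``missing_frequencies``
    (tuple of Hz), ``count`` and ``fraction``, sorted by descending count
    (ties broken by pattern string).  Fractions sum to 1 and counts sum to
    the dataset size.
    """
    if len(dataset) == 0:
        raise ValueError("missing_pattern_table requires a non-empty dataset")
    aud = dataset.frame[list(AUDIOGRAM_COLUMNS)].to_numpy(dtype=float)
    miss = np.isnan(aud)
    patterns = ["".join("x" if m else "-" for m in row) for row in miss]
    counts = pd.Series(patterns).value_counts()
    table = pd.DataFrame(
        {
            "pattern": counts.index,
            "missing_frequencies": [
                tuple(
                    f
                    for f, ch in zip(AUDIOGRAM_FREQUENCIES, p)
                    if ch == "x"
                )
                for p in counts.index
            ],
            "count": counts.to_numpy(),
        }
    )
    table = table.sort_values(
        ["count", "pattern"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["fraction"] = table["count"] / len(dataset)
    return table
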