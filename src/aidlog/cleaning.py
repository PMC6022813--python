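"""Record-selection (cleaning) rules for datalog datasets.

Primary rules, applied to every analysis:

(i)  drop records with 7 or fewer days since the last visit — too little
     usage for the logged proportions to represent typical listening;
(ii) drop records whose stored time-proportion sum, in either the input-SPL
     histogram or the acoustic classification, is below 0.9 — a symptom of
     low usage combined with two-significant-figure quantization.

Secondary, per-analysis rules:

(iii) require a complete 8-frequency audiogram;
(iv)  analysis-specific provenance predicates (e.g. restriction to a single
      device style), supplied by the caller as a boolean predicate.

All operations return row subsets (no mutation) and a
:class:`CleaningReport` attributing each removal to the first rule that
fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .datalog_model import (
    ACOUSTIC_COLUMNS,
    AUDIOGRAM_COLUMNS,
    Dataset,
    SPL_COLUMNS,
)

__all__ = [
    "CleaningReport",
    "apply_primary_rules",
    "require_complete_audiogram",
    "apply_predicate",
    "latest_snapshot_per_device",
]

#: Proportion-sum threshold of primary rule (ii).
MIN_PROPORTION_SUM = 0.9
#: Day threshold of primary rule (i): records with days <= 7 are dropped.
MAX_SHORT_USE_DAYS = 7


@dataclass
class CleaningReport:
    """Removal bookkeeping: ``input_size == output_size + sum(removed)``."""

    removed: dict[str, int] = field(default_factory=dict)
    input_size: int = 0
    output_size: int = 0

    def check(self) -> None:
        if self.input_size != self.output_size + sum(self.removed.values()):
            raise AssertionError("cleaning report does not balance")


def apply_primary_rules(dataset: Dataset) -> tuple[Dataset, CleaningReport]:
    """Apply rules (i) and (ii); removals attributed to the first rule firing.

    Rule (i): ``days_since_last_visit <= 7`` (missing days are retained —
    absence of the field is not evidence of short usage).  Rule (ii): the
    stored proportion sum of *either* the input-SPL histogram *or* the
    acoustic classes is below 0.9 (missing proportions count as zero usage).
    """
    f = dataset.frame
    days = f["days_since_last_visit"].to_numpy(dtype=float)
    short_use = ~np.isnan(days) & (days <= MAX_SHORT_USE_DAYS)
    spl_sum = np.nansum(f[list(SPL_COLUMNS)].to_numpy(dtype=float), axis=1)
    ac_sum = np.nansum(f[list(ACOUSTIC_COLUMNS)].to_numpy(dtype=float), axis=1)
    # tolerance guards the boundary against float summation noise: a stored
    # sum of exactly 0.90 is retained
    eps = 1e-9
    low_sum = (spl_sum < MIN_PROPORTION_SUM - eps) | (ac_sum < MIN_PROPORTION_SUM - eps)

    keep = ~(short_use | low_sum)
    report = CleaningReport(
        removed={
            "short_use": int(short_use.sum()),
            "low_sum": int((low_sum & ~short_use).sum()),
        },
        input_size=len(dataset),
        output_size=int(keep.sum()),
    )
    report.check()
    return dataset.subset(keep), report


def require_complete_audiogram(dataset: Dataset) -> tuple[Dataset, CleaningReport]:
    """Secondary rule (iii): retain only snapshots with all 8 thresholds present."""
    aud = dataset.frame[list(AUDIOGRAM_COLUMNS)].to_numpy(dtype=float)
    keep = ~np.isnan(aud).any(axis=1)
    report = CleaningReport(
        removed={"incomplete_audiogram": int((~keep).sum())},
        input_size=len(dataset),
        output_size=int(keep.sum()),
    )
    report.check()
    return dataset.subset(keep), report


def apply_predicate(
    dataset: Dataset, predicate: Callable[[pd.DataFrame], np.ndarray], name: str = "other"
) -> tuple[Dataset, CleaningReport]:
    """Secondary rule (iv): a pluggable per-analysis provenance predicate.

    ``predicate`` maps the dataset frame to a boolean keep-mask, e.g.
    ``lambda f: f["style"].eq("BTEa").to_numpy()`` for the directionality
    analysis.
    """
    keep = np.asarray(predicate(dataset.frame), dtype=bool)
    report = CleaningReport(
        removed={name: int((~keep).sum())},
        input_size=len(dataset),
        output_size=int(keep.sum()),
    )
    report.check()
    return dataset.subset(keep), report


def latest_snapshot_per_device(dataset: Dataset) -> Dataset:
    """Keep, for each device, only the snapshot with maximal session_seq."""
    f = dataset.frame
    seq = f["session_seq"].to_numpy(dtype=np.int64)
    best = pd.Series(seq).groupby(f["device_id"].to_numpy()).idxmax()
    keep = np.zeros(len(f), dtype=bool)
    keep[best.to_numpy()] = True
    return dataset.subset(keep)
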