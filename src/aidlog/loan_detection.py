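"""Loan-device (anomalous audiogram series) detection.

A hearing aid is normally worn by one person, so the audiogram recorded at
successive fitting visits should only drift within test--retest
variability.  A device whose thresholds *improve* by 15 dB or more at three
or more frequencies between consecutive visits — with the visit gap
strictly between 7 and 60 days — was most plausibly worn by a different
person (a loan device while the wearer's own aid was repaired), or fitted
off-protocol.  Custom-molded in-ear styles cannot be loaned, so comparing
flag rates across styles (Fisher's exact test) separates the loan effect
from the background off-protocol rate.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .datalog_model import AUDIOGRAM_COLUMNS, Dataset, STYLES

__all__ = ["LoanFlagResult", "audiogram_improvement", "flag_loan_devices", "compare_style_rates"]


def audiogram_improvement(prev, curr) -> np.ndarray:
    """Per-frequency threshold improvement (dB): ``prev - curr``.

    Positive values mean better hearing recorded at the later visit.  Both
    audiograms must be complete.
    """
    p = prev.values if hasattr(prev, "values") else np.asarray(prev, dtype=float)
    c = curr.values if hasattr(curr, "values") else np.asarray(curr, dtype=float)
    if np.isnan(p).any() or np.isnan(c).any():
        raise ValueError("audiogram_improvement requires complete audiograms")
    return p - c


@dataclass
class LoanFlagResult:
    """Output of :func:`flag_loan_devices`.

    ``devices``: one row per device with >= 1 snapshot — columns ``device_id``,
    ``style``, ``n_snapshots``, ``flagged``, and for flagged devices the
    triggering pair (``trigger_prev_seq``, ``trigger_curr_seq``,
    ``trigger_days``) and per-frequency improvements (``improve_<freq>``).
    ``by_style``: per-style totals, flag counts and percentages.
    """

    devices: pd.DataFrame
    by_style: pd.DataFrame
    improve_dB: float
    min_freqs: int
    day_window: tuple[float, float]


def flag_loan_devices(
    dataset: Dataset,
    improve_dB: float = 15.0,
    min_freqs: int = 3,
    day_window: tuple[float, float] = (7, 60),
) -> LoanFlagResult:
    """Flag devices whose consecutive-visit audiograms improve implausibly.

    A device is flagged iff some *consecutive* snapshot pair (by
    ``session_seq``) improves by ``improve_dB`` or more at ``min_freqs`` or
    more frequencies while the later snapshot's days-since-last-visit lies
    strictly inside ``day_window``.  The dataset must already be cleaned of
    missing audiograms.
    """
    f = dataset.frame
    aud = f[list(AUDIOGRAM_COLUMNS)].to_numpy(dtype=float)
    if np.isnan(aud).any():
        raise ValueError("flag_loan_devices requires complete audiograms; apply require_complete_audiogram first")

    order = np.lexsort((f["session_seq"].to_numpy(dtype=np.int64), f["device_id"].to_numpy()))
    dev = f["device_id"].to_numpy()[order]
    seq = f["session_seq"].to_numpy(dtype=np.int64)[order]
    days = f["days_since_last_visit"].to_numpy(dtype=float)[order]
    style = f["style"].to_numpy(object)[order]
    aud = aud[order]

    same_dev = np.concatenate([[False], dev[1:] == dev[:-1]])
    improvement = np.full_like(aud, np.nan)
    improvement[1:] = aud[:-1] - aud[1:]  # prev - curr
    n_improved = np.where(same_dev[:, None], improvement >= improve_dB, False).sum(axis=1)
    lo, hi = day_window
    in_window = ~np.isnan(days) & (days > lo) & (days < hi)
    hit = same_dev & (n_improved >= min_freqs) & in_window

    rows = []
    start = 0
    bounds = np.flatnonzero(np.concatenate([[True], dev[1:] != dev[:-1], [True]]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        hits = np.flatnonzero(hit[a:b]) + a
        row = {
            "device_id": dev[a],
            "style": style[a],
            "n_snapshots": b - a,
            "flagged": hits.size > 0,
            "trigger_prev_seq": np.nan,
            "trigger_curr_seq": np.nan,
            "trigger_days": np.nan,
        }
        row.update({f"improve_{fq}": np.nan for fq in (250, 500, 1000, 2000, 3000, 4000, 6000, 8000)})
        if hits.size:
            h = hits[0]
            row["trigger_prev_seq"] = seq[h - 1]
            row["trigger_curr_seq"] = seq[h]
            row["trigger_days"] = days[h]
            for k, fq in enumerate((250, 500, 1000, 2000, 3000, 4000, 6000, 8000)):
                row[f"improve_{fq}"] = improvement[h, k]
        rows.append(row)
    devices = pd.DataFrame(rows)

    by_style = (
        devices.groupby("style", observed=True)
        .agg(total=("flagged", "size"), flagged=("flagged", "sum"))
        .reindex([s for s in STYLES if s in set(devices["style"])])
        .reset_index()
    )
    by_style["percentage"] = 100.0 * by_style["flagged"] / by_style["total"]
    return LoanFlagResult(devices, by_style, improve_dB, min_freqs, (lo, hi))


def compare_style_rates(result: LoanFlagResult, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise two-sided Fisher exact tests of flag rates across styles.

    Each style pair contributes a 2x2 table (flagged / not-flagged by
    style).  Returns a symmetric DataFrame of p-values (diagonal 1.0),
    unadjusted for multiplicity, with an attached boolean ``significant``
    frame in ``.attrs`` at level ``alpha``.  Styles with zero totals are
    excluded with a warning.
    """
    t = result.by_style.set_index("style")
    nonzero = t.index[t["total"] > 0]
    dropped = [s for s in t.index if s not in set(nonzero)]
    if dropped:
        warnings.warn(f"styles with zero totals excluded: {dropped}")
    if len(nonzero) < 2:
        raise ValueError("need at least two styles with non-zero totals")
    p = pd.DataFrame(1.0, index=nonzero, columns=nonzero)
    for i, a in enumerate(nonzero):
        for b in nonzero[i + 1 :]:
            table = [
                [int(t.loc[a, "flagged"]), int(t.loc[a, "total"] - t.loc[a, "flagged"])],
                [int(t.loc[b, "flagged"]), int(t.loc[b, "total"] - t.loc[b, "flagged"])],
            ]
            _, pv = fisher_exact(table, alternative="two-sided")
            p.loc[a, b] = p.loc[b, a] = pv
    p.attrs["significant"] = p < alpha
    p.attrs["alpha"] = alpha
    return p
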