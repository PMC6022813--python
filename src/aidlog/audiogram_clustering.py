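"""Generic audiogram-shape clustering.

Audiograms are first *calibrated*: every threshold is offset so the 250-Hz
value is exactly 0, turning absolute levels into shapes (the clustering then
sees changes across frequency rather than overall severity).  K-means with
K = 11 and multiple restarts summarizes the population into generic shapes.
Screening the population to a low-frequency pure-tone average
(PTA over 250 and 500 Hz) below 20 dB HL preferentially keeps otologically
younger/normal ears, in which the characteristic noise-induced 3--6 kHz
notch — swamped in the unscreened population by presbyacusis-like sloping
losses — becomes visible as notch-bearing cluster centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .datalog_model import AUDIOGRAM_COLUMNS, AUDIOGRAM_FREQUENCIES, Dataset, DegenerateDataError

__all__ = [
    "ClusterModel",
    "calibrate_audiogram",
    "calibration_matrix",
    "pta_low",
    "screen_low_pta",
    "cluster_audiograms",
    "notch_score",
    "count_notch_centers",
]

_F = {f: i for i, f in enumerate(AUDIOGRAM_FREQUENCIES)}


def calibrate_audiogram(a) -> np.ndarray:
    """Offset a complete audiogram so its 250-Hz value is 0 dB (calibrated).

    Accepts an :class:`~aidlog.datalog_model.Audiogram` or an 8-vector.
    Values at higher frequencies may become negative when hearing there is
    better than at 250 Hz.  Idempotent.
    """
    v = a.values if hasattr(a, "values") else np.asarray(a, dtype=float)
    if np.isnan(v).any():
        raise ValueError("calibration requires a complete audiogram")
    return v - v[_F[250]]


def calibration_matrix(dataset: Dataset) -> np.ndarray:
    """Calibrated 8-column matrix for all (complete) audiograms in a dataset."""
    aud = dataset.frame[list(AUDIOGRAM_COLUMNS)].to_numpy(dtype=float)
    if np.isnan(aud).any():
        raise ValueError("calibration requires complete audiograms")
    return aud - aud[:, [_F[250]]]


def pta_low(a) -> float | np.ndarray:
    """Low-frequency pure-tone average: mean of the 250- and 500-Hz thresholds."""
    v = a.values if hasattr(a, "values") else np.asarray(a, dtype=float)
    single = v.ndim == 1
    pair = np.atleast_2d(v)[:, [_F[250], _F[500]]]
    if np.isnan(pair).any():
        raise ValueError("pta_low requires thresholds at 250 and 500 Hz")
    out = pair.mean(axis=1)
    return float(out[0]) if single else out


def screen_low_pta(dataset: Dataset, max_pta: float = 20.0, strict: bool = True) -> Dataset:
    """Retain snapshots with low-frequency PTA below ``max_pta`` dB HL.

    ``strict`` controls the boundary (default ``pta < max_pta``; set False
    for ``pta <= max_pta``).
    """
    f = dataset.frame
    pta = (f["ac250"].to_numpy(dtype=float) + f["ac500"].to_numpy(dtype=float)) / 2.0
    if np.isnan(pta).any():
        raise ValueError("screen_low_pta requires thresholds at 250 and 500 Hz")
    keep = pta < max_pta if strict else pta <= max_pta
    return dataset.subset(keep)


@dataclass
class ClusterModel:
    """A fitted K-means model over calibrated audiogram shapes."""

    centers: np.ndarray  # (k, 8) dB calibrated
    labels: np.ndarray  # (n,)
    inertia: float  # best within-cluster sum of squares
    k: int
    n_starts: int
    seed: int

    def recompute_inertia(self, X: np.ndarray) -> float:
        return float(((X - self.centers[self.labels]) ** 2).sum())


def cluster_audiograms(
    dataset: Dataset, k: int = 11, n_starts: int = 20, seed: int = 0
) -> ClusterModel:
    """K-means (Euclidean, unweighted dimensions) on calibrated audiograms.

    Runs ``n_starts`` k-means++ restarts and keeps the lowest within-cluster
    sum of squares; deterministic given ``seed``.
    """
    X = calibration_matrix(dataset)
    if len(X) < k:
        raise DegenerateDataError(f"need at least k={k} complete audiograms, got {len(X)}")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    return ClusterModel(
        centers=km.cluster_centers_,
        labels=labels,
        inertia=float(km.inertia_),
        k=k,
        n_starts=n_starts,
        seed=seed,
    )


def notch_score(center, min_depth: float = 10.0) -> tuple[bool, float]:
    """Score a cluster center for a noise-induced-loss notch.

    The notch depth is the largest excess of the 3, 4 or 6 kHz value over
    the *better* of the flanking 2 kHz and 8 kHz values:
    ``depth = max(center[3k,4k,6k]) - max(center[2k], center[8k])``.
    A center bears a notch when the depth reaches ``min_depth`` dB (default
    10 dB, exposed as a parameter).
    """
    c = np.asarray(center, dtype=float)
    depth = float(c[[_F[3000], _F[4000], _F[6000]]].max() - max(c[_F[2000]], c[_F[8000]]))
    return depth >= min_depth, depth


def count_notch_centers(model: ClusterModel, min_depth: float = 10.0) -> int:
    """Number of cluster centers bearing a notch of at least ``min_depth`` dB."""
    return sum(notch_score(c, min_depth)[0] for c in model.centers)
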