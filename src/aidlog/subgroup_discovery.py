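"""Exhaustive cross-modality subgroup discovery.

A *modality* is a named group of interrelated dimensions (the 8-frequency
audiogram, the 12-bin input-SPL histogram, the pair of environmental gain
reductions, the categorical device style).  For a pair of modalities the
search enumerates **every** non-empty subset of each ordinal modality's
dimensions, quantizes each subset into a fixed number of clusters (K-means
with k = 5 for ordinal modalities; one cluster per category for categorical
ones), and tests every (cluster-A, cluster-B) cell of the resulting
contingency table against independence.

With ``d``-dimensional ordinal modalities this yields

    tests = (2^dA - 1) * (2^dB - 1) * kA * kB

individual cell tests (e.g. (2^12 - 1) * 5 * 6 = 122,850 for input-SPL vs
style), so the significance level is Bonferroni-corrected by the total test
count.  A cell is *reported* when its corrected p-value survives AND its
effect size — the lift ``observed / expected`` under independence — reaches
``min_effect`` (default 1.1).  Reported subgroups carry population-share
flags: ``*`` for interesting subgroups below 0.1 of the population, ``#``
at or above 0.1, ``+`` for effect over 1.1.

The cell test is a one-sided binomial tail: with margins ``rowTotal`` and
``colTotal`` out of ``N``, the cell count under independence is
Binomial(N, rowTotal*colTotal/N^2), and p = P(X >= observed).  Testing
cells (not whole tables) matches the ``... x kA x kB`` test accounting.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.cluster import KMeans

from .datalog_model import Dataset, DegenerateDataError

__all__ = [
    "Modality",
    "Subgroup",
    "SubgroupSearchResult",
    "enumerate_dimension_subsets",
    "total_test_count",
    "cluster_subset",
    "score_cell",
    "discover_subgroups",
    "STYLE_MODALITY",
    "INPUT_SPL_MODALITY",
    "AUDIOGRAM_MODALITY",
    "GAIN_REDUCTION_MODALITY",
]


@dataclass(frozen=True)
class Modality:
    """A named dimension group with its quantization rule.

    Ordinal modalities are quantized by K-means into ``n_clusters`` (5 by
    default); categorical modalities have exactly one dimension and one
    cluster per category.
    """

    name: str
    dims: tuple[str, ...]
    scale: str = "ordinal"  # or "categorical"
    n_clusters: int = 5

    def __post_init__(self) -> None:
        if self.scale not in ("ordinal", "categorical"):
            raise ValueError("scale must be 'ordinal' or 'categorical'")
        if len(self.dims) < 1:
            raise ValueError("a modality needs at least one dimension")
        if self.scale == "categorical" and len(self.dims) != 1:
            raise ValueError("categorical modalities have exactly one dimension")

    @property
    def n_subsets(self) -> int:
        return 1 if self.scale == "categorical" else 2 ** len(self.dims) - 1


# Canonical modalities of the datalog schema.
from .datalog_model import AUDIOGRAM_COLUMNS as _AUD, SPL_COLUMNS as _SPL

STYLE_MODALITY = Modality("style", ("style",), "categorical", 6)
INPUT_SPL_MODALITY = Modality("input_spl", tuple(_SPL))
AUDIOGRAM_MODALITY = Modality("audiogram", tuple(_AUD))
GAIN_REDUCTION_MODALITY = Modality(
    "gain_reduction", ("gain_reduction_noise", "gain_reduction_quiet")
)


def enumerate_dimension_subsets(modality: Modality) -> list[tuple[str, ...]]:
    """All non-empty dimension subsets, ordered by size then lexicographic
    position in the modality's dimension list.  Categorical modalities have
    the single trivial subset."""
    if modality.scale == "categorical":
        return [modality.dims]
    d = modality.dims
    out: list[tuple[str, ...]] = []
    for r in range(1, len(d) + 1):
        out.extend(itertools.combinations(d, r))
    return out


def total_test_count(modA: Modality, modB: Modality) -> int:
    """Bonferroni denominator: subsets(A) * subsets(B) * kA * kB."""
    return modA.n_subsets * modB.n_subsets * modA.n_clusters * modB.n_clusters


def cluster_subset(
    dataset: Dataset,
    modality: Modality,
    subset: Sequence[str],
    k: int | None = None,
    seed: int = 0,
    n_starts: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Quantize the rows of one dimension subset into cluster labels.

    Ordinal: K-means (best of ``n_starts`` restarts, seeded) on the subset's
    columns; returns ``(labels, centers)`` with centers of shape (k, |subset|).
    Categorical: labels are the category codes; centers are the category
    values.  Constant (zero-variance) ordinal subsets are degenerate and
    raise :class:`DegenerateDataError` (callers skip them with a warning).
    """
    f = dataset.frame
    if modality.scale == "categorical":
        col = f[subset[0]]
        if col.isna().any():
            raise ValueError(f"missing values in categorical dimension {subset[0]!r}")
        cats = np.array(sorted(col.unique()), dtype=object)
        codes = pd.Categorical(col, categories=cats).codes.astype(np.int64)
        return codes, cats
    k = modality.n_clusters if k is None else k
    X = f[list(subset)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in ordinal dimensions; clean the dataset first")
    if len(X) < k:
        raise DegenerateDataError(f"fewer rows ({len(X)}) than clusters ({k})")
    if np.allclose(np.ptp(X, axis=0), 0):
        raise DegenerateDataError(f"constant dimensions {tuple(subset)}; nothing to cluster")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    return labels.astype(np.int64), km.cluster_centers_


def score_cell(observed: int, row_total: int, col_total: int, n: int) -> tuple[float, float]:
    """Effect size (lift) and one-sided binomial-tail p-value of one cell.

    ``effect = observed * N / (rowTotal * colTotal)``;
    ``p = P(X >= observed)`` for ``X ~ Binomial(N, rowTotal*colTotal/N^2)``.
    Zero margins are undefined and must be skipped by the caller.
    """
    if n <= 0:
        raise ValueError("N must be positive")
    if row_total == 0 or col_total == 0:
        raise ValueError("zero margin: cell undefined")
    p0 = (row_total / n) * (col_total / n)
    effect = observed * n / (row_total * col_total)
    p_value = float(binom.sf(observed - 1, n, p0))
    return float(effect), p_value


@dataclass
class Subgroup:
    """One reported (cluster-A, cluster-B) cell of one subset pair."""

    modality_a: str
    modality_b: str
    subset_a: tuple[str, ...]
    subset_b: tuple[str, ...]
    cluster_a: int
    cluster_b: int
    center_a: object
    center_b: object
    observed: int
    expected: float
    effect: float
    p_value: float
    share: float
    flags: str  # any of "*", "#", "+"


@dataclass
class SubgroupSearchResult:
    subgroups: list[Subgroup]
    total_tests: int
    tests_performed: int
    cells_skipped: int
    alpha: float
    min_effect: float
    n: int

    @property
    def best(self) -> Subgroup | None:
        return self.subgroups[0] if self.subgroups else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.subgroups])


def discover_subgroups(
    dataset: Dataset,
    modA: Modality,
    modB: Modality,
    alpha: float = 0.05,
    min_effect: float = 1.1,
    seed: int = 0,
    n_starts: int = 2,
    max_cells: int = 2**20,
    subset_sample: int | None = None,
) -> SubgroupSearchResult:
    """Exhaustive Bonferroni-corrected subgroup search over a modality pair.

    Iterates all (subset-A, subset-B) pairs, re-clustering each subset
    (clusterings are cached per modality, since a subset's clustering does
    not depend on the partner modality), and reports every cell with
    ``p < alpha / total_test_count`` and ``effect >= min_effect``, ranked by
    descending effect.  Deterministic given ``seed``.

    Pairs whose full enumeration exceeds ``max_cells`` cells are refused
    unless ``subset_sample`` is set, in which case that many subset pairs
    are sampled uniformly (a documented exploration mode; the Bonferroni
    denominator still counts the full search).
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    total = total_test_count(modA, modB)
    n_pairs = modA.n_subsets * modB.n_subsets
    if total > max_cells and subset_sample is None:
        raise ValueError(
            f"{total} cells exceed max_cells={max_cells}; "
            "set subset_sample to search a random subset of subset pairs"
        )

    rng = np.random.default_rng(seed)
    bonf = alpha / total

    def clusterings(mod: Modality, base_seed: int):
        labels, centers = {}, {}
        for i, sub in enumerate(enumerate_dimension_subsets(mod)):
            try:
                lab, cen = cluster_subset(
                    dataset, mod, sub, seed=base_seed + i, n_starts=n_starts
                )
            except DegenerateDataError as e:
                warnings.warn(f"skipping degenerate subset {sub}: {e}")
                continue
            labels[sub], centers[sub] = lab, cen
        return labels, centers

    labels_a, centers_a = clusterings(modA, seed)
    labels_b, centers_b = clusterings(modB, seed + 100_000)

    pairs = list(itertools.product(labels_a, labels_b))
    if subset_sample is not None and subset_sample < len(pairs):
        idx = rng.choice(len(pairs), size=subset_sample, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]

    found: list[Subgroup] = []
    tests_performed = 0
    cells_skipped = 0
    for sub_a, sub_b in pairs:
        la, lb = labels_a[sub_a], labels_b[sub_b]
        ka = len(centers_a[sub_a])
        kb = len(centers_b[sub_b])
        table = np.bincount(la * kb + lb, minlength=ka * kb).reshape(ka, kb)
        row_tot = table.sum(axis=1)
        col_tot = table.sum(axis=0)
        for i in range(ka):
            for j in range(kb):
                if row_tot[i] == 0 or col_tot[j] == 0:
                    cells_skipped += 1
                    continue
                effect, p_value = score_cell(int(table[i, j]), int(row_tot[i]), int(col_tot[j]), n)
                tests_performed += 1
                if p_value < bonf and effect >= min_effect:
                    share = table[i, j] / n
                    flags = ("*" if share < 0.1 else "#") + ("+" if effect > 1.1 else "")
                    found.append(
                        Subgroup(
                            modality_a=modA.name,
                            modality_b=modB.name,
                            subset_a=sub_a,
                            subset_b=sub_b,
                            cluster_a=i,
                            cluster_b=j,
                            center_a=_center_repr(centers_a[sub_a], i),
                            center_b=_center_repr(centers_b[sub_b], j),
                            observed=int(table[i, j]),
                            expected=float(row_tot[i] * col_tot[j] / n),
                            effect=effect,
                            p_value=p_value,
                            share=float(share),
                            flags=flags,
                        )
                    )
    found.sort(key=lambda s: (-s.effect, s.p_value))
    return SubgroupSearchResult(
        subgroups=found,
        total_tests=total,
        tests_performed=tests_performed,
        cells_skipped=cells_skipped,
        alpha=alpha,
        min_effect=min_effect,
        n=n,
    )


def _center_repr(centers, i):
    c = centers[i]
    if isinstance(c, (str, np.str_)):
        return str(c)
    c = np.atleast_1d(np.asarray(c, dtype=float))
    return float(c[0]) if c.size == 1 else tuple(np.round(c, 4))
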