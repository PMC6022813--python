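"""Device-style prediction from the input-SPL histogram.

A stratified 10-fold cross-validated Random Forest (50 trees, Gini
impurity; optionally depth-limited to 4) predicts the device style from the
12 input-SPL time proportions.  The pooled out-of-fold confusion matrix
summarizes how separable the styles' acoustic-demand phenotypes are — on a
heavily imbalanced population the forest collapses onto the majority style,
which is itself an informative finding.

:func:`region_heatmap` opens the forest up: for every leaf that predicts a
chosen target style, the root-to-leaf split constraints are intersected
into per-dimension intervals, and the leaf's training-sample weight is
accumulated onto a (dimension x proportion-value) grid over the cells the
intervals cover.  Dark regions of the normalized grid are the parts of
input-SPL space that drive predictions of the target style.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .datalog_model import Dataset, SPL_COLUMNS, STYLES

__all__ = ["ConfusionMatrix", "RegionHeatmap", "crossval_forest", "region_heatmap", "max_tree_depth"]


@dataclass
class ConfusionMatrix:
    """Pooled out-of-fold confusion counts (true style x predicted style)."""

    counts: pd.DataFrame
    labels: tuple[str, ...]

    @property
    def proportions(self) -> pd.DataFrame:
        """Row-normalized proportions; rows with zero counts stay zero."""
        c = self.counts.to_numpy(dtype=float)
        rows = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(rows > 0, c / rows, 0.0)
        return pd.DataFrame(p, index=self.counts.index, columns=self.counts.columns)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


def crossval_forest(
    dataset: Dataset,
    trees: int = 50,
    folds: int = 10,
    max_depth: int | None = None,
    seed: int = 0,
) -> tuple[ConfusionMatrix, list[RandomForestClassifier]]:
    """Stratified k-fold CV of a Random Forest predicting style from input SPL.

    Features are the 12 stored SPL proportions; splits use Gini impurity.
    Returns the pooled out-of-fold confusion matrix and the per-fold fitted
    forests (used by :func:`region_heatmap`).  Deterministic given ``seed``.
    """
    f = dataset.frame
    X = f[list(SPL_COLUMNS)].to_numpy(dtype=float)
    y = f["style"].to_numpy(object)
    if pd.isna(y).any() or np.isnan(X).any():
        raise ValueError("crossval_forest requires complete style and SPL columns")
    present = [s for s in STYLES if s in set(y)]
    class_counts = pd.Series(y).value_counts()
    if (class_counts < folds).any():
        raise ValueError(
            f"every style needs at least {folds} examples for stratified {folds}-fold CV"
        )

    codes = np.array([present.index(s) for s in y])
    labels = np.array(present, dtype=object)[codes]  # plain strings for sklearn
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    counts = np.zeros((len(present), len(present)), dtype=int)
    pos = {s: i for i, s in enumerate(present)}
    models: list[RandomForestClassifier] = []
    for k, (tr, te) in enumerate(skf.split(X, codes)):
        rf = RandomForestClassifier(
            n_estimators=trees,
            criterion="gini",
            max_depth=max_depth,
            random_state=seed + k,
            n_jobs=1,
        )
        rf.fit(X[tr], labels[tr])
        pred = rf.predict(X[te])
        np.add.at(counts, (codes[te], [pos[p] for p in pred]), 1)
        models.append(rf)
    cm = pd.DataFrame(counts, index=present, columns=present)
    cm.index.name = "true"
    cm.columns.name = "predicted"
    return ConfusionMatrix(cm, tuple(present)), models


@dataclass
class RegionHeatmap:
    """Accumulated predictive weight per (SPL dimension, proportion bin)."""

    weights: np.ndarray  # (n_dims, n_bins), max-normalized to 1 (all zero if empty)
    dims: tuple[str, ...]
    bin_edges: np.ndarray
    target_style: str

    def to_frame(self) -> pd.DataFrame:
        cols = [f"[{a:.2f},{b:.2f})" for a, b in zip(self.bin_edges[:-1], self.bin_edges[1:])]
        return pd.DataFrame(self.weights, index=self.dims, columns=cols)


def region_heatmap(
    models: list[RandomForestClassifier],
    target_style: str = "CIC",
    n_bins: int = 50,
    dims: tuple[str, ...] = tuple(SPL_COLUMNS),
) -> RegionHeatmap:
    """Map the input-SPL subspaces in which the forest predicts a style.

    For every tree of every fold model, every leaf whose majority class is
    ``target_style`` contributes its training-sample count as weight; the
    weight is added, for each dimension, to all grid cells overlapped by the
    leaf's root-to-leaf interval on that dimension (unsplit dimensions span
    [0, 1]).  The grid is ``n_bins`` equal-width proportion bins on [0, 1]
    and the result is normalized to a maximum of 1.  Invariant to tree and
    fold order (pure accumulation).
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    weights = np.zeros((len(dims), n_bins))
    if not models:
        raise ValueError("no fitted models given")
    any_hit = False
    for rf in models:
        classes = list(rf.classes_)
        for tree in rf.estimators_:
            t = tree.tree_
            # walk the tree carrying the interval constraints of the path
            stack = [(0, {})]  # node id, {feature: (lo, hi)}
            while stack:
                node, box = stack.pop()
                if t.children_left[node] == -1:  # leaf
                    value = t.value[node][0]
                    maj = classes[int(np.argmax(value))]
                    if str(maj) == target_style:
                        any_hit = True
                        w = float(t.n_node_samples[node])
                        for d in range(len(dims)):
                            lo, hi = box.get(d, (0.0, 1.0))
                            cover = (edges[1:] > lo) & (edges[:-1] < hi)
                            weights[d, cover] += w
                    continue
                feat, thr = int(t.feature[node]), float(t.threshold[node])
                lo, hi = box.get(feat, (0.0, 1.0))
                left = dict(box)
                left[feat] = (lo, min(hi, thr))
                right = dict(box)
                right[feat] = (max(lo, thr), hi)
                stack.append((t.children_left[node], left))
                stack.append((t.children_right[node], right))
    if not any_hit:
        warnings.warn(f"style {target_style!r} is never predicted; heatmap is all zero")
    elif weights.max() > 0:
        weights = weights / weights.max()
    return RegionHeatmap(weights, tuple(dims), edges, target_style)


def max_tree_depth(models: list[RandomForestClassifier]) -> int:
    """Longest root-to-leaf path over all trees (structural audit helper)."""
    return max(t.tree_.max_depth for rf in models for t in rf.estimators_)
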