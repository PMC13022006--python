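"""Decision-tree prediction of the dominant trophic mode.

A C4.5-family classifier over numeric station features: binary splits on
attribute thresholds chosen by information gain ratio, fractional
case-weighting of missing values down both children, and pessimistic
error-based pruning with a configurable confidence factor.  The tree
reports the two summaries used to interpret it: *attribute usage* (percent
of training case weight passing through any node testing an attribute;
the root attribute is always 100%) and the resubstitution *training error*.

Thresholds are placed at the midpoint of the straddling observed values,
and ties in split selection are broken toward the earlier feature column
and the lower threshold, so induction is deterministic and invariant to
row order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

_EPS = 1e-12


@dataclass
class Node:
    """One tree node; internal nodes test ``attr <= threshold``."""

    weight: float
    class_weights: dict[str, float]
    attr: str | None = None
    threshold: float | None = None
    left: "Node | None" = None  # attr <= threshold
    right: "Node | None" = None  # attr > threshold
    known_fracs: tuple[float, float] = (0.5, 0.5)  # routing for missing values

    @property
    def is_leaf(self) -> bool:
        return self.attr is None

    @property
    def majority(self) -> str:
        # ties toward the lexicographically first class
        return max(sorted(self.class_weights), key=lambda c: self.class_weights[c])


@dataclass
class DecisionTree:
    """A fitted tree plus the training summaries."""

    root: Node
    features: list[str]
    classes: list[str]
    min_cases: float = 2.0
    cf: float = 0.25
    training_error_pct: float = field(default=math.nan)
    attribute_usage_pct: dict[str, float] = field(default_factory=dict)

    def predict_distribution(self, row: pd.Series) -> dict[str, float]:
        """Class-weight distribution for one observation.

        Missing tested attributes send the case down both children with the
        training known-weight fractions; the returned distribution sums to 1.
        """
        agg = {c: 0.0 for c in self.classes}

        def walk(node: Node, w: float) -> None:
            if node.is_leaf:
                total = sum(node.class_weights.values())
                if total <= 0:
                    agg[node.majority] += w
                    return
                for c, cw in node.class_weights.items():
                    agg[c] += w * cw / total
                return
            x = row.get(node.attr, math.nan)
            if x is None or (isinstance(x, float) and math.isnan(x)):
                walk(node.left, w * node.known_fracs[0])
                walk(node.right, w * node.known_fracs[1])
            elif float(x) <= node.threshold:
                walk(node.left, w)
            else:
                walk(node.right, w)

        walk(self.root, 1.0)
        return agg

    def predict(self, table: pd.DataFrame) -> pd.Series:
        """Majority-path class per row."""
        preds = []
        for _, row in table.iterrows():
            dist = self.predict_distribution(row)
            preds.append(max(sorted(dist), key=lambda c: dist[c]))
        return pd.Series(preds, index=table.index, name="predicted")

    def render(self) -> str:
        """Indented text rendering of the tree."""
        lines: list[str] = []

        def walk(node: Node, indent: int, prefix: str) -> None:
            pad = "    " * indent
            if node.is_leaf:
                lines.append(
                    f"{pad}{prefix}-> {node.majority} "
                    f"(weight {node.weight:.1f})"
                )
                return
            lines.append(f"{pad}{prefix}{node.attr} <= {node.threshold:g}?")
            walk(node.left, indent + 1, "yes: ")
            walk(node.right, indent + 1, "no:  ")

        walk(self.root, 0, "")
        return "\n".join(lines)

    def node_listing(self) -> pd.DataFrame:
        """Flat machine-readable node table."""
        rows = []

        def walk(node: Node, node_id: int, depth: int) -> int:
            rows.append(
                {
                    "node": node_id,
                    "depth": depth,
                    "attr": node.attr or "",
                    "threshold": node.threshold if node.threshold is not None else math.nan,
                    "leaf_class": node.majority if node.is_leaf else "",
                    "weight": node.weight,
                }
            )
            nid = node_id
            if not node.is_leaf:
                nid = walk(node.left, nid + 1, depth + 1)
                nid = walk(node.right, nid + 1, depth + 1)
            return nid

        walk(self.root, 0, 0)
        return pd.DataFrame(rows)


def _entropy(class_weights: np.ndarray) -> float:
    total = class_weights.sum()
    if total <= 0:
        return 0.0
    p = class_weights[class_weights > 0] / total
    return float(-(p * np.log2(p)).sum())


def _best_threshold(x: np.ndarray, y_idx: np.ndarray, w: np.ndarray,
                    n_classes: int, min_cases: float) -> tuple[float, float, float]:
    """Best (gain, gain_ratio, threshold) for one attribute's known values."""
    order = np.argsort(x, kind="stable")
    xs, ys, ws = x[order], y_idx[order], w[order]
    total_w = ws.sum()
    # cumulative class weights below each boundary
    onehot = np.zeros((len(xs), n_classes))
    onehot[np.arange(len(xs)), ys] = ws
    cum = np.cumsum(onehot, axis=0)
    total_cls = cum[-1]
    parent_h = _entropy(total_cls)
    boundaries = np.nonzero(np.diff(xs) > _EPS)[0]  # split after index i
    best = (-math.inf, -math.inf, math.nan)
    for i in boundaries:
        left_cls = cum[i]
        wl = left_cls.sum()
        wr = total_w - wl
        if wl < min_cases or wr < min_cases:
            continue
        h = (wl * _entropy(left_cls) + wr * _entropy(total_cls - left_cls)) / total_w
        gain = parent_h - h
        pl, pr = wl / total_w, wr / total_w
        split_info = -(pl * math.log2(pl) + pr * math.log2(pr))
        ratio = gain / split_info if split_info > _EPS else 0.0
        thr = 0.5 * (xs[i] + xs[i + 1])
        cand = (gain, ratio, thr)
        # prefer the higher ratio; ties toward the lower threshold
        if ratio > best[1] + _EPS or (abs(ratio - best[1]) <= _EPS and thr < best[2]):
            best = cand
    return best


def _grow(table: pd.DataFrame, y: np.ndarray, w: np.ndarray, features: list[str],
          classes: list[str], min_cases: float) -> Node:
    n_classes = len(classes)
    cls_w = np.zeros(n_classes)
    for k in range(n_classes):
        cls_w[k] = w[y == k].sum()
    node = Node(weight=float(w.sum()),
                class_weights={c: float(cls_w[k]) for k, c in enumerate(classes)})
    if node.weight < 2 * min_cases or (cls_w > 0).sum() <= 1:
        return node
    best = None  # (ratio, gain, attr_idx, attr, threshold)
    for ai, attr in enumerate(features):
        x = table[attr].to_numpy(float)
        known = np.isfinite(x)
        known_w = w[known].sum()
        if known_w < 2 * min_cases:
            continue
        gain, ratio, thr = _best_threshold(
            x[known], y[known], w[known], n_classes, min_cases
        )
        if not math.isfinite(thr):
            continue
        # discount the gain by the fraction of known cases
        gain *= known_w / node.weight
        if gain <= _EPS:
            continue
        if best is None or ratio > best[0] + _EPS or (
            abs(ratio - best[0]) <= _EPS and gain > best[1] + _EPS
        ):
            best = (ratio, gain, ai, attr, thr)
    if best is None:
        return node
    _, _, _, attr, thr = best
    x = table[attr].to_numpy(float)
    known = np.isfinite(x)
    go_left = known & (x <= thr)
    go_right = known & (x > thr)
    wl_known = w[go_left].sum()
    wr_known = w[go_right].sum()
    fl = wl_known / (wl_known + wr_known)
    w_left = np.where(go_left, w, np.where(known, 0.0, w * fl))
    w_right = np.where(go_right, w, np.where(known, 0.0, w * (1.0 - fl)))
    keep_l = w_left > _EPS
    keep_r = w_right > _EPS
    node.attr = attr
    node.threshold = float(thr)
    node.known_fracs = (float(fl), float(1.0 - fl))
    node.left = _grow(table[keep_l], y[keep_l], w_left[keep_l],
                      features, classes, min_cases)
    node.right = _grow(table[keep_r], y[keep_r], w_right[keep_r],
                       features, classes, min_cases)
    return node


def _pessimistic_errors(node: Node, cf: float) -> float:
    """Upper-confidence-bound error count for a node treated as a leaf."""
    n = sum(node.class_weights.values())
    if n <= 0:
        return 0.0
    e = n - node.class_weights[node.majority]
    if e >= n:
        return n
    # Clopper-Pearson upper limit on the error rate at confidence cf
    p_up = float(beta_dist.ppf(1.0 - cf, e + 1.0, max(n - e, _EPS)))
    return n * min(p_up, 1.0)


def _prune(node: Node, cf: float) -> float:
    """Bottom-up error-based pruning; returns the subtree error estimate."""
    leaf_est = _pessimistic_errors(node, cf)
    if node.is_leaf:
        return leaf_est
    sub_est = _prune(node.left, cf) + _prune(node.right, cf)
    if leaf_est <= sub_est + _EPS:
        node.attr = None
        node.threshold = None
        node.left = None
        node.right = None
        return leaf_est
    return sub_est


def induce_tree(
    table: pd.DataFrame,
    label: str = "label",
    min_cases: float = 2.0,
    cf: float = 0.25,
    prune: bool = True,
    features: list[str] | None = None,
    seed: int | None = None,
) -> DecisionTree:
    """Fit a gain-ratio decision tree to a feature table.

    Parameters
    ----------
    table : rows with numeric feature columns (NaN allowed) and a ``label``
        column present for every row.
    min_cases : minimum case weight per child branch.
    cf : confidence factor of pessimistic pruning; smaller prunes harder.
    prune : disable to keep the fully grown tree.
    features : restrict the candidate attributes (default: every numeric
        column except the label).
    seed : accepted for interface symmetry; induction is deterministic.
    """
    if label not in table.columns:
        raise ValueError(f"label column {label!r} missing")
    if table[label].isna().any():
        raise ValueError("every training row needs a label")
    if features is None:
        features = [
            c for c in table.columns
            if c != label and pd.api.types.is_numeric_dtype(table[c])
        ]
    classes = sorted(table[label].astype(str).unique())
    y = np.array([classes.index(v) for v in table[label].astype(str)])
    w = np.ones(len(table), dtype=float)
    root = _grow(table[features], y, w, features, classes, min_cases)
    if prune:
        _prune(root, cf)
    model = DecisionTree(root=root, features=features, classes=classes,
                         min_cases=min_cases, cf=cf)
    model.attribute_usage_pct = attribute_usage(model, table)
    model.training_error_pct = training_error(model, table)
    return model


def attribute_usage(model: DecisionTree, table: pd.DataFrame) -> dict[str, float]:
    """Percent of training case weight passing through nodes testing each attribute.

    Each case's weight is counted once per attribute, at the topmost node
    on its (possibly fractional) path that tests it; the root attribute is
    therefore always 100%.
    """
    usage = {a: 0.0 for a in model.features}

    def walk(node: Node, row: pd.Series, wgt: float, seen: frozenset[str]) -> None:
        if node.is_leaf or wgt <= 0:
            return
        if node.attr not in seen:
            usage[node.attr] += wgt
            seen = seen | {node.attr}
        x = row.get(node.attr, math.nan)
        if x is None or (isinstance(x, float) and math.isnan(x)):
            walk(node.left, row, wgt * node.known_fracs[0], seen)
            walk(node.right, row, wgt * node.known_fracs[1], seen)
        elif float(x) <= node.threshold:
            walk(node.left, row, wgt, seen)
        else:
            walk(node.right, row, wgt, seen)

    for _, row in table.iterrows():
        walk(model.root, row, 1.0, frozenset())
    n = len(table)
    return {a: 100.0 * u / n for a, u in usage.items()}


def training_error(model: DecisionTree, table: pd.DataFrame, label: str = "label") -> float:
    """Resubstitution error: percent of training rows misclassified."""
    preds = model.predict(table)
    truth = table[label].astype(str)
    return float(100.0 * (preds.to_numpy() != truth.to_numpy()).mean())
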