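"""Community clustering and the pigment-based mean-size index.

Chemotaxonomic compositions (percent of total chlorophyll a per class) are
clustered by Manhattan-distance hierarchical agglomeration — the L1 metric
is robust to the outlier stations typical of river plumes — and the
clustering tendency is checked by an unscaled principal-component
decomposition.  A diagnostic-pigment size index summarises the pigmented
community as a weighted mean of micro/nano/pico size classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform


def manhattan_distance_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise L1 (cityblock) distances between composition rows."""
    if len(table) < 2:
        raise ValueError("need at least 2 samples")
    X = table.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("composition table contains missing values")
    D = squareform(pdist(X, metric="cityblock"))
    return pd.DataFrame(D, index=table.index, columns=table.index)


@dataclass
class ClusterResult:
    """Agglomerative merge tree, a k-cut labelling, and the PCA check."""

    merge_tree: np.ndarray  # scipy linkage matrix
    labels: pd.Series
    k: int
    scores: pd.DataFrame | None = None
    variance_fractions: np.ndarray | None = None
    separation: pd.DataFrame | None = None


def hca_cut(dist: pd.DataFrame, k: int = 4, method: str = "average") -> ClusterResult:
    """Agglomerative clustering of a precomputed distance matrix, cut at k.

    Linkage defaults to average (UPGMA); Ward is refused because the input
    metric is non-Euclidean.  Labels are renumbered 1..k in order of first
    appearance so they are invariant to sample order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(dist):
        raise ValueError("k cannot exceed the number of samples")
    if method == "ward":
        raise ValueError("Ward linkage requires Euclidean distances")
    Z = scipy_linkage(squareform(dist.to_numpy(float), checks=False), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    canon = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        canon[i] = remap[lab]
    return ClusterResult(
        merge_tree=Z, labels=pd.Series(canon, index=dist.index, name="cluster"), k=k
    )


def pca_validation(
    table: pd.DataFrame, labels: pd.Series, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Principal-component check of clustering tendency.

    Centered (optionally scaled) SVD decomposition of the composition
    table.  Returns scores, per-component variance fractions, and a
    per-label-pair summary: centroid distance in the PC1–PC2 plane divided
    by the mean within-cluster spread (RMS distance to own centroid).
    Well-separated clusters give ratios well above 1.
    """
    if len(table) < 3:
        raise ValueError("PCA check needs at least 3 samples")
    X = table.to_numpy(float)
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    if not np.any(Xc):
        raise ValueError("composition table is constant")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    var_frac = var / var.sum()
    ncomp = min(Xc.shape)
    scores = pd.DataFrame(
        U * s,
        index=table.index,
        columns=[f"PC{i + 1}" for i in range(ncomp)],
    )
    pc12 = scores.iloc[:, : min(2, ncomp)].to_numpy()
    labs = np.asarray(labels)
    uniq = sorted(set(labs))
    cents = {g: pc12[labs == g].mean(axis=0) for g in uniq}
    spread = {}
    for g in uniq:
        d = pc12[labs == g] - cents[g]
        spread[g] = math.sqrt(float(np.mean(np.sum(d**2, axis=1))))
    rows = []
    for i, g in enumerate(uniq):
        for h in uniq[i + 1:]:
            dc = float(np.linalg.norm(cents[g] - cents[h]))
            ws = 0.5 * (spread[g] + spread[h])
            rows.append(
                {
                    "cluster_a": g,
                    "cluster_b": h,
                    "centroid_distance": dc,
                    "within_spread": ws,
                    "separation_ratio": dc / ws if ws > 0 else math.inf,
                }
            )
    return scores, var_frac, pd.DataFrame(rows)


# Diagnostic-pigment size-class weights (Uitz/Bricaud convention):
# micro ~ fucoxanthin + peridinin; nano ~ 19'-acyloxyfucoxanthins +
# alloxanthin; pico ~ chlorophyll b + zeaxanthin.
SIZE_WEIGHTS = {
    "micro": {"Fuco": 1.41, "Perid": 1.41},
    "nano": {"Hex Fuco": 1.27, "But Fuco": 0.35, "Allo": 0.60},
    "pico": {"Chl b": 1.01, "Zea": 0.86},
}
_SIZE_TAG = {"micro": 3.0, "nano": 2.0, "pico": 1.0}


def mean_size_index(pigments: pd.DataFrame) -> pd.DataFrame:
    """Per-sample micro/nano/pico fractions and the mean size class.

    The seven diagnostic pigments are combined with the standard
    weights; fractions normalise to 1 and the index is their weighted mean
    of the class tags micro=3, nano=2, pico=1.  Samples with all seven
    pigments zero get NaN.
    """
    needed = sorted({p for w in SIZE_WEIGHTS.values() for p in w})
    missing = [p for p in needed if p not in pigments.columns]
    if missing:
        raise ValueError(f"pigment table lacks diagnostic pigments: {missing}")
    parts = {
        cls: sum(w * pigments[p].to_numpy(float) for p, w in weights.items())
        for cls, weights in SIZE_WEIGHTS.items()
    }
    total = sum(parts.values())
    out = pd.DataFrame(index=pigments.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        for cls in ("micro", "nano", "pico"):
            out[f"{cls}_fraction"] = np.where(total > 0, parts[cls] / total, np.nan)
        out["size_index"] = sum(
            _SIZE_TAG[cls] * out[f"{cls}_fraction"] for cls in _SIZE_TAG
        )
    return out
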