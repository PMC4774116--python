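"""Accuracy metrics for predicted abundance profiles, and sample clustering.

All metrics are computed over the union of taxa of the predicted and true
tables, with absent taxa filled as zero; they are therefore symmetric under
exchanging prediction and truth. "Within 1 % deviation" means an absolute
deviation of at most 0.01 in relative-abundance units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy

__all__ = [
    "EvalReport",
    "rmse",
    "mean_absolute_error",
    "within_deviation",
    "pearson",
    "evaluate_profile",
    "ClusterResult",
    "cluster_samples",
]


def _union_vectors(
    pred: Mapping[str, float], truth: Mapping[str, float]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    taxa = sorted(set(pred) | set(truth))
    if not taxa:
        raise ValueError("both abundance maps are empty")
    p = np.array([pred.get(t, 0.0) for t in taxa])
    q = np.array([truth.get(t, 0.0) for t in taxa])
    return taxa, p, q


def rmse(pred: Mapping[str, float], truth: Mapping[str, float]) -> float:
    """Root-mean-square error over the union taxa."""
    _, p, q = _union_vectors(pred, truth)
    return float(np.sqrt(np.mean((p - q) ** 2)))


def mean_absolute_error(pred: Mapping[str, float], truth: Mapping[str, float]) -> float:
    _, p, q = _union_vectors(pred, truth)
    return float(np.mean(np.abs(p - q)))


def absolute_deviations(
    pred: Mapping[str, float], truth: Mapping[str, float]
) -> dict[str, float]:
    taxa, p, q = _union_vectors(pred, truth)
    return dict(zip(taxa, np.abs(p - q)))


def within_deviation(
    pred: Mapping[str, float], truth: Mapping[str, float], tol: float = 0.01
) -> float:
    """Fraction of truth taxa whose predicted abundance is within ``tol``
    (inclusive) of the true value; taxa absent from pred count as 0."""
    if not truth:
        raise ValueError("truth table is empty")
    eps = 1e-12  # keep the inclusive boundary robust to float rounding
    ok = sum(1 for t, v in truth.items() if abs(pred.get(t, 0.0) - v) <= tol + eps)
    return ok / len(truth)


def pearson(pred: Mapping[str, float], truth: Mapping[str, float]) -> float:
    """Pearson product-moment correlation over the union-taxa vectors.

    NaN (with a warning) when either vector has zero variance.
    """
    _, p, q = _union_vectors(pred, truth)
    if len(p) < 2:
        raise ValueError("need at least two taxa in the union")
    if np.ptp(p) == 0 or np.ptp(q) == 0:
        warnings.warn("zero variance: Pearson correlation undefined", stacklevel=2)
        return math.nan
    return float(sps.pearsonr(p, q).statistic)


@dataclass
class EvalReport:
    """Per-level accuracy of one predicted profile against its truth."""

    rmse: dict[str, float]
    mae: dict[str, float]
    deviations: dict[str, dict[str, float]]
    pearson_r: dict[str, float]
    fraction_within_1pct: dict[str, float]

    def to_rows(self) -> list[tuple[str, float, float, float, float]]:
        return [
            (level, self.rmse[level], self.mae[level], self.pearson_r[level],
             self.fraction_within_1pct[level])
            for level in self.rmse
        ]


def evaluate_profile(profile, truth_levels: Mapping[str, Mapping[str, float]],
                     tol: float = 0.01) -> EvalReport:
    """Score an AbundanceProfile (or any object with ``rel_abundance``)
    against per-level truth tables."""
    rel = profile.rel_abundance if hasattr(profile, "rel_abundance") else profile
    out_rmse, out_mae, out_dev, out_r, out_frac = {}, {}, {}, {}, {}
    for level, truth in truth_levels.items():
        pred = rel.get(level, {})
        out_rmse[level] = rmse(pred, truth)
        out_mae[level] = mean_absolute_error(pred, truth)
        out_dev[level] = absolute_deviations(pred, truth)
        out_r[level] = pearson(pred, truth)
        out_frac[level] = within_deviation(pred, truth, tol)
    return EvalReport(rmse=out_rmse, mae=out_mae, deviations=out_dev,
                      pearson_r=out_r, fraction_within_1pct=out_frac)


@dataclass
class ClusterResult:
    sample_ids: list[str]  # input order of the distance matrix (sorted)
    taxa: list[str]
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str


def _to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    body = render(tree, tree.dist)
    # strip the root's zero-length branch
    return body.rsplit(":", 1)[0] + ";"


def cluster_samples(
    profiles: Sequence, level: str = "family", min_abundance: float = 0.005,
    min_prevalence: float = 0.25
) -> ClusterResult:
    """Ward-linkage hierarchical clustering of samples on 1 − Spearman
    correlation of their abundance profiles.

    At species level, only species reaching ``min_abundance`` in at least
    ``min_prevalence`` of the samples are used as features; at family level
    all detected taxa are kept. Samples are ordered by sample_id before
    computing distances, so the leaf order is deterministic.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to cluster")
    profiles = sorted(profiles, key=lambda p: p.sample_id)
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id among profiles")
    tables = [p.rel_abundance[level] for p in profiles]
    taxa = sorted(set().union(*tables))
    if level == "species":
        need = math.ceil(min_prevalence * len(profiles))
        taxa = [t for t in taxa
                if sum(tab.get(t, 0.0) >= min_abundance for tab in tables) >= need]
    if len(taxa) < 2:
        raise ValueError("fewer than two taxa survive the feature filter")
    X = np.array([[tab.get(t, 0.0) for t in taxa] for tab in tables])
    for i, row in enumerate(X):
        if np.ptp(row) == 0:
            raise ValueError(
                f"sample {ids[i]!r} has a constant abundance vector; "
                "Spearman correlation undefined"
            )
    rho = sps.spearmanr(X.T).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two samples
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(len(ids), k=1)]
    linkage = hierarchy.ward(condensed)
    order = hierarchy.leaves_list(linkage)
    return ClusterResult(
        sample_ids=ids,
        taxa=taxa,
        linkage=linkage,
        leaf_order=[ids[i] for i in order],
        newick=_to_newick(linkage, ids),
    )
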