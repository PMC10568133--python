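"""Tri-omic feature integration and Gini-importance feature selection.

Three feature blocks are concatenated per timepoint — NMR latent variables,
sample coordinates on the leading PCoA axes of the taxonomic profile, and
functional-pathway abundances — then standard scaled column-wise.  An
extremely-randomized-trees classifier discriminating the treatment groups
assigns each feature its Gini importance (mean decrease in impurity,
node-weighted, averaged over the ensemble); features whose normalized
importance is strictly greater than the mean importance — i.e. strictly
greater than 1/p — are selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier

from .diversity import OrdinationResult
from .io import AbundanceTable, LatentVariableMatrix, SampleMetadata

__all__ = [
    "IntegratedFeatureMatrix",
    "ImportanceReport",
    "integrate_features",
    "standard_scale",
    "gini_importance",
    "select_features",
]

BLOCK_LV = "LV"
BLOCK_MDS = "MDS_AXIS"
BLOCK_PATHWAY = "PATHWAY"


@dataclass
class IntegratedFeatureMatrix:
    """Standard-scaled per-timepoint feature matrix with block labels."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    blocks: dict[str, str]
    timepoint: str
    constant_features: set[str] = field(default_factory=set)

    def block_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.feature_ids:
            counts[self.blocks[f]] = counts.get(self.blocks[f], 0) + 1
        return counts

    def subset_features(self, feature_ids: Sequence[str]) -> "IntegratedFeatureMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return IntegratedFeatureMatrix(
            sample_ids=list(self.sample_ids),
            feature_ids=list(feature_ids),
            values=self.values[:, idx],
            blocks={f: self.blocks[f] for f in feature_ids},
            timepoint=self.timepoint,
            constant_features=self.constant_features & set(feature_ids),
        )


@dataclass
class ImportanceReport:
    feature_ids: list[str]
    importance: np.ndarray  # normalized, sums to 1
    threshold: float  # mean importance = 1/p
    selected: np.ndarray  # boolean, importance strictly > threshold
    n_trees: int
    seed: int

    def selected_ids(self) -> list[str]:
        return [f for f, s in zip(self.feature_ids, self.selected) if s]


def standard_scale(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise z-scoring; constant columns become all-zero and flagged.

    Returns the scaled matrix and a boolean mask of constant columns.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    constant = sd == 0
    safe_sd = np.where(constant, 1.0, sd)
    scaled = (values - mean) / safe_sd
    scaled[:, constant] = 0.0
    return scaled, constant


def integrate_features(
    lv: LatentVariableMatrix,
    ordination: OrdinationResult,
    pathways: AbundanceTable,
    meta: SampleMetadata,
    timepoint: str,
    n_mds_axes: int | None = None,
) -> IntegratedFeatureMatrix:
    """Concatenate and standard scale the three feature blocks of a timepoint.

    Sample order follows the metadata; a mismatch between the blocks'
    sample sets is an error listing the missing ids rather than a silent
    intersection.
    """
    samples = meta.samples_at(timepoint)
    for name, have in [
        ("latent variables", set(lv.sample_ids)),
        ("ordination", set(ordination.sample_ids)),
        ("pathways", set(pathways.sample_ids)),
    ]:
        missing = set(samples) - have
        if missing:
            raise ValueError(
                f"{name} block is missing samples {sorted(missing)} at {timepoint}"
            )

    lv = lv.subset_samples(samples)
    pathways = pathways.subset_samples(samples)
    ord_pos = {s: i for i, s in enumerate(ordination.sample_ids)}
    n_axes = ordination.coordinates.shape[1]
    if n_mds_axes is not None:
        n_axes = min(n_mds_axes, n_axes)
    coords = ordination.coordinates[[ord_pos[s] for s in samples], :n_axes]
    axis_ids = ordination.axis_ids[:n_axes]

    feature_ids = list(lv.lv_ids) + list(axis_ids) + list(pathways.feature_ids)
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError("feature ids collide across blocks")
    blocks = (
        {f: BLOCK_LV for f in lv.lv_ids}
        | {f: BLOCK_MDS for f in axis_ids}
        | {f: BLOCK_PATHWAY for f in pathways.feature_ids}
    )
    raw = np.hstack([lv.scores, coords, pathways.values])
    scaled, constant = standard_scale(raw)
    return IntegratedFeatureMatrix(
        sample_ids=list(samples),
        feature_ids=feature_ids,
        values=scaled,
        blocks=blocks,
        timepoint=timepoint,
        constant_features={f for f, c in zip(feature_ids, constant) if c},
    )


def gini_importance(
    X: IntegratedFeatureMatrix,
    y: Sequence[str],
    n_trees: int = 500,
    seed: int = 42,
) -> ImportanceReport:
    """Gini importances from an extra-trees group classifier.

    The ensemble uses randomized split thresholds on sqrt(p) candidate
    features per node, no bootstrap (every tree sees all samples), and
    unlimited depth.  Per-feature importance is the impurity decrease at
    each node splitting on the feature, weighted by the fraction of samples
    reaching the node, averaged over trees, then normalized to sum to one.
    Constant (zero-variance) columns are excluded from the fit and assigned
    importance zero.
    """
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise ValueError("need at least two classes to compute discriminative importance")
    if n_trees < 1:
        raise ValueError("n_trees must be positive")
    usable = np.array([f not in X.constant_features for f in X.feature_ids])
    clf = ExtraTreesClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=False,
        random_state=seed,
    )
    clf.fit(X.values[:, usable], y)
    importance = np.zeros(len(X.feature_ids))
    importance[usable] = clf.feature_importances_
    total = importance.sum()
    if total > 0:
        importance = importance / total
    threshold = float(importance.mean())
    return ImportanceReport(
        feature_ids=list(X.feature_ids),
        importance=importance,
        threshold=threshold,
        selected=importance > threshold,
        n_trees=n_trees,
        seed=seed,
    )


def select_features(report: ImportanceReport) -> list[str]:
    """Features with importance strictly greater than the ensemble mean.

    With normalized importances the mean is exactly 1/p, so an exactly
    uniform importance vector (or a single feature) selects nothing.
    """
    return [
        f
        for f, imp in zip(report.feature_ids, report.importance)
        if imp > report.threshold
    ]
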