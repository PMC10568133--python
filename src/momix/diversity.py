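"""Alpha/beta diversity and per-feature differential-abundance statistics.

Alpha diversity is the Gini–Simpson index 1 - sum(p_i^2); beta diversity is
Bray–Curtis dissimilarity (Euclidean is available for non-compositional
blocks); ordination is classical scaling (PCoA) of the double-centered
squared-distance matrix.  Group differences are tested per feature with the
tie-corrected Kruskal–Wallis H and corrected across features by
Benjamini–Hochberg at FDR <= 0.05 (Bonferroni available as an alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.spatial.distance as ssd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "DifferentialResult",
    "simpson_index",
    "bray_curtis",
    "distance_matrix",
    "pcoa",
    "correlate_axes_with_species",
    "kruskal_wallis",
    "benjamini_hochberg",
    "differential_abundance",
]


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if np.any(np.abs(self.values - self.values.T) > 1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diagonal(self.values) != 0.0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise ValueError("negative distances")


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes, axis j scaled by sqrt(eigval j)
    eigenvalues: np.ndarray  # descending, positive only
    variance_explained: np.ndarray
    axis_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.axis_ids:
            self.axis_ids = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]


@dataclass
class DifferentialResult:
    feature_id: str
    H: float
    p_raw: float
    p_adjusted: float
    significant: bool


def simpson_index(abundances: Sequence[float]) -> float:
    """Gini–Simpson diversity 1 - sum(p_i^2) of a community profile.

    Proportions are renormalized internally, so the index is invariant to
    the overall scale of the input counts.
    """
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector has no defined diversity")
    p = x / total
    return float(1.0 - np.sum(p**2))


def bray_curtis(a: Sequence[float], b: Sequence[float]) -> float:
    """Bray–Curtis dissimilarity sum|a-b| / sum(a+b) in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("abundances must be non-negative")
    denom = float(np.sum(a + b))
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.sum(np.abs(a - b)) / denom)


def distance_matrix(table: AbundanceTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """All-pairs sample distances for an abundance table."""
    scipy_metric = {"bray_curtis": "braycurtis", "euclidean": "euclidean"}[metric]
    condensed = ssd.pdist(table.values, metric=scipy_metric)
    return DistanceMatrix(list(table.sample_ids), ssd.squareform(condensed))


def pcoa(d: DistanceMatrix, n_axes: int) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Eigendecomposition of -1/2 J D^2 J with J the centering matrix; axes are
    eigenvectors scaled by sqrt(eigenvalue), kept in descending eigenvalue
    order.  Axes with non-positive eigenvalues (possible for non-Euclidean
    dissimilarities such as Bray–Curtis) are discarded; asking for more axes
    than are available yields fewer axes with a warning.
    """
    n = len(d.sample_ids)
    if n_axes < 1:
        raise ValueError("n_axes must be positive")
    if n_axes > n - 1:
        raise ValueError("n_axes must be at most n_samples - 1")
    D2 = d.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10 * max(eigvals.max(), 1.0)
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        warnings.warn(
            f"only {n_pos} positive-eigenvalue axes available; "
            f"returning {n_pos} instead of {n_axes}",
            stacklevel=2,
        )
    k = min(n_axes, n_pos)
    lam = eigvals[:k]
    coords = eigvecs[:, :k] * np.sqrt(lam)
    total = float(eigvals[eigvals > 0].sum())
    var_exp = lam / total if total > 0 else np.zeros(k)
    return OrdinationResult(list(d.sample_ids), coords, lam, var_exp)


def correlate_axes_with_species(
    ordination: OrdinationResult, taxa: AbundanceTable
) -> dict[tuple[str, str], tuple[float | None, float | None]]:
    """Spearman rank correlation of each ordination axis with each species.

    Constant species vectors yield an undefined marker ``(None, None)``
    rather than propagating NaN.
    """
    if list(ordination.sample_ids) != list(taxa.sample_ids):
        taxa = taxa.subset_samples(ordination.sample_ids)
    out: dict[tuple[str, str], tuple[float | None, float | None]] = {}
    for j, axis in enumerate(ordination.axis_ids):
        coord = ordination.coordinates[:, j]
        for i, sp in enumerate(taxa.feature_ids):
            vec = taxa.values[:, i]
            if np.all(vec == vec[0]):
                out[(axis, sp)] = (None, None)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho, p = sps.spearmanr(coord, vec)
            out[(axis, sp)] = (float(rho), float(p))
    return out


def kruskal_wallis(values: Sequence[float], groups: Sequence[str]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square p (k-1 df).

    Identical values across all groups give H = 0, p = 1 instead of the
    undefined tie-correction division.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    if np.all(values == values[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*samples)
    return float(H), float(p)


def benjamini_hochberg(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Step-up FDR adjustment; significant where adjusted p <= q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, adjusted <= q


def bonferroni(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni family-wise correction, the conservative alternative."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.minimum(p * p.size, 1.0)
    return adjusted, adjusted <= q


def differential_abundance(
    table: AbundanceTable,
    groups: Sequence[str],
    fdr_threshold: float = 0.05,
    method: str = "benjamini_hochberg",
) -> list[DifferentialResult]:
    """Per-feature Kruskal–Wallis across groups with multiplicity correction."""
    stats = [kruskal_wallis(table.values[:, i], groups) for i in range(len(table.feature_ids))]
    H = np.array([s[0] for s in stats])
    p = np.array([s[1] for s in stats])
    correct = {"benjamini_hochberg": benjamini_hochberg, "bonferroni": bonferroni}[method]
    p_adj, sig = correct(p, fdr_threshold)
    return [
        DifferentialResult(fid, float(H[i]), float(p[i]), float(p_adj[i]), bool(sig[i]))
        for i, fid in enumerate(table.feature_ids)
    ]
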