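"""Closed-form statistics against independent brute-force oracles."""

from collections import Counter
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from momix.diversity import (
    DistanceMatrix,
    benjamini_hochberg,
    bonferroni,
    bray_curtis,
    correlate_axes_with_species,
    distance_matrix,
    kruskal_wallis,
    pcoa,
    simpson_index,
)
from momix.io import AbundanceTable

# ---------------------------------------------------------------------------
# oracles


def simpson_oracle(xs) -> Fraction:
    """Exact Gini-Simpson on rationals."""
    xs = [Fraction(x) for x in xs]
    total = sum(xs)
    return 1 - sum((x / total) ** 2 for x in xs)


def bray_curtis_oracle(a, b) -> Fraction:
    a, b = [Fraction(x) for x in a], [Fraction(x) for x in b]
    return sum(abs(x - y) for x, y in zip(a, b)) / sum(x + y for x, y in zip(a, b))


def kruskal_oracle(values, groups):
    """Midrank enumeration of the tie-corrected H statistic."""
    N = len(values)
    sv = sorted(values)
    ranks = [
        sum(j + 1 for j, x in enumerate(sv) if x == v) / sv.count(v) for v in values
    ]
    labels = sorted(set(groups))
    H = 0.0
    for lab in labels:
        rs = [r for r, g in zip(ranks, groups) if g == lab]
        H += len(rs) * (np.mean(rs) - (N + 1) / 2) ** 2
    H *= 12 / (N * (N + 1))
    tie = 1 - sum(t**3 - t for t in Counter(values).values()) / (N**3 - N)
    return 0.0 if tie == 0 else H / tie


def bh_oracle(p, q):
    """Step-up adjustment by direct definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted, [a <= q for a in adjusted]


# ---------------------------------------------------------------------------
# Simpson index


@pytest.mark.parametrize(
    "vec,expected",
    [
        ((1, 0, 0), 0.0),
        ((0.5, 0.5), 0.5),
        ((0.7, 0.1, 0.1, 0.1), 0.48),
    ],
)
def test_simpson_known_values(vec, expected):
    assert simpson_index(vec) == pytest.approx(expected, abs=1e-12)


def test_simpson_matches_exact_oracle_small_inputs(rng):
    for _ in range(200):
        n = rng.integers(1, 13)
        vec = rng.integers(0, 20, size=n)
        if vec.sum() == 0:
            continue
        assert simpson_index(vec) == pytest.approx(
            float(simpson_oracle(vec.tolist())), abs=1e-14
        )


@given(
    st.lists(st.floats(0.01, 100), min_size=1, max_size=12),
    st.floats(0.01, 1000),
)
@settings(max_examples=50, deadline=None)
def test_simpson_scale_invariant(vec, c):
    assert simpson_index([c * x for x in vec]) == pytest.approx(
        simpson_index(vec), abs=1e-9
    )


def test_simpson_rejects_all_zero():
    with pytest.raises(ValueError):
        simpson_index([0.0, 0.0])


def test_simpson_agrees_with_scikit_bio(rng):
    skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
    counts = rng.integers(0, 50, size=10)
    counts[0] = 5
    assert simpson_index(counts) == pytest.approx(
        float(skbio_alpha.simpson(counts)), abs=1e-12
    )


# ---------------------------------------------------------------------------
# Bray-Curtis


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((1, 2, 3), (1, 2, 3), 0.0),
        ((1, 0), (0, 1), 1.0),
        ((2, 1, 0), (1, 1, 1), 1 / 3),
    ],
)
def test_bray_curtis_known_values(a, b, expected):
    assert bray_curtis(a, b) == pytest.approx(expected, abs=1e-12)


def test_bray_curtis_matches_exact_oracle(rng):
    for _ in range(200):
        n = rng.integers(1, 13)
        a = rng.integers(0, 10, size=n)
        b = rng.integers(0, 10, size=n)
        if (a + b).sum() == 0:
            continue
        assert bray_curtis(a, b) == pytest.approx(
            float(bray_curtis_oracle(a.tolist(), b.tolist())), abs=1e-14
        )


@given(
    st.lists(st.floats(0, 10), min_size=2, max_size=10),
    st.lists(st.floats(0, 10), min_size=2, max_size=10),
)
@settings(max_examples=50, deadline=None)
def test_bray_curtis_symmetry_and_identity(a, b):
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    if sum(a) + sum(b) == 0:
        return
    assert bray_curtis(a, b) == pytest.approx(bray_curtis(b, a), abs=1e-12)
    if sum(a) > 0:
        assert bray_curtis(a, a) == 0.0
    assert 0.0 <= bray_curtis(a, b) <= 1.0


def test_bray_curtis_length_mismatch():
    with pytest.raises(ValueError):
        bray_curtis([1, 2], [1, 2, 3])


# ---------------------------------------------------------------------------
# PCoA


def _euclidean_dm(points):
    from scipy.spatial.distance import pdist, squareform

    ids = [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(ids, squareform(pdist(points)))


def test_pcoa_reconstructs_euclidean_distances(rng):
    points = rng.normal(size=(6, 2))
    dm = _euclidean_dm(points)
    res = pcoa(dm, n_axes=5)
    from scipy.spatial.distance import pdist, squareform

    rec = squareform(pdist(res.coordinates))
    assert np.allclose(rec, dm.values, atol=1e-8)


def test_pcoa_two_samples_closed_form():
    dm = DistanceMatrix(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]]))
    res = pcoa(dm, 1)
    assert res.coordinates.shape == (2, 1)
    assert abs(res.coordinates[0, 0] - res.coordinates[1, 0]) == pytest.approx(3.0)


def test_pcoa_equilateral_distances_give_equal_eigenvalues():
    d = np.ones((3, 3)) - np.eye(3)
    res = pcoa(DistanceMatrix(["a", "b", "c"], d), 2)
    assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-9)


def test_pcoa_warns_when_axes_unavailable():
    # three samples on a line: only one positive axis, asking for two warns
    pts = np.array([[0.0], [1.0], [2.0]])
    with pytest.warns(UserWarning, match="positive-eigenvalue"):
        res = pcoa(_euclidean_dm(pts), 2)
    assert res.coordinates.shape[1] == 1


def test_pcoa_matches_scikit_bio(rng):
    skbio_ord = pytest.importorskip("skbio.stats.ordination")
    import skbio

    points = rng.normal(size=(8, 3))
    dm = _euclidean_dm(points)
    ours = pcoa(dm, 3)
    theirs = skbio_ord.pcoa(skbio.DistanceMatrix(dm.values, ids=dm.sample_ids))
    assert np.allclose(
        np.abs(ours.coordinates),
        np.abs(theirs.samples.values[:, :3]),
        atol=1e-6,
    )


def test_distance_matrix_bray_curtis_range():
    table = AbundanceTable(
        ["a", "b", "c"],
        ["x", "y"],
        np.array([[0.5, 0.5], [0.9, 0.1], [0.1, 0.9]]),
        "TAXON",
    )
    dm = distance_matrix(table)
    assert np.all(dm.values >= 0) and np.all(dm.values <= 1)
    assert dm.values[0, 1] == pytest.approx(bray_curtis([0.5, 0.5], [0.9, 0.1]))


# ---------------------------------------------------------------------------
# axis-species correlation


def test_correlation_monotone_identity_and_constant_marker(rng):
    points = rng.normal(size=(10, 2))
    dm = _euclidean_dm(points)
    res = pcoa(dm, 2)
    monotone = np.exp(res.coordinates[:, 0])  # rank-preserving transform
    values = np.column_stack([monotone, np.full(10, 0.3)])
    values = values / values.sum(axis=1, keepdims=True)
    # keep the raw monotone column unnormalized to preserve ranks
    taxa = AbundanceTable(res.sample_ids, ["mono", "flat"],
                          np.column_stack([monotone, np.full(10, 0.3)]), "PATHWAY")
    out = correlate_axes_with_species(res, taxa)
    rho, p = out[("axis1", "mono")]
    assert rho == pytest.approx(1.0)
    assert out[("axis1", "flat")] == (None, None)


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def test_kruskal_identical_values_gives_zero():
    assert kruskal_wallis([2.0] * 6, ["a", "a", "b", "b", "c", "c"]) == (0.0, 1.0)


def test_kruskal_separated_groups():
    H, p = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
    oracle = kruskal_oracle([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
    assert H == pytest.approx(oracle, abs=1e-12)
    assert p < 0.1


def test_kruskal_tie_correction_matches_midrank_oracle():
    values = [1, 1, 2, 2, 3, 3]
    groups = ["a", "a", "a", "b", "b", "b"]
    H, _ = kruskal_wallis(values, groups)
    assert H == pytest.approx(kruskal_oracle(values, groups), abs=1e-12)


def test_kruskal_matches_oracle_exhaustive_small_instances():
    """Every assignment of values from {1,2,3} to two small groups."""
    from itertools import product

    groups = ["a", "a", "a", "b", "b"]
    for values in product([1, 2, 3], repeat=5):
        ours = kruskal_wallis(list(values), groups)[0]
        assert ours == pytest.approx(kruskal_oracle(list(values), groups), abs=1e-10)


def test_kruskal_matches_oracle_random_instances(rng):
    for _ in range(100):
        n = int(rng.integers(4, 13))
        values = rng.integers(0, 6, size=n).astype(float).tolist()
        groups = rng.choice(["a", "b", "c"], size=n).tolist()
        if len(set(groups)) < 2 or len(set(values)) == 1:
            continue
        assert kruskal_wallis(values, groups)[0] == pytest.approx(
            kruskal_oracle(values, groups), abs=1e-10
        )


def test_kruskal_contract_errors():
    with pytest.raises(ValueError):
        kruskal_wallis([1, 2, 3], ["a", "a", "a"])


# ---------------------------------------------------------------------------
# multiple testing


def test_bh_hand_computed_example():
    adjusted, sig = benjamini_hochberg([0.01, 0.02, 0.04], q=0.05)
    assert np.allclose(adjusted, [0.03, 0.03, 0.04])
    assert sig.all()


def test_bh_tied_and_single():
    adjusted, _ = benjamini_hochberg([0.5] * 10, q=0.05)
    assert np.allclose(adjusted, 0.5)
    adjusted, _ = benjamini_hochberg([0.123], q=0.05)
    assert adjusted[0] == pytest.approx(0.123)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
@settings(max_examples=100, deadline=None)
def test_bh_matches_step_up_oracle(p):
    adjusted, sig = benjamini_hochberg(p, q=0.05)
    oracle_adj, oracle_sig = bh_oracle(p, 0.05)
    assert np.allclose(adjusted, oracle_adj, atol=1e-12)
    assert list(sig) == oracle_sig
    # monotone non-decreasing in sorted-p order, never below the raw p
    order = np.argsort(p)
    assert np.all(np.diff(adjusted[order]) >= -1e-12)
    assert np.all(adjusted >= np.asarray(p) - 1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.5])


def test_bonferroni_alternative():
    adjusted, sig = bonferroni([0.01, 0.2], q=0.05)
    assert np.allclose(adjusted, [0.02, 0.4])
    assert list(sig) == [True, False]
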