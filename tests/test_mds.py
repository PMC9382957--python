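"""Scaling machinery: Torgerson initialisation, SMACOF majorization,
stress-1 properties, orientation, and a reference cross-check."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from emovocab import classical_mds, orient, smacof, to_dissimilarity
from emovocab.matrices import SimilarityMatrix
from emovocab.mds import DissimilarityMatrix, _pava, kruskal_stress


def _planar_config(n=20, seed=0, scale=0.2):
    rng = np.random.default_rng(seed)
    return rng.uniform(-scale, scale, size=(n, 2))


def _dissim_from_points(X):
    d = squareform(pdist(X))
    return d / d.max()


# --- dissimilarity transform --------------------------------------------

def test_to_dissimilarity_endpoints_and_midpoint():
    ids = [1, 2, 3]
    n_pairs = np.full((3, 3), 10)
    s = np.array([[10, 10, 0], [10, 10, 5], [0, 5, 10]])
    d = to_dissimilarity(SimilarityMatrix("g", ids, s, n_pairs))
    assert d.d[0, 1] == pytest.approx(0.0)  # always co-named
    assert d.d[0, 2] == pytest.approx(1.0)  # never co-named
    assert d.d[1, 2] == pytest.approx(0.5)
    assert np.allclose(np.diag(d.d), 0.0)


def test_to_dissimilarity_rejects_empty_pairs():
    n_pairs = np.array([[2, 0], [0, 2]])
    s = np.zeros((2, 2), dtype=int)
    with pytest.raises(ValueError):
        to_dissimilarity(SimilarityMatrix("g", [1, 2], s, n_pairs))


# --- classical scaling ---------------------------------------------------

def test_classical_recovers_planar_distances():
    X = _planar_config(seed=4)
    d = squareform(pdist(X))
    Y = classical_mds(d, k=2)
    assert np.allclose(pdist(Y), pdist(X), atol=1e-8)


def test_classical_collinear_points_have_flat_second_axis():
    pts = np.array([[0.0], [1.0], [2.5], [4.0]])
    d = squareform(pdist(pts))
    Y = classical_mds(d, k=2)
    assert np.abs(Y[:, 1]).max() < 1e-6


def test_classical_equilateral_triangle_symmetric():
    d = np.ones((3, 3)) - np.eye(3)
    Y = classical_mds(d, k=2)
    dists = pdist(Y)
    assert np.allclose(dists, dists[0])


# --- PAVA ----------------------------------------------------------------

def test_pava_is_monotone_least_squares():
    y = np.array([1.0, 3.0, 2.0, 4.0, 0.0])
    fit = _pava(y)
    assert np.all(np.diff(fit) >= 0)
    # PAVA of a sorted array is the array itself
    s = np.sort(y)
    assert np.allclose(_pava(s), s)
    # and total squared error never exceeds naive flat fit
    assert ((fit - y) ** 2).sum() <= ((y.mean() - y) ** 2).sum() + 1e-12


def test_pava_pools_violators_to_block_means():
    assert np.allclose(_pava(np.array([2.0, 1.0])), [1.5, 1.5])
    assert np.allclose(_pava(np.array([3.0, 1.0, 2.0])), [2.0, 2.0, 2.0])


# --- SMACOF --------------------------------------------------------------

@pytest.mark.parametrize("nonmetric", [True, False])
def test_smacof_zero_stress_on_embeddable_input(nonmetric):
    d = _dissim_from_points(_planar_config(seed=1))
    res = smacof(d, k=2, nonmetric=nonmetric)
    assert res.stress < 1e-6
    assert res.converged


def test_smacof_stress_sequence_non_increasing():
    rng = np.random.default_rng(5)
    d = _dissim_from_points(_planar_config(seed=2))
    noisy = np.clip(d + rng.normal(0, 0.05, d.shape), 0, 1)
    noisy = (noisy + noisy.T) / 2
    np.fill_diagonal(noisy, 0)
    res = smacof(noisy, k=2)
    diffs = np.diff(res.stress_history)
    assert (diffs <= 1e-8).all()


def test_smacof_low_stress_under_one_percent_noise():
    rng = np.random.default_rng(6)
    X = _planar_config(seed=6)
    d = squareform(pdist(X))
    d *= rng.normal(1.0, 0.01, d.shape)  # 1% multiplicative noise
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    res = smacof(d / d.max(), k=2)
    assert res.stress < 0.05


def test_smacof_stress_invariant_under_similarity_transform():
    d = _dissim_from_points(_planar_config(seed=7))
    res = smacof(d, k=2, max_iter=50)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    transformed = 3.0 * res.coords @ R
    dist = pdist(transformed)
    # recompute disparities for the transformed configuration
    from emovocab.mds import _disparities
    from scipy.spatial.distance import squareform as sf
    delta = sf(np.asarray(d.d if hasattr(d, "d") else d), checks=False)
    base_dist = pdist(res.coords)
    s1 = kruskal_stress(_disparities(delta, base_dist, True), base_dist)
    s2 = kruskal_stress(_disparities(delta, dist, True), dist)
    assert s1 == pytest.approx(s2, abs=1e-9)


def test_smacof_rejects_bad_inputs():
    d = np.full((4, 4), np.nan)
    with pytest.raises(ValueError):
        smacof(d)
    good = _dissim_from_points(_planar_config(n=5, seed=3))
    with pytest.raises(ValueError):
        smacof(good, init=np.zeros((3, 2)))


def test_smacof_agrees_with_reference_solver():
    """Independent check: sklearn's SMACOF reaches a comparable metric
    stress on the same noisy input."""
    from sklearn.manifold import smacof as sk_smacof

    rng = np.random.default_rng(8)
    d = _dissim_from_points(_planar_config(seed=8))
    noisy = np.clip(d + rng.normal(0, 0.03, d.shape), 0.0, 1.0)
    noisy = (noisy + noisy.T) / 2
    np.fill_diagonal(noisy, 0)
    ours = smacof(noisy, k=2, nonmetric=False)
    _, sk_raw = sk_smacof(noisy, n_components=2, random_state=0, n_init=4,
                          normalized_stress=False)
    # convert reference raw stress to stress-1 against the same input
    ours_raw = kruskal_stress(
        squareform(noisy, checks=False)
        * np.sqrt((pdist(ours.coords) ** 2).sum()
                  / (squareform(noisy, checks=False) ** 2).sum()),
        pdist(ours.coords),
    )
    assert ours_raw == pytest.approx(ours.stress, abs=1e-6)
    # our final configuration should fit at least as well as sklearn's
    # within a small slack
    sk_stress1 = np.sqrt(
        2 * sk_raw / (squareform(noisy, checks=False) ** 2).sum()
    )
    assert ours.stress <= sk_stress1 * 1.10 + 1e-6


# --- orientation ---------------------------------------------------------

def _valence_result(seed=9):
    pos = _planar_config(n=10, seed=seed) + np.array([1.0, 0.0])
    neg = _planar_config(n=10, seed=seed + 1) - np.array([1.0, 0.0])
    X = np.vstack([pos, neg])
    val = np.array([1] * 10 + [-1] * 10)
    d = _dissim_from_points(X)
    return smacof(d, k=2), val


def test_orient_puts_positive_centroid_right():
    res, val = _valence_result()
    oriented = orient(res, val)
    assert oriented.coords[val > 0, 0].mean() > 0
    assert oriented.coords[val < 0, 0].mean() < 0


def test_orient_invariant_to_input_reflection():
    import dataclasses

    res, val = _valence_result()
    flipped = dataclasses.replace(res, coords=-res.coords.copy())
    a = orient(res, val)
    b = orient(flipped, val)
    assert np.allclose(np.abs(a.coords), np.abs(b.coords), atol=1e-6)
    assert np.sign(a.coords[0, 0]) == np.sign(b.coords[0, 0])


def test_orient_requires_both_valences():
    res, _ = _valence_result()
    with pytest.raises(ValueError):
        orient(res, np.ones(20))


def test_orient_separates_clean_valence_clusters():
    """Two tight valence clusters give near-perfect separation on axis 1."""
    res, val = _valence_result(seed=12)
    oriented = orient(res, val)
    x = oriented.coords[:, 0]
    # silhouette-style check on the first axis only
    from sklearn.metrics import silhouette_score
    score = silhouette_score(x.reshape(-1, 1), val)
    assert score > 0.5
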