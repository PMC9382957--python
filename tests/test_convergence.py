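"""Vocabulary ANOVA, Spearman convergence (against a brute-force
average-rank oracle), and the Fisher r-to-z comparison."""

import itertools

import numpy as np
import pytest
from scipy import stats

from emovocab import fisher_z_test, matrix_convergence, per_word_convergence, vocab_stats
from emovocab.coding import CodedResponse
from emovocab.matrices import ProductionMatrix


def _pm(counts, words=None, group="child"):
    counts = np.atleast_2d(np.asarray(counts))
    words = words or [f"w{j}" for j in range(counts.shape[1])]
    return ProductionMatrix(group, list(range(1, counts.shape[0] + 1)), words, counts)


def _average_ranks(x):
    """Brute-force average ranks, ties share the mean of their positions."""
    x = np.asarray(x, dtype=float)
    ranks = np.empty_like(x)
    order = sorted(range(len(x)), key=lambda i: x[i])
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        mean_rank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def _spearman_oracle(x, y):
    rx, ry = _average_ranks(x), _average_ranks(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def test_matrix_convergence_of_matrix_with_itself_is_one():
    m = _pm([[0, 1, 3], [2, 0, 5]])
    res = matrix_convergence(m, _pm([[0, 1, 3], [2, 0, 5]], group="adult"))
    assert res.rho == pytest.approx(1.0)
    assert res.n_cells == 6


def test_matrix_convergence_rank_reversal_is_minus_one():
    child = _pm([[1, 2, 3], [4, 5, 6]])
    adult = _pm([[6, 5, 4], [3, 2, 1]], group="adult")
    assert matrix_convergence(child, adult).rho == pytest.approx(-1.0)


def test_matrix_convergence_shape_mismatch_raises():
    with pytest.raises(ValueError):
        matrix_convergence(_pm([[1, 2]]), _pm([[1, 2, 3]], group="adult"))


def test_matrix_convergence_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    child = _pm(rng.integers(0, 5, (4, 5)))
    adult = _pm(rng.integers(0, 5, (4, 5)), group="adult")
    base = matrix_convergence(child, adult).rho
    squared = _pm(child.counts ** 2)  # strictly monotone on counts >= 0
    assert matrix_convergence(squared, adult).rho == pytest.approx(base)


def test_matrix_convergence_matches_oracle_exhaustively():
    """All 2x2 matrices with counts in {0,1,2} against a fixed partner."""
    adult = _pm([[2, 0], [1, 2]], group="adult")
    for cells in itertools.product(range(3), repeat=4):
        child = _pm(np.array(cells).reshape(2, 2))
        x, y = child.counts.ravel(), adult.counts.ravel()
        if np.ptp(x) == 0:
            continue  # undefined correlation
        assert matrix_convergence(child, adult).rho == pytest.approx(
            _spearman_oracle(x, y)
        )


@pytest.mark.parametrize("seed", range(50))
def test_matrix_convergence_matches_oracle_random(seed):
    rng = np.random.default_rng(seed)
    shape = (rng.integers(2, 6), rng.integers(2, 8))
    child = _pm(rng.integers(0, 4, shape))
    adult = _pm(rng.integers(0, 4, shape), group="adult")
    x, y = child.counts.ravel(), adult.counts.ravel()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        pytest.skip("degenerate draw")
    assert matrix_convergence(child, adult).rho == pytest.approx(
        _spearman_oracle(x, y), abs=1e-12
    )


def test_per_word_convergence_identical_and_tied_vectors():
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 3, (20, 2))
    child = _pm(counts, words=["Ekel", "Angst"])
    adult = _pm(counts.copy(), words=["Ekel", "Angst"], group="adult")
    res = per_word_convergence(child, adult)
    assert res["Ekel"] == pytest.approx(1.0)
    assert res["Angst"] == pytest.approx(1.0)


def test_per_word_convergence_concentrated_word_scores_one():
    # child and adult both use the word for exactly the same single vignette
    child = np.zeros((20, 1), dtype=int)
    adult = np.zeros((20, 1), dtype=int)
    child[4, 0], adult[4, 0] = 3, 9
    res = per_word_convergence(_pm(child, words=["Ekel"]),
                               _pm(adult, words=["Ekel"], group="adult"))
    assert res["Ekel"] == pytest.approx(1.0)


def test_per_word_convergence_zero_variance_is_missing_not_zero():
    child = _pm(np.zeros((20, 1), dtype=int), words=["froh"])
    adult = _pm(np.ones((20, 1), dtype=int), words=["froh"], group="adult")
    assert np.isnan(per_word_convergence(child, adult)["froh"])


@pytest.mark.parametrize("seed", range(20))
def test_per_word_convergence_matches_oracle_with_ties(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 3, (20, 1))
    b = rng.integers(0, 3, (20, 1))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        pytest.skip("degenerate draw")
    res = per_word_convergence(_pm(a, words=["w"]), _pm(b, words=["w"], group="adult"))
    assert res["w"] == pytest.approx(_spearman_oracle(a.ravel(), b.ravel()))


# --- Fisher r-to-z -------------------------------------------------------

def test_fisher_z_published_comparisons():
    """The printed comparisons of adjacent age groups (rounded rhos,
    N = 1,320 cells each)."""
    res = fisher_z_test(0.443, 0.551, 1320, 1320)
    assert round(res.z, 1) == -3.7
    assert res.p_one_tailed < 0.001
    res = fisher_z_test(0.405, 0.443, 1320, 1320)
    assert round(res.z, 1) == -1.2
    assert res.p_one_tailed == pytest.approx(0.117, abs=0.005)


def test_fisher_z_antisymmetry_and_zero():
    a = fisher_z_test(0.3, 0.5, 100, 150)
    b = fisher_z_test(0.5, 0.3, 150, 100)
    assert a.z == pytest.approx(-b.z)
    assert fisher_z_test(0.4, 0.4, 50, 80).z == 0.0


def test_fisher_z_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        fisher_z_test(1.0, 0.5, 100, 100)
    with pytest.raises(ValueError):
        fisher_z_test(0.2, 0.5, 3, 100)


# --- vocabulary ANOVA ----------------------------------------------------

def _counts_to_coded(counts_by_group):
    """Give each participant as many distinct words as their target count."""
    words = [f"w{k}" for k in range(30)]
    coded = []
    for g, counts in counts_by_group.items():
        for i, n in enumerate(counts):
            pid = f"{g}-{i}"
            for k in range(n):
                coded.append(CodedResponse(pid, g, k + 1, words[k]))
            if n == 0:
                coded.append(CodedResponse(pid, g, 1, "<no_answer>"))
    return coded


def test_two_group_f_equals_squared_t():
    data = {"a": [3, 5, 4, 6, 2], "b": [7, 9, 8, 6, 10]}
    res = vocab_stats(_counts_to_coded(data), group_order=["a", "b"])
    t = stats.ttest_ind(data["a"], data["b"], equal_var=True)
    assert res.anova.F == pytest.approx(t.statistic ** 2)
    assert res.anova.p == pytest.approx(t.pvalue)


def test_anova_agrees_with_reference_implementation():
    data = {"a": [1, 2, 2, 3], "b": [2, 4, 3, 5], "c": [6, 5, 7, 8]}
    res = vocab_stats(_counts_to_coded(data), group_order=list(data))
    ref = stats.f_oneway(*data.values())
    assert res.anova.F == pytest.approx(ref.statistic)
    assert res.anova.p == pytest.approx(ref.pvalue)
    assert res.anova.df_between == 2 and res.anova.df_within == 9
    assert 0 <= res.anova.eta_squared <= 1


def test_anova_degenerate_when_all_counts_equal():
    data = {"a": [3, 3, 3], "b": [3, 3, 3]}
    res = vocab_stats(_counts_to_coded(data), group_order=["a", "b"])
    assert res.anova.degenerate and np.isnan(res.anova.F)


def test_posthoc_bonferroni_caps_at_one():
    data = {"a": [3, 4, 3, 4], "b": [3, 4, 4, 3], "c": [3, 4, 3, 5]}
    res = vocab_stats(_counts_to_coded(data), group_order=list(data))
    assert len(res.posthoc) == 3
    assert all(0 <= p <= 1 for _, p in res.posthoc)


def test_vocab_stats_rejects_tiny_groups():
    data = {"a": [3], "b": [4, 5]}
    with pytest.raises(ValueError):
        vocab_stats(_counts_to_coded(data), group_order=["a", "b"])


def test_synthetic_group_means_increase(coded):
    res = vocab_stats(coded, group_order=["4-5", "6-7", "8-9", "10-11", "adult"])
    means = [res.group_means[g] for g in ("4-5", "6-7", "8-9", "10-11", "adult")]
    assert all(b > a for a, b in zip(means, means[1:]))
    assert res.anova.p < 0.001 and res.anova.eta_squared > 0.5
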