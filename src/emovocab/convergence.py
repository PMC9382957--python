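"""Vocabulary-size statistics and convergence of child toward adult usage.

Two questions are answered here.  How many different emotion words does
each age group use (one-way ANOVA over per-participant distinct-word
counts, with eta-squared and Bonferroni-corrected pairwise post hocs)?
And how similar is a child group's *pattern* of usage to the adult
pattern — the Spearman correlation between the two production matrices
flattened cell-by-cell, compared across age groups with Fisher's r-to-z
test for independent correlations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .coding import CodedResponse
from .matrices import ProductionMatrix


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_squared: float
    degenerate: bool = False  # SS_total == 0: statistic undefined


@dataclass
class VocabStats:
    counts: dict[str, list[int]]  # group -> per-participant distinct-word counts
    group_means: dict[str, float]
    group_sds: dict[str, float]
    anova: AnovaResult
    posthoc: list[tuple[tuple[str, str], float]]  # ((g1, g2), adjusted p)


@dataclass
class ConvergenceResult:
    group: str
    rho: float
    p: float
    n_cells: int


@dataclass
class FisherZResult:
    z: float
    p_one_tailed: float
    p_two_tailed: float


def distinct_word_counts(coded: Sequence[CodedResponse]) -> dict[str, dict[str, int]]:
    """group -> participant -> number of different emotion words produced.

    The two unspecific pseudo-words count as words, like in the word list.
    """
    words: dict[str, dict[str, set[str]]] = {}
    participants: dict[str, set[str]] = {}
    for c in coded:
        participants.setdefault(c.age_group, set()).add(c.participant_id)
        if c.is_emotion_word:
            words.setdefault(c.age_group, {}).setdefault(
                c.participant_id, set()
            ).add(c.code)
    return {
        g: {p: len(words.get(g, {}).get(p, ())) for p in sorted(pids)}
        for g, pids in participants.items()
    }


def vocab_stats(
    coded: Sequence[CodedResponse], group_order: Sequence[str] | None = None
) -> VocabStats:
    """Per-group vocabulary sizes with one-way ANOVA and Bonferroni post hocs.

    The ANOVA is computed from explicit sums of squares so eta-squared
    (SS_between / SS_total) comes for free; post hocs are pooled-variance
    two-sample t tests with p multiplied by the number of pairs (capped
    at 1).
    """
    per_group = distinct_word_counts(coded)
    groups = list(group_order) if group_order is not None else sorted(per_group)
    counts = {g: list(per_group[g].values()) for g in groups}
    if len(groups) < 2 or any(len(v) < 2 for v in counts.values()):
        raise ValueError("need >= 2 groups with >= 2 participants each")

    samples = [np.asarray(counts[g], dtype=float) for g in groups]
    grand = np.concatenate(samples)
    ss_total = float(((grand - grand.mean()) ** 2).sum())
    ss_between = float(
        sum(len(x) * (x.mean() - grand.mean()) ** 2 for x in samples)
    )
    df_b = len(groups) - 1
    df_w = len(grand) - len(groups)
    if ss_total == 0.0:
        anova = AnovaResult(float("nan"), df_b, df_w, float("nan"),
                            float("nan"), degenerate=True)
    else:
        ms_b = ss_between / df_b
        ms_w = (ss_total - ss_between) / df_w
        F = ms_b / ms_w if ms_w > 0 else float("inf")
        p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
        anova = AnovaResult(F, df_b, df_w, p, ss_between / ss_total)

    pairs = list(itertools.combinations(groups, 2))
    posthoc = []
    for g1, g2 in pairs:
        t = stats.ttest_ind(counts[g1], counts[g2], equal_var=True)
        posthoc.append(((g1, g2), min(1.0, float(t.pvalue) * len(pairs))))

    return VocabStats(
        counts=counts,
        group_means={g: float(np.mean(counts[g])) for g in groups},
        group_sds={g: float(np.std(counts[g], ddof=1)) for g in groups},
        anova=anova,
        posthoc=posthoc,
    )


def _check_aligned(child: ProductionMatrix, adult: ProductionMatrix) -> None:
    if child.vignette_ids != adult.vignette_ids or child.words != adult.words:
        raise ValueError("matrices must share vignette and word order")


def matrix_convergence(
    child: ProductionMatrix, adult: ProductionMatrix
) -> ConvergenceResult:
    """Spearman correlation between the flattened production matrices.

    All cells enter, zeros included: the mass of zero cells forms one large
    tie group under average ranks, which is what makes n equal the full
    20 x W cell count (1,320 for the 66-word universe).
    """
    _check_aligned(child, adult)
    x = child.counts.ravel()
    y = adult.counts.ravel()
    rho, p = stats.spearmanr(x, y)
    return ConvergenceResult(child.age_group, float(rho), float(p), x.size)


def per_word_convergence(
    child: ProductionMatrix, adult: ProductionMatrix
) -> dict[str, float]:
    """Word -> Spearman rho over the word's per-vignette count vectors.

    A word with zero variance in either group's vector (typically: never
    produced) has no defined correlation and is reported as NaN, not 0.
    """
    _check_aligned(child, adult)
    out: dict[str, float] = {}
    for j, w in enumerate(child.words):
        x = child.counts[:, j]
        y = adult.counts[:, j]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[w] = float("nan")
        else:
            out[w] = float(stats.spearmanr(x, y).statistic)
    return out


def fisher_z_test(r1: float, r2: float, n1: int, n2: int) -> FisherZResult:
    """Compare two independent correlations via Fisher's r-to-z transform.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); the one-tailed
    p is the normal tail beyond |z|, the two-tailed p twice that.
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("sample sizes must exceed 3")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p_one = float(stats.norm.sf(abs(z)))
    return FisherZResult(z=z, p_one_tailed=p_one, p_two_tailed=2.0 * p_one)
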