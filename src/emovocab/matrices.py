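"""Production matrices, frequency profiles and co-naming similarity.

The production matrix — vignettes x emotion words, cell = number of
participants in an age group producing that word for that vignette — is the
central object: convergence statistics correlate a child group's matrix
with the adult matrix, and word-level measures read its columns.  The
co-naming similarity matrix counts, for each pair of vignettes, how often
one participant gave both the same emotion word; it feeds the MDS stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coding import CodedResponse
from .lexicon import UNSPECIFIC


@dataclass
class ProductionMatrix:
    age_group: str
    vignette_ids: list[int]
    words: list[str]
    counts: np.ndarray  # shape (n_vignettes, n_words), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.vignette_ids), len(self.words)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.size

    @property
    def total_tokens(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.vignette_ids, columns=self.words)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("vignette_id").to_csv(path)


@dataclass
class SimilarityMatrix:
    """Vignette x vignette co-naming counts for one age group.

    ``s[i, j]`` (i != j) counts participants who gave vignettes i and j the
    same emotion word; ``n_pairs[i, j]`` counts participants with codable
    answers to both.  The diagonal holds the per-vignette codable-answer
    count and is excluded from scaling input.
    """

    age_group: str
    vignette_ids: list[int]
    s: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s)
        self.n_pairs = np.asarray(self.n_pairs)
        n = len(self.vignette_ids)
        if self.s.shape != (n, n) or self.n_pairs.shape != (n, n):
            raise ValueError("matrix shape does not match vignette count")
        if not np.array_equal(self.s, self.s.T):
            raise ValueError("similarity counts must be symmetric")
        off = ~np.eye(n, dtype=bool)
        if (self.s[off] > self.n_pairs[off]).any() or (self.s < 0).any():
            raise ValueError("0 <= s[i, j] <= n_pairs[i, j] violated")


def production_matrix(
    coded: Sequence[CodedResponse],
    group: str,
    words: Sequence[str],
    vignette_ids: Sequence[int] | None = None,
) -> ProductionMatrix:
    """Tally participants in ``group`` producing each word for each vignette.

    ``words`` fixes the column universe study-wide so matrices of different
    groups are comparable cell-by-cell.  No-answer and non-emotion codes
    contribute nothing.
    """
    rows = [c for c in coded if c.age_group == group]
    if vignette_ids is None:
        vignette_ids = sorted({c.vignette_id for c in coded})
    v_index = {v: i for i, v in enumerate(vignette_ids)}
    w_index = {w: j for j, w in enumerate(words)}
    # distinct participants per (vignette, word)
    seen: dict[tuple[int, int], set[str]] = {}
    for c in rows:
        if c.is_emotion_word and c.code in w_index:
            key = (v_index[c.vignette_id], w_index[c.code])
            seen.setdefault(key, set()).add(c.participant_id)
    counts = np.zeros((len(vignette_ids), len(words)), dtype=int)
    for (i, j), pids in seen.items():
        counts[i, j] = len(pids)
    return ProductionMatrix(group, list(vignette_ids), list(words), counts)


def frequency_profile(matrix: ProductionMatrix) -> dict[str, float]:
    """Word -> percentage of all emotion-word tokens produced by the group."""
    total = matrix.total_tokens
    if total == 0:
        raise ValueError("group produced no emotion-word tokens")
    sums = matrix.counts.sum(axis=0)
    return {w: 100.0 * s / total for w, s in zip(matrix.words, sums)}


def similarity_matrix(
    coded: Sequence[CodedResponse],
    group: str,
    vignette_ids: Sequence[int] | None = None,
    match_unspecific: bool = True,
) -> SimilarityMatrix:
    """Participant-level co-naming counts.

    For each participant and unordered vignette pair (i, j) with codable
    answers to both, ``n_pairs`` is incremented and ``s`` is incremented
    when the two coded words are identical.  With
    ``match_unspecific=False`` the two valence-only pseudo-words never
    count as a match (they still count toward ``n_pairs``).
    """
    rows = [c for c in coded if c.age_group == group]
    if vignette_ids is None:
        vignette_ids = sorted({c.vignette_id for c in coded})
    v_index = {v: i for i, v in enumerate(vignette_ids)}
    n = len(vignette_ids)
    by_participant: dict[str, dict[int, str]] = {}
    for c in rows:
        if c.is_emotion_word:
            by_participant.setdefault(c.participant_id, {})[v_index[c.vignette_id]] = c.code
    s = np.zeros((n, n), dtype=int)
    n_pairs = np.zeros((n, n), dtype=int)
    for answers in by_participant.values():
        idx = sorted(answers)
        for a, i in enumerate(idx):
            n_pairs[i, i] += 1
            s[i, i] += 1
            for j in idx[a + 1:]:
                n_pairs[i, j] += 1
                n_pairs[j, i] += 1
                same = answers[i] == answers[j]
                if same and not match_unspecific and answers[i] in UNSPECIFIC:
                    same = False
                if same:
                    s[i, j] += 1
                    s[j, i] += 1
    return SimilarityMatrix(group, list(vignette_ids), s, n_pairs)
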