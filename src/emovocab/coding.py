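"""Coding of free-label answers into canonical emotion-word tokens.

Implements the two-step scheme of free-labeling studies: first decide
whether an answer is an emotion word at all (physiological, cognitive or
behavioral descriptors are not), then collapse surface forms onto canonical
stems.  Valence-only answers ("gut", "schlecht") become the two unspecific
pseudo-words; negations of specific emotions ("nicht traurig") flip to the
unspecific category of the opposite valence.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .lexicon import (
    NO_ANSWER,
    NOT_EMOTION,
    UNSPECIFIC_NEGATIVE,
    UNSPECIFIC_POSITIVE,
    EmotionLexicon,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RawResponse:
    """One participant's raw answer to one vignette."""

    participant_id: str
    age_group: str
    vignette_id: int
    answer: str


@dataclass(frozen=True)
class CodedResponse:
    """One answer after lexicon coding.

    ``code`` is a canonical stem, one of the two unspecific pseudo-words,
    or the ``NOT_EMOTION`` / ``NO_ANSWER`` sentinels.
    """

    participant_id: str
    age_group: str
    vignette_id: int
    code: str

    @property
    def is_emotion_word(self) -> bool:
        return self.code not in (NOT_EMOTION, NO_ANSWER)


def code_answer(answer: str | None, lexicon: EmotionLexicon) -> str:
    """Code a single raw answer string.

    Rules, in order: no-answer markers; negation prefixes (the negated
    remainder maps to the unspecific category of the *opposite* valence);
    valence-only forms; stem / synonym lookup; non-emotion descriptors.
    Unknown strings are coded ``NOT_EMOTION`` with a warning — the real
    study resolved these with human coders.
    """
    if answer is None:
        return NO_ANSWER
    text = " ".join(answer.split())
    folded = text.casefold()
    if folded in lexicon._no_answer:
        return NO_ANSWER

    for prefix in lexicon.negation_prefixes:
        if folded.startswith(prefix):
            inner = _code_positive_form(folded[len(prefix):], lexicon)
            if inner == UNSPECIFIC_POSITIVE:
                return UNSPECIFIC_NEGATIVE
            if inner == UNSPECIFIC_NEGATIVE:
                return UNSPECIFIC_POSITIVE
            if inner is not None:  # a specific stem: flip its valence
                return (
                    UNSPECIFIC_NEGATIVE
                    if lexicon.valence[inner] > 0
                    else UNSPECIFIC_POSITIVE
                )
            break  # negated unknown falls through to NOT_EMOTION

    direct = _code_positive_form(folded, lexicon)
    if direct is not None:
        return direct
    if folded in lexicon._non_emotion:
        return NOT_EMOTION
    logger.warning("uncodable answer %r -> not_emotion", text)
    return NOT_EMOTION


def _code_positive_form(folded: str, lexicon: EmotionLexicon) -> str | None:
    """Resolve an (un-negated) case-folded form; None when unknown."""
    if folded in lexicon._unspec_pos:
        return UNSPECIFIC_POSITIVE
    if folded in lexicon._unspec_neg:
        return UNSPECIFIC_NEGATIVE
    return lexicon.lookup_stem(folded)


def code_dataset(
    responses: Iterable[RawResponse],
    lexicon: EmotionLexicon,
    design=None,
) -> list[CodedResponse]:
    """Code a whole dataset, preserving order (one coded row per raw row).

    When ``design`` is given, unknown age-group labels or vignette ids
    raise ``ValueError``.
    """
    if design is not None:
        groups = set(design.age_groups)
        vignettes = {v.id for v in design.vignettes}
    coded: list[CodedResponse] = []
    for r in responses:
        if design is not None:
            if r.age_group not in groups:
                raise ValueError(f"unknown age group {r.age_group!r}")
            if r.vignette_id not in vignettes:
                raise ValueError(f"unknown vignette id {r.vignette_id}")
        coded.append(
            CodedResponse(
                participant_id=r.participant_id,
                age_group=r.age_group,
                vignette_id=r.vignette_id,
                code=code_answer(r.answer, lexicon),
            )
        )
    return coded


def _ordered_words(token_counts: Counter) -> list[str]:
    """Descending total frequency, ties alphabetical."""
    return sorted(token_counts, key=lambda w: (-token_counts[w], w))


def build_word_list(
    coded: Sequence[CodedResponse], min_participants: int = 5
) -> list[str]:
    """Emotion words used by at least ``min_participants`` distinct
    participants of the total (pooled) sample.

    The two unspecific pseudo-words are list-eligible like any stem.
    Order is deterministic: descending total token count, ties alphabetical.
    """
    if min_participants < 1:
        raise ValueError("min_participants must be >= 1")
    if not coded:
        raise ValueError("no coded responses")
    users: defaultdict[str, set[str]] = defaultdict(set)
    tokens: Counter = Counter()
    for c in coded:
        if c.is_emotion_word:
            users[c.code].add(c.participant_id)
            tokens[c.code] += 1
    kept = Counter(
        {w: tokens[w] for w in tokens if len(users[w]) >= min_participants}
    )
    return _ordered_words(kept)


def all_words_produced(coded: Sequence[CodedResponse]) -> list[str]:
    """Every emotion word produced anywhere in the sample — the column
    universe of the production matrices (threshold-free, unlike
    :func:`build_word_list`)."""
    tokens = Counter(c.code for c in coded if c.is_emotion_word)
    return _ordered_words(tokens)
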