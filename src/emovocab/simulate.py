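"""Synthetic vignette-labeling datasets with the structure of the study design.

Emulates free-labeling sessions in which four child age groups (about 30
children each) and a reference adult group (n = 27) label 20 illustrated
emotion vignettes — six basic emotions plus 14 subordinate ("complex")
emotions.  The generative model encodes the developmental regularities the
analyses are built to detect:

* a vocabulary curve — the probability that a subordinate word is in a
  child's active vocabulary rises with age;
* overgeneralization — an unknown subordinate word is replaced by its
  basic-category word or by a valence-only ("unspecific") label;
* don't-know responses, falling with age, with the discontinue rule:
  after five consecutive unanswered vignettes a child's session ends;
* adults always know the target and answer from a profile concentrated on
  the target stem with a small synonym and basic-word mass, so adult usage
  of subordinate words is highly specific (low entropy).

Responses are generated at the coded-token level (stems, valence-only
forms); a small synonym table injects surface variation so the coding
module has real work to do.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coding import RawResponse
from .lexicon import EmotionLexicon, default_lexicon

ADULT_GROUP = "adult"
CHILD_GROUPS = ("4-5", "6-7", "8-9", "10-11")
AGE_GROUPS = CHILD_GROUPS + (ADULT_GROUP,)

#: consecutive no-answers after which a child's test is discontinued
DISCONTINUE_RUN = 5

# share of known-word productions rendered as a surface synonym rather
# than the canonical stem (exercises the coding step)
_SYNONYM_PROB = 0.15

# adult per-vignette answer profile: target stem / synonym surface /
# basic-category word; the basic-word mass reflects that adults, too, often
# label a subordinate scene with its basic emotion word
_ADULT_TARGET_P = 0.55
_ADULT_SYNONYM_P = 0.12


@dataclass(frozen=True)
class VignetteSpec:
    """One illustrated scenario with its intended target emotion word."""

    id: int
    target_word: str
    basic_category: str  # joy | fear | sadness | anger | disgust | surprise
    valence: int  # +1 or -1


@dataclass
class StudyDesign:
    """The fixed frame of one study: stimuli, lexicon, groups."""

    vignettes: list[VignetteSpec]
    lexicon: EmotionLexicon
    group_sizes: dict[str, int]
    age_groups: tuple[str, ...] = AGE_GROUPS

    def __post_init__(self) -> None:
        if not self.vignettes:
            raise ValueError("design needs at least one vignette")
        for v in self.vignettes:
            if v.target_word not in self.lexicon.valence:
                raise ValueError(f"target {v.target_word!r} not in lexicon")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if set(self.group_sizes) != set(self.age_groups):
            raise ValueError("group_sizes keys must match age_groups")

    @property
    def n_vignettes(self) -> int:
        return len(self.vignettes)

    @property
    def vignette_ids(self) -> list[int]:
        return [v.id for v in self.vignettes]

    def vignette_valence(self) -> dict[int, int]:
        return {v.id: v.valence for v in self.vignettes}


@dataclass
class SimulationParams:
    """Tunable rates of the generative model; all probabilities in [0, 1].

    ``vocab_curve`` must be non-decreasing and ``dont_know_rate``
    non-increasing across the age order — the age-gradedness the study
    design assumes.
    """

    vocab_curve: dict[str, float] = field(
        default_factory=lambda: {
            "4-5": 0.04, "6-7": 0.08, "8-9": 0.15, "10-11": 0.27, ADULT_GROUP: 1.0,
        }
    )
    overgeneralize_basic: float = 0.95
    unspecific_rate: float | dict[str, float] = field(
        default_factory=lambda: {
            "4-5": 0.25, "6-7": 0.08, "8-9": 0.05, "10-11": 0.03, ADULT_GROUP: 0.0,
        }
    )
    dont_know_rate: dict[str, float] = field(
        default_factory=lambda: {
            "4-5": 0.18, "6-7": 0.08, "8-9": 0.04, "10-11": 0.02, ADULT_GROUP: 0.0,
        }
    )
    valence_error_rate: float = 0.02
    seed: int = 0

    def unspecific(self, group: str) -> float:
        if isinstance(self.unspecific_rate, dict):
            return self.unspecific_rate[group]
        return self.unspecific_rate

    def validate(self, age_groups: tuple[str, ...] = AGE_GROUPS) -> None:
        rates = (
            [self.overgeneralize_basic, self.valence_error_rate]
            + [self.vocab_curve[g] for g in age_groups]
            + [self.dont_know_rate[g] for g in age_groups]
            + [self.unspecific(g) for g in age_groups]
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        vc = [self.vocab_curve[g] for g in age_groups]
        if any(b < a for a, b in zip(vc, vc[1:])):
            raise ValueError("vocab_curve must be non-decreasing with age")
        dk = [self.dont_know_rate[g] for g in age_groups]
        if any(b > a for a, b in zip(dk, dk[1:])):
            raise ValueError("dont_know_rate must be non-increasing with age")


# 20 vignettes: 6 basic emotions + 14 subordinate emotions, each carrying
# its superordinate basic category and valence.
_DEFAULT_VIGNETTES: list[tuple[str, str, int]] = [
    ("Freude", "joy", 1),
    ("traurig", "sadness", -1),
    ("Angst", "fear", -1),
    ("wütend", "anger", -1),
    ("Ekel", "disgust", -1),
    ("überrascht", "surprise", 1),
    ("stolz", "joy", 1),
    ("zufrieden", "joy", 1),
    ("begierig", "joy", 1),
    ("Vorfreude", "joy", 1),
    ("geborgen", "joy", 1),
    ("besorgt", "fear", -1),
    ("erschrocken", "fear", -1),
    ("einsam", "sadness", -1),
    ("enttäuscht", "sadness", -1),
    ("Sehnsucht", "sadness", -1),
    ("schuldig", "sadness", -1),
    ("Scham", "sadness", -1),
    ("frustiert", "anger", -1),
    ("neidisch", "anger", -1),
]

_BASIC_WORD = {
    "joy": "Freude",
    "fear": "Angst",
    "sadness": "traurig",
    "anger": "wütend",
    "disgust": "Ekel",
    "surprise": "überrascht",
}

# child-register variants of basic words: stems children use where adults
# prefer the canonical basic word, so some columns of the child matrices
# have no adult counterpart (their specificity is undefined) — a robust
# feature of free-labeling corpora
#: category -> (variant stems, their weights, swap probability)
_CHILD_VARIANTS: dict[str, tuple[tuple[str, ...], tuple[float, ...], float]] = {
    "joy": (("fröhlich", "froh"), (0.875, 0.125), 0.80),
    "anger": (("sauer",), (1.0,), 0.25),
    "fear": (("Grusel",), (1.0,), 0.10),
}

# relative ease of acquiring each basic-category word: the availability of
# the category word at vocabulary level v is min(1, ease * v).  The two
# valence anchors (sad / happy) come first, fear and anger words next,
# disgust and surprise words last
_CATEGORY_EASE = {
    "sadness": 20.0, "joy": 20.0, "fear": 2.0, "anger": 2.0,
    "disgust": 1.0, "surprise": 1.0,
}

# overgeneralization target of last resort: the valence-anchor basic word
_ANCHOR_CATEGORY = {-1: "sadness", 1: "joy"}


def _knows_category(rng: np.random.Generator, category: str, vocab: float) -> bool:
    return rng.random() < min(1.0, _CATEGORY_EASE[category] * vocab)


def _child_register(rng: np.random.Generator, stem: str, vocab: float) -> str:
    """Possibly swap a basic word for its child-register variant.

    The swap probability shrinks as the vocabulary curve matures —
    children grow out of the child register."""
    for category, word in _BASIC_WORD.items():
        if word == stem and category in _CHILD_VARIANTS:
            variants, weights, p = _CHILD_VARIANTS[category]
            if rng.random() < p * (1.0 - vocab):
                return variants[rng.choice(len(variants), p=weights)]
    return stem


def default_design() -> StudyDesign:
    """The default study frame: 20 vignettes (6 basic + 14 complex),
    child group sizes 30/31/32/30 and 27 adults, packaged lexicon."""
    vignettes = [
        VignetteSpec(id=i + 1, target_word=w, basic_category=c, valence=s)
        for i, (w, c, s) in enumerate(_DEFAULT_VIGNETTES)
    ]
    sizes = {"4-5": 30, "6-7": 31, "8-9": 32, "10-11": 30, ADULT_GROUP: 27}
    return StudyDesign(vignettes=vignettes, lexicon=default_lexicon(), group_sizes=sizes)


def _surface(rng: np.random.Generator, stem: str, lexicon: EmotionLexicon,
             p_synonym: float) -> str:
    syns = lexicon.synonyms_of(stem)
    if syns and rng.random() < p_synonym:
        return syns[rng.integers(len(syns))]
    return stem


def _unspecific_surface(rng: np.random.Generator, valence: int,
                        lexicon: EmotionLexicon) -> str:
    if valence > 0:
        forms = sorted(lexicon.unspecific_positive_forms)
    else:
        # includes an explicit negation so the coding path is exercised
        forms = sorted(lexicon.unspecific_negative_forms) + ["nicht gut"]
    return forms[rng.integers(len(forms))]


def _child_answer(rng: np.random.Generator, v: VignetteSpec,
                  lexicon: EmotionLexicon, params: SimulationParams,
                  group: str) -> str | None:
    """One child's answer to one vignette; None means no answer.

    Encodes the developmental progression of labeling strategies:
    valence-only label (early) -> basic-category word, falling back on the
    valence-anchor basic word (sad / happy) -> the subordinate target.
    """
    if rng.random() < params.dont_know_rate[group]:
        return None
    vocab = params.vocab_curve[group]
    basic_word = _BASIC_WORD[v.basic_category]
    is_basic = v.target_word == basic_word

    valence = v.valence
    if rng.random() < params.valence_error_rate:
        valence = -valence
        # a mis-read scene gets a valence-only label of the flipped valence
        return _unspecific_surface(rng, valence, lexicon)

    # early strategy: valence-only labeling regardless of vocabulary
    if rng.random() < params.unspecific(group):
        return _unspecific_surface(rng, valence, lexicon)

    knows_target = (
        _knows_category(rng, v.basic_category, vocab)
        if is_basic
        else rng.random() < vocab
    )
    if knows_target:
        word = _child_register(rng, v.target_word, vocab) if is_basic else v.target_word
        return _surface(rng, word, lexicon, _SYNONYM_PROB)

    # overgeneralize: own basic-category word, else the valence anchor
    if rng.random() < params.overgeneralize_basic:
        if not is_basic and _knows_category(rng, v.basic_category, vocab):
            return _surface(
                rng, _child_register(rng, basic_word, vocab), lexicon, _SYNONYM_PROB
            )
        anchor_cat = _ANCHOR_CATEGORY[valence]
        if v.basic_category != anchor_cat and _knows_category(rng, anchor_cat, vocab):
            anchor = _BASIC_WORD[anchor_cat]
            return _surface(
                rng, _child_register(rng, anchor, vocab), lexicon, _SYNONYM_PROB
            )
    return _unspecific_surface(rng, valence, lexicon)


def _adult_answer(rng: np.random.Generator, v: VignetteSpec,
                  lexicon: EmotionLexicon) -> str:
    u = rng.random()
    if u < _ADULT_TARGET_P:
        return v.target_word
    if u < _ADULT_TARGET_P + _ADULT_SYNONYM_P:
        return _surface(rng, v.target_word, lexicon, p_synonym=1.0)
    return _BASIC_WORD[v.basic_category]


def simulate_responses(
    design: StudyDesign, params: SimulationParams
) -> list[RawResponse]:
    """Generate one response per participant x vignette, in presentation
    order.  Identical (design, params) including the seed give identical
    output; per-participant random streams are derived from
    ``(seed, participant index)`` so participants are independent.
    """
    params.validate(design.age_groups)
    responses: list[RawResponse] = []
    pidx = 0
    for group in design.age_groups:
        for k in range(design.group_sizes[group]):
            rng = np.random.default_rng(np.random.SeedSequence([params.seed, pidx]))
            pid = f"{group}-{k + 1:03d}"
            consecutive_blank = 0
            discontinued = False
            for v in design.vignettes:
                if group == ADULT_GROUP:
                    answer = _adult_answer(rng, v, design.lexicon)
                elif discontinued:
                    answer = None
                else:
                    answer = _child_answer(rng, v, design.lexicon, params, group)
                if answer is None:
                    consecutive_blank += 1
                    if consecutive_blank >= DISCONTINUE_RUN:
                        discontinued = True
                else:
                    consecutive_blank = 0
                responses.append(
                    RawResponse(pid, group, v.id, "" if answer is None else answer)
                )
            pidx += 1
    return responses


def write_fixture(responses: list[RawResponse], path: str | Path) -> None:
    """Write responses as UTF-8 CSV (participant_id, age_group,
    vignette_id, answer); round-trips losslessly through
    :func:`read_fixture`."""
    if not responses:
        raise ValueError("no responses to write")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["participant_id", "age_group", "vignette_id", "answer"])
        for r in responses:
            w.writerow([r.participant_id, r.age_group, r.vignette_id, r.answer])


def read_fixture(path: str | Path) -> list[RawResponse]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        return [
            RawResponse(
                participant_id=row["participant_id"],
                age_group=row["age_group"],
                vignette_id=int(row["vignette_id"]),
                answer=row["answer"],
            )
            for row in reader
        ]
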