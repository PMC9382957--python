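"""Emotion-word lexicon: canonical stems, synonyms, valence and coding rules.

The lexicon is the lookup table against which free-label answers are coded.
It covers the German emotion vocabulary elicited by the 20-vignette test —
six basic-emotion words (joy, fear, sadness, anger, disgust, surprise) and
the subordinate words children and adults produce for the complex-emotion
vignettes — plus the two valence-only pseudo-words (*unspezifisch positiv*
and *unspezifisch negativ*) that absorb answers like "gut" or "nicht gut".

Stemming is lookup-table based: surface forms are collapsed onto canonical
stems through an explicit synonym map, not an algorithmic stemmer, mirroring
how coders in free-labeling studies work from a curated word list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

# Sentinel codes used alongside canonical stems.  The two unspecific
# categories are pseudo-words: they take part in word lists, production
# matrices and similarity matching exactly like stems.
UNSPECIFIC_POSITIVE = "unspezifisch positiv"
UNSPECIFIC_NEGATIVE = "unspezifisch negativ"
NOT_EMOTION = "<not_emotion>"
NO_ANSWER = "<no_answer>"

UNSPECIFIC = (UNSPECIFIC_POSITIVE, UNSPECIFIC_NEGATIVE)

#: stem -> (english gloss, valence)
_DEFAULT_WORDS: dict[str, tuple[str, int]] = {
    "Angst": ("fear", -1),
    "Ärger": ("anger", -1),
    "aufgeregt": ("excited", 1),
    "begeistert": ("enthusiastic", 1),
    "begierig": ("avid", 1),
    "besorgt": ("worried", -1),
    "eifersüchtig": ("jealous", -1),
    "einsam": ("lonely", -1),
    "Ekel": ("disgust", -1),
    "enttäuscht": ("disappointed", -1),
    "erschrocken": ("scared", -1),
    "Freude": ("joy", 1),
    "froh": ("glad", 1),
    "fröhlich": ("happy", 1),
    "frustiert": ("frustrated", -1),
    "geborgen": ("safe", 1),
    "genervt": ("annoyed", -1),
    "glücklich": ("happy", 1),
    "Grusel": ("horror", -1),
    "Kummer": ("sorrow", -1),
    "Liebe": ("love", 1),
    "neidisch": ("envious", -1),
    "peinlich": ("embarrassed", -1),
    "Reue": ("remorse", -1),
    "sauer": ("angry", -1),
    "Scham": ("shame", -1),
    "schuldig": ("guilty", -1),
    "Sehnsucht": ("longing", -1),
    "stolz": ("proud", 1),
    "traurig": ("sad", -1),
    "überrascht": ("surprised", 1),
    "unglücklich": ("unhappy", -1),
    "verzweifelt": ("desperate", -1),
    "Vorfreude": ("anticipation", 1),
    "wütend": ("furious", -1),
    "zufrieden": ("satisfied", 1),
}

# Inflected and synonymous surface forms -> canonical stem.  Deliberately
# non-exhaustive: the real coding scheme was curated by humans and the map
# is meant to be extended per study.
_DEFAULT_SYNONYMS: dict[str, str] = {
    "ängstlich": "Angst",
    "angst": "Angst",
    "fürchtet sich": "Angst",
    "ärgerlich": "Ärger",
    "ärger": "Ärger",
    "verärgert": "Ärger",
    "aufgeregte": "aufgeregt",
    "begeisterte": "begeistert",
    "besorgte": "besorgt",
    "einsame": "einsam",
    "ekelt sich": "Ekel",
    "angeekelt": "Ekel",
    "eklig": "Ekel",
    "enttäuschte": "enttäuscht",
    "erschrockene": "erschrocken",
    "freude": "Freude",
    "freut sich": "Freude",
    "erfreut": "Freude",
    "frohe": "froh",
    "fröhliche": "fröhlich",
    "frustrierte": "frustiert",
    "frustriert": "frustiert",
    "geborgene": "geborgen",
    "genervte": "genervt",
    "glückliche": "glücklich",
    "gruselig": "Grusel",
    "gruselt sich": "Grusel",
    "kummer": "Kummer",
    "liebe": "Liebe",
    "verliebt": "Liebe",
    "neidische": "neidisch",
    "beschämt": "Scham",
    "schämt sich": "Scham",
    "scham": "Scham",
    "schuldige": "schuldig",
    "sehnsucht": "Sehnsucht",
    "sehnsüchtig": "Sehnsucht",
    "stolze": "stolz",
    "traurige": "traurig",
    "betrübt": "traurig",
    "überraschte": "überrascht",
    "verwundert": "überrascht",
    "unglückliche": "unglücklich",
    "verzweifelte": "verzweifelt",
    "vorfreude": "Vorfreude",
    "wütende": "wütend",
    "zornig": "wütend",
    "zufriedene": "zufrieden",
}

_DEFAULT_UNSPECIFIC_POSITIVE = {"gut", "schön", "lustig", "toll", "prima", "okay"}
_DEFAULT_UNSPECIFIC_NEGATIVE = {"schlecht", "böse", "blöd", "doof", "mies"}

# Physiological / cognitive / behavioral descriptors that are not emotion
# words under the coding scheme.
_DEFAULT_NON_EMOTION = {
    "müde", "hungrig", "durstig", "krank",
    "nachdenklich", "unverstanden", "allein",
    "lacht", "weint", "schreit", "hell",
}

_DEFAULT_NEGATION_PREFIXES = ("gar nicht so ", "gar nicht ", "nicht so ", "nicht ")

_DEFAULT_NO_ANSWER = {"", "-", "?", "weiß nicht", "weiß ich nicht", "keine antwort", "na"}


@dataclass
class EmotionLexicon:
    """Curated coding lexicon for one study.

    Attributes
    ----------
    valence:
        Canonical stem -> +1 (positive) or -1 (negative).  The key set
        defines the stems.
    synonym_map:
        Surface form -> stem; lookups are case-folded.
    english:
        Optional stem -> English gloss, for reports only.
    """

    valence: dict[str, int]
    synonym_map: dict[str, str] = field(default_factory=dict)
    unspecific_positive_forms: set[str] = field(default_factory=set)
    unspecific_negative_forms: set[str] = field(default_factory=set)
    non_emotion_markers: set[str] = field(default_factory=set)
    negation_prefixes: tuple[str, ...] = _DEFAULT_NEGATION_PREFIXES
    no_answer_markers: set[str] = field(default_factory=lambda: set(_DEFAULT_NO_ANSWER))
    english: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for form, stem in self.synonym_map.items():
            if stem not in self.valence:
                raise ValueError(f"synonym {form!r} maps to unknown stem {stem!r}")
        for stem, v in self.valence.items():
            if v not in (-1, 1):
                raise ValueError(f"valence of {stem!r} must be +1 or -1, got {v}")
        # case-folded lookup tables
        self._stem_by_form = {s.casefold(): s for s in self.valence}
        self._stem_by_form.update(
            {f.casefold(): s for f, s in self.synonym_map.items()}
        )
        self._unspec_pos = {f.casefold() for f in self.unspecific_positive_forms}
        self._unspec_neg = {f.casefold() for f in self.unspecific_negative_forms}
        self._non_emotion = {f.casefold() for f in self.non_emotion_markers}
        self._no_answer = {f.casefold() for f in self.no_answer_markers}

    @property
    def stems(self) -> set[str]:
        return set(self.valence)

    def lookup_stem(self, form: str) -> str | None:
        """Canonical stem for a surface form, or None if unknown."""
        return self._stem_by_form.get(form.casefold())

    def synonyms_of(self, stem: str) -> list[str]:
        """Surface forms (other than the stem itself) mapping to ``stem``."""
        return sorted(f for f, s in self.synonym_map.items() if s == stem)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "valence": self.valence,
            "synonym_map": self.synonym_map,
            "unspecific_positive_forms": sorted(self.unspecific_positive_forms),
            "unspecific_negative_forms": sorted(self.unspecific_negative_forms),
            "non_emotion_markers": sorted(self.non_emotion_markers),
            "negation_prefixes": list(self.negation_prefixes),
            "no_answer_markers": sorted(self.no_answer_markers),
            "english": self.english,
        }
        Path(path).write_text(
            json.dumps(payload, ensure_ascii=False, indent=1), encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EmotionLexicon":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            valence=dict(raw["valence"]),
            synonym_map=dict(raw.get("synonym_map", {})),
            unspecific_positive_forms=set(raw.get("unspecific_positive_forms", ())),
            unspecific_negative_forms=set(raw.get("unspecific_negative_forms", ())),
            non_emotion_markers=set(raw.get("non_emotion_markers", ())),
            negation_prefixes=tuple(raw.get("negation_prefixes", _DEFAULT_NEGATION_PREFIXES)),
            no_answer_markers=set(raw.get("no_answer_markers", _DEFAULT_NO_ANSWER)),
            english=dict(raw.get("english", {})),
        )


def default_lexicon() -> EmotionLexicon:
    """The packaged 36-stem German emotion lexicon (38 codes with the two
    unspecific pseudo-words)."""
    return EmotionLexicon(
        valence={s: v for s, (_, v) in _DEFAULT_WORDS.items()},
        synonym_map=dict(_DEFAULT_SYNONYMS),
        unspecific_positive_forms=set(_DEFAULT_UNSPECIFIC_POSITIVE),
        unspecific_negative_forms=set(_DEFAULT_UNSPECIFIC_NEGATIVE),
        non_emotion_markers=set(_DEFAULT_NON_EMOTION),
        english={s: e for s, (e, _) in _DEFAULT_WORDS.items()},
    )
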