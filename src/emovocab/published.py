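"""Accessors for the published word-level and group-level reference tables.

These are the study's printed summary tables, shipped as package data so
analyses that only need published numbers (Fisher r-to-z comparisons,
word-level regressions) run without the raw response data, which is not
redistributed here.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

_DATA = resources.files("emovocab") / "data"

AGE_GROUPS_PUBLISHED = ("4-5", "6-7", "8-9", "10-11", "adult")


def load_word_measures() -> pd.DataFrame:
    """The published word-level table: 38 emotion words (36 stems + the
    two unspecific pseudo-words) with per-group production frequencies
    (%), per-group degree of convergence (Spearman rho), child-directed
    input frequency, and specificity (adult entropy, log10; NaN for words
    adults never produced)."""
    with resources.as_file(_DATA / "word_measures_published.csv") as p:
        df = pd.read_csv(p)
    return df.set_index("german")


def load_group_summary() -> dict:
    """Published per-group vocabulary means/SDs and matrix-level
    similarity-to-adult correlations (N = 1,320 flattened cells)."""
    return json.loads((_DATA / "group_summary_published.json").read_text("utf-8"))
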