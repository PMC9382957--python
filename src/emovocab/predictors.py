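"""Word-level predictors of ease of learning and the regression models.

Two word properties are candidate predictors of how easily children pick
up an emotion word: *input frequency* — how often caregivers use the word
in child-directed speech, consumed here as a precomputed per-form count
table — and *word specificity* — the entropy of the word's usage
distribution over the 20 vignettes in the adult reference group,

    H(w) = - sum_v p(v) * log10 p(v),

low when adults reserve the word for one or two vignettes, high (up to
log10 20 ~ 1.301) when they spread it broadly.  Ease of learning is
operationalised as the word's production frequency in a child group and as
its degree of convergence with adult usage; both are regressed on the
predictors with standardized (z-scored) OLS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lexicon import EmotionLexicon
from .matrices import ProductionMatrix

logger = logging.getLogger(__name__)

MAX_ENTROPY_20 = math.log10(20.0)


@dataclass
class RegressionResult:
    dv: str
    group: str
    predictors: list[str]
    beta: dict[str, float]  # standardized coefficients
    r_squared: float
    F: float
    df1: int
    df2: int
    p: float
    n: int


def word_entropy(adult: ProductionMatrix, stem: str, base: float = 10.0) -> float:
    """Entropy of a word's usage distribution over vignettes in the adult
    group; NaN (missing, not zero) when adults never produced the word."""
    if stem not in adult.words:
        raise KeyError(f"{stem!r} not a column of the adult matrix")
    col = adult.counts[:, adult.words.index(stem)].astype(float)
    total = col.sum()
    if total == 0:
        return float("nan")
    p = col[col > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


def entropy_table(
    adult: ProductionMatrix, words: Sequence[str] | None = None, base: float = 10.0
) -> dict[str, float]:
    """Word -> specificity H for every requested word (NaN when unused)."""
    return {w: word_entropy(adult, w, base) for w in (words or adult.words)}


def load_input_frequency(
    path: str | Path, lexicon: EmotionLexicon
) -> dict[str, int]:
    """Read a (surface_form, count) table and sum counts per stem.

    A form is attributed to a stem via the lexicon's synonym map or, like
    corpus stem queries, when it contains a stem as a substring (the
    longest containing stem wins).  Stems absent from the file get 0 with
    a warning.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected columns: surface_form, count")
    form_col, count_col = df.columns[:2]
    counts = {stem: 0 for stem in lexicon.valence}
    stems_folded = sorted(
        ((s.casefold(), s) for s in lexicon.valence),
        key=lambda t: -len(t[0]),
    )
    for form, n in zip(df[form_col].astype(str), df[count_col]):
        if pd.isna(n):
            raise ValueError(f"malformed count for form {form!r}")
        stem = lexicon.lookup_stem(form)
        if stem is None:
            folded = form.casefold()
            stem = next((s for sf, s in stems_folded if sf in folded), None)
        if stem is not None:
            counts[stem] += int(n)
    missing = [s for s, n in counts.items() if n == 0]
    if missing:
        logger.warning("no input-frequency entries for %d stems (count 0)", len(missing))
    return counts


def word_measures(
    word_list: Sequence[str],
    profiles: dict[str, dict[str, float]],
    convergence: dict[str, dict[str, float]],
    input_frequency: dict[str, int] | None = None,
    specificity: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble the word-level measures table (one row per listed word).

    ``profiles`` and ``convergence`` map age group -> word -> value.
    """
    out = pd.DataFrame(index=pd.Index(word_list, name="word"))
    for g, prof in profiles.items():
        out[f"production_frequency_{g}"] = [prof.get(w, 0.0) for w in word_list]
    for g, conv in convergence.items():
        out[f"convergence_{g}"] = [conv.get(w, float("nan")) for w in word_list]
    if input_frequency is not None:
        out["input_frequency"] = [input_frequency.get(w, 0) for w in word_list]
    if specificity is not None:
        out["specificity"] = [specificity.get(w, float("nan")) for w in word_list]
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance variable in regression")
    return (x - x.mean()) / sd


def fit_models(
    measures: pd.DataFrame,
    dv: str,
    predictors: Sequence[str],
    group: str = "",
    missing_specificity: str = "zero",
) -> RegressionResult:
    """Standardized OLS of ``dv`` on ``predictors`` over the word rows.

    ``missing_specificity`` governs words without an entropy value
    (adults never produced them): ``"zero"`` (default) scores them as
    maximally specific (H = 0), ``"max"`` imputes log10(20), ``"exclude"``
    drops the rows.  Convergence NaNs (undefined per-word rho) are scored
    0, matching how such cells are tabulated.
    """
    import statsmodels.api as sm

    cols = [dv, *predictors]
    data = measures[cols].copy()
    for c in cols:
        if c.startswith("convergence"):
            data[c] = data[c].fillna(0.0)
    if "specificity" in cols:
        if missing_specificity == "zero":
            data["specificity"] = data["specificity"].fillna(0.0)
        elif missing_specificity == "max":
            data["specificity"] = data["specificity"].fillna(MAX_ENTROPY_20)
        elif missing_specificity == "exclude":
            data = data.dropna(subset=["specificity"])
        else:
            raise ValueError(f"unknown policy {missing_specificity!r}")
    data = data.dropna()
    n = len(data)
    if n < len(predictors) + 2:
        raise ValueError("too few complete rows for the regression")

    y = _zscore(data[dv].to_numpy(dtype=float))
    X = np.column_stack([_zscore(data[p].to_numpy(dtype=float)) for p in predictors])
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return RegressionResult(
        dv=dv,
        group=group,
        predictors=list(predictors),
        beta={p: float(b) for p, b in zip(predictors, model.params[1:])},
        r_squared=float(model.rsquared),
        F=float(model.fvalue),
        df1=int(model.df_model),
        df2=int(model.df_resid),
        p=float(model.f_pvalue),
        n=n,
    )
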