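"""End-to-end orchestration of the five analyses.

Given raw responses (from a fixture file or the synthetic generator), the
pipeline codes them, builds the word list and matrices, and runs in order:

1. vocabulary counts with one-way ANOVA and post hocs;
2. production-frequency profiles per age group;
3. matrix-level convergence to adult usage with Fisher r-to-z
   comparisons of adjacent age groups;
4. co-naming similarity matrices, nonmetric MDS per group, and
   valence-oriented two-dimensional solutions;
5. word-level measures (production frequency, per-word convergence,
   input frequency, specificity) and the ease-of-learning regressions.

Everything is returned in one bundle (plain dict / DataFrames) and
optionally written to an output directory as JSON and CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import coding, convergence, matrices, mds, predictors, simulate
from .lexicon import EmotionLexicon, default_lexicon

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and knobs of one pipeline run.

    Either ``responses_path`` points at a raw-response CSV, or the
    synthetic generator is used with ``sim_params``.
    """

    responses_path: str | None = None
    lexicon_path: str | None = None
    input_frequency_path: str | None = None
    adult_group: str = simulate.ADULT_GROUP
    min_participants: int = 5
    mds_dimensions: int = 2
    mds_nonmetric: bool = True
    dissimilarity_method: str = "pair_fraction"
    missing_specificity: str = "zero"
    entropy_base: float = 10.0
    seed: int = 0
    output_dir: str | None = None
    sim_params: simulate.SimulationParams | None = None

    def __post_init__(self) -> None:
        if self.min_participants < 1:
            raise ValueError("min_participants must be >= 1")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute analyses 1-5 and return the report bundle."""
    lexicon = (
        EmotionLexicon.from_json(config.lexicon_path)
        if config.lexicon_path
        else default_lexicon()
    )
    if config.responses_path:
        responses = simulate.read_fixture(config.responses_path)
        design = simulate.default_design()
    else:
        design = simulate.default_design()
        params = config.sim_params or simulate.SimulationParams(seed=config.seed)
        responses = simulate.simulate_responses(design, params)
    if not responses:
        raise ValueError("no responses to analyze")

    groups_present = {r.age_group for r in responses}
    if config.adult_group not in groups_present:
        raise ValueError(
            f"adult reference group {config.adult_group!r} absent from the data"
        )
    child_groups = [g for g in design.age_groups if g in groups_present
                    and g != config.adult_group]
    all_groups = child_groups + [config.adult_group]

    coded = coding.code_dataset(responses, lexicon, design=design)
    word_list = coding.build_word_list(coded, config.min_participants)
    universe = coding.all_words_produced(coded)
    vignette_ids = design.vignette_ids

    # Analysis 1 — vocabulary size
    stats1 = convergence.vocab_stats(coded, group_order=all_groups)

    # production matrices over the full produced-word universe
    prod = {
        g: matrices.production_matrix(coded, g, universe, vignette_ids)
        for g in all_groups
    }
    adult_matrix = prod[config.adult_group]

    # Analysis 2 — frequency profiles
    profiles = {g: matrices.frequency_profile(prod[g]) for g in all_groups}

    # Analysis 3 — convergence to adult usage + Fisher r-to-z
    conv = {g: convergence.matrix_convergence(prod[g], adult_matrix)
            for g in child_groups}
    fisher = {}
    for g1, g2 in zip(child_groups, child_groups[1:]):
        res = convergence.fisher_z_test(
            conv[g1].rho, conv[g2].rho, conv[g1].n_cells, conv[g2].n_cells
        )
        fisher[f"{g1} vs {g2}"] = res

    # Analysis 4 — co-naming similarity and MDS
    valence = design.vignette_valence()
    mds_results = {}
    for g in all_groups:
        sim = matrices.similarity_matrix(coded, g, vignette_ids)
        diss = mds.to_dissimilarity(sim, config.dissimilarity_method)
        sol = mds.smacof(diss, k=config.mds_dimensions,
                         nonmetric=config.mds_nonmetric)
        mds_results[g] = mds.orient(sol, valence)

    # Analysis 5 — word measures and ease-of-learning regressions
    per_word = {
        g: convergence.per_word_convergence(prod[g], adult_matrix)
        for g in child_groups
    }
    specificity = predictors.entropy_table(
        adult_matrix, word_list, base=config.entropy_base
    )
    input_freq = None
    if config.input_frequency_path:
        input_freq = predictors.load_input_frequency(
            config.input_frequency_path, lexicon
        )
        input_freq = {w: input_freq.get(w, 0) for w in word_list}
    measures = predictors.word_measures(
        word_list, profiles, per_word, input_freq, specificity
    )
    regressions = []
    for g in child_groups:
        preds = ["specificity"]
        if input_freq is not None and g == child_groups[0]:
            preds = ["input_frequency", "specificity"]
        for dv_kind in ("production_frequency", "convergence"):
            try:
                regressions.append(
                    predictors.fit_models(
                        measures, f"{dv_kind}_{g}", preds, group=g,
                        missing_specificity=config.missing_specificity,
                    )
                )
            except ValueError as exc:
                logger.warning("regression %s/%s skipped: %s", g, dv_kind, exc)

    bundle = {
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if k != "sim_params"},
        "word_list": word_list,
        "word_universe": universe,
        "analysis1_vocabulary": stats1,
        "analysis2_profiles": profiles,
        "analysis3_convergence": conv,
        "analysis3_fisher_z": fisher,
        "analysis4_mds": mds_results,
        "analysis5_measures": measures,
        "analysis5_regressions": regressions,
        "production_matrices": prod,
    }
    if config.output_dir:
        write_bundle(bundle, config.output_dir)
    return bundle


def write_bundle(bundle: dict, output_dir: str | Path) -> None:
    """Serialise a report bundle as JSON + CSV under ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {
        "config": bundle["config"],
        "word_list": bundle["word_list"],
        "word_universe": bundle["word_universe"],
        "analysis1_vocabulary": _jsonable(bundle["analysis1_vocabulary"]),
        "analysis2_profiles": _jsonable(bundle["analysis2_profiles"]),
        "analysis3_convergence": _jsonable(bundle["analysis3_convergence"]),
        "analysis3_fisher_z": _jsonable(bundle["analysis3_fisher_z"]),
        "analysis4_mds": {
            g: {
                "coords": _jsonable(r.coords),
                "stress": r.stress,
                "n_iter": r.n_iter,
                "converged": r.converged,
                "vignette_ids": r.vignette_ids,
            }
            for g, r in bundle["analysis4_mds"].items()
        },
        "analysis5_regressions": _jsonable(bundle["analysis5_regressions"]),
    }
    (out / "report.json").write_text(
        json.dumps(report, ensure_ascii=False, indent=1), encoding="utf-8"
    )
    bundle["analysis5_measures"].to_csv(out / "word_measures.csv")
    for g, m in bundle["production_matrices"].items():
        m.to_csv(out / f"production_matrix_{g}.csv")


def plot_mds(bundle: dict, output_dir: str | Path) -> None:
    """Optional per-group scatter of the oriented MDS solutions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for g, r in bundle["analysis4_mds"].items():
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(r.coords[:, 0], r.coords[:, 1])
        for vid, (x, y) in zip(r.vignette_ids, r.coords):
            ax.annotate(str(vid), (x, y), fontsize=8)
        ax.set_xlabel("dimension 1 (valence)")
        ax.set_ylabel("dimension 2")
        ax.set_title(f"{g} (stress-1 = {r.stress:.3f})")
        fig.tight_layout()
        fig.savefig(out / f"mds_{g}.png", dpi=100)
        plt.close(fig)
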