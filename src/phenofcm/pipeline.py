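"""End-to-end convenience drivers: simulate -> fit -> predict -> evaluate.

These wrap the module-level pieces into the study design: fit the FCM
on a reference (training) season's element space, freeze centers,
stage map and threshold, then score a second season within-season and
evaluate against its ground truth on the metaclass scale.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Sequence

import numpy as np

from .evaluation import EvaluationReport, evaluate
from .features import DOY_FEATURES, assemble_element_space
from .model import PhenologyFCM
from .simulate import SeasonData, SimConfig, simulate_season, truth_metaclasses

__all__ = ["DEFAULT_FEATURE_SET", "simulate_train_test", "fit_and_evaluate"]

#: Default predictor set for the single-model pipeline, selected by this
#: package's own random feature search on independent simulated season
#: pairs: features from every category (single-date VIs, cumulative VI
#: integrals, accumulated weather incl. AGDD) plus the mandatory DoY
#: encoding.  Cumulative integrals and thermal accumulations carry most
#: of the signal — they track each field's individual development clock.
DEFAULT_FEATURE_SET = (
    "sin_doy",
    "cos_doy",
    "I_GVMI",
    "I_NDMI",
    "NDMI",
    "VARIgreen",
    "WDRVI",
    "acc_gdd",
    "acc_tsoil_max",
    "acc_tsurf_min",
)


def simulate_train_test(config: SimConfig, test_seed_offset: int = 1000):
    """A (train, test) season pair: same conditions, independent draws."""
    train = simulate_season(config)
    test = simulate_season(
        dataclasses.replace(config, seed=config.seed + test_seed_offset)
    )
    return train, test


def fit_and_evaluate(
    train: SeasonData,
    test: SeasonData,
    feature_set: Sequence[str] = DEFAULT_FEATURE_SET,
    seed: int = 0,
    with_baseline: bool = True,
) -> Dict[str, object]:
    """Fit on the training season, score the test season within-season.

    Returns a dict with the fitted results object, the evaluation
    report, and (optionally) the DoY-only baseline report computed on
    the identical truth rows.
    """
    train_space = assemble_element_space(train.bands, train.weather, list(feature_set))
    results = PhenologyFCM(train_space).fit(seed=seed)

    test_space = assemble_element_space(test.bands, test.weather, list(feature_set))
    mask, truths = truth_metaclasses(test, test_space.index)
    eval_rows = test_space.loc[mask]
    records = results.predict_records(eval_rows)
    preds = [r.metaclass for r in records]
    rankings = [[s for s, _ in r.ranking] for r in records]
    report = evaluate(preds, truths, rankings)

    out: Dict[str, object] = {
        "results": results,
        "report": report,
        "n_eval": len(truths),
    }
    if with_baseline:
        base_train = assemble_element_space(
            train.bands, train.weather, list(DOY_FEATURES)
        )
        base_results = PhenologyFCM(base_train).fit(seed=seed)
        base_space = assemble_element_space(
            test.bands, test.weather, list(DOY_FEATURES)
        )
        base_records = base_results.predict_records(base_space.loc[mask])
        base_preds = [r.metaclass for r in base_records]
        base_rankings = [[s for s, _ in r.ranking] for r in base_records]
        out["baseline_results"] = base_results
        out["baseline_report"] = evaluate(base_preds, truths, base_rankings)
    return out
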