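"""Random feature-set search, model filtering and majority-vote ensembling.

The search follows a two-pass design.  Pass 1 samples random feature
combinations per set length (the DoY sine/cosine pair is forced into
every set), fits one FCM model each on the training season, scores it
on the validation split of the test season and keeps the top percent by
Cohen's kappa.  The most frequent features across those winners define
a reduced pool; pass 2 sweeps combinations from that pool, and models
passing the kappa / maxdiff-1 filter vote on the final predictions.

Desk-scale defaults (200 combinations per length over a 12-feature
pool) keep a full run in the minutes range; the scope of each pass is
plain configuration.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .evaluation import kappa as _kappa, maxdiff_accuracy
from .features import DOY_FEATURES, FEATURE_VOCABULARY
from .model import PhenologyFCM, PhenologyFCMResults
from .stages import Metaclass

logger = logging.getLogger(__name__)

__all__ = [
    "SearchResult",
    "random_feature_sets",
    "split_validation",
    "select_top_percent",
    "most_frequent_features",
    "filter_models",
    "majority_vote",
    "evaluate_feature_sets",
    "ensemble_predict",
]


@dataclass(frozen=True)
class SearchResult:
    """Validation scores for one candidate feature set."""

    feature_set: Tuple[str, ...]
    kappa: float
    maxdiff1: float


def random_feature_sets(
    pool: Sequence[str],
    lengths: Iterable[int],
    n_per_length: int,
    seed: int = 0,
) -> List[Tuple[str, ...]]:
    """Sample distinct feature sets per length; DoY features always included.

    ``pool`` is drawn from the 32-name vocabulary; set lengths count the
    two forced DoY features, so a length-L set adds L-2 free features.
    When a length admits fewer distinct combinations than requested, all
    of them are returned.
    """
    free = sorted(set(pool) - set(DOY_FEATURES))
    unknown = [f for f in free if f not in FEATURE_VOCABULARY]
    if unknown:
        raise ValueError(f"unknown feature name(s) in pool: {unknown}")
    rng = np.random.default_rng(seed)
    out: List[Tuple[str, ...]] = []
    for length in sorted(lengths):
        if not 3 <= length <= 15:
            raise ValueError(f"set length {length} outside the supported 3..15 range")
        n_free = length - len(DOY_FEATURES)
        n_available = math.comb(len(free), n_free)
        if n_per_length >= n_available:
            logger.info(
                "length %d: requested %d sets but only %d distinct exist; using all",
                length,
                n_per_length,
                n_available,
            )
            combos = list(itertools.combinations(free, n_free))
        else:
            seen = set()
            combos = []
            while len(combos) < n_per_length:
                pick = tuple(sorted(rng.choice(len(free), size=n_free, replace=False)))
                if pick not in seen:
                    seen.add(pick)
                    combos.append(tuple(free[i] for i in pick))
        out.extend(tuple(DOY_FEATURES) + c for c in combos)
    return out


def split_validation(
    field_ids: Sequence[str],
    fractions: Tuple[float, float] = (0.70, 0.30),
    seed: int = 0,
) -> Tuple[List[str], List[str]]:
    """Field-level random (test, validation) split, leakage-free by design."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    unique = sorted(set(field_ids))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    n_test = int(round(fractions[0] * len(unique)))
    test = sorted(unique[i] for i in order[:n_test])
    validation = sorted(unique[i] for i in order[n_test:])
    return test, validation


def select_top_percent(results: Sequence[SearchResult], pct: float = 1.0) -> List[SearchResult]:
    """Best ``pct`` percent of results by validation kappa.

    Ties break by maxdiff-1, then lexicographic feature names; at least
    one result is always returned.
    """
    if not results:
        raise ValueError("no search results to select from")
    n_keep = max(1, math.ceil(pct * len(results) / 100.0))
    ranked = sorted(results, key=lambda r: (-r.kappa, -r.maxdiff1, r.feature_set))
    return ranked[:n_keep]


def most_frequent_features(
    top_results: Sequence[SearchResult], n_features: int = 15
) -> List[str]:
    """Features ranked by how many of the top sets contain them (ties by name)."""
    if not top_results:
        raise ValueError("no results given")
    counts: Counter = Counter()
    for res in top_results:
        counts.update(res.feature_set)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in ranked[:n_features]]


def filter_models(
    results: Sequence[SearchResult],
    kappa_min: float = 0.46,
    maxdiff1_min: float = 0.86,
) -> List[SearchResult]:
    """Keep models strictly above both validation cut-offs."""
    return [r for r in results if r.kappa > kappa_min and r.maxdiff1 > maxdiff1_min]


def majority_vote(
    votes: Sequence[Metaclass],
    top_weights: Optional[Sequence[float]] = None,
) -> Metaclass:
    """Modal metaclass across model votes for one element.

    Count ties break by the largest summed top-rank weight among the
    tied metaclasses, then by the lower metaclass index.
    """
    if not votes:
        raise ValueError("no votes")
    counts: Counter = Counter(mc.index for mc in votes)
    top_count = max(counts.values())
    tied = [idx for idx, n in counts.items() if n == top_count]
    if len(tied) > 1 and top_weights is not None:
        sums: Dict[int, float] = {idx: 0.0 for idx in tied}
        for mc, w in zip(votes, top_weights):
            if mc.index in sums:
                sums[mc.index] += float(w)
        best = max(sums.values())
        tied = [idx for idx in tied if sums[idx] >= best - 1e-12]
    winner = min(tied)
    return next(mc for mc in votes if mc.index == winner)


def evaluate_feature_sets(
    train_space: pd.DataFrame,
    test_space: pd.DataFrame,
    truths: Sequence[Metaclass],
    eval_mask: np.ndarray,
    feature_sets: Sequence[Sequence[str]],
    seed: int = 0,
    **model_kwargs,
) -> List[SearchResult]:
    """Fit/score one FCM model per feature set.

    ``train_space``/``test_space`` are full-vocabulary element spaces
    for the training and scoring seasons; each model uses its columns
    only.  ``eval_mask`` marks the rows of ``test_space`` (e.g. the
    validation-split, in-season rows) that align with ``truths``.
    """
    results = []
    for fs in feature_sets:
        cols = list(fs)
        res = PhenologyFCM(train_space[cols], **model_kwargs).fit(seed=seed)
        preds = res.predict_records(test_space.loc[eval_mask, cols])
        pred_mcs = [r.metaclass for r in preds]
        results.append(
            SearchResult(
                feature_set=tuple(fs),
                kappa=_kappa(pred_mcs, list(truths)),
                maxdiff1=maxdiff_accuracy(pred_mcs, list(truths), 1),
            )
        )
    return results


def ensemble_predict(
    train_space: pd.DataFrame,
    test_space: pd.DataFrame,
    feature_sets: Sequence[Sequence[str]],
    seed: int = 0,
    **model_kwargs,
) -> Tuple[List[Metaclass], List[List[Metaclass]]]:
    """Majority-vote ensemble over one fitted model per feature set.

    Returns the voted metaclass per row of ``test_space`` plus each
    model's individual predictions (outer list over models).
    """
    per_model: List[List[Metaclass]] = []
    per_model_w: List[List[float]] = []
    for fs in feature_sets:
        cols = list(fs)
        res = PhenologyFCM(train_space[cols], **model_kwargs).fit(seed=seed)
        recs = res.predict_records(test_space[cols])
        per_model.append([r.metaclass for r in recs])
        per_model_w.append([r.ranking[0][1] for r in recs])
    voted = []
    for i in range(test_space.shape[0]):
        votes = [preds[i] for preds in per_model]
        weights = [w[i] for w in per_model_w]
        voted.append(majority_vote(votes, weights))
    return voted, per_model
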