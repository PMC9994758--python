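"""Fitted phenology model: FCM over an element space, statsmodels-style.

:class:`PhenologyFCM` holds the (training-season) element space and the
clustering hyper-parameters; :meth:`PhenologyFCM.fit` standardizes the
features, runs fuzzy c-means, matches clusters to growth stages by their
time order, derives the secondary-label threshold, and returns a
:class:`PhenologyFCMResults` that can score new seasons within-season.

The stage matching exploits phenology's arrow of time: within each
field, the sequence of hard (argmax) cluster assignments ordered by DoY
is reduced to its first-appearance order; the modal order across fields
maps the first-appearing cluster to RE and the last to BO.

The secondary-label threshold ``th_w`` is the 98th percentile of the
3rd-ranked partition weights of the training fit: weights ranked third
or lower can never be valid stage labels under the two-label protocol,
so their upper tail marks the smallest weight worth reporting as a
secondary stage.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import fcm as _fcm
from .features import DOY_FEATURES, START_DOY, assemble_element_space
from .stages import Metaclass, PhenologyStage

logger = logging.getLogger(__name__)

__all__ = [
    "PhenologyFCM",
    "PhenologyFCMResults",
    "PredictionRecord",
    "assign_stage_order",
    "compute_threshold",
    "threshold_metaclass",
    "build_baseline",
]

MODEL_SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class PredictionRecord:
    """Ranked stage prediction for one field-date element."""

    field_id: object
    doy: int
    ranking: Tuple[Tuple[PhenologyStage, float], ...]  # descending by weight
    metaclass: Metaclass


def assign_stage_order(
    W: np.ndarray, index: pd.MultiIndex, n_clusters: int = 6
) -> Tuple[Dict[int, PhenologyStage], bool]:
    """Map cluster indices to stages using the time order of cluster visits.

    Per field, the DoY-ordered argmax-cluster sequence is reduced to its
    first-appearance order; among fields that visit all ``n_clusters``
    clusters, the most common order is matched position-by-position to
    RE..BO.  If no field visits every cluster, clusters fall back to
    being ordered by the membership-weighted mean DoY of their elements.

    Returns the mapping and a flag marking whether the fallback was used.
    """
    frame = pd.DataFrame(
        {"cluster": np.argmax(W, axis=1)}, index=index
    ).reset_index()
    orders: Counter = Counter()
    for _, grp in frame.groupby("field_id", sort=True):
        seq = grp.sort_values("doy")["cluster"].to_numpy()
        first_order = tuple(dict.fromkeys(seq.tolist()))
        if len(first_order) == n_clusters:
            orders[first_order] += 1
    if orders:
        top = max(orders.values())
        order = min(o for o, n in orders.items() if n == top)  # deterministic tie-break
        fallback = False
    else:
        logger.warning(
            "no field exhibits all %d clusters; ordering clusters by "
            "membership-weighted mean DoY",
            n_clusters,
        )
        doys = index.get_level_values("doy").to_numpy(dtype=float)
        mean_doy = (W * doys[:, None]).sum(axis=0) / W.sum(axis=0)
        order = tuple(int(i) for i in np.argsort(mean_doy, kind="stable"))
        fallback = True
    mapping = {
        cluster: PhenologyStage(position + 1) for position, cluster in enumerate(order)
    }
    return mapping, fallback


def compute_threshold(W: np.ndarray, percentile: float = 98.0) -> float:
    """Secondary-label threshold: percentile of the 3rd-ranked weights."""
    W = np.asarray(W, dtype=float)
    if W.shape[1] < 3:
        raise ValueError("threshold needs at least 3 clusters")
    third = np.sort(W, axis=1)[:, -3]
    return float(np.percentile(third, percentile))


def threshold_metaclass(
    ranking: Sequence[Tuple[PhenologyStage, float]], th_w: float
) -> Tuple[Metaclass, bool]:
    """Metaclass from a descending (stage, weight) ranking and threshold.

    The 2nd-ranked stage becomes secondary only when its weight strictly
    exceeds ``th_w`` and it is adjacent to the primary; the returned flag
    marks a suppressed non-adjacent runner-up.
    """
    primary = ranking[0][0]
    second_stage, second_weight = ranking[1]
    if second_weight > th_w:
        if primary.is_adjacent(second_stage):
            return Metaclass(primary, second_stage), False
        return Metaclass(primary), True
    return Metaclass(primary), False


class PhenologyFCM:
    """Unsupervised within-season phenology model for cotton.

    Parameters
    ----------
    element_space : DataFrame
        K x E feature matrix indexed by (field_id, doy); typically built
        by :func:`phenofcm.features.assemble_element_space` from the
        training season's band and weather tables.
    n_clusters : int
        Number of fuzzy clusters; six, one per principal growth stage.
    fuzzifier : float
        FCM fuzzifier m > 1 (default 2).
    threshold_percentile : float
        Percentile of 3rd-ranked training weights defining ``th_w``.
    tol, max_iter, n_restarts
        FCM convergence settings and random restarts.
    """

    def __init__(
        self,
        element_space: pd.DataFrame,
        n_clusters: int = 6,
        fuzzifier: float = 2.0,
        threshold_percentile: float = 98.0,
        tol: float = 1e-6,
        max_iter: int = 300,
        n_restarts: int = 5,
    ) -> None:
        if not isinstance(element_space.index, pd.MultiIndex):
            raise ValueError("element_space must be indexed by (field_id, doy)")
        self.element_space = element_space
        self.feature_names = list(element_space.columns)
        self.n_clusters = n_clusters
        self.fuzzifier = fuzzifier
        self.threshold_percentile = threshold_percentile
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts

    @classmethod
    def from_tables(
        cls,
        bands: pd.DataFrame,
        weather: pd.DataFrame,
        feature_set: Optional[Sequence[str]] = None,
        start_doy: int = START_DOY,
        **kwargs,
    ) -> "PhenologyFCM":
        """Build the model straight from band and weather long tables."""
        X = assemble_element_space(bands, weather, feature_set, start_doy)
        return cls(X, **kwargs)

    def fit(self, seed: int = 0) -> "PhenologyFCMResults":
        """Standardize, cluster, order clusters in time, set the threshold."""
        X = self.element_space.to_numpy(dtype=float)
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0  # constant feature: centred, left unscaled
        Z = (X - mean) / scale
        centers, W = _fcm.fit_fcm(
            Z,
            c=self.n_clusters,
            m=self.fuzzifier,
            tol=self.tol,
            max_iter=self.max_iter,
            seed=seed,
            n_restarts=self.n_restarts,
        )
        mapping, fallback = assign_stage_order(W, self.element_space.index, self.n_clusters)
        th_w = compute_threshold(W, self.threshold_percentile)
        return PhenologyFCMResults(
            model=self,
            centers=centers,
            scaler_mean=mean,
            scaler_scale=scale,
            cluster_to_stage=mapping,
            th_w=th_w,
            train_partition=pd.DataFrame(W, index=self.element_space.index),
            seed=seed,
            used_order_fallback=fallback,
        )


@dataclass
class PhenologyFCMResults:
    """Fitted FCM phenology model and its prediction machinery."""

    model: Optional[PhenologyFCM]
    centers: np.ndarray
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    cluster_to_stage: Dict[int, PhenologyStage]
    th_w: float
    train_partition: Optional[pd.DataFrame]
    seed: Optional[int]
    used_order_fallback: bool = False
    feature_names: List[str] = field(default_factory=list)
    fuzzifier: float = 2.0
    n_suppressed_secondary: int = 0

    def __post_init__(self) -> None:
        if self.model is not None:
            self.feature_names = list(self.model.feature_names)
            self.fuzzifier = self.model.fuzzifier
        stages = sorted(int(s) for s in self.cluster_to_stage.values())
        if stages != list(range(1, len(self.cluster_to_stage) + 1)):
            raise ValueError("cluster_to_stage must be a bijection onto the stage scale")
        if not 0.0 < self.th_w < 0.5:
            raise ValueError(f"partition threshold out of range (0, 0.5): {self.th_w}")

    # -- scoring -----------------------------------------------------------

    def memberships(self, element_space: pd.DataFrame) -> pd.DataFrame:
        """Partition weights of new elements against the frozen centers."""
        if list(element_space.columns) != self.feature_names:
            raise ValueError(
                "element space columns do not match the fitted feature set"
            )
        Z = (element_space.to_numpy(dtype=float) - self.scaler_mean) / self.scaler_scale
        W = _fcm.memberships(self.centers, Z, self.fuzzifier)
        return pd.DataFrame(W, index=element_space.index)

    def _rank_row(self, w: np.ndarray) -> Tuple[Tuple[PhenologyStage, float], ...]:
        # descending weight, cluster index breaks exact ties deterministically
        order = np.lexsort((np.arange(w.size), -w))
        return tuple((self.cluster_to_stage[int(l)], float(w[l])) for l in order)

    def predict_records(self, element_space: pd.DataFrame) -> List[PredictionRecord]:
        """Ranked metaclass prediction for each row of ``element_space``.

        The top-ranked cluster's stage is the primary label; the
        2nd-ranked cluster's stage becomes the secondary label only when
        its weight strictly exceeds ``th_w`` *and* it is adjacent to the
        primary on the stage scale (non-adjacent runners-up are
        suppressed and counted in ``n_suppressed_secondary``).
        """
        W = self.memberships(element_space).to_numpy()
        records: List[PredictionRecord] = []
        for (fid, doy), w in zip(element_space.index, W):
            ranking = self._rank_row(w)
            mc, suppressed = threshold_metaclass(ranking, self.th_w)
            if suppressed:
                self.n_suppressed_secondary += 1
                logger.debug(
                    "suppressed non-adjacent secondary at field=%s doy=%s", fid, doy
                )
            records.append(PredictionRecord(fid, int(doy), ranking, mc))
        return records

    def predict(self, element_space: pd.DataFrame) -> pd.DataFrame:
        """Predictions as a table: metaclass string + stage-ordered weights."""
        records = self.predict_records(element_space)
        stage_cols = {f"w_{s.code}": [] for s in PhenologyStage}
        rows = []
        for rec in records:
            rows.append(
                {"field_id": rec.field_id, "doy": rec.doy, "metaclass": str(rec.metaclass)}
            )
            by_stage = {s: w for s, w in rec.ranking}
            for s in PhenologyStage:
                stage_cols[f"w_{s.code}"].append(by_stage[s])
        out = pd.DataFrame(rows)
        for col, vals in stage_cols.items():
            out[col] = vals
        return out

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fitted model."""
        lines = [
            "Phenology FCM results",
            "=" * 54,
            f"clusters:            {len(self.cluster_to_stage)}",
            f"fuzzifier m:         {self.fuzzifier:g}",
            f"features ({len(self.feature_names)}):".ljust(21)
            + ", ".join(self.feature_names),
            f"threshold th_w:      {self.th_w:.4f}",
            f"seed:                {self.seed}",
            f"stage order fallback: {'yes' if self.used_order_fallback else 'no'}",
            "-" * 54,
            "cluster -> stage map (by time order):",
        ]
        for cluster in sorted(self.cluster_to_stage):
            lines.append(f"  cluster {cluster} -> {self.cluster_to_stage[cluster].code}")
        if self.train_partition is not None:
            K = self.train_partition.shape[0]
            lines.append("-" * 54)
            lines.append(f"training elements K: {K}")
        return "\n".join(lines)

    def plot_weight_distribution(self, ax=None):
        """Histogram of training partition weights by rank (threshold shown)."""
        import matplotlib.pyplot as plt

        if self.train_partition is None:
            raise ValueError("no training partition stored")
        if ax is None:
            _, ax = plt.subplots()
        W = np.sort(self.train_partition.to_numpy(), axis=1)[:, ::-1]
        for rank in range(W.shape[1]):
            ax.hist(W[:, rank], bins=40, alpha=0.5, label=f"rank {rank + 1}")
        ax.axvline(self.th_w, linestyle=":", color="k", label=f"th_w={self.th_w:.3f}")
        ax.set_xlabel("partition weight")
        ax.set_ylabel("count")
        ax.legend()
        return ax

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "centers": self.centers.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "cluster_to_stage": {
                str(k): v.code for k, v in self.cluster_to_stage.items()
            },
            "th_w": self.th_w,
            "fuzzifier": self.fuzzifier,
            "feature_names": self.feature_names,
            "seed": self.seed,
            "used_order_fallback": self.used_order_fallback,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PhenologyFCMResults":
        payload = json.loads(text)
        major = int(str(payload.get("schema_version", "1.0")).split(".")[0])
        if major > int(MODEL_SCHEMA_VERSION.split(".")[0]):
            raise ValueError(
                f"model schema version {payload['schema_version']} is newer than "
                f"supported {MODEL_SCHEMA_VERSION}"
            )
        res = cls(
            model=None,
            centers=np.asarray(payload["centers"], dtype=float),
            scaler_mean=np.asarray(payload["scaler_mean"], dtype=float),
            scaler_scale=np.asarray(payload["scaler_scale"], dtype=float),
            cluster_to_stage={
                int(k): PhenologyStage.from_code(v)
                for k, v in payload["cluster_to_stage"].items()
            },
            th_w=float(payload["th_w"]),
            train_partition=None,
            seed=payload.get("seed"),
            used_order_fallback=bool(payload.get("used_order_fallback", False)),
        )
        res.feature_names = list(payload["feature_names"])
        res.fuzzifier = float(payload["fuzzifier"])
        return res

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "PhenologyFCMResults":
        with open(path) as fh:
            return cls.from_json(fh.read())


def build_baseline(
    bands: pd.DataFrame,
    weather: Optional[pd.DataFrame] = None,
    start_doy: int = START_DOY,
    **kwargs,
) -> PhenologyFCM:
    """DoY-only reference model: same pipeline, features {sin_doy, cos_doy}.

    Phenology correlates strongly with the calendar, so this model
    captures the agreement attainable from acquisition dates alone; the
    full model must beat it to demonstrate genuine signal.
    """
    if weather is None:
        weather = pd.DataFrame(columns=["field_id", "doy"])
    X = assemble_element_space(bands, weather, list(DOY_FEATURES), start_doy)
    return PhenologyFCM(X, **kwargs)
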