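"""Bag-level evaluation: ROC AUC and the intensity-ranking label protocol.

PBM probes are not labeled directly; binding intensity ranks them. The
protocol takes the top ``n_top`` probes by intensity as positive bags and
the bottom ``n_bottom`` as negative bags, discarding the ambiguous middle.
Classifiers are then compared by bag-level ROC AUC on a held-out probe
table — the probability that a randomly chosen positive bag scores above a
randomly chosen negative bag (ties counted 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .bags import BagConfig, LabeledBag, bags_from_sequences
from .mil import MilSvmModel, TrainingConfig, bag_score, fit_md_svm, fit_mi_svm


@dataclass
class EvalResult:
    auc: float
    roc_points: np.ndarray  # ordered (fpr, tpr) pairs
    n_pos: int
    n_neg: int


def roc_auc(scores, labels) -> EvalResult:
    """ROC AUC with the Mann-Whitney tie convention (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {-1, 1}:
        raise ValueError("labels must be -1 or +1")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    fpr, tpr, _ = roc_curve(labels, scores, pos_label=1, drop_intermediate=False)
    return EvalResult(
        auc=float(_trapezoid_auc(fpr, tpr)),
        roc_points=np.column_stack([fpr, tpr]),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def label_by_intensity(
    probes: pd.DataFrame, n_top: int = 200, n_bottom: int = 200
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a probe table into positive / negative subsets by intensity.

    Stable sort by intensity descending (the original row order breaks
    ties); the first ``n_top`` rows become positives, the last
    ``n_bottom`` negatives, and the middle is discarded.
    """
    if n_top < 1 or n_bottom < 1:
        raise ValueError("n_top and n_bottom must be >= 1")
    if n_top + n_bottom > len(probes):
        raise ValueError(
            f"n_top + n_bottom = {n_top + n_bottom} exceeds the "
            f"{len(probes)} probes available"
        )
    intensity = pd.to_numeric(probes["intensity"], errors="raise").to_numpy()
    order = np.argsort(-intensity, kind="stable")
    positives = probes.iloc[order[:n_top]]
    negatives = probes.iloc[order[len(probes) - n_bottom :]]
    return positives, negatives


def score_bags(model: MilSvmModel, bags: list[LabeledBag]) -> np.ndarray:
    return np.asarray([bag_score(model, bag)[0] for bag in bags])


_FITTERS = {"mi-svm": fit_mi_svm, "md-svm": fit_md_svm}


def compare_models(
    bags_train: list[LabeledBag],
    bags_test: list[LabeledBag],
    config: TrainingConfig = TrainingConfig(),
    algorithms: tuple[str, ...] = ("mi-svm", "md-svm"),
    bag_config: BagConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, MilSvmModel]]:
    """Train each algorithm on the same split; report held-out bag AUC."""
    train_ids = {b.bag_id for b in bags_train}
    test_ids = {b.bag_id for b in bags_test}
    leaked = train_ids & test_ids
    if leaked:
        raise ValueError(
            f"bag_id leakage between train and test splits: {sorted(leaked)[:5]}"
        )
    labels = np.asarray([b.label for b in bags_test])
    rows, models = [], {}
    for name in algorithms:
        if name not in _FITTERS:
            raise ValueError(f"unknown algorithm {name!r}")
        model, _ = _FITTERS[name](bags_train, config, bag_config=bag_config)
        result = roc_auc(score_bags(model, bags_test), labels)
        rows.append(
            {"model": name, "n_pos": result.n_pos, "n_neg": result.n_neg, "auc": result.auc}
        )
        models[name] = model
    return pd.DataFrame(rows), models


def labeled_bags_from_table(
    probes: pd.DataFrame,
    bag_config: BagConfig,
    n_top: int = 200,
    n_bottom: int = 200,
    id_prefix: str = "probe",
) -> list[LabeledBag]:
    """Label a probe table by intensity rank and build bags from it."""
    pos_df, neg_df = label_by_intensity(probes, n_top=n_top, n_bottom=n_bottom)
    pos = bags_from_sequences(
        pos_df["sequence"], bag_config, label=1,
        ids=[f"{id_prefix}{i}" for i in pos_df.index],
    )
    neg = bags_from_sequences(
        neg_df["sequence"], bag_config, label=-1,
        ids=[f"{id_prefix}{i}" for i in neg_df.index],
    )
    return pos + neg
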