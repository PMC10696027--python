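"""Similarity-weighted neighbor-vote toxicity classification.

Read-across on the network: a test molecule's score is the similarity-
weighted average of its labelled training neighbours' labels (toxic = 1,
non-toxic = 0), so the most similar chemicals dominate the vote. Scores at
or above 0.5 predict toxic — the tie goes to the positive class because the
intended use is hazard prioritisation. Uncertainty comes from repeated
stratified hold-out cross-validation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from csncrit.mcs import SimilarityStore
from csncrit.network import ThresholdNetwork, build_network
from csncrit.mol_io import LABEL_NONTOXIC, LABEL_TOXIC

#: Marker returned for a node with no labelled training neighbour.
UNCLASSIFIABLE = None

_METRICS = ("accuracy", "sensitivity", "specificity", "f1")


def neighbor_vote_score(
    node: int,
    net: ThresholdNetwork,
    train_labels: Mapping[int, int],
    store: SimilarityStore,
) -> float | None:
    """Similarity-weighted mean of training neighbours' labels, in [0, 1].

    ``train_labels`` maps training node -> {1: toxic, 0: non-toxic}; the node
    itself must not be in it. Returns :data:`UNCLASSIFIABLE` (None) when no
    neighbour carries a training label.
    """
    if node in train_labels:
        raise ValueError(f"node {node} appears in its own training labels")
    num = 0.0
    den = 0.0
    for nb in net.graph.neighbors(node):
        y = train_labels.get(nb)
        if y is None:
            continue
        s = store.similarity(node, nb)
        num += s * y
        den += s
    if den == 0.0:
        return UNCLASSIFIABLE
    return num / den


def classification_metrics(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity and F1 with toxic (1) positive.

    Ratios with a zero denominator are returned as None (missing), never 0.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    if prec is None or sens is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return {
        "accuracy": (tp + tn) / y_true.size,
        "sensitivity": sens,
        "specificity": spec,
        "f1": f1,
    }


@dataclass
class ClassificationReport:
    """CV-aggregated metrics for one threshold."""

    threshold: float
    n_iterations: int
    holdout_fraction: float
    seed: int
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    mean_unclassifiable: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def _labels_to_binary(labels: Sequence[str]) -> dict[int, int]:
    out = {}
    for i, lab in enumerate(labels):
        if lab == LABEL_TOXIC:
            out[i] = 1
        elif lab == LABEL_NONTOXIC:
            out[i] = 0
    return out


def holdout_cv(
    store: SimilarityStore,
    labels: Sequence[str] | Mapping[int, int],
    t: float,
    holdout: float = 0.8,
    iters: int = 100,
    seed: int = 0,
) -> ClassificationReport:
    """Repeated stratified hold-out CV of the neighbor-vote classifier at cut-off t.

    Each iteration keeps a ``holdout`` fraction of each class as the training
    set (stratified, so the minority non-toxic class never vanishes from
    either side), scores the remaining nodes using only training labels on
    the network built at ``t``, and predicts toxic when score >= 0.5. Test
    nodes with no labelled neighbour are imputed with the training majority
    class and counted. Metrics are aggregated as mean and sd over iterations;
    an iteration's undefined metric (zero denominator) is skipped for that
    metric's aggregate.
    """
    if not 0.0 < holdout < 1.0:
        raise ValueError("holdout fraction must be in (0, 1)")
    if isinstance(labels, Mapping):
        binary = dict(labels)
    else:
        binary = _labels_to_binary(labels)
    toxic = sorted(i for i, y in binary.items() if y == 1)
    nontoxic = sorted(i for i, y in binary.items() if y == 0)
    if not toxic or not nontoxic:
        raise ValueError("both classes must be present for cross-validation")

    net = build_network(store, t)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    per_iter: dict[str, list[float]] = {m: [] for m in _METRICS}
    unclassifiable_counts = []

    for _ in range(iters):
        train: set[int] = set()
        for cls_nodes in (toxic, nontoxic):
            k = int(round(holdout * len(cls_nodes)))
            k = min(max(k, 1), len(cls_nodes) - 1)
            train.update(rng.choice(cls_nodes, size=k, replace=False).tolist())
        test = [i for i in binary if i not in train]
        train_labels = {i: binary[i] for i in train}
        majority = 1 if sum(train_labels.values()) * 2 >= len(train_labels) else 0

        y_true, y_pred = [], []
        n_unclassifiable = 0
        for node in test:
            score = neighbor_vote_score(node, net, train_labels, store)
            if score is UNCLASSIFIABLE:
                pred = majority
                n_unclassifiable += 1
            else:
                pred = 1 if score >= 0.5 else 0
            y_true.append(binary[node])
            y_pred.append(pred)
        metrics = classification_metrics(y_true, y_pred)
        for m in _METRICS:
            if metrics[m] is not None:
                per_iter[m].append(metrics[m])
        unclassifiable_counts.append(n_unclassifiable)

    report = ClassificationReport(
        threshold=t,
        n_iterations=iters,
        holdout_fraction=holdout,
        seed=seed,
        mean_unclassifiable=float(np.mean(unclassifiable_counts)),
    )
    for m in _METRICS:
        vals = np.asarray(per_iter[m], dtype=float)
        report.mean[m] = float(vals.mean()) if vals.size else float("nan")
        report.sd[m] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return report


def classification_sweep(
    store: SimilarityStore,
    labels: Sequence[str] | Mapping[int, int],
    grid: Sequence[float],
    holdout: float = 0.8,
    iters: int = 100,
    seed: int = 0,
) -> list[ClassificationReport]:
    """Run :func:`holdout_cv` at every threshold on the grid."""
    ss = np.random.SeedSequence(seed)
    sub = ss.generate_state(len(grid)) % (2**31)
    return [
        holdout_cv(store, labels, float(t), holdout=holdout, iters=iters, seed=int(s))
        for t, s in zip(sorted(grid), sub)
    ]


def reports_to_csv(reports: Sequence[ClassificationReport], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["threshold", "metric", "mean", "sd"])
        for rep in reports:
            for m in _METRICS:
                writer.writerow([rep.threshold, m, rep.mean[m], rep.sd[m]])
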