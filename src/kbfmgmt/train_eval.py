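"""Training and evaluation protocol: stratified 5-fold cross-validation,
Adam-based training of the methylation classifier, and the six standard
binary-classification metrics (ACC, SPE, SEN, PRE, F1, AUC).

The positive class is "methylation present".  Besides the single-cohort
protocol, two multi-cohort modes probe generalisation: *cross* trains on one
cohort's fold-train portions and tests on the other cohort (keeping its fold
structure, so numbers stay comparable), and *merged* joins the matching
folds of both cohorts in every iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from .model import (AugmentationConfig, ClassifierSpec, augment,
                    build_classifier)
from .nn import Adam, Sequential, bce_with_logits, sigmoid

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "MetricsReport",
    "ArrayDataset",
    "CVResult",
    "make_folds",
    "train_fold",
    "predict_patient",
    "evaluate",
    "run_cv",
]


@dataclass
class TrainConfig:
    """Optimisation protocol: Adam, max 150 epochs, batch size 8, lr 5e-4."""

    max_epochs: int = 150
    batch_size: int = 8
    learning_rate: float = 5e-4
    optimizer: str = "Adam"
    seed: int = 0
    augmentation: Optional[AugmentationConfig] = None

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.optimizer != "Adam":
            raise ValueError("only the Adam optimizer is supported")


@dataclass
class FoldSplit:
    """Patient-level fold assignment (stratified by label)."""

    k: int
    assignment: Dict[str, int]

    def fold_patients(self, i: int) -> List[str]:
        return [p for p, f in self.assignment.items() if f == i]


@dataclass
class MetricsReport:
    """Confusion counts at threshold 0.5 plus the six derived metrics.

    A metric whose defining ratio has a zero denominator is reported as
    ``None`` (absent), never coerced to 0.
    """

    TP: int
    TN: int
    FP: int
    FN: int
    ACC: Optional[float]
    SPE: Optional[float]
    SEN: Optional[float]
    PRE: Optional[float]
    F1: Optional[float]
    AUC: Optional[float]

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {m: getattr(self, m) for m in
                ("ACC", "SPE", "SEN", "PRE", "F1", "AUC")}


#: One subject: (patient_id, model input, binary label).  For the 3D variant
#: the input is a (side, side, side) array; for the 2D variant a stack
#: (n_slices, side, side) of the informative slices.
Sample = Tuple[str, np.ndarray, int]


@dataclass
class ArrayDataset:
    """An in-memory labeled cohort, optionally with precomputed folds."""

    name: str
    samples: List[Sample]
    folds: Optional[FoldSplit] = None

    @property
    def patients(self) -> List[Tuple[str, int]]:
        return [(pid, label) for pid, _x, label in self.samples]


def make_folds(patients: Sequence[Tuple[str, int]], k: int,
               seed: int) -> FoldSplit:
    """Seeded stratified patient-level partition into ``k`` folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(patients):
        raise ValueError("k exceeds the number of patients")
    ids = [p for p, _ in patients]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    labels = [int(l) for _, l in patients]
    assignment: Dict[str, int] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        try:
            splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                       random_state=seed)
            split_iter = list(splitter.split(ids, labels))
        except ValueError:
            # stratification impossible (e.g. the leave-one-out limit):
            # plain shuffled partition
            splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
            split_iter = list(splitter.split(ids))
    for fold, (_tr, te) in enumerate(split_iter):
        for j in te:
            assignment[ids[j]] = fold
    return FoldSplit(k=k, assignment=assignment)


def _instances(samples: Sequence[Sample], dims: int):
    xs, ys = [], []
    for _pid, x, label in samples:
        x = np.asarray(x, dtype=np.float32)
        if dims == 3:
            xs.append(x[None])  # add channel axis
            ys.append(label)
        else:
            for sl in x:  # each informative slice is one training instance
                xs.append(sl[None])
                ys.append(label)
    return np.stack(xs), np.asarray(ys, dtype=np.float32)


def train_fold(train_set: Sequence[Sample], config: TrainConfig,
               spec: ClassifierSpec) -> Tuple[Sequential, List[float]]:
    """Train one classifier on ``train_set``; returns the model and the
    per-epoch mean training loss."""
    if len(train_set) == 0:
        raise ValueError("empty train set")
    labels = {label for _p, _x, label in train_set}
    if len(labels) < 2:
        raise ValueError("train set contains a single class")
    model = build_classifier(spec)
    X, y = _instances(train_set, spec.dims)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: List[float] = []
    n = X.shape[0]
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = X[idx]
            if config.augmentation is not None:
                xb = np.stack([
                    augment(x[0], config.augmentation,
                            int(rng.integers(0, 2**31 - 1)))[None]
                    for x in xb
                ]).astype(np.float32)
            model.zero_grad()
            logits = model.forward(xb, train=True)
            loss, gz = bce_with_logits(logits, y[idx])
            model.backward(gz)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def predict_patient(model: Sequential, x: np.ndarray, dims: int) -> float:
    """Patient-level methylation probability.

    3D: the sigmoid of the volume's logit.  2D: the mean sigmoid over the
    subject's informative slices.
    """
    x = np.asarray(x, dtype=np.float32)
    if dims == 3:
        logit = model.forward(x[None, None], train=False)
        return float(sigmoid(logit)[0, 0])
    logits = model.forward(x[:, None], train=False)
    return float(np.mean(sigmoid(logits)))


def evaluate(scores: Sequence[float], labels: Sequence[int]) -> MetricsReport:
    """Compute the confusion matrix at threshold 0.5 and the six metrics.

    AUC is the rank-based (Mann-Whitney) statistic with half credit for
    tied scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size == 0:
        raise ValueError("cannot evaluate an empty score vector")
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be binary")
    pred = s >= 0.5
    TP = int(np.sum(pred & (y == 1)))
    TN = int(np.sum(~pred & (y == 0)))
    FP = int(np.sum(pred & (y == 0)))
    FN = int(np.sum(~pred & (y == 1)))

    def ratio(num, den):
        return num / den if den > 0 else None

    ACC = ratio(TP + TN, TP + TN + FP + FN)
    SEN = ratio(TP, TP + FN)
    SPE = ratio(TN, TN + FP)
    PRE = ratio(TP, TP + FP)
    if PRE is None or SEN is None or (PRE + SEN) == 0:
        F1 = None
    else:
        F1 = 2 * PRE * SEN / (PRE + SEN)
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        AUC = None
    else:
        ranks = rankdata(s)  # average ranks: half credit for ties
        AUC = (float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2.0) \
            / (n_pos * n_neg)
    return MetricsReport(TP=TP, TN=TN, FP=FP, FN=FN, ACC=ACC, SPE=SPE,
                         SEN=SEN, PRE=PRE, F1=F1, AUC=AUC)


@dataclass
class CVResult:
    """Per-fold metrics, their arithmetic mean, and out-of-fold scores."""

    fold_reports: List[MetricsReport]
    mean_report: Dict[str, Optional[float]]
    oof_scores: Dict[str, Tuple[float, int]]  # patient -> (score, label)

    def pooled_report(self) -> MetricsReport:
        scores = [s for s, _l in self.oof_scores.values()]
        labels = [l for _s, l in self.oof_scores.values()]
        return evaluate(scores, labels)

    def to_csv(self, path) -> None:
        rows = []
        for i, r in enumerate(self.fold_reports):
            rows.append({"fold": i, **r.as_dict(),
                         "TP": r.TP, "TN": r.TN, "FP": r.FP, "FN": r.FN})
        rows.append({"fold": "mean", **self.mean_report})
        pd.DataFrame(rows).to_csv(path, index=False)


def _mean_metrics(reports: List[MetricsReport]) -> Dict[str, Optional[float]]:
    out: Dict[str, Optional[float]] = {}
    for m in ("ACC", "SPE", "SEN", "PRE", "F1", "AUC"):
        vals = [getattr(r, m) for r in reports if getattr(r, m) is not None]
        out[m] = float(np.mean(vals)) if vals else None
    return out


def _ensure_folds(ds: ArrayDataset, k: int, seed: int) -> FoldSplit:
    if ds.folds is None:
        ds.folds = make_folds(ds.patients, k, seed)
    return ds.folds


def run_cv(datasets, mode: str, config: TrainConfig, spec: ClassifierSpec,
           k: int = 5) -> CVResult:
    """K-fold cross-validation in one of three modes.

    ``single``: ``datasets`` is one :class:`ArrayDataset`; classic K-fold.
    ``cross``: ``datasets = (train_ds, test_ds)``; fold ``i`` trains on
    ``train_ds`` minus its fold ``i`` and tests on ``test_ds``'s fold ``i``.
    ``merged``: fold ``i`` of the union joins fold ``i`` of each cohort for
    both training and testing.

    Training and test patient sets are disjoint in every mode (patients
    never leak: folds are patient-level and cohorts share no ids).
    """
    if mode not in ("single", "cross", "merged"):
        raise ValueError("mode must be 'single', 'cross' or 'merged'")
    if mode == "single":
        ds = datasets
        folds = _ensure_folds(ds, k, config.seed)
        pairs = []
        for i in range(folds.k):
            test_ids = set(folds.fold_patients(i))
            train = [s for s in ds.samples if s[0] not in test_ids]
            test = [s for s in ds.samples if s[0] in test_ids]
            pairs.append((train, test))
    else:
        ds_a, ds_b = datasets
        folds_a = _ensure_folds(ds_a, k, config.seed)
        folds_b = _ensure_folds(ds_b, k, config.seed + 1)
        if folds_a.k != folds_b.k:
            raise ValueError("merged/cross modes need matching fold counts")
        pairs = []
        for i in range(folds_a.k):
            a_test = set(folds_a.fold_patients(i))
            b_test = set(folds_b.fold_patients(i))
            if mode == "cross":
                train = [s for s in ds_a.samples if s[0] not in a_test]
                test = [s for s in ds_b.samples if s[0] in b_test]
            else:
                train = ([s for s in ds_a.samples if s[0] not in a_test]
                         + [s for s in ds_b.samples if s[0] not in b_test])
                test = ([s for s in ds_a.samples if s[0] in a_test]
                        + [s for s in ds_b.samples if s[0] in b_test])
            pairs.append((train, test))

    fold_reports: List[MetricsReport] = []
    oof: Dict[str, Tuple[float, int]] = {}
    for i, (train, test) in enumerate(pairs):
        train_ids = {s[0] for s in train}
        assert not train_ids & {s[0] for s in test}, "patient leakage"
        fold_cfg = replace(config, seed=config.seed + 101 * i)
        fold_spec = replace(spec, seed=config.seed + 101 * i)
        model, _history = train_fold(train, fold_cfg, fold_spec)
        scores = [predict_patient(model, x, spec.dims) for _p, x, _l in test]
        labels = [l for _p, _x, l in test]
        fold_reports.append(evaluate(scores, labels))
        for (pid, _x, label), sc in zip(test, scores):
            oof[pid] = (sc, int(label))
    return CVResult(fold_reports=fold_reports,
                    mean_report=_mean_metrics(fold_reports),
                    oof_scores=oof)
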