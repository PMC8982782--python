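"""Evaluation regimes: participant-specific, leave-one-participant-out,
within-group and bidirectional cross-group, with imbalance-aware metrics.

Metrics: accuracy, rank-based AUC (probability that a random attention
score exceeds a random inattention score, ties counting one half), and the
F1 score with attention as the positive class (the majority class;
configurable). The 2x2 confusion matrix has truth on rows (attention,
inattention) and predictions on columns.

Participant independence: in the leave-one-participant-out and group
regimes no participant ever contributes rows to both the training and the
test side; this is asserted at split time. Feature selection and
standardization are refit inside every training fold (they are part of the
model, see :class:`faceattn.svm.AttentionSvmModel`), so nothing computed on
test rows leaks into training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score

from .cnn import AttentionCnnModel, CnnConfig
from .errors import FaceAttnError, InsufficientDataError
from .svm import AttentionSvmModel, SvmConfig

logger = logging.getLogger(__name__)

REGIMES = ("participant_specific", "leave_one_participant_out", "within_group", "cross_group")


@dataclass
class EvalResult:
    """Metrics for one train/test configuration."""

    acc: float
    auc: float | None
    f1: float
    confusion: np.ndarray  # rows: truth (attention, inattention); cols: predicted
    n_train: int
    n_test: int
    regime: str = ""
    iteration: int = 0

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "auc": self.auc,
            "f1": self.f1,
            "tp": int(self.confusion[0, 0]),
            "fn": int(self.confusion[0, 1]),
            "fp": int(self.confusion[1, 0]),
            "tn": int(self.confusion[1, 1]),
            "n_train": self.n_train,
            "n_test": self.n_test,
            "regime": self.regime,
            "iteration": self.iteration,
        }


def metric_suite(
    truth: np.ndarray,
    pred: np.ndarray,
    scores: np.ndarray | None = None,
    positive: int = 1,
    n_train: int = 0,
    regime: str = "",
    iteration: int = 0,
) -> EvalResult:
    """ACC, AUC, F1 and the confusion matrix for one prediction vector.

    AUC needs ``scores`` and both classes present in ``truth``; otherwise it
    is reported as ``None`` with a warning (ACC/F1 are still computed).
    """
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if len(truth) != len(pred):
        raise FaceAttnError("truth and pred must have equal length")
    negative = 1 - positive
    conf = confusion_matrix(truth, pred, labels=[positive, negative])
    acc = float((truth == pred).mean())
    f1 = float(f1_score(truth, pred, pos_label=positive, zero_division=0))
    auc = None
    if scores is not None:
        if len(np.unique(truth)) == 2:
            auc = float(roc_auc_score(truth == positive, np.asarray(scores, dtype=float)))
        else:
            warnings.warn("AUC undefined: single-class truth", stacklevel=2)
    return EvalResult(
        acc=acc,
        auc=auc,
        f1=f1,
        confusion=conf,
        n_train=n_train,
        n_test=len(truth),
        regime=regime,
        iteration=iteration,
    )


def summarize(results: list[EvalResult]) -> dict:
    """Mean (and sd) of ACC/AUC/F1; folds with undefined AUC are excluded
    from the AUC average and counted in ``n_auc_excluded``."""
    accs = [r.acc for r in results]
    f1s = [r.f1 for r in results]
    aucs = [r.auc for r in results if r.auc is not None]
    return {
        "n": len(results),
        "acc_mean": float(np.mean(accs)) if accs else float("nan"),
        "acc_sd": float(np.std(accs)) if accs else float("nan"),
        "f1_mean": float(np.mean(f1s)) if f1s else float("nan"),
        "f1_sd": float(np.std(f1s)) if f1s else float("nan"),
        "auc_mean": float(np.mean(aucs)) if aucs else float("nan"),
        "auc_sd": float(np.std(aucs)) if aucs else float("nan"),
        "n_auc_excluded": len(results) - len(aucs),
    }


ModelFactory = Callable[[], object]


def make_model_factory(
    kind: str = "svm",
    n_features: int = 20,
    svm_config: SvmConfig | None = None,
    cnn_config: CnnConfig | None = None,
    tune: bool = False,
) -> ModelFactory:
    """Factory for fresh per-fold models ('svm' on FeatureMatrix data,
    'cnn' on RasterDataset data)."""
    if kind == "svm":
        cfg = svm_config or SvmConfig()
        return lambda: AttentionSvmModel(n_features=n_features, config=cfg, tune=tune)
    if kind == "cnn":
        ccfg = cnn_config or CnnConfig()
        return lambda: AttentionCnnModel(config=ccfg)
    raise ValueError(f"unknown model kind {kind!r}")


def _fit_eval(model_factory, train, test, regime, iteration) -> EvalResult:
    model = model_factory()
    model.fit(train)
    pred, scores = model.predict(test)
    return metric_suite(
        test.labels, pred, scores, n_train=train.n, regime=regime, iteration=iteration
    )


def _stratified_row_split(labels: np.ndarray, test_fraction: float, rng: np.random.Generator):
    test_idx = []
    for cls in np.unique(labels):
        rows = np.flatnonzero(labels == cls)
        rng.shuffle(rows)
        n_test = max(1, int(round(test_fraction * len(rows))))
        test_idx.append(rows[:n_test])
    test_idx = np.concatenate(test_idx)
    mask = np.zeros(len(labels), dtype=bool)
    mask[test_idx] = True
    return np.flatnonzero(~mask), np.flatnonzero(mask)


def participant_specific_eval(
    data,
    model_factory: ModelFactory,
    seed: int = 0,
    n_repeats: int = 10,
    test_fraction: float = 0.2,
) -> tuple[dict[str, list[EvalResult]], dict]:
    """Train and test within each participant (repeated stratified 80/20).

    ``n_repeats`` fresh splits per participant; per-participant results are
    averaged, then averaged across participants. Participants missing a
    class are excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    per_participant: dict[str, list[EvalResult]] = {}
    for pid in np.unique(data.participant_ids):
        rows = np.flatnonzero(data.participant_ids == pid)
        sub = data.subset_rows(rows)
        if len(np.unique(sub.labels)) < 2:
            warnings.warn(f"participant {pid} lacks a class; excluded", stacklevel=2)
            continue
        results = []
        for rep in range(n_repeats):
            tr, te = _stratified_row_split(sub.labels, test_fraction, rng)
            results.append(
                _fit_eval(
                    model_factory,
                    sub.subset_rows(tr),
                    sub.subset_rows(te),
                    "participant_specific",
                    rep,
                )
            )
        per_participant[str(pid)] = results
    if not per_participant:
        raise InsufficientDataError("no participant has both classes")
    participant_means = [
        EvalResultMean(pid, summarize(res)) for pid, res in per_participant.items()
    ]
    averaged = {
        "acc_mean": float(np.mean([m.summary["acc_mean"] for m in participant_means])),
        "f1_mean": float(np.mean([m.summary["f1_mean"] for m in participant_means])),
        "auc_mean": float(
            np.mean(
                [
                    m.summary["auc_mean"]
                    for m in participant_means
                    if not np.isnan(m.summary["auc_mean"])
                ]
            )
        ),
        "n_participants": len(participant_means),
    }
    return per_participant, averaged


@dataclass
class EvalResultMean:
    participant_id: str
    summary: dict


def leave_one_participant_out(
    data, model_factory: ModelFactory, seed: int = 0
) -> tuple[dict[str, EvalResult], dict]:
    """Train on all participants but one, test on the held-out participant.

    One fold per participant (fold count == participant count); feature
    selection and standardization are refit inside each fold by the model.
    Folds whose test participant lacks a class get AUC ``None`` and are
    excluded from the AUC average (flagged in the summary).
    """
    pids = np.unique(data.participant_ids)
    if len(pids) < 2:
        raise InsufficientDataError("leave-one-participant-out needs >= 2 participants")
    per_participant: dict[str, EvalResult] = {}
    for pid in pids:
        test_rows = np.flatnonzero(data.participant_ids == pid)
        train_rows = np.flatnonzero(data.participant_ids != pid)
        train = data.subset_rows(train_rows)
        test = data.subset_rows(test_rows)
        assert not set(np.unique(train.participant_ids)) & set(np.unique(test.participant_ids))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_participant[str(pid)] = _fit_eval(
                model_factory, train, test, "leave_one_participant_out", 0
            )
    return per_participant, summarize(list(per_participant.values()))


def _participant_level_split(
    pids: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    pids = np.array(sorted(pids), dtype=object)
    if len(pids) < 2:
        raise InsufficientDataError("group too small for a participant-level split")
    rng.shuffle(pids)
    n_test = max(1, int(round(test_fraction * len(pids))))
    if n_test >= len(pids):
        raise InsufficientDataError("group too small for a participant-level split")
    return pids[n_test:], pids[:n_test]


def cross_group_eval(
    group_a,
    group_b,
    model_factory: ModelFactory,
    iterations: int = 50,
    seed: int = 0,
    test_fraction: float = 0.2,
    names: tuple[str, str] = ("A", "B"),
) -> tuple[dict[str, list[EvalResult]], dict[str, dict]]:
    """Bidirectional cross-group plus within-group evaluation.

    Four cells — train A/test A, train A/test B, train B/test A,
    train B/test B — each repeated ``iterations`` times. Every iteration
    draws a fresh 80/20 *participant-level* split inside each group; a cell
    trains on the train-participants of its training group and tests on the
    test-participants of its test group, so all cells are participant
    independent and the two cells sharing a test group see the same test
    participants.
    """
    rng = np.random.default_rng(seed)
    na, nb = names
    cells: dict[str, list[EvalResult]] = {
        f"{na}->{na}": [], f"{na}->{nb}": [], f"{nb}->{na}": [], f"{nb}->{nb}": []
    }
    for it in range(iterations):
        tr_a, te_a = _participant_level_split(np.unique(group_a.participant_ids), test_fraction, rng)
        tr_b, te_b = _participant_level_split(np.unique(group_b.participant_ids), test_fraction, rng)
        parts = {
            na: (
                group_a.subset_rows(np.flatnonzero(np.isin(group_a.participant_ids, tr_a))),
                group_a.subset_rows(np.flatnonzero(np.isin(group_a.participant_ids, te_a))),
            ),
            nb: (
                group_b.subset_rows(np.flatnonzero(np.isin(group_b.participant_ids, tr_b))),
                group_b.subset_rows(np.flatnonzero(np.isin(group_b.participant_ids, te_b))),
            ),
        }
        for gtrain in (na, nb):
            for gtest in (na, nb):
                train = parts[gtrain][0]
                test = parts[gtest][1]
                assert not set(np.unique(train.participant_ids)) & set(
                    np.unique(test.participant_ids)
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cells[f"{gtrain}->{gtest}"].append(
                        _fit_eval(model_factory, train, test, "cross_group", it)
                    )
    return cells, {cell: summarize(res) for cell, res in cells.items()}


def results_to_frame(results: dict[str, list[EvalResult]]):
    """Tidy DataFrame (one row per fold/iteration) for CSV export."""
    import pandas as pd

    rows = []
    for key, res_list in results.items():
        if isinstance(res_list, EvalResult):
            res_list = [res_list]
        for r in res_list:
            d = r.to_dict()
            d["unit"] = key
            rows.append(d)
    return pd.DataFrame(rows)
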