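"""Pairwise-distance features, z-score standardization, and the MAE jitter check.

A valid frame's 34 landmarks are turned into the 561 inter-landmark
Euclidean distances (mm), ordered by canonical feature id. Distances are
invariant to rigid translation of the landmarks and scale linearly under
uniform scaling, which is what makes them usable across head positions.

Standardization is the usual z-score, fitted on training rows only and
applied unchanged to test rows. The standard-deviation convention is
population (divide by n) by default; ``ddof`` is configurable. Features that
are constant on the training data have no defined z-score and are dropped
(and recorded on the fitted params).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import ATTENTION, INATTENTION
from .errors import InsufficientDataError, SchemaError, ValidationError
from .io import FrameLandmarks, SessionRecording
from .schema import N_PAIRS, PairIndex, iter_pair_arrays, pair_from_feature_id

logger = logging.getLogger(__name__)

_PAIR_I, _PAIR_J = iter_pair_arrays()

#: integer encoding of the class labels used throughout the package
LABEL_CODE = {ATTENTION: 1, INATTENTION: 0}
CODE_LABEL = {v: k for k, v in LABEL_CODE.items()}


def euclidean_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Euclidean distance between two 2D points (mm)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValidationError("euclidean_distance requires finite coordinates")
    return math.hypot(p[0] - q[0], p[1] - q[1])


def frame_distance_vector(frame: FrameLandmarks) -> np.ndarray | None:
    """All 561 pairwise distances of one frame, in feature_id order.

    Returns ``None`` (a skip signal, not an exception) for invalid frames.
    """
    if not frame.valid:
        logger.debug("skipping invalid frame %d", frame.frame_index)
        return None
    d = frame.coords[_PAIR_I] - frame.coords[_PAIR_J]
    return np.sqrt(np.einsum("ij,ij->i", d, d))


def _stack_distances(coords: np.ndarray) -> np.ndarray:
    """(n, 34, 2) coords -> (n, 561) distances, vectorized over frames."""
    d = coords[:, _PAIR_I, :] - coords[:, _PAIR_J, :]
    return np.sqrt(np.einsum("nij,nij->ni", d, d))


@dataclass
class FeatureMatrix:
    """samples x distance-features with labels and participant ids.

    ``labels`` is an int array (1 = attention, 0 = inattention);
    ``feature_ids`` names the columns by canonical pair id.
    """

    X: np.ndarray
    feature_ids: np.ndarray
    labels: np.ndarray
    participant_ids: np.ndarray
    frame_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.feature_ids = np.asarray(self.feature_ids, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        self.participant_ids = np.asarray(self.participant_ids, dtype=object)
        if self.frame_indices is None:
            self.frame_indices = np.arange(len(self.labels))
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        n, f = self.X.shape
        if not (len(self.labels) == len(self.participant_ids) == len(self.frame_indices) == n):
            raise ValidationError("row metadata length mismatch")
        if len(self.feature_ids) != f:
            raise ValidationError("feature_ids length must match X columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset_rows(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.X[idx],
            self.feature_ids,
            self.labels[idx],
            self.participant_ids[idx],
            self.frame_indices[idx],
        )

    def subset_features(self, feature_ids: Sequence[int]) -> "FeatureMatrix":
        feature_ids = np.asarray(feature_ids, dtype=int)
        pos = {fid: k for k, fid in enumerate(self.feature_ids)}
        missing = [int(f) for f in feature_ids if int(f) not in pos]
        if missing:
            raise SchemaError(f"feature ids not present in matrix: {missing}")
        cols = np.array([pos[int(f)] for f in feature_ids])
        return FeatureMatrix(
            self.X[:, cols], feature_ids, self.labels, self.participant_ids, self.frame_indices
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        cols["participant_id"] = self.participant_ids
        cols["frame"] = self.frame_indices
        cols["label"] = [CODE_LABEL[c] for c in self.labels]
        for k, fid in enumerate(self.feature_ids):
            p = pair_from_feature_id(int(fid))
            cols[f"f_{p.i}_{p.j}"] = self.X[:, k]
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        feat_cols = [c for c in df.columns if c.startswith("f_")]
        fids = []
        for c in feat_cols:
            _, i, j = c.split("_")
            from .schema import pair_index

            fids.append(pair_index(int(i), int(j)).feature_id)
        return cls(
            df[feat_cols].to_numpy(dtype=float),
            np.array(fids),
            np.array([LABEL_CODE[s] for s in df["label"]]),
            df["participant_id"].to_numpy(dtype=object),
            df["frame"].to_numpy(dtype=int),
        )


def concat_matrices(parts: Sequence[FeatureMatrix]) -> FeatureMatrix:
    if not parts:
        raise InsufficientDataError("no matrices to concatenate")
    fids = parts[0].feature_ids
    for p in parts[1:]:
        if not np.array_equal(p.feature_ids, fids):
            raise SchemaError("feature_ids differ across matrices")
    return FeatureMatrix(
        np.vstack([p.X for p in parts]),
        fids,
        np.concatenate([p.labels for p in parts]),
        np.concatenate([p.participant_ids for p in parts]),
        np.concatenate([p.frame_indices for p in parts]),
    )


def session_feature_matrix(
    session: SessionRecording,
    frame_labels: np.ndarray,
    drop_pair: PairIndex | None = None,
) -> FeatureMatrix:
    """Distance features for every valid, class-labeled frame of a session.

    Frames labeled ``invalid`` (and invalid frames) contribute no rows.
    ``drop_pair`` removes one named pair for strict 560-feature replication.
    """
    frame_labels = np.asarray(frame_labels)
    if len(frame_labels) != session.n_frames:
        raise ValidationError("frame_labels must align with session frames")
    keep = session.valid_mask() & np.isin(frame_labels, [ATTENTION, INATTENTION])
    coords = session.coords_array()[keep]
    X = _stack_distances(coords) if len(coords) else np.empty((0, N_PAIRS))
    feature_ids = np.arange(N_PAIRS)
    if drop_pair is not None:
        keep_cols = feature_ids != drop_pair.feature_id
        X = X[:, keep_cols]
        feature_ids = feature_ids[keep_cols]
    labels = np.array([LABEL_CODE[s] for s in frame_labels[keep]], dtype=int)
    return FeatureMatrix(
        X,
        feature_ids,
        labels,
        np.full(int(keep.sum()), session.participant_id, dtype=object),
        session.frame_indices()[keep],
    )


@dataclass
class StandardizationParams:
    """Per-feature mean and standard deviation fitted on training rows."""

    feature_ids: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    ddof: int = 0
    dropped_feature_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def standardize_fit(train: FeatureMatrix, ddof: int = 0) -> StandardizationParams:
    """Fit z-score parameters on training rows (population sd by default).

    Constant training features (sd == 0) are dropped with a warning and
    recorded in ``dropped_feature_ids``.
    """
    if train.n < 2:
        raise InsufficientDataError("standardization needs at least 2 rows")
    m = train.X.mean(axis=0)
    s = train.X.std(axis=0, ddof=ddof)
    # constant up to float cancellation error counts as constant
    keep = s > 1e-12 * np.maximum(1.0, np.abs(m))
    if not np.all(keep):
        dropped = train.feature_ids[~keep]
        logger.warning("dropping %d constant features: %s", len(dropped), dropped[:10])
    else:
        dropped = np.array([], dtype=int)
    return StandardizationParams(
        feature_ids=train.feature_ids[keep],
        mean=m[keep],
        std=s[keep],
        ddof=ddof,
        dropped_feature_ids=dropped,
    )


def standardize_apply(params: StandardizationParams, matrix: FeatureMatrix) -> FeatureMatrix:
    """Apply training z-score params: Z = (x - m) / s. No refit on test."""
    aligned = matrix.subset_features(params.feature_ids)
    Z = (aligned.X - params.mean) / params.std
    return FeatureMatrix(
        Z, aligned.feature_ids, aligned.labels, aligned.participant_ids, aligned.frame_indices
    )


def standardize_invert(params: StandardizationParams, matrix: FeatureMatrix) -> FeatureMatrix:
    """Undo :func:`standardize_apply` (round-trips within float precision)."""
    if not np.array_equal(matrix.feature_ids, params.feature_ids):
        raise SchemaError("matrix features do not match standardization params")
    X = matrix.X * params.std + params.mean
    return FeatureMatrix(
        X, matrix.feature_ids, matrix.labels, matrix.participant_ids, matrix.frame_indices
    )


def landmark_mae(
    session: SessionRecording,
    frame_labels: np.ndarray,
    pair: PairIndex | None = None,
    label: str = ATTENTION,
) -> float:
    """Mean absolute change of one pair's distance across consecutive frames.

    A quality check for landmark distortion under head pose and lighting: on
    a stable recording the distance between the two top-jaw landmarks barely
    moves between adjacent frames, so the MAE stays near zero. Only pairs of
    consecutive (adjacent frame index) valid frames carrying the requested
    class label are compared; invalid frames break the pairing.
    """
    from .schema import pair_index as _pair_index

    if pair is None:
        pair = _pair_index(0, 4)  # right top jaw <-> left top jaw
    frame_labels = np.asarray(frame_labels)
    usable = session.valid_mask() & (frame_labels == label)
    idx = session.frame_indices()
    coords = session.coords_array()
    dvals = {}
    for k in np.flatnonzero(usable):
        dvals[int(idx[k])] = euclidean_distance(coords[k, pair.i], coords[k, pair.j])
    diffs = [
        abs(dvals[f + 1] - dvals[f]) for f in sorted(dvals) if (f + 1) in dvals
    ]
    if not diffs:
        raise InsufficientDataError(
            f"need at least 2 consecutive valid {label!r} frames for MAE"
        )
    return float(np.mean(diffs))
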