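"""Distance-threshold feature selection.

The selection statistic for each landmark pair is the difference of class
mean distances,

    gf = mean(distance | inattention) - mean(distance | attention),

computed on training frames only. Pairs are ranked by gf in descending
order (an absolute-value ranking is available but off by default) and the
top k are kept, with k chosen in multiples of 10 (k = 20 by default, the
best-performing menu size). Ties are broken by smaller feature id so the
selection is deterministic.

Two readings of the class-mean step exist: mean landmark *coordinates* per
class (useful for visualizing the mean attention/inattention face) versus
mean per-frame *distances* per class. The published per-pair threshold
tables are in distance units, so the selection pipeline uses mean distances;
:func:`class_mean_face` provides the coordinate version for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import ATTENTION
from .errors import InsufficientDataError, SchemaError
from .features import LABEL_CODE, FeatureMatrix
from .io import SessionRecording
from .schema import DEFAULT_SCHEMA, PairIndex, pair_from_feature_id


@dataclass
class ClassMeanFace:
    """Per-class arithmetic mean of each landmark coordinate (mm)."""

    label: str
    mean_coords: np.ndarray  # (34, 2)
    n_frames: int


@dataclass
class ThresholdTable:
    """Per-pair class mean distances and the gf threshold, sorted by gf.

    ``gf_mm == inattention_mean_mm - attention_mean_mm`` exactly, per row;
    rows are ordered by descending gf (ties by smaller feature id).
    """

    feature_ids: np.ndarray
    attention_mean_mm: np.ndarray
    inattention_mean_mm: np.ndarray
    gf_mm: np.ndarray

    def __len__(self) -> int:
        return len(self.feature_ids)

    def pairs(self) -> list[PairIndex]:
        return [pair_from_feature_id(int(f)) for f in self.feature_ids]

    def to_frame(self, schema=DEFAULT_SCHEMA) -> pd.DataFrame:
        pairs = self.pairs()
        return pd.DataFrame(
            {
                "pair": [f"D:{p.i}-{p.j}" for p in pairs],
                "description": [
                    f"{schema.name(p.i)} - {schema.name(p.j)}" for p in pairs
                ],
                "inattention_mean_mm": self.inattention_mean_mm,
                "attention_mean_mm": self.attention_mean_mm,
                "gf_mm": self.gf_mm,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def class_mean_face(
    session: SessionRecording, frame_labels: np.ndarray, label: str = ATTENTION
) -> ClassMeanFace:
    """Mean landmark coordinates over a session's valid frames of one class."""
    frame_labels = np.asarray(frame_labels)
    keep = session.valid_mask() & (frame_labels == label)
    if not keep.any():
        raise InsufficientDataError(f"no valid frames with label {label!r}")
    coords = session.coords_array()[keep]
    return ClassMeanFace(label=label, mean_coords=coords.mean(axis=0), n_frames=int(keep.sum()))


def class_mean_distances(matrix: FeatureMatrix, label: str) -> np.ndarray:
    """Per-pair arithmetic mean distance over the class's rows."""
    code = LABEL_CODE[label]
    rows = matrix.labels == code
    if not rows.any():
        raise InsufficientDataError(f"no rows with label {label!r}")
    return matrix.X[rows].mean(axis=0)


def distance_thresholds(
    attention_means: np.ndarray,
    inattention_means: np.ndarray,
    feature_ids: np.ndarray | None = None,
) -> ThresholdTable:
    """gf = inattention mean - attention mean per pair, sorted descending.

    Swapping the two classes negates every gf (antisymmetry).
    """
    attention_means = np.asarray(attention_means, dtype=float)
    inattention_means = np.asarray(inattention_means, dtype=float)
    if attention_means.shape != inattention_means.shape:
        raise SchemaError("class mean vectors are misaligned")
    if feature_ids is None:
        feature_ids = np.arange(len(attention_means))
    feature_ids = np.asarray(feature_ids, dtype=int)
    if len(feature_ids) != len(attention_means):
        raise SchemaError("feature_ids misaligned with mean vectors")
    gf = inattention_means - attention_means
    # descending gf, ties by smaller feature_id
    order = np.lexsort((feature_ids, -gf))
    return ThresholdTable(
        feature_ids=feature_ids[order],
        attention_mean_mm=attention_means[order],
        inattention_mean_mm=inattention_means[order],
        gf_mm=gf[order],
    )


def thresholds_from_matrix(matrix: FeatureMatrix) -> ThresholdTable:
    """Convenience: class means + thresholds straight from a feature matrix."""
    att = class_mean_distances(matrix, "attention")
    inatt = class_mean_distances(matrix, "inattention")
    return distance_thresholds(att, inatt, matrix.feature_ids)


def select_top_k(table: ThresholdTable, k: int = 20, by_abs: bool = False) -> list[PairIndex]:
    """The k pairs with largest gf (ties -> smaller feature id); deterministic.

    ``select_top_k(k)`` is always a prefix of ``select_top_k(k + 10)``.
    With ``by_abs`` the ranking uses \\|gf\\| instead of signed gf.
    """
    if not (1 <= k <= len(table)):
        raise ValueError(f"k must be in 1..{len(table)}, got {k}")
    key = np.abs(table.gf_mm) if by_abs else table.gf_mm
    order = np.lexsort((table.feature_ids, -key))
    chosen = table.feature_ids[order[:k]]
    return [pair_from_feature_id(int(f)) for f in chosen]
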