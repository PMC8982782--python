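"""The 34-landmark face schema and the canonical pairwise-feature indexing.

The tracker this pipeline consumes reports 34 named fiducial points per video
frame (jaw line, brows, nose, eyes, lips), as 2D coordinates in millimetres.
Every unordered pair of distinct landmarks defines one geometric feature (the
Euclidean distance between the two points), giving C(34,2) = 561 features.
Features are identified by the rank of the pair (i, j), i < j, in
lexicographic order; that rank is stable across the whole package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import ValidationError

N_LANDMARKS = 34
N_PAIRS = N_LANDMARKS * (N_LANDMARKS - 1) // 2  # 561

#: Index -> name map of the tracked landmarks. The numbering is the tracker's
#: own and is not spatially sequential (e.g. 12 = nose tip sits between the
#: nose-boundary indices); it is kept verbatim so feature ids stay comparable
#: with published threshold tables.
LANDMARK_NAMES: tuple[str, ...] = (
    "right top jaw",            # 0
    "right jaw angle",          # 1
    "gnathion",                 # 2
    "left jaw angle",           # 3
    "left top jaw",             # 4
    "outer right brow",         # 5
    "right brow corner",        # 6
    "inner right brow corner",  # 7
    "inner left brow corner",   # 8
    "left brow center",         # 9
    "outer left brow corner",   # 10
    "nose root",                # 11
    "nose tip",                 # 12
    "nose lower right boundary",  # 13
    "nose bottom boundary",     # 14
    "nose lower left boundary",  # 15
    "outer right eye",          # 16
    "inner right eye",          # 17
    "inner left eye",           # 18
    "outer left eye",           # 19
    "right lip corner",         # 20
    "right apex upper lip",     # 21
    "upper lip center",         # 22
    "left apex upper lip",      # 23
    "left lip corner",          # 24
    "left edge lower lip",      # 25
    "lower lip center",         # 26
    "right edge lower lip",     # 27
    "bottom lower lip",         # 28
    "top lower lip",            # 29
    "upper corner right eye",   # 30
    "lower corner right eye",   # 31
    "upper corner left eye",    # 32
    "lower corner left eye",    # 33
)


@dataclass(frozen=True)
class LandmarkSchema:
    """Ordered list of (index, name) landmark entries.

    Invariants: exactly 34 entries, indices 0..33 each once, names unique.
    """

    points: tuple[tuple[int, str], ...] = tuple(enumerate(LANDMARK_NAMES))

    def __post_init__(self) -> None:
        if len(self.points) != N_LANDMARKS:
            raise ValidationError(
                f"schema must have {N_LANDMARKS} landmarks, got {len(self.points)}"
            )
        indices = [i for i, _ in self.points]
        names = [n for _, n in self.points]
        if sorted(indices) != list(range(N_LANDMARKS)):
            raise ValidationError("landmark indices must be 0..33, each exactly once")
        if len(set(names)) != N_LANDMARKS:
            raise ValidationError("landmark names must be unique")

    def name(self, index: int) -> str:
        return dict(self.points)[index]


DEFAULT_SCHEMA = LandmarkSchema()


@dataclass(frozen=True, order=True)
class PairIndex:
    """An unordered landmark pair and its canonical feature id.

    ``feature_id`` is the rank of (i, j), i < j, in lexicographic order over
    all unordered pairs, i.e. (0,1) -> 0 ... (32,33) -> 560.
    """

    i: int
    j: int
    feature_id: int

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"D:{self.i}-{self.j}"


def _check_landmark_index(k: int) -> None:
    if not (0 <= k < N_LANDMARKS):
        raise ValueError(f"landmark index {k} out of range 0..{N_LANDMARKS - 1}")


def pair_index(i: int, j: int) -> PairIndex:
    """Canonical feature index of the unordered pair {i, j}.

    Order-insensitive; raises ``ValueError`` for i == j or out-of-range
    indices. The mapping is a bijection between unordered pairs and
    feature ids 0..560.
    """
    _check_landmark_index(i)
    _check_landmark_index(j)
    if i == j:
        raise ValueError(f"a pair needs two distinct landmarks, got ({i}, {j})")
    a, b = (i, j) if i < j else (j, i)
    fid = a * N_LANDMARKS - a * (a + 1) // 2 + (b - a - 1)
    return PairIndex(a, b, fid)


def all_pairs() -> list[PairIndex]:
    """All 561 pairs in feature_id order."""
    return [pair_index(i, j) for i in range(N_LANDMARKS) for j in range(i + 1, N_LANDMARKS)]


def pair_from_feature_id(feature_id: int) -> PairIndex:
    """Inverse of :func:`pair_index` on the feature_id component."""
    if not (0 <= feature_id < N_PAIRS):
        raise ValueError(f"feature_id {feature_id} out of range 0..{N_PAIRS - 1}")
    return _PAIRS_BY_ID[feature_id]


def iter_pair_arrays() -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (i, j) index arrays over all pairs, in feature_id order."""
    return _PAIR_I.copy(), _PAIR_J.copy()


_PAIRS_BY_ID = all_pairs()
_PAIR_I = np.array([p.i for p in _PAIRS_BY_ID], dtype=np.intp)
_PAIR_J = np.array([p.j for p in _PAIRS_BY_ID], dtype=np.intp)


def feature_column_name(pair: PairIndex) -> str:
    """CSV column name for a pair feature, ``f_<i>_<j>``."""
    return f"f_{pair.i}_{pair.j}"


def _iter_feature_columns() -> Iterator[str]:
    for p in _PAIRS_BY_ID:
        yield feature_column_name(p)
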