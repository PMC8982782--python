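"""Reading and writing landmark-stream and stimulus-event CSV files.

Landmark CSV layout (one header row, comma separated, dot decimal, UTF-8)::

    frame,timestamp_ms,valid,x_0,y_0,...,x_33,y_33

A frame whose ``valid`` flag is false, or that has any missing/NaN
coordinate, is kept in the stream but marked invalid; invalid frames never
enter feature computation. This mirrors the confidence gating of the
landmark tracker: low-confidence frames are dropped, not imputed.

Event CSV layout::

    onset_ms,letter,is_target,clicked,looking_at_screen[,duration_ms]
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import StimulusEvent
from .errors import FormatError, ValidationError
from .schema import DEFAULT_SCHEMA, N_LANDMARKS, LandmarkSchema

logger = logging.getLogger(__name__)

_COORD_COLUMNS = [f"{axis}_{k}" for k in range(N_LANDMARKS) for axis in ("x", "y")]
_HEADER = ["frame", "timestamp_ms", "valid", *_COORD_COLUMNS]
_EVENT_HEADER = ["onset_ms", "letter", "is_target", "clicked", "looking_at_screen"]


@dataclass
class FrameLandmarks:
    """One video frame: 34 (x, y) landmark coordinates in mm plus validity."""

    frame_index: int
    timestamp_ms: float
    coords: np.ndarray  # (34, 2) float, mm; may be NaN when invalid
    valid: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_LANDMARKS, 2):
            raise ValidationError(
                f"coords must have shape ({N_LANDMARKS}, 2), got {self.coords.shape}"
            )
        if self.frame_index < 0 or self.timestamp_ms < 0:
            raise ValidationError("frame_index and timestamp_ms must be non-negative")
        if self.valid and not np.all(np.isfinite(self.coords)):
            self.valid = False


@dataclass
class SessionRecording:
    """An ordered landmark stream for one participant and one task level."""

    participant_id: str
    frames: list[FrameLandmarks]
    group: str = "TD"  # {"ASD", "TD"}
    severity: str = "none"  # {"mild", "moderate", "none"}
    task_level: str = "baseline"  # {"baseline", "easy", "medium", "hard"}
    frame_rate_hz: float = 16.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValidationError("frame_rate_hz must be positive")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("frame indices must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords_array(self) -> np.ndarray:
        """(n_frames, 34, 2) stacked coordinates (NaN for invalid frames)."""
        if not self.frames:
            return np.empty((0, N_LANDMARKS, 2))
        return np.stack([f.coords for f in self.frames])

    def valid_mask(self) -> np.ndarray:
        return np.array([f.valid for f in self.frames], dtype=bool)

    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp_ms for f in self.frames], dtype=float)

    def frame_indices(self) -> np.ndarray:
        return np.array([f.frame_index for f in self.frames], dtype=int)


def load_session(
    path: str | Path,
    schema: LandmarkSchema = DEFAULT_SCHEMA,
    **session_kwargs,
) -> SessionRecording:
    """Load a landmark CSV into a :class:`SessionRecording`.

    Rows with any missing/NaN coordinate get ``valid=False``. Raises
    :class:`FormatError` naming the first missing column for a malformed
    header and :class:`ValidationError` for non-monotone frame indices.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in _HEADER:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    coords = df[_COORD_COLUMNS].to_numpy(dtype=float).reshape(-1, N_LANDMARKS, 2)
    declared_valid = df["valid"].astype(bool).to_numpy()
    finite = np.all(np.isfinite(coords), axis=(1, 2))
    valid = declared_valid & finite

    frames = []
    for k in range(len(df)):
        frames.append(
            FrameLandmarks(
                frame_index=int(df["frame"].iloc[k]),
                timestamp_ms=float(df["timestamp_ms"].iloc[k]),
                coords=coords[k],
                valid=bool(valid[k]),
            )
        )
    session_kwargs.setdefault("participant_id", path.stem)
    session = SessionRecording(frames=frames, **session_kwargs)
    logger.info(
        "%s: loaded %d frames (%d invalid)", path, len(frames), int((~valid).sum())
    )
    return session


def write_session(session: SessionRecording, path: str | Path) -> None:
    """Write a session as a landmark CSV with fixed 6-decimal coordinates.

    ``load_session(write_session(s))`` reproduces the coordinates exactly at
    that rendering precision; an empty session yields a header-only file.
    """
    path = Path(path)
    rows = []
    for f in session.frames:
        row = {
            "frame": f.frame_index,
            "timestamp_ms": f"{f.timestamp_ms:.6f}",
            "valid": int(f.valid),
        }
        for k in range(N_LANDMARKS):
            x, y = f.coords[k]
            row[f"x_{k}"] = "" if not np.isfinite(x) else f"{x:.6f}"
            row[f"y_{k}"] = "" if not np.isfinite(y) else f"{y:.6f}"
        rows.append(row)
    df = pd.DataFrame(rows, columns=_HEADER)
    df.to_csv(path, index=False)


def load_events(path: str | Path, default_duration_ms: float = 1400.0) -> list[StimulusEvent]:
    """Load a CPT stimulus/response event log."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in _EVENT_HEADER:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    has_duration = "duration_ms" in df.columns
    events = []
    for _, r in df.iterrows():
        events.append(
            StimulusEvent(
                onset_ms=float(r["onset_ms"]),
                letter=str(r["letter"]),
                is_target=bool(r["is_target"]),
                clicked=bool(r["clicked"]),
                looking_at_screen=bool(r["looking_at_screen"]),
                duration_ms=float(r["duration_ms"]) if has_duration else default_duration_ms,
            )
        )
    return events


def write_events(events: list[StimulusEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "onset_ms": [e.onset_ms for e in events],
            "letter": [e.letter for e in events],
            "is_target": [int(e.is_target) for e in events],
            "clicked": [int(e.clicked) for e in events],
            "looking_at_screen": [int(e.looking_at_screen) for e in events],
            "duration_ms": [e.duration_ms for e in events],
        }
    )
    df.to_csv(path, index=False)
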