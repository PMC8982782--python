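"""Behavioral labeling of landmark frames from CPT stimulus/response logs.

The continuous performance task (CPT) shows one letter per trial for a fixed
duration (1400 ms by default); the subject clicks when the target letter
appears. Each letter presentation defines a time slot of the video; the slot
is labeled from observable behavior and response correctness:

======================  =========  =======  ============
looking_at_screen       is_target  clicked  slot label
======================  =========  =======  ============
True                    True       True     attention     (hit)
True                    False      False    attention     (correct rejection)
True                    True       False    inattention   (miss)
True                    False      True     inattention   (false alarm)
False                   *          *        inattention   (gaze off screen)
======================  =========  =======  ============

i.e. attention iff the subject is looking at the screen AND the response is
correct (``is_target == clicked``). Every frame inside a slot inherits the
slot label; invalid frames and frames outside all slots are labeled
``invalid``.

Slot membership convention: a frame belongs to a slot iff its full exposure
interval ``[t, t + 1/frame_rate)`` lies inside ``[onset, onset + duration)``.
At 16 Hz and 1400 ms this gives exactly ``floor(1400 * 16 / 1000) = 22``
frames per slot (frames 0..21 for an onset at 0 ms); the frame straddling
the slot boundary belongs to no slot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .errors import CoverageError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .io import SessionRecording

ATTENTION = "attention"
INATTENTION = "inattention"
INVALID = "invalid"


@dataclass(frozen=True)
class StimulusEvent:
    """One CPT letter presentation with the subject's response."""

    onset_ms: float
    letter: str
    is_target: bool
    clicked: bool
    looking_at_screen: bool
    duration_ms: float = 1400.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValidationError("duration_ms must be positive")


@dataclass(frozen=True)
class SlotLabel:
    """A labeled stimulus slot; ``frame_span`` is half-open on the right."""

    slot_index: int
    label: str
    frame_span: tuple[int, int]  # (first frame index, last frame index + 1)


def label_slot(event: StimulusEvent) -> str:
    """Attention iff looking at the screen and the response is correct."""
    correct = event.is_target == event.clicked
    return ATTENTION if (event.looking_at_screen and correct) else INATTENTION


def build_slots(session: "SessionRecording", events: list[StimulusEvent]) -> list[SlotLabel]:
    """Segment a session into labeled stimulus slots.

    Events must be sorted by onset with non-overlapping windows and must lie
    inside the recorded session window (else :class:`CoverageError` listing
    the offending onsets).
    """
    onsets = [e.onset_ms for e in events]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValidationError("events must be sorted by onset")
    for a, b in zip(events, events[1:]):
        if a.onset_ms + a.duration_ms > b.onset_ms + 1e-9:
            raise ValidationError("event windows must not overlap")

    if not events:
        return []
    if not session.frames:
        raise CoverageError(f"empty session cannot cover onsets {onsets}")

    dt = 1000.0 / session.frame_rate_hz
    t = session.timestamps()
    session_start = t[0]
    session_end = t[-1] + dt
    bad = [
        e.onset_ms
        for e in events
        if e.onset_ms < session_start - 1e-9 or e.onset_ms + e.duration_ms > session_end + 1e-9
    ]
    if bad:
        raise CoverageError(f"events outside session time range, onsets: {bad}")

    frame_idx = session.frame_indices()
    slots = []
    eps = 1e-6
    for k, e in enumerate(events):
        # frame fully contained in [onset, onset + duration)
        inside = (t >= e.onset_ms - eps) & (t + dt <= e.onset_ms + e.duration_ms + eps)
        pos = np.flatnonzero(inside)
        if pos.size:
            span = (int(frame_idx[pos[0]]), int(frame_idx[pos[-1]]) + 1)
        else:
            span = (0, 0)  # degenerate: slot shorter than a frame
        slots.append(SlotLabel(slot_index=k, label=label_slot(e), frame_span=span))
    return slots


def propagate_labels(session: "SessionRecording", slots: list[SlotLabel]) -> np.ndarray:
    """Per-frame label array aligned with ``session.frames``.

    Frames inside a slot inherit the slot label; invalid frames stay
    ``invalid`` regardless of slot; frames outside all slots are ``invalid``.
    Conservation: the three label counts always sum to ``session.n_frames``.
    """
    labels = np.full(session.n_frames, INVALID, dtype=object)
    frame_idx = session.frame_indices()
    for slot in slots:
        lo, hi = slot.frame_span
        in_span = (frame_idx >= lo) & (frame_idx < hi)
        labels[in_span] = slot.label
    labels[~session.valid_mask()] = INVALID
    return labels.astype(str)
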