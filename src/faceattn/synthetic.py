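"""Synthetic labeled landmark sessions with the structure the method assumes.

The generator emulates a child seated in front of a screen during a
continuous performance task. A canonical 3D face template (34 landmarks,
mm, bilaterally symmetric, scaled so cross-face pair distances span roughly
75-175 mm) is perturbed per participant (additive 3D shape offset), rotated
by a state-dependent head pose, orthographically projected to the 2D image
plane, and jittered with per-frame coordinate noise. Attention frames look
at the screen center (yaw ~ N(0, 3) degrees); inattention frames look
sideways (yaw ~ N(25, 5) degrees, direction fixed per participant). The
attention/inattention state evolves per stimulus slot as a two-state Markov
chain whose stationary distribution sets the class imbalance (~87%
attention at the defaults, matching the strong imbalance the method is
designed around). Event logs are generated to be consistent with the latent
state, so the annotation pipeline can be tested against the ground truth.

Positive yaw is defined as the head turn that swings the (deep-set) left
jaw landmarks toward the image plane; under orthographic projection this
*lengthens* the projected left-jaw-to-right-face distances, reproducing the
published pattern of positive distance thresholds concentrated on left
jaw x right brow/eye/nose pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotation import ATTENTION, INATTENTION, INVALID, StimulusEvent, build_slots, propagate_labels
from .errors import ValidationError
from .features import FeatureMatrix, concat_matrices, session_feature_matrix
from .io import FrameLandmarks, SessionRecording
from .schema import N_LANDMARKS, PairIndex, iter_pair_arrays
from .selection import ThresholdTable, distance_thresholds, select_top_k

# canonical frontal face template, mm: columns (x, y, z);
# +x toward the subject's left cheek as projected, +y up, +z toward camera.
_TEMPLATE_RAW = np.array(
    [
        (-72, 10, -60),   # 0 right top jaw
        (-62, -40, -50),  # 1 right jaw angle
        (0, -75, 10),     # 2 gnathion
        (62, -40, -50),   # 3 left jaw angle
        (72, 10, -60),    # 4 left top jaw
        (-52, 42, 5),     # 5 outer right brow
        (-30, 48, 12),    # 6 right brow corner
        (-12, 45, 15),    # 7 inner right brow corner
        (12, 45, 15),     # 8 inner left brow corner
        (30, 48, 12),     # 9 left brow center
        (52, 42, 5),      # 10 outer left brow corner
        (0, 35, 12),      # 11 nose root
        (0, 2, 30),       # 12 nose tip
        (-14, -6, 16),    # 13 nose lower right boundary
        (0, -10, 22),     # 14 nose bottom boundary
        (14, -6, 16),     # 15 nose lower left boundary
        (-45, 30, 2),     # 16 outer right eye
        (-16, 28, 8),     # 17 inner right eye
        (16, 28, 8),      # 18 inner left eye
        (45, 30, 2),      # 19 outer left eye
        (-26, -32, 12),   # 20 right lip corner
        (-10, -27, 18),   # 21 right apex upper lip
        (0, -26, 20),     # 22 upper lip center
        (10, -27, 18),    # 23 left apex upper lip
        (26, -32, 12),    # 24 left lip corner
        (14, -38, 14),    # 25 left edge lower lip
        (0, -40, 17),     # 26 lower lip center
        (-14, -38, 14),   # 27 right edge lower lip
        (0, -44, 15),     # 28 bottom lower lip
        (0, -34, 18),     # 29 top lower lip
        (-30, 33, 6),     # 30 upper corner right eye
        (-30, 25, 6),     # 31 lower corner right eye
        (30, 33, 6),      # 32 upper corner left eye
        (30, 25, 6),      # 33 lower corner left eye
    ],
    dtype=float,
)
DEFAULT_TEMPLATE = _TEMPLATE_RAW * 1.05


def _default_template() -> np.ndarray:
    return DEFAULT_TEMPLATE.copy()


@dataclass
class SyntheticConfig:
    """Generator parameters; the defaults define the standard study cohort."""

    n_participants_per_group: int = 8
    frames_per_participant: int = 3000
    frame_rate_hz: float = 16.0
    slot_duration_ms: float = 1400.0
    template: np.ndarray = field(default_factory=_default_template)
    attention_yaw_mean_deg: float = 0.0
    attention_yaw_sd_deg: float = 3.0
    inattention_yaw_mean_deg: float = 25.0
    inattention_yaw_sd_deg: float = 5.0
    yaw_sign_mode: str = "fixed"  # "fixed" (+1 for everyone) or "random" per participant
    pitch_jitter_sd_deg: float = 2.0
    participant_offset_sd_mm: float = 2.0
    coordinate_noise_sd_mm: float = 1.0
    invalid_rate: float = 0.02
    p_stay_attention: float = 0.90
    p_recover_attention: float = 0.65  # P(attention | previous inattention)
    seed: int = 0

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=float)
        if self.template.shape != (N_LANDMARKS, 3):
            raise ValidationError(f"template must be ({N_LANDMARKS}, 3)")
        for name in (
            "attention_yaw_sd_deg",
            "inattention_yaw_sd_deg",
            "pitch_jitter_sd_deg",
            "participant_offset_sd_mm",
            "coordinate_noise_sd_mm",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0 <= self.invalid_rate < 1):
            raise ValidationError("invalid_rate must be in [0, 1)")
        for name in ("p_stay_attention", "p_recover_attention"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.yaw_sign_mode not in ("fixed", "random"):
            raise ValidationError("yaw_sign_mode must be 'fixed' or 'random'")

    @classmethod
    def heterogeneous(cls, **overrides) -> "SyntheticConfig":
        """A cohort with strong participant idiosyncrasy: large per-person
        shape offsets and a per-participant gaze-aversion side."""
        defaults = dict(participant_offset_sd_mm=8.0, yaw_sign_mode="random")
        defaults.update(overrides)
        return cls(**defaults)


def stationary_attention_fraction(config: SyntheticConfig) -> float:
    """Stationary P(attention) of the two-state slot Markov chain."""
    p_ai = 1.0 - config.p_stay_attention
    p_ia = config.p_recover_attention
    if p_ai + p_ia == 0:
        return 1.0
    return p_ia / (p_ai + p_ia)


def project_pose(points3d: np.ndarray, yaw_deg: float, pitch_deg: float = 0.0) -> np.ndarray:
    """Rotate by yaw (about the vertical axis) then pitch (about the lateral
    axis) and orthographically project to the (x, y) image plane."""
    t = np.deg2rad(yaw_deg)
    p = np.deg2rad(pitch_deg)
    x, y, z = points3d[:, 0], points3d[:, 1], points3d[:, 2]
    x1 = x * np.cos(t) - z * np.sin(t)
    z1 = x * np.sin(t) + z * np.cos(t)
    y1 = y * np.cos(p) - z1 * np.sin(p)
    return np.column_stack([x1, y1])


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery tests."""

    frame_labels: np.ndarray  # true per-frame label (attention/inattention/invalid)
    yaw_sign: int
    inattention_yaw_mean_deg: float
    planted_table: ThresholdTable  # analytic per-pair projected-distance shifts


@dataclass
class ParticipantBundle:
    session: SessionRecording
    events: list[StimulusEvent]
    truth: GroundTruth


def planted_discriminative_pairs(
    config: SyntheticConfig, yaw_sign: int = 1, n_quadrature: int = 21
) -> ThresholdTable:
    """Analytic per-pair shift of the expected projected distance.

    For each class the expected pairwise distance is integrated over the
    class's yaw distribution (Gauss-Hermite quadrature; pitch at its zero
    mean). The returned table has gf = inattention - attention expectation
    per pair, sorted descending — the planted counterpart of the empirical
    distance-threshold table. Rankings are invariant to uniform scaling of
    the template. With zero yaw difference all shifts are zero.
    """
    pi, pj = iter_pair_arrays()
    nodes, weights = np.polynomial.hermite.hermgauss(n_quadrature)
    weights = weights / np.sqrt(np.pi)

    def expected_distances(mean_deg: float, sd_deg: float) -> np.ndarray:
        acc = np.zeros(len(pi))
        for xk, wk in zip(nodes, weights):
            yaw = mean_deg + np.sqrt(2.0) * sd_deg * xk
            pts = project_pose(config.template, yaw)
            d = pts[pi] - pts[pj]
            acc += wk * np.sqrt(np.einsum("ij,ij->i", d, d))
        return acc

    att = expected_distances(config.attention_yaw_mean_deg, config.attention_yaw_sd_deg)
    inatt = expected_distances(
        yaw_sign * config.inattention_yaw_mean_deg, config.inattention_yaw_sd_deg
    )
    return distance_thresholds(att, inatt)


def planted_top_pairs(config: SyntheticConfig, k: int = 20, yaw_sign: int = 1) -> list[PairIndex]:
    """The k pairs with the largest planted (signed) distance shift."""
    return select_top_k(planted_discriminative_pairs(config, yaw_sign=yaw_sign), k=k)


_LETTERS = "ABCDEFGHKLMNPRSTUVZ"


def _event_for_state(state: str, rng: np.random.Generator) -> StimulusEvent:
    """A CPT event whose (target, click, gaze) combination maps back to
    ``state`` under the annotation truth table."""
    if state == ATTENTION:
        if rng.random() < 0.5:  # hit
            target, clicked, looking = True, True, True
        else:  # correct rejection
            target, clicked, looking = False, False, True
    else:
        variant = rng.integers(4)
        if variant == 0:  # miss while looking
            target, clicked, looking = True, False, True
        elif variant == 1:  # false alarm while looking
            target, clicked, looking = False, True, True
        elif variant == 2:  # looked away on a target
            target, clicked, looking = True, bool(rng.random() < 0.5), False
        else:  # looked away on a non-target
            target, clicked, looking = False, bool(rng.random() < 0.5), False
    letter = "X" if target else _LETTERS[rng.integers(len(_LETTERS))]
    return StimulusEvent(
        onset_ms=0.0,  # filled by caller
        letter=letter,
        is_target=target,
        clicked=clicked,
        looking_at_screen=looking,
    )


def generate_participant(
    config: SyntheticConfig,
    participant_seed,
    participant_id: str = "P1",
    group: str = "TD",
    severity: str = "none",
) -> ParticipantBundle:
    """One participant's session, event log and ground truth.

    Per slot the attention state follows the Markov chain; frames are the
    participant's perturbed template rotated by the state-dependent pose,
    projected, translated to screen coordinates and jittered; a fraction
    ``invalid_rate`` of frames is dropped as tracking failures (NaN
    coordinates, valid=False).
    """
    rng = np.random.default_rng(participant_seed)
    offset = rng.normal(0.0, config.participant_offset_sd_mm, size=(N_LANDMARKS, 3))
    face = config.template + offset
    if config.yaw_sign_mode == "random":
        yaw_sign = int(rng.choice([-1, 1]))
    else:
        yaw_sign = 1

    dt = 1000.0 / config.frame_rate_hz
    n_frames = config.frames_per_participant
    duration_ms = n_frames * dt
    n_slots = int(duration_ms // config.slot_duration_ms)

    # slot states from the two-state Markov chain
    p_att = stationary_attention_fraction(config)
    states = []
    state = ATTENTION if rng.random() < p_att else INATTENTION
    for _ in range(n_slots):
        states.append(state)
        if state == ATTENTION:
            state = ATTENTION if rng.random() < config.p_stay_attention else INATTENTION
        else:
            state = ATTENTION if rng.random() < config.p_recover_attention else INATTENTION

    events = []
    for k, st in enumerate(states):
        e = _event_for_state(st, rng)
        events.append(replace(e, onset_ms=k * config.slot_duration_ms, duration_ms=config.slot_duration_ms))

    center = np.array([200.0, 150.0])
    frames = []
    true_labels = np.full(n_frames, INVALID, dtype=object)
    for f in range(n_frames):
        t = f * dt
        slot = int(t // config.slot_duration_ms)
        in_slot = slot < n_slots and (
            t >= slot * config.slot_duration_ms - 1e-9
            and t + dt <= (slot + 1) * config.slot_duration_ms + 1e-9
        )
        st = states[min(slot, n_slots - 1)] if n_slots else ATTENTION
        if st == ATTENTION:
            yaw = rng.normal(config.attention_yaw_mean_deg, config.attention_yaw_sd_deg)
        else:
            yaw = yaw_sign * rng.normal(
                config.inattention_yaw_mean_deg, config.inattention_yaw_sd_deg
            )
        pitch = rng.normal(0.0, config.pitch_jitter_sd_deg)
        coords = project_pose(face, yaw, pitch) + center
        if config.coordinate_noise_sd_mm > 0:
            coords = coords + rng.normal(0.0, config.coordinate_noise_sd_mm, size=coords.shape)
        valid = rng.random() >= config.invalid_rate
        if not valid:
            coords = np.full((N_LANDMARKS, 2), np.nan)
        frames.append(FrameLandmarks(frame_index=f, timestamp_ms=t, coords=coords, valid=valid))
        if in_slot and valid:
            true_labels[f] = st

    session = SessionRecording(
        participant_id=participant_id,
        frames=frames,
        group=group,
        severity=severity,
        frame_rate_hz=config.frame_rate_hz,
    )
    truth = GroundTruth(
        frame_labels=true_labels.astype(str),
        yaw_sign=yaw_sign,
        inattention_yaw_mean_deg=config.inattention_yaw_mean_deg,
        planted_table=planted_discriminative_pairs(config, yaw_sign=yaw_sign),
    )
    return ParticipantBundle(session=session, events=events, truth=truth)


def generate_cohort(config: SyntheticConfig) -> list[ParticipantBundle]:
    """Both groups (ASD then TD), reproducible from ``config.seed``.

    Per-participant seeds are spawned deterministically from the cohort
    seed, so the same seed yields bit-identical cohorts and different seeds
    yield independent noise realizations.
    """
    ss = np.random.SeedSequence(config.seed)
    n = config.n_participants_per_group
    children = ss.spawn(2 * n)
    bundles = []
    sev_rng = np.random.default_rng(ss.spawn(1)[0])
    for k in range(n):
        severity = str(sev_rng.choice(["mild", "moderate"]))
        bundles.append(
            generate_participant(
                config, children[k], participant_id=f"A{k + 1:02d}", group="ASD", severity=severity
            )
        )
    for k in range(n):
        bundles.append(
            generate_participant(
                config, children[n + k], participant_id=f"T{k + 1:02d}", group="TD", severity="none"
            )
        )
    return bundles


def bundle_feature_matrix(bundle: ParticipantBundle) -> FeatureMatrix:
    """Run the annotation pipeline on one bundle and extract distances."""
    slots = build_slots(bundle.session, bundle.events)
    labels = propagate_labels(bundle.session, slots)
    return session_feature_matrix(bundle.session, labels)


def cohort_feature_matrix(bundles: list[ParticipantBundle]) -> FeatureMatrix:
    return concat_matrices([bundle_feature_matrix(b) for b in bundles])


def write_bundle(bundle: ParticipantBundle, directory: str | Path) -> None:
    """Emit landmark CSV + event CSV + ground-truth JSON for one participant."""
    import json

    from .io import write_events, write_session

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pid = bundle.session.participant_id
    write_session(bundle.session, directory / f"{pid}_landmarks.csv")
    write_events(bundle.events, directory / f"{pid}_events.csv")
    planted = bundle.truth.planted_table
    payload = {
        "participant_id": pid,
        "group": bundle.session.group,
        "yaw_sign": bundle.truth.yaw_sign,
        "inattention_yaw_mean_deg": bundle.truth.inattention_yaw_mean_deg,
        "frame_labels": bundle.truth.frame_labels.tolist(),
        "planted_top20": [str(p) for p in select_top_k(planted, k=20)],
    }
    with open(directory / f"{pid}_truth.json", "w") as fh:
        json.dump(payload, fh, indent=1)
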