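import numpy as np
import pytest

from faceattn import (
    ATTENTION,
    SyntheticConfig,
    build_slots,
    generate_cohort,
    generate_participant,
    landmark_mae,
    pair_index,
    planted_discriminative_pairs,
    planted_top_pairs,
    propagate_labels,
    select_top_k,
    stationary_attention_fraction,
    thresholds_from_matrix,
)
from faceattn.errors import ValidationError
from faceattn.synthetic import bundle_feature_matrix, cohort_feature_matrix


def test_same_seed_identical_cohorts_different_seeds_differ():
    cfg = SyntheticConfig(n_participants_per_group=1, frames_per_participant=100, seed=3)
    c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
    for b1, b2 in zip(c1, c2):
        np.testing.assert_array_equal(b1.session.coords_array(), b2.session.coords_array())
        assert b1.events == b2.events
        np.testing.assert_array_equal(b1.truth.frame_labels, b2.truth.frame_labels)
    cfg2 = SyntheticConfig(n_participants_per_group=1, frames_per_participant=100, seed=4)
    c3 = generate_cohort(cfg2)
    assert not np.array_equal(
        np.nan_to_num(c1[0].session.coords_array()), np.nan_to_num(c3[0].session.coords_array())
    )


def _frozen_config(**kw):
    """All randomness off: one pose, no noise, no dropouts."""
    base = dict(
        n_participants_per_group=1,
        frames_per_participant=100,
        attention_yaw_sd_deg=0.0,
        inattention_yaw_sd_deg=0.0,
        pitch_jitter_sd_deg=0.0,
        participant_offset_sd_mm=0.0,
        coordinate_noise_sd_mm=0.0,
        invalid_rate=0.0,
        p_stay_attention=1.0,
        p_recover_attention=1.0,  # stationary distribution = all attention
        seed=0,
    )
    base.update(kw)
    return SyntheticConfig(**base)


def test_zero_noise_fixed_pose_frames_identical_and_mae_zero():
    bundle = generate_participant(_frozen_config(), 0)
    coords = bundle.session.coords_array()
    assert np.ptp(coords, axis=0).max() == 0.0
    labels = bundle.truth.frame_labels
    assert set(labels[labels != "invalid"]) == {ATTENTION}
    for pair in (pair_index(0, 4), pair_index(3, 16), pair_index(12, 22)):
        assert landmark_mae(bundle.session, labels, pair=pair) == 0.0


def test_annotation_pipeline_reproduces_generated_truth():
    cfg = SyntheticConfig(n_participants_per_group=1, frames_per_participant=500, seed=9)
    bundle = generate_participant(cfg, 11)
    slots = build_slots(bundle.session, bundle.events)
    labels = propagate_labels(bundle.session, slots)
    np.testing.assert_array_equal(labels, bundle.truth.frame_labels)


def test_no_pose_difference_yields_null_thresholds():
    cfg = SyntheticConfig(
        n_participants_per_group=2,
        frames_per_participant=800,
        inattention_yaw_mean_deg=0.0,
        inattention_yaw_sd_deg=3.0,  # same distribution as attention
        seed=5,
    )
    table = planted_discriminative_pairs(cfg)
    np.testing.assert_allclose(table.gf_mm, 0.0, atol=1e-9)
    mat = cohort_feature_matrix(generate_cohort(cfg))
    emp = thresholds_from_matrix(mat)
    assert np.abs(emp.gf_mm).max() < 2.0  # only sampling noise remains


def test_empirical_gf_matches_analytic_shift_within_3_se():
    """Per-participant gf estimates of the planted top pair scatter around
    the quadrature expectation; participants are the independent units."""
    cfg = SyntheticConfig(seed=21, n_participants_per_group=6, frames_per_participant=1500)
    top = planted_top_pairs(cfg, k=1)[0]
    table = planted_discriminative_pairs(cfg)
    analytic = table.gf_mm[list(table.feature_ids).index(top.feature_id)]

    per_participant = []
    for bundle in generate_cohort(cfg):
        t = thresholds_from_matrix(bundle_feature_matrix(bundle))
        per_participant.append(t.gf_mm[list(t.feature_ids).index(top.feature_id)])
    per_participant = np.array(per_participant)
    se = per_participant.std(ddof=1) / np.sqrt(len(per_participant))
    assert abs(per_participant.mean() - analytic) < 3 * se


def test_class_balance_matches_stationary_distribution():
    cfg = SyntheticConfig(n_participants_per_group=4, frames_per_participant=2000, seed=2)
    mat = cohort_feature_matrix(generate_cohort(cfg))
    expected = stationary_attention_fraction(cfg)
    n = len(mat.labels)
    # slots are correlated; allow a generous multiple of the iid binomial se
    tol = 6 * np.sqrt(expected * (1 - expected) / (n / 22))
    assert abs(mat.labels.mean() - expected) < tol


def test_planted_ranking_invariant_to_uniform_template_scaling():
    cfg = SyntheticConfig()
    scaled = SyntheticConfig(template=cfg.template * 3.0)
    ids1 = [p.feature_id for p in planted_top_pairs(cfg, k=30)]
    ids2 = [p.feature_id for p in planted_top_pairs(scaled, k=30)]
    assert ids1 == ids2


def test_yaw_shifts_concentrate_on_cross_face_left_jaw_pairs():
    """Pure yaw moves the deep-set left-jaw landmarks most in projection, so
    the biggest planted shifts pair the left jaw region with right-side or
    midline landmarks — the published pattern of selected regions."""
    top = planted_top_pairs(SyntheticConfig(), k=20)
    left_jaw = {2, 3, 4}
    assert sum(1 for p in top if p.i in left_jaw or p.j in left_jaw) >= 15
    # all top planted shifts are positive (inattention mean larger)
    table = planted_discriminative_pairs(SyntheticConfig())
    assert table.gf_mm[0] > 10.0 and np.all(table.gf_mm[:20] > 0)


def test_top20_selection_recovers_planted_pairs_on_small_cohort(small_config, small_matrix):
    table = thresholds_from_matrix(small_matrix)
    got = {p.feature_id for p in select_top_k(table, k=20)}
    planted = {p.feature_id for p in planted_top_pairs(small_config, k=20)}
    assert len(got & planted) >= 15


def test_heterogeneity_knob_widens_participant_specific_vs_lopo_gap():
    from faceattn import leave_one_participant_out, make_model_factory, participant_specific_eval

    factory = make_model_factory("svm")
    gaps = []
    for offset_sd, sign_mode in ((0.5, "fixed"), (8.0, "random")):
        cfg = SyntheticConfig(
            n_participants_per_group=3,
            frames_per_participant=600,
            participant_offset_sd_mm=offset_sd,
            yaw_sign_mode=sign_mode,
            seed=13,
        )
        mat = cohort_feature_matrix(generate_cohort(cfg))
        _, ps = participant_specific_eval(mat, factory, seed=0, n_repeats=2)
        _, lopo = leave_one_participant_out(mat, factory, seed=0)
        gaps.append(ps["acc_mean"] - lopo["acc_mean"])
    assert gaps[1] > gaps[0]


def test_config_validation():
    with pytest.raises(ValidationError):
        SyntheticConfig(invalid_rate=1.5)
    with pytest.raises(ValidationError):
        SyntheticConfig(coordinate_noise_sd_mm=-1.0)
    with pytest.raises(ValidationError):
        SyntheticConfig(yaw_sign_mode="sometimes")
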