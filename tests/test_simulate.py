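"""Generator ground truth: determinism, event geometry, artifacts, scores."""

import numpy as np
import pytest
from scipy.signal import welch

from aimnet.montage import CHANNELS_10_20
from aimnet.simulate import (
    ConfigurationError,
    CouplingSpec,
    PerformanceRecord,
    SimulationConfig,
    inject_artifacts,
    simulate_cohort,
    simulate_subject,
)

from _utils import small_config


def test_same_seed_gives_identical_subjects():
    cfg = small_config(seed=7, artifact_rate=0.1)
    a = simulate_subject(cfg, 0)
    b = simulate_subject(cfg, 0)
    assert np.array_equal(a.recordings["control"].samples, b.recordings["control"].samples)
    assert np.array_equal(a.resting.samples, b.resting.samples)
    assert a.performance["control"].ring_scores == b.performance["control"].ring_scores
    assert a.artifact_trials == b.artifact_trials


def test_different_seeds_differ():
    a = simulate_subject(small_config(seed=1), 0)
    b = simulate_subject(small_config(seed=2), 0)
    assert not np.array_equal(a.recordings["control"].samples, b.recordings["control"].samples)


def test_event_margins_admit_widest_window():
    cfg = small_config(shots_per_condition=15)
    sub = simulate_subject(cfg, 0)
    for rec in sub.recordings.values():
        assert len(rec.events) == 15
        fs = rec.sampling_rate
        assert rec.events.min() >= 5 * fs
        assert rec.events.max() <= rec.n_samples - 2 * fs


def test_unknown_coupling_channel_rejected():
    with pytest.raises(ConfigurationError, match="not in the montage"):
        small_config(coupling_specs=(CouplingSpec(pair=("C3", "XX"), band="beta"),))


def test_excessive_effect_delta_rejected():
    with pytest.raises(ConfigurationError, match="must not exceed 1"):
        small_config(
            coupling_specs=(
                CouplingSpec(pair=("C3", "C4"), band="beta", strength=0.9,
                             condition_effect_delta=0.2),
            )
        )


def test_montage_has_30_analysis_channels():
    assert len(CHANNELS_10_20) == 30
    assert "A1" not in CHANNELS_10_20 and "A2" not in CHANNELS_10_20


def test_resting_alpha_peak_matches_drawn_iaf(plain_subject):
    _, sub = plain_subject
    rec = sub.resting
    a, b = rec.resting_segments["eyes_closed"]
    occ = [rec.channel_labels.index(c) for c in ("O1", "O2", "Oz")]
    fs = rec.sampling_rate
    f, p = welch(rec.samples[occ, a:b], fs=fs, nperseg=int(2 * fs))
    band = (f >= 8) & (f <= 12)
    peak = f[band][np.argmax(p.mean(axis=0)[band])]
    assert abs(peak - sub.iaf) <= 0.5


class TestInjectArtifacts:
    def test_zero_rate_leaves_recording_unchanged(self, plain_subject):
        _, sub = plain_subject
        rec = sub.recordings["control"]
        out, flagged = inject_artifacts(rec, 0.0, 500.0, seed=3)
        assert flagged == []
        assert np.array_equal(out.samples, rec.samples)

    def test_unit_rate_flags_every_trial(self, plain_subject):
        _, sub = plain_subject
        rec = sub.recordings["control"]
        out, flagged = inject_artifacts(rec, 1.0, 500.0, seed=3)
        assert flagged == list(range(len(rec.events)))

    def test_flagged_trials_carry_transient_above_amplitude(self, plain_subject):
        _, sub = plain_subject
        rec = sub.recordings["control"]
        out, flagged = inject_artifacts(rec, 0.5, 500.0, seed=3)
        fs = int(rec.sampling_rate)
        for t in flagged:
            ev = rec.events[t]
            seg = out.samples[:, ev - 3 * fs : ev]
            assert np.ptp(seg, axis=1).max() > 400.0
        untouched = [t for t in range(len(rec.events)) if t not in flagged]
        for t in untouched[:3]:
            ev = rec.events[t]
            sl = slice(ev - 3 * fs, ev)
            assert np.array_equal(out.samples[:, sl], rec.samples[:, sl])

    def test_negative_amplitude_rejected(self, plain_subject):
        _, sub = plain_subject
        with pytest.raises(ValueError, match="non-negative"):
            inject_artifacts(sub.recordings["control"], 0.1, -5.0, seed=0)


class TestScores:
    def test_ring_scores_live_on_the_scoring_scale(self):
        cfg = small_config(n_subjects=3, conditions=("control", "weak_light"), seed=5)
        for i in range(3):
            sub = simulate_subject(cfg, i)
            for rec in sub.performance.values():
                assert len(rec.ring_scores) == cfg.shots_per_condition
                assert all(s == 0 or 5 <= s <= 10 for s in rec.ring_scores)

    def test_mean_score_is_arithmetic_mean(self):
        rec = PerformanceRecord("sub-01", "control", [0, 5, 10])
        assert rec.mean_score == pytest.approx(5.0)

    def test_invalid_ring_score_rejected(self):
        with pytest.raises(ValueError, match="ring scores"):
            PerformanceRecord("sub-01", "control", [3])

    def test_latent_calibration_hits_observed_group_means(self):
        # the latent Gaussian mean is solved so that the *discretized*
        # {0,5..10} expectation equals the configured observed group mean
        from aimnet.simulate import SCORE_MEANS, SCORE_SDS, _calibrated_latent_mean, _discretize_scores

        rng = np.random.default_rng(0)
        for cond, target in SCORE_MEANS.items():
            sigma = float(np.hypot(SCORE_SDS[cond], 1.0))
            mu = _calibrated_latent_mean(target, sigma)
            draws = _discretize_scores(mu + sigma * rng.standard_normal(200_000))
            assert draws.mean() == pytest.approx(target, abs=0.03)

    def test_group_means_track_study_conditions(self):
        cfg = small_config(n_subjects=12, conditions=("control", "weak_light"),
                          shots_per_condition=60, seed=9)
        means = {"control": [], "weak_light": []}
        for i in range(cfg.n_subjects):
            sub = simulate_subject(cfg, i)
            for cond, rec in sub.performance.items():
                means[cond].append(rec.mean_score)
        # 12 subjects: ~3 standard errors of the between-subject spread
        assert np.mean(means["control"]) == pytest.approx(8.02, abs=0.8)
        assert np.mean(means["weak_light"]) == pytest.approx(5.38, abs=1.5)


def test_strong_coupling_yields_high_downstream_wpli(coupled_subject):
    # strength 0.9, lag pi/4 in beta between C3-C4: the full preprocessing +
    # connectivity chain must report near-saturated synchrony on clean data
    from _utils import subject_band_wpli

    _, sub = coupled_subject
    m = subject_band_wpli(sub)
    i = m.channel_labels.index("C3")
    j = m.channel_labels.index("C4")
    assert m.values[i, j] > 0.8


def test_downstream_wpli_monotone_in_coupling_strength():
    # stronger planted coupling must never lower the measured WPLI of the pair
    from _utils import subject_band_wpli

    wplis = []
    for strength in (0.2, 0.5, 0.9):
        cfg = small_config(
            n_subjects=1,
            coupling_specs=(CouplingSpec(pair=("C3", "C4"), band="beta", strength=strength),),
            subject_coupling_sd=0.0,
            seed=55,
        )
        m = subject_band_wpli(simulate_subject(cfg, 0))
        i = m.channel_labels.index("C3")
        j = m.channel_labels.index("C4")
        wplis.append(float(m.values[i, j]))
    assert wplis[0] < wplis[1] < wplis[2]


def test_cohort_writes_files_and_manifest(tmp_path):
    cfg = small_config(n_subjects=1, shots_per_condition=3, seed=4)
    subjects, manifest = simulate_cohort(cfg, tmp_path / "cohort")
    assert (tmp_path / "cohort" / "ground_truth.json").exists()
    assert (tmp_path / "cohort" / "scores.csv").exists()
    assert (tmp_path / "cohort" / "sub-01" / "sub-01_control.csv").exists()
    assert manifest["subjects"]["sub-01"]["iaf"] == subjects[0].iaf


def test_single_subject_cohort_is_valid():
    cfg = small_config(n_subjects=1, shots_per_condition=2, seed=8)
    subjects, manifest = simulate_cohort(cfg)
    assert len(subjects) == 1
    assert list(manifest["subjects"]) == ["sub-01"]
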