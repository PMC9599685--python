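"""Synthetic shooting-EEG cohort generator with known ground truth.

Emulates the study design this package analyzes: 30 subjects fire
2 x 30 shots under each of three conditions (control, noise disturbance,
weak light) while 30-channel 10-20 EEG is recorded at 1000 Hz, preceded
by eyes-closed / eyes-open resting runs. Every downstream quantity the
pipeline estimates — individual alpha frequency, band-limited lagged
coupling (hence WPLI), condition effects, artifact contamination, and
the rank correlation between a network feature and ring scores — is
planted with a known value and recorded in a ground-truth manifest.

Signal model
------------
Each channel is 1/f^alpha background noise (microvolts). A coupled pair
shares a narrowband oscillator; the second channel receives a copy
delayed by lag/(2*pi*f_center) seconds (exact fractional delay applied
in the frequency domain), so the pair carries a genuine non-zero phase
lag. A single broadband source added with zero lag and channel-specific
gains stands in for volume conduction. Eyes-closed resting segments
carry an amplitude-modulated sinusoid at the subject's drawn IAF on the
occipital channels. Artifacts are large transient pulses inserted into
randomly chosen trials.

Ring scores are drawn through a discretized Gaussian copula against the
subject-level coupling perturbation, clipped to the {0, 5..10} scoring
scale, so a target Spearman correlation between a network feature and
mean score can be planted exactly at the latent level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy import fft as sfft
from scipy.optimize import brentq
from scipy.stats import norm

from .bands import BAND_NAMES, bands_from_iaf
from .montage import CHANNELS_10_20, OCCIPITAL_CHANNELS

CONDITIONS = ("control", "noise", "weak_light")

# Observed group ring-score means/SDs of the study design being emulated.
SCORE_MEANS = {"control": 8.02, "noise": 8.00, "weak_light": 5.38}
SCORE_SDS = {"control": 0.76, "noise": 0.81, "weak_light": 1.56}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class CouplingSpec:
    """Planted band-limited, phase-lagged coupling between one channel pair.

    ``strength`` in [0, 1] is the mixing proportion of the shared
    oscillator (1 = pure oscillator); ``condition_effect_delta`` is added
    to the strength in ``effect_condition`` only.
    """

    pair: tuple[str, str]
    band: str
    phase_lag: float = math.pi / 4
    strength: float = 0.5
    condition_effect_delta: float = 0.0
    effect_condition: str = "noise"


@dataclass(frozen=True)
class PerformanceSpec:
    """Planted rank correlation between a network feature and mean score.

    ``network_feature`` is a descriptive tag recorded in the manifest
    (e.g. ``"edge:C3-C4:beta"``); the latent driver is the subject-level
    coupling-strength perturbation, which is what the named feature
    measures downstream.
    """

    network_feature: str = "mean_wpli:beta"
    rho: float = 0.6


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 30
    conditions: tuple[str, ...] = CONDITIONS
    shots_per_condition: int = 60
    sampling_rate: float = 1000.0
    channel_labels: tuple[str, ...] = CHANNELS_10_20
    iaf_mean: float = 10.0
    iaf_sd: float = 1.0
    coupling_specs: tuple[CouplingSpec, ...] = ()
    common_source_gain: float = 0.3
    noise_color: float = 1.0
    background_std: float = 12.0  # microvolts
    artifact_rate: float = 0.0
    artifact_amplitude: float = 500.0  # microvolts
    performance_spec: PerformanceSpec | None = None
    score_means: dict[str, float] = field(default_factory=lambda: dict(SCORE_MEANS))
    score_sds: dict[str, float] = field(default_factory=lambda: dict(SCORE_SDS))
    shot_noise_sd: float = 1.0
    subject_coupling_sd: float = 0.12
    shot_interval_s: float = 5.0
    lead_s: float = 6.0
    tail_s: float = 3.0
    rest_eyes_closed_s: float = 150.0
    rest_eyes_open_s: float = 150.0
    alpha_amplitude: float = 15.0  # microvolts, occipital eyes-closed peak
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shots_per_condition <= 0:
            raise ConfigurationError("shots_per_condition must be positive")
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ConfigurationError("artifact_rate must lie in [0, 1]")
        if len(self.channel_labels) != len(set(self.channel_labels)):
            raise ConfigurationError("channel_labels contains duplicates")
        for spec in self.coupling_specs:
            for ch in spec.pair:
                if ch not in self.channel_labels:
                    raise ConfigurationError(
                        f"coupling channel {ch!r} is not in the montage"
                    )
            if spec.band not in BAND_NAMES:
                raise ConfigurationError(f"unknown coupling band {spec.band!r}")
            if not 0.0 <= spec.strength <= 1.0:
                raise ConfigurationError("coupling_strength must lie in [0, 1]")
            if spec.strength + abs(spec.condition_effect_delta) > 1.0 + 1e-12:
                raise ConfigurationError(
                    "coupling_strength + |condition_effect_delta| must not exceed 1"
                )
            # a spec whose effect_condition is not simulated is legal: the
            # delta is simply never applied (e.g. a control-only sub-cohort)


@dataclass
class ContinuousRecording:
    """One continuous multichannel recording with event markers.

    ``samples`` is channels x time in microvolts. ``events`` holds the
    sample indices of shot instants; every event leaves at least 5 s of
    signal before it and 2 s after it, so the widest analysis cut
    (-5..+2 s) always fits. ``resting_segments`` maps segment names
    (``eyes_closed`` / ``eyes_open``) to half-open sample ranges.
    """

    subject_id: str
    condition_label: str
    sampling_rate: float
    samples: np.ndarray
    channel_labels: tuple[str, ...]
    events: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    resting_segments: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if not np.issubdtype(self.samples.dtype, np.floating):
            self.samples = self.samples.astype(np.float64)
        self.events = np.asarray(self.events, dtype=np.int64)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("samples must be channels x time matching channel_labels")
        n = self.samples.shape[1]
        lo = int(round(5.0 * self.sampling_rate))
        hi = n - int(round(2.0 * self.sampling_rate))
        if self.events.size and (self.events.min() < lo or self.events.max() > hi):
            raise ValueError("events must lie in [5 s, length - 2 s]")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class PerformanceRecord:
    """Per-shot ring scores for one subject under one condition."""

    subject_id: str
    condition_label: str
    ring_scores: list[int]

    def __post_init__(self) -> None:
        bad = [s for s in self.ring_scores if s != 0 and not 5 <= s <= 10]
        if bad:
            raise ValueError(f"ring scores must lie in {{0, 5..10}}, got {bad}")

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.ring_scores))


@dataclass
class SubjectData:
    """Everything generated for one subject, plus its ground truth."""

    subject_id: str
    iaf: float
    coupling_offset_z: float
    recordings: dict[str, ContinuousRecording]
    resting: ContinuousRecording
    performance: dict[str, PerformanceRecord]
    artifact_trials: dict[str, list[int]]
    realized_strengths: dict[str, list[float]]


# ---------------------------------------------------------------------------
# low-level signal builders


def _powerlaw_noise(rng: np.random.Generator, shape: tuple[int, int], alpha: float) -> np.ndarray:
    """1/f^alpha noise, unit standard deviation per channel."""
    n_ch, n = shape
    n_fast = sfft.next_fast_len(n)
    white = rng.standard_normal((n_ch, n))
    if alpha == 0.0:
        return white
    spec = sfft.rfft(white, n_fast, axis=-1)
    f = sfft.rfftfreq(n_fast)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-alpha / 2.0)
    x = sfft.irfft(spec * scale, n_fast, axis=-1)[:, :n]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _narrowband_pair(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float, delay_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """A unit-variance narrowband oscillator and its fractionally delayed copy."""
    n_fast = sfft.next_fast_len(n)
    white = rng.standard_normal(n)
    spec = sfft.rfft(white, n_fast)
    f = sfft.rfftfreq(n_fast, 1.0 / fs)
    mask = (f >= low) & (f <= high)
    spec = spec * mask
    x = sfft.irfft(spec, n_fast)[:n]
    shifted = sfft.irfft(spec * np.exp(-2j * np.pi * f * delay_s), n_fast)[:n]
    sd = x.std()
    if sd == 0:
        raise ValueError("narrowband oscillator degenerate (empty band)")
    return x / sd, shifted / sd


@lru_cache(maxsize=64)
def _calibrated_latent_mean(target_mean: float, sigma_total: float) -> float:
    """Latent Gaussian mean whose discretized {0,5..10} expectation hits target_mean."""

    def expected(mu: float) -> float:
        edges_lo = np.array([4.5, 5.5, 6.5, 7.5, 8.5, 9.5])
        probs_hit = norm.cdf((np.append(edges_lo[1:], np.inf) - mu) / sigma_total) - norm.cdf(
            (edges_lo - mu) / sigma_total
        )
        return float(np.sum(np.arange(5, 11) * probs_hit))

    return float(brentq(lambda m: expected(m) - target_mean, -5.0, 25.0, xtol=1e-8))


def _discretize_scores(latent: np.ndarray) -> np.ndarray:
    r = np.rint(latent)
    r = np.where(r < 5, 0, r)
    return np.clip(r, 0, 10).astype(np.int64)


# ---------------------------------------------------------------------------
# public operations


def _subject_rng(config: SimulationConfig, subject_index: int, stream: int) -> np.random.Generator:
    return default_rng(SeedSequence(config.seed, spawn_key=(subject_index, stream)))


def simulate_subject(config: SimulationConfig, subject_index: int) -> SubjectData:
    """Generate all recordings, scores, and ground truth for one subject.

    Deterministic in (config, subject_index): the subject's random
    streams are spawned from the config seed keyed by subject index, so
    cohort order and size do not perturb individual subjects.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError(f"subject_index {subject_index} outside cohort of {config.n_subjects}")
    fs = config.sampling_rate
    subject_id = f"sub-{subject_index + 1:02d}"

    draw = _subject_rng(config, subject_index, 0)
    iaf_raw = draw.normal(config.iaf_mean, config.iaf_sd)
    iaf = float(np.clip(np.round(iaf_raw * 2.0) / 2.0, 8.5, 11.5))
    offset_z = float(draw.standard_normal())
    offset = offset_z * config.subject_coupling_sd
    source_gains = config.common_source_gain * draw.uniform(0.5, 1.5, len(config.channel_labels))
    band_by_name = {b.name: b for b in bands_from_iaf(iaf)}

    n_shots = config.shots_per_condition
    rec_len = int(round((config.lead_s + (n_shots - 1) * config.shot_interval_s + config.tail_s) * fs))

    recordings: dict[str, ContinuousRecording] = {}
    artifact_trials: dict[str, list[int]] = {}
    realized: dict[str, list[float]] = {}
    for c_idx, cond in enumerate(config.conditions):
        rng = _subject_rng(config, subject_index, 1 + c_idx)
        x = config.background_std * _powerlaw_noise(rng, (len(config.channel_labels), rec_len), config.noise_color)
        if config.common_source_gain > 0:
            common = _powerlaw_noise(rng, (1, rec_len), config.noise_color)[0]
            x += config.background_std * source_gains[:, None] * common

        strengths = []
        for spec in config.coupling_specs:
            band = band_by_name[spec.band]
            s = spec.strength + offset
            if cond == spec.effect_condition:
                s += spec.condition_effect_delta
            s = float(np.clip(s, 0.0, 1.0))
            strengths.append(s)
            delay = spec.phase_lag / (2.0 * np.pi * band.center)
            osc, osc_delayed = _narrowband_pair(rng, rec_len, fs, band.low, band.high, delay)
            ia = config.channel_labels.index(spec.pair[0])
            ib = config.channel_labels.index(spec.pair[1])
            mix = math.sqrt(1.0 - s * s)
            x[ia] = mix * x[ia] + s * config.background_std * osc
            x[ib] = mix * x[ib] + s * config.background_std * osc_delayed
        realized[cond] = strengths

        jitter = rng.uniform(-0.3, 0.3, n_shots) if n_shots > 1 else np.zeros(1)
        jitter[0] = abs(jitter[0])  # keep the first event past the 5 s lead
        events = (config.lead_s + np.arange(n_shots) * config.shot_interval_s + jitter) * fs
        rec = ContinuousRecording(
            subject_id=subject_id,
            condition_label=cond,
            sampling_rate=fs,
            samples=x,
            channel_labels=config.channel_labels,
            events=np.round(events).astype(np.int64),
        )
        if config.artifact_rate > 0:
            art_seed = SeedSequence(config.seed, spawn_key=(subject_index, 100 + c_idx))
            rec, flagged = inject_artifacts(
                rec, config.artifact_rate, config.artifact_amplitude, art_seed
            )
        else:
            flagged = []
        recordings[cond] = rec
        artifact_trials[cond] = flagged

    # resting run: eyes-closed alpha peak at the drawn IAF on occipital leads
    rng = _subject_rng(config, subject_index, 50)
    n_ec = int(round(config.rest_eyes_closed_s * fs))
    n_eo = int(round(config.rest_eyes_open_s * fs))
    rest = config.background_std * _powerlaw_noise(rng, (len(config.channel_labels), n_ec + n_eo), config.noise_color)
    t = np.arange(n_ec) / fs
    for ch in OCCIPITAL_CHANNELS:
        if ch not in config.channel_labels:
            continue
        phase = rng.uniform(0, 2 * np.pi)
        mod = 1.0 + 0.3 * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
        rest[config.channel_labels.index(ch), :n_ec] += (
            config.alpha_amplitude * mod * np.sin(2 * np.pi * iaf * t + phase)
        )
    resting = ContinuousRecording(
        subject_id=subject_id,
        condition_label="resting",
        sampling_rate=fs,
        samples=rest,
        channel_labels=config.channel_labels,
        resting_segments={"eyes_closed": (0, n_ec), "eyes_open": (n_ec, n_ec + n_eo)},
    )

    # ring scores through the Gaussian copula against the coupling offset
    rng = _subject_rng(config, subject_index, 60)
    performance: dict[str, PerformanceRecord] = {}
    for cond in config.conditions:
        if config.performance_spec is not None:
            rho = config.performance_spec.rho
            g = rho * offset_z + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal()
        else:
            g = rng.standard_normal()
        sd = config.score_sds[cond]
        sigma_total = math.hypot(sd, config.shot_noise_sd)
        mu = _calibrated_latent_mean(config.score_means[cond], sigma_total)
        latent = mu + sd * g + config.shot_noise_sd * rng.standard_normal(n_shots)
        performance[cond] = PerformanceRecord(
            subject_id=subject_id,
            condition_label=cond,
            ring_scores=_discretize_scores(latent).tolist(),
        )

    return SubjectData(
        subject_id=subject_id,
        iaf=iaf,
        coupling_offset_z=offset_z,
        recordings=recordings,
        resting=resting,
        performance=performance,
        artifact_trials=artifact_trials,
        realized_strengths=realized,
    )


def inject_artifacts(
    recording: ContinuousRecording,
    rate: float,
    amplitude: float,
    seed,
    pulse_offset_s: float = -1.5,
    pulse_duration_s: float = 0.1,
    n_channels: int = 6,
) -> tuple[ContinuousRecording, list[int]]:
    """Add threshold-detectable transients to a random subset of trials.

    Each flagged trial receives a raised-cosine pulse of the given
    amplitude (microvolts) on ``n_channels`` random channels, centered
    ``pulse_offset_s`` seconds from the shot event (inside the aiming
    window). Returns the contaminated copy and the flagged trial indices.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = default_rng(seed)
    x = recording.samples.copy()
    flagged: list[int] = []
    fs = recording.sampling_rate
    n_pulse = max(2, int(round(pulse_duration_s * fs)))
    pulse = amplitude * np.hanning(n_pulse)
    for t_idx, ev in enumerate(recording.events):
        if rng.random() >= rate:
            continue
        flagged.append(t_idx)
        start = int(ev + round(pulse_offset_s * fs) - n_pulse // 2)
        start = max(0, min(start, x.shape[1] - n_pulse))
        chans = rng.choice(x.shape[0], size=min(n_channels, x.shape[0]), replace=False)
        x[np.ix_(chans, np.arange(start, start + n_pulse))] += pulse
    out = ContinuousRecording(
        subject_id=recording.subject_id,
        condition_label=recording.condition_label,
        sampling_rate=fs,
        samples=x,
        channel_labels=recording.channel_labels,
        events=recording.events.copy(),
        resting_segments=dict(recording.resting_segments),
    )
    return out, flagged


def simulate_cohort(config: SimulationConfig, out_dir=None):
    """Generate the whole cohort; optionally write it to disk.

    Returns ``(subjects, manifest)`` where ``manifest`` records the
    planted ground truth (per-subject IAFs, realized coupling strengths,
    artifact trials, score means, and the planted performance
    correlation). With ``out_dir`` set, recordings, events, scores and
    the manifest are written via :mod:`aimnet.io`.
    """
    subjects = [simulate_subject(config, i) for i in range(config.n_subjects)]
    manifest = {
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "conditions": list(config.conditions),
        "shots_per_condition": config.shots_per_condition,
        "sampling_rate": config.sampling_rate,
        "planted_performance": (
            {
                "network_feature": config.performance_spec.network_feature,
                "rho": config.performance_spec.rho,
            }
            if config.performance_spec
            else None
        ),
        "couplings": [
            {
                "pair": list(s.pair),
                "band": s.band,
                "phase_lag": s.phase_lag,
                "strength": s.strength,
                "condition_effect_delta": s.condition_effect_delta,
                "effect_condition": s.effect_condition,
            }
            for s in config.coupling_specs
        ],
        "subjects": {
            s.subject_id: {
                "iaf": s.iaf,
                "coupling_offset_z": s.coupling_offset_z,
                "realized_strengths": s.realized_strengths,
                "artifact_trials": s.artifact_trials,
                "mean_scores": {c: p.mean_score for c, p in s.performance.items()},
            }
            for s in subjects
        },
    }
    if out_dir is not None:
        from . import io

        io.write_cohort(out_dir, subjects, manifest)
    return subjects, manifest
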