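"""Shared helpers for the test suite: small configs and a lean
single-band per-subject path used by the calibration/power simulations."""

from __future__ import annotations

import numpy as np

from aimnet.connectivity import analytic_signal, wpli
from aimnet.pipeline import PipelineSettings
from aimnet.preprocess import (
    bandpass_fir,
    bands_from_iaf,
    epoch,
    estimate_iaf,
    reject_artifacts,
    replace_recording,
)
from aimnet.simulate import SimulationConfig, simulate_subject

SETTINGS = PipelineSettings()


# ---------------------------------------------------------------------------
# brute-force graph oracles: exhaustive simple-path enumeration and dense
# eigendecomposition, independent of the implementation under test


def brute_distance(w: np.ndarray, i: int, j: int) -> float:
    import itertools

    n = w.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    others = [k for k in range(n) if k not in (i, j)]
    best = np.inf
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = (i, *mid, j)
            d = 0.0
            for a, b in zip(path, path[1:]):
                d += lengths[a, b]
                if d >= best:
                    break
            else:
                best = d
    return best


def brute_distance_matrix(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = brute_distance(w, i, j)
    return d


def brute_global_efficiency(w: np.ndarray) -> float:
    d = brute_distance_matrix(w)
    n = w.shape[0]
    vals = [
        1.0 / d[i, j] if np.isfinite(d[i, j]) and d[i, j] > 0 else 0.0
        for i in range(n)
        for j in range(n)
        if i != j
    ]
    return float(np.mean(vals))


def brute_clustering(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    norm = w / w.max()
    c = np.zeros(n)
    for i in range(n):
        k = np.count_nonzero(w[i] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                total += (norm[i, j] * norm[i, h] * norm[j, h]) ** (1.0 / 3.0)
        c[i] = total / (k * (k - 1))
    return c


def random_connected_graph(rng, n=8, density=0.7):
    from scipy.sparse.csgraph import connected_components

    while True:
        w = rng.uniform(0.05, 1.0, (n, n)) * (rng.random((n, n)) < density)
        w = np.triu(w, 1)
        w = w + w.T
        if connected_components(w > 0, directed=False)[0] == 1:
            return w


def assert_graph_metrics_match_brute_force(w: np.ndarray, tol: float = 1e-8) -> None:
    """Every weighted metric against its independent brute-force oracle."""
    from aimnet.graph import (
        WeightedGraph,
        clustering_weighted,
        eigenvector_centrality,
        global_efficiency,
        local_efficiency,
        shortest_path_lengths,
    )

    g = WeightedGraph(w)
    np.testing.assert_allclose(shortest_path_lengths(g), brute_distance_matrix(w), atol=tol)
    assert abs(global_efficiency(g) - brute_global_efficiency(w)) < tol
    c, _ = clustering_weighted(g)
    np.testing.assert_allclose(c, brute_clustering(w), atol=tol)
    vals, vecs = np.linalg.eigh(w)
    lead = np.abs(vecs[:, np.argmax(vals)])
    cent, _ = eigenvector_centrality(g)
    np.testing.assert_allclose(cent, lead / np.linalg.norm(lead), atol=tol)
    eff = local_efficiency(g)
    for i in range(w.shape[0]):
        nbrs = np.flatnonzero(w[i] > 0)
        expect = brute_global_efficiency(w[np.ix_(nbrs, nbrs)]) if nbrs.size >= 2 else 0.0
        assert abs(eff[i] - expect) < tol


def small_config(**overrides) -> SimulationConfig:
    """A reduced-scale cohort: short resting runs, default study values otherwise."""
    kwargs = dict(
        n_subjects=2,
        conditions=("control",),
        shots_per_condition=20,
        rest_eyes_closed_s=8.0,
        rest_eyes_open_s=2.0,
        seed=0,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def subject_band_wpli(subject, condition: str = "control", band_name: str = "beta",
                      settings: PipelineSettings = SETTINGS):
    """Full per-subject chain (IAF -> filter -> epoch -> reject -> WPLI) for one band."""
    iaf = estimate_iaf(subject.resting, resolution=settings.iaf_resolution)
    band = {b.name: b for b in bands_from_iaf(iaf)}[band_name]
    rec = subject.recordings[condition]
    rec = replace_recording(rec, rec.samples.astype(settings.compute_dtype))
    broad = bandpass_fir(rec, *settings.broadband, order=settings.fir_order)
    full = epoch(broad, settings.full_window)
    clean, _ = reject_artifacts(full, settings.reject_uv)
    banded = bandpass_fir(broad, band.low, band.high, order=settings.fir_order)
    band_full = epoch(banded, settings.full_window,
                      event_ids=clean.retained_trial_ids, band_label=band_name)
    aiming = band_full.subwindow(*settings.aiming_window)
    return wpli(analytic_signal(aiming, settings.trim_fraction), settings.wpli_average)


def cohort_band_matrices(config: SimulationConfig, condition: str = "control",
                         band_name: str = "beta"):
    """Stack of per-subject WPLI matrices for one condition/band."""
    out = []
    for i in range(config.n_subjects):
        sub = simulate_subject(config, i)
        out.append(subject_band_wpli(sub, condition, band_name))
    return out


def sine_epochs(freq: float, lags: np.ndarray, n_trials: int = 1, n_samples: int = 1000,
                fs: float = 1000.0, noise_sd: float = 0.0, seed: int = 0):
    """Two-channel sinusoid trials with a fixed phase lag between channels."""
    from aimnet.preprocess import EpochTensor

    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    trials = []
    for _ in range(n_trials):
        phi = rng.uniform(0, 2 * np.pi)
        a = np.sin(2 * np.pi * freq * t + phi)
        b = np.sin(2 * np.pi * freq * t + phi - lags)
        if noise_sd:
            a = a + noise_sd * rng.standard_normal(n_samples)
            b = b + noise_sd * rng.standard_normal(n_samples)
        trials.append(np.stack([a, b]))
    return EpochTensor(
        data=np.stack(trials),
        window=(0.0, n_samples / fs),
        sampling_rate=fs,
        channel_labels=("A", "B"),
        retained_trial_ids=np.arange(n_trials),
        band_label="test",
    )
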