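"""Weighted phase lag index (WPLI) and its event-related change rate.

WPLI quantifies phase synchrony between two channels while discounting
zero-lag (volume-conducted) coupling. With the analytic signals
``a_x(t)``, ``a_y(t)`` of band-filtered channels and the cross-spectrum
``S_xy(t) = a_x(t) * conj(a_y(t))``:

    WPLI_xy = | < |Im S_xy| * sign(Im S_xy) > | / < |Im S_xy| >

where ``< . >`` averages over time within a trial (default) or over all
pooled samples. ``|Im S| * sign(Im S)`` is algebraically just ``Im S``;
the implementation uses the simplified numerator, and the test suite
checks the literal term-by-term form against it. Purely zero-lag
coupling makes ``Im S`` vanish identically, so WPLI is 0 there by
convention, and a consistent lead/lag drives it toward 1.

The event-related WPLI (ERWPLI) is the relative change of the aiming
window's WPLI against a pre-event baseline window:

    ERWPLI = (WPLI - R) / R

computed elementwise on matrices, with a small positive floor guarding
R = 0 (flagged, never silent).

Analytic signals come from the Hilbert transform of band-filtered
trials, with a fraction of samples (default 10 % per end) discarded to
suppress transform edge effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocess import EpochTensor

try:  # optional fast path; the numpy fallback computes the same sums
    from numba import njit

    @njit(cache=True)
    def _pair_stats_jit(xr, xi):  # pragma: no cover - exercised via wpli
        n_ch, n_t = xr.shape
        num = np.zeros((n_ch, n_ch))
        den = np.zeros((n_ch, n_ch))
        for i in range(n_ch):
            for j in range(i + 1, n_ch):
                s = 0.0
                sa = 0.0
                for t in range(n_t):
                    im = xi[i, t] * xr[j, t] - xr[i, t] * xi[j, t]
                    s += im
                    sa += abs(im)
                num[i, j] = num[j, i] = s
                den[i, j] = den[j, i] = sa
        return num, den

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "AnalyticSignalSet",
    "ConnectivityMatrix",
    "ERWPLIMatrix",
    "analytic_signal",
    "wpli",
    "mean_wpli",
    "channel_mean_wpli",
    "erwpli",
]

DEFAULT_TRIM_FRACTION = 0.10
DEFAULT_ERWPLI_FLOOR = 1e-6


@dataclass
class AnalyticSignalSet:
    """Complex analytic signals, trials x channels x retained samples."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]
    trim_fraction: float
    band_label: str | None = None
    subject_id: str | None = None
    condition_label: str | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel WPLI in [0, 1], zero diagonal."""

    values: np.ndarray
    channel_labels: tuple[str, ...]
    band_label: str | None = None
    subject_id: str | None = None
    condition_label: str | None = None
    n_trials_averaged: int = 0
    kind: str = "wpli"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if self.kind == "wpli" and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("WPLI values must lie in [0, 1]")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class ERWPLIMatrix:
    """Baseline-normalized WPLI change rate; entries >= -1, unbounded above."""

    values: np.ndarray
    channel_labels: tuple[str, ...]
    band_label: str | None = None
    subject_id: str | None = None
    condition_label: str | None = None
    n_floored: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if v.min() < -1.0 - 1e-9:
            raise ValueError("ERWPLI entries cannot fall below -1")
        self.values = v


def analytic_signal(epochs: EpochTensor, trim_fraction: float = DEFAULT_TRIM_FRACTION) -> AnalyticSignalSet:
    """Hilbert analytic signal per trial/channel, edge-trimmed.

    ``trim_fraction`` of the samples is discarded at *each* end; the
    retained length is floor(samples * (1 - 2 * trim_fraction)).
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    if epochs.band_label is None:
        warnings.warn(
            "epochs carry no band label; Hilbert phase is only well defined "
            "for narrowband signals",
            stacklevel=2,
        )
    analytic = hilbert(epochs.data, axis=-1)
    n = epochs.n_samples
    n_keep = int(np.floor(n * (1.0 - 2.0 * trim_fraction)))
    start = int(np.floor(n * trim_fraction))
    return AnalyticSignalSet(
        data=analytic[:, :, start : start + n_keep],
        sampling_rate=epochs.sampling_rate,
        channel_labels=epochs.channel_labels,
        trim_fraction=trim_fraction,
        band_label=epochs.band_label,
        subject_id=epochs.subject_id,
        condition_label=epochs.condition_label,
    )


def wpli(analytic: AnalyticSignalSet, average: str = "within_trial") -> ConnectivityMatrix:
    """Channel-pair WPLI matrix from analytic signals.

    ``average="within_trial"`` (default) computes one WPLI per trial
    from that trial's time average and then averages the per-trial
    matrices; ``"pooled"`` pools every retained sample of every trial
    into a single expectation. Pairs whose imaginary cross-spectrum is
    identically zero (e.g. a channel with itself, or purely zero-lag
    coupling) are set to 0 by convention.
    """
    if average not in ("within_trial", "pooled"):
        raise ValueError(f"average must be 'within_trial' or 'pooled', got {average!r}")
    a = analytic.data
    if a.ndim != 3 or a.shape[0] < 1:
        raise ValueError("need at least one trial")
    if a.shape[2] < 2:
        raise ValueError("need at least 2 retained samples per trial")
    n_trials, n_ch, _ = a.shape
    # A pair whose imaginary cross-spectrum is numerically zero relative to
    # its cross-spectral power has no defined lead/lag: WPLI is 0 there by
    # convention (identical signals, pure zero-lag coupling).
    rel_tol = 1e-9
    if average == "within_trial":
        acc = np.zeros((n_ch, n_ch))
        for t in range(n_trials):
            num, den, scale = _pair_stats(a[t])
            ok = den > rel_tol * scale
            acc += np.where(ok, np.abs(num) / np.maximum(den, np.finfo(float).tiny), 0.0)
        values = acc / n_trials
    else:
        num_sum = np.zeros((n_ch, n_ch))
        den_sum = np.zeros((n_ch, n_ch))
        scale_sum = np.zeros((n_ch, n_ch))
        for t in range(n_trials):
            num, den, scale = _pair_stats(a[t])
            num_sum += num
            den_sum += den
            scale_sum += scale
        ok = den_sum > rel_tol * scale_sum
        values = np.where(ok, np.abs(num_sum) / np.maximum(den_sum, np.finfo(float).tiny), 0.0)
    values = 0.5 * (values + values.T)  # exact symmetry against rounding
    np.fill_diagonal(values, 0.0)
    values = np.clip(values, 0.0, 1.0)
    return ConnectivityMatrix(
        values=values,
        channel_labels=analytic.channel_labels,
        band_label=analytic.band_label,
        subject_id=analytic.subject_id,
        condition_label=analytic.condition_label,
        n_trials_averaged=n_trials,
    )


def _pair_stats(a_trial: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair sums over time of Im S_xy, |Im S_xy|, and a power scale.

    The scale — n_samples * sqrt of the product of mean channel powers —
    bounds the attainable |Im S| sum and anchors the numerical-zero
    tolerance.
    """
    xr = np.ascontiguousarray(a_trial.real)
    xi = np.ascontiguousarray(a_trial.imag)
    if _HAVE_NUMBA:
        num, den = _pair_stats_jit(xr, xi)
    else:
        imag = xi[:, None, :] * xr[None, :, :]
        imag -= xr[:, None, :] * xi[None, :, :]
        num = imag.sum(axis=-1)
        den = np.abs(imag).sum(axis=-1)
    power = (xr * xr + xi * xi).mean(axis=-1)
    scale = np.sqrt(np.outer(power, power)) * a_trial.shape[-1]
    return num, den, scale


def _as_array(matrix) -> np.ndarray:
    return matrix.values if hasattr(matrix, "values") else np.asarray(matrix, dtype=np.float64)


def mean_wpli(matrix) -> float:
    """Mean over the strict upper triangle (435 pairs for 30 channels)."""
    v = _as_array(matrix)
    iu = np.triu_indices(v.shape[0], k=1)
    return float(v[iu].mean())


def channel_mean_wpli(matrix) -> np.ndarray:
    """Per-channel mean connection strength (row mean excluding the diagonal)."""
    v = _as_array(matrix)
    n = v.shape[0]
    return (v.sum(axis=1) - np.diag(v)) / (n - 1)


def erwpli(
    aiming: ConnectivityMatrix,
    baseline: ConnectivityMatrix,
    floor: float = DEFAULT_ERWPLI_FLOOR,
) -> ERWPLIMatrix:
    """Elementwise (W - R) / max(R, floor) with a flagged division floor."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    w = _as_array(aiming)
    r = _as_array(baseline)
    if w.shape != r.shape:
        raise ValueError(f"shape mismatch: {w.shape} vs {r.shape}")
    if aiming.channel_labels != baseline.channel_labels:
        raise ValueError("aiming and baseline matrices carry different channel labels")
    values = (w - r) / np.maximum(r, floor)
    np.fill_diagonal(values, 0.0)
    off_diag = ~np.eye(r.shape[0], dtype=bool)
    n_floored = int(np.count_nonzero((r < floor) & off_diag))
    return ERWPLIMatrix(
        values=values,
        channel_labels=aiming.channel_labels,
        band_label=aiming.band_label,
        subject_id=aiming.subject_id,
        condition_label=aiming.condition_label,
        n_floored=n_floored,
    )
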