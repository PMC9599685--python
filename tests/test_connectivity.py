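"""WPLI against the literal formula, lag/zero-lag behavior, ERWPLI rules."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st
from scipy.signal import hilbert

from aimnet.connectivity import (
    ConnectivityMatrix,
    analytic_signal,
    channel_mean_wpli,
    erwpli,
    mean_wpli,
    wpli,
)
from aimnet.preprocess import EpochTensor

from _utils import sine_epochs

FS = 1000.0


def literal_wpli(ax: np.ndarray, ay: np.ndarray) -> float:
    """Term-by-term transcription of the WPLI definition for one pair."""
    s_xy = ax * np.conj(ay)
    imag = np.imag(s_xy)
    num = np.abs(np.mean(np.abs(imag) * np.sign(imag)))
    den = np.mean(np.abs(imag))
    return num / den if den > 0 else 0.0


def _tensor(data, fs=FS, band="test"):
    n = data.shape[-1]
    return EpochTensor(
        data=data, window=(0.0, n / fs), sampling_rate=fs,
        channel_labels=tuple(f"ch{i}" for i in range(data.shape[1])),
        retained_trial_ids=np.arange(data.shape[0]), band_label=band,
    )


class TestAnalyticSignal:
    def test_cosine_has_unit_modulus_and_correct_frequency(self):
        t = np.arange(3000) / FS
        ep = _tensor(np.cos(2 * np.pi * 10 * t)[None, None, :])
        a = analytic_signal(ep, 0.10)
        assert a.data.shape[-1] == 2400
        mod = np.abs(a.data[0, 0])
        assert np.allclose(mod, 1.0, atol=0.01)
        inst_freq = np.diff(np.unwrap(np.angle(a.data[0, 0]))) * FS / (2 * np.pi)
        assert np.allclose(inst_freq, 10.0, atol=0.1)

    @pytest.mark.parametrize("n, trim, kept", [(3000, 0.10, 2400), (100, 0.0, 100), (101, 0.25, 50)])
    def test_trim_arithmetic(self, n, trim, kept):
        ep = _tensor(np.zeros((1, 1, n)))
        assert analytic_signal(ep, trim).data.shape[-1] == kept

    def test_broadband_input_warns(self):
        ep = _tensor(np.zeros((1, 1, 100)), band=None)
        with pytest.warns(UserWarning, match="narrowband"):
            analytic_signal(ep)

    def test_invalid_trim_rejected(self):
        with pytest.raises(ValueError, match="trim_fraction"):
            analytic_signal(_tensor(np.zeros((1, 1, 100))), 0.5)


class TestWpliOracle:
    def test_matches_literal_transcription_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.standard_normal((1, 2, 200))
            ep = _tensor(x)
            ours = wpli(analytic_signal(ep, 0.10)).values[0, 1]
            a = hilbert(x[0], axis=-1)[:, 20:180]  # same 10% trim per end
            assert ours == pytest.approx(literal_wpli(a[0], a[1]), abs=1e-12)

    def test_pooled_average_matches_literal_pooling(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((5, 2, 200))
        ep = _tensor(x)
        ours = wpli(analytic_signal(ep, 0.0), average="pooled").values[0, 1]
        a = hilbert(x, axis=-1)
        assert ours == pytest.approx(
            literal_wpli(a[:, 0].ravel(), a[:, 1].ravel()), abs=1e-12
        )

    def test_constant_lag_sinusoids_give_unit_wpli(self):
        ep = sine_epochs(10.0, np.pi / 4, n_trials=3, n_samples=3000)
        assert wpli(analytic_signal(ep)).values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_identical_signals_give_zero_by_convention(self):
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 10 * t)
        ep = _tensor(np.stack([x, x])[None])
        assert wpli(analytic_signal(ep)).values[0, 1] == 0.0

    def test_independent_noise_stays_low_at_60_trials(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((60, 2, 3000))
        assert wpli(analytic_signal(_tensor(x))).values[0, 1] < 0.1

    def test_zero_lag_common_source_stays_low(self):
        # volume-conduction surrogate: same broadband source at different
        # gains plus independent noise must not create spurious WPLI
        rng = np.random.default_rng(6)
        common = rng.standard_normal((60, 1, 3000))
        noise = rng.standard_normal((60, 2, 3000))
        x = np.concatenate([1.0 * common, 0.4 * common], axis=1) + 0.7 * noise
        assert wpli(analytic_signal(_tensor(x))).values[0, 1] < 0.1

    def test_zero_lag_component_barely_moves_lagged_pair(self):
        # a moderate zero-lag common component never inflates the lagged
        # pair's WPLI and perturbs it only slightly (it adds |Im S| mass
        # without adding sign-consistent lag)
        base = sine_epochs(10.0, np.pi / 3, n_trials=60, n_samples=1000, noise_sd=0.5, seed=8)
        w0 = wpli(analytic_signal(base)).values[0, 1]
        rng = np.random.default_rng(9)
        common = rng.standard_normal((60, 1, 1000))
        contaminated = _tensor(base.data + 0.3 * np.concatenate([common, common], axis=1))
        w1 = wpli(analytic_signal(contaminated)).values[0, 1]
        assert w1 <= w0 + 0.01
        assert abs(w1 - w0) < 0.05


@given(seed=st.integers(0, 10_000))
@hsettings(max_examples=25, deadline=None, derandomize=True)
def test_wpli_range_symmetry_zero_diagonal(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((3, 4, 64))
    m = wpli(analytic_signal(_tensor(x), 0.0)).values
    assert np.all((m >= 0) & (m <= 1))
    assert np.array_equal(m, m.T)
    assert np.all(np.diag(m) == 0)


class TestMatrixSummaries:
    def test_mean_wpli_upper_triangle(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.1
        v[0, 2] = v[2, 0] = 0.2
        v[1, 2] = v[2, 1] = 0.3
        m = ConnectivityMatrix(v, ("a", "b", "c"))
        assert mean_wpli(m) == pytest.approx(0.2)

    def test_mean_wpli_uniform_and_zero(self):
        uniform = np.full((4, 4), 0.4)
        np.fill_diagonal(uniform, 0.0)
        assert mean_wpli(ConnectivityMatrix(uniform, tuple("abcd"))) == pytest.approx(0.4)
        assert mean_wpli(ConnectivityMatrix(np.zeros((4, 4)), tuple("abcd"))) == 0.0

    def test_channel_mean_excludes_diagonal(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.6
        v[0, 2] = v[2, 0] = 0.2
        v[1, 2] = v[2, 1] = 0.4
        out = channel_mean_wpli(ConnectivityMatrix(v, ("a", "b", "c")))
        assert out == pytest.approx([0.4, 0.5, 0.3])


class TestErwpli:
    def _mat(self, v, labels=("a", "b", "c")):
        return ConnectivityMatrix(v, labels)

    def test_equal_matrices_give_zero(self):
        v = np.full((3, 3), 0.5)
        np.fill_diagonal(v, 0.0)
        out = erwpli(self._mat(v), self._mat(v))
        assert np.all(out.values == 0)

    def test_doubling_gives_unit_change(self):
        r = np.full((3, 3), 0.3)
        np.fill_diagonal(r, 0.0)
        out = erwpli(self._mat(2 * r), self._mat(r))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(out.values[off], 1.0)

    def test_zero_baseline_floored_and_flagged(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        r = np.zeros((3, 3))
        out = erwpli(self._mat(w), self._mat(r), floor=1e-6)
        assert out.n_floored == 6
        assert out.values[0, 1] == pytest.approx(0.5 / 1e-6)

    def test_entries_never_below_minus_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = rng.uniform(0, 1, (4, 4))
            w = np.triu(w, 1) + np.triu(w, 1).T
            r = rng.uniform(0, 1, (4, 4))
            r = np.triu(r, 1) + np.triu(r, 1).T
            out = erwpli(self._mat(w, tuple("abcd")), self._mat(r, tuple("abcd")))
            assert out.values.min() >= -1.0
            off = ~np.eye(4, dtype=bool)
            assert np.all(np.sign(out.values[off]) == np.sign((w - r)[off]))

    def test_shape_mismatch_rejected(self):
        a = self._mat(np.zeros((3, 3)))
        b = ConnectivityMatrix(np.zeros((4, 4)), tuple("abcd"))
        with pytest.raises(ValueError, match="mismatch"):
            erwpli(a, b)
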