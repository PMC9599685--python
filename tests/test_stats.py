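"""Rank-sum enumeration, BH step-up, Spearman, K-S, and family pipelines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hsettings, strategies as st
from scipy import stats as sst

from aimnet.stats import (
    correlate_with_performance,
    edgewise_compare,
    fdr_bh,
    ks_normality,
    nodewise_compare,
    spearman,
    wilcoxon_ranksum,
)


def bh_by_hand(p: np.ndarray) -> np.ndarray:
    """Literal step-up rule: q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestWilcoxonRanksum:
    def test_small_sample_exact_p(self):
        r = wilcoxon_ranksum([1, 2], [3, 4])
        assert r.method == "ranksum_exact"
        assert r.p_raw == pytest.approx(2 / 6)

    def test_exact_matches_mannwhitney_for_all_small_partitions(self):
        rng = np.random.default_rng(0)
        for n_a in range(1, 6):
            for n_b in range(1, 6):
                for _ in range(3):
                    a = rng.standard_normal(n_a)
                    b = rng.standard_normal(n_b)
                    ours = wilcoxon_ranksum(a, b, mode="exact")
                    ref = sst.mannwhitneyu(a, b, alternative="two-sided", method="exact")
                    assert ours.p_raw == pytest.approx(ref.pvalue, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        r = wilcoxon_ranksum(x, x)
        assert r.p_raw == 1.0

    def test_exact_and_approx_agree_at_moderate_n(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.standard_normal(6)
            b = rng.standard_normal(6)
            pe = wilcoxon_ranksum(a, b, mode="exact").p_raw
            pa = wilcoxon_ranksum(a, b, mode="approx").p_raw
            assert pa == pytest.approx(pe, abs=0.02)

    def test_approx_matches_mannwhitney_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.integers(0, 5, 20).astype(float)
            b = rng.integers(0, 6, 25).astype(float)
            ours = wilcoxon_ranksum(a, b).p_raw
            ref = sst.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                   use_continuity=True).pvalue
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_ranksum([], [1.0])


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.linspace(0, 3, 10)
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_textbook_rank_example(self):
        r = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert r.rho == pytest.approx(0.8)

    def test_invariant_under_strictly_monotone_transforms(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base)
        assert spearman(x, y**3 + 5 * y).rho == pytest.approx(base)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestFdrBh:
    def test_hand_step_up_toy_vector(self):
        assert fdr_bh([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_equal_ps_unchanged(self):
        assert fdr_bh([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_single_p_unchanged(self):
        assert fdr_bh([0.123]) == pytest.approx([0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @hsettings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_hand_step_up_and_is_permutation_invariant(self, ps):
        p = np.asarray(ps)
        q = fdr_bh(p)
        assert q == pytest.approx(bh_by_hand(p), abs=1e-12)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        assert fdr_bh(p[perm]) == pytest.approx(q[perm], abs=1e-12)


class TestKsNormality:
    def test_calibrated_under_its_own_family(self):
        rng = np.random.default_rng(4)
        hits = sum(ks_normality(rng.standard_normal(1000)).p_raw > 0.05 for _ in range(50))
        assert hits >= 45

    def test_detects_uniform_data(self):
        rng = np.random.default_rng(5)
        assert ks_normality(rng.uniform(0, 1, 1000)).p_raw < 0.01

    def test_tiny_or_constant_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            ks_normality([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="constant"):
            ks_normality([2.0, 2.0, 2.0, 2.0])


def _sym_stack(rng, n_subj, n_ch, shift=0.0, edge=None):
    out = np.zeros((n_subj, n_ch, n_ch))
    for s in range(n_subj):
        w = rng.uniform(0.2, 0.6, (n_ch, n_ch))
        w = np.triu(w, 1)
        w = w + w.T
        if edge is not None:
            i, j = edge
            w[i, j] += shift
            w[j, i] = w[i, j]
        out[s] = w
    return out


class TestFamilyPipelines:
    def test_self_comparison_gives_all_p_one(self):
        rng = np.random.default_rng(6)
        a = _sym_stack(rng, 5, 4)
        df = edgewise_compare(a, a, list("abcd"))
        assert np.all(df["p_raw"] == 1.0)
        assert not df["significant"].any()

    def test_planted_edge_shift_detected(self):
        rng = np.random.default_rng(7)
        a = _sym_stack(rng, 15, 4, shift=0.5, edge=(0, 1))
        b = _sym_stack(rng, 15, 4)
        df = edgewise_compare(a, b, list("abcd"), contrast="shifted_vs_null")
        hit = df[(df["chan_a"] == "a") & (df["chan_b"] == "b")].iloc[0]
        assert hit["significant"]
        assert hit["direction"] == "a>b"

    def test_nodewise_planted_shift_flags_only_target_nodes(self):
        rng = np.random.default_rng(18)
        a = rng.normal(0.5, 0.05, (20, 6))
        b = rng.normal(0.5, 0.05, (20, 6))
        a[:, 2] += 0.4
        df = nodewise_compare(a, b, list("abcdef"))
        assert df.loc[df["feature_id"] == "c", "significant"].all()
        assert df.loc[df["feature_id"] != "c", "significant"].sum() == 0

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(9)
        a = _sym_stack(rng, 1, 3)
        with pytest.raises(ValueError, match="2 subjects"):
            edgewise_compare(a, a, list("abc"))

    def test_feature_as_its_own_score_gives_unit_rho(self):
        rng = np.random.default_rng(10)
        feats = pd.DataFrame({"f": rng.standard_normal(10)},
                             index=[f"s{i}" for i in range(10)])
        scores = feats["f"].rename("score")
        df = correlate_with_performance(feats, scores)
        assert df["rho"].iloc[0] == pytest.approx(1.0)

    def test_misaligned_subjects_rejected(self):
        feats = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=list("abcde"))
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcdf"))
        with pytest.raises(ValueError, match="misaligned"):
            correlate_with_performance(feats, scores)
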