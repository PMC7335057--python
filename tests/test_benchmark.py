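"""Benchmarking statistics: baseline correction, extraction, errors,
offset removal and repeated-measures ANOVA."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import make_trace
from pupilbench.benchmark import (
    baseline_correct,
    extract_diameter,
    offset_correct,
    prediction_error,
    rm_anova,
)


def brute_force_rm_anova(x):
    """Definitional oracle: explicit sums of squares, covariance-matrix
    Mauchly W and Greenhouse–Geisser ε via Helmert contrasts, written
    independently of the library implementation (loops, no shortcuts)."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    cond_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    subj_means = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    ss_total = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_cond = n * sum((m - grand) ** 2 for m in cond_means)
    ss_subj = k * sum((m - grand) ** 2 for m in subj_means)
    ss_err = ss_total - ss_cond - ss_subj
    f = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))

    # sample covariance of condition columns
    cov = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            cov[a, b] = sum(
                (x[i][a] - cond_means[a]) * (x[i][b] - cond_means[b])
                for i in range(n)
            ) / (n - 1)
    # Helmert contrasts, orthonormalized
    helmert = np.zeros((k - 1, k))
    for r in range(k - 1):
        helmert[r, : r + 1] = 1.0
        helmert[r, r + 1] = -(r + 1.0)
        helmert[r] /= math.sqrt((r + 1.0) ** 2 + (r + 1.0))
    s = helmert @ cov @ helmert.T
    eig = np.linalg.eigvalsh(s)
    p = k - 1
    w = float(np.prod(eig) / (np.mean(eig) ** p))
    dd = 1.0 - (2.0 * p * p + p + 2.0) / (6.0 * p * (n - 1))
    chi2 = -(n - 1) * dd * math.log(w)
    eps = float(eig.sum() ** 2 / (p * (eig**2).sum()))
    return {
        "f": f, "w": w, "chi2": chi2, "eps": eps,
        "eta_sq": ss_cond / ss_total,
    }


class TestBaselineCorrection:
    def test_identical_constant_traces_give_zero(self):
        anchor = make_trace(np.full(2400, 5.0))
        stim = make_trace(np.full(2400, 5.0))
        out = baseline_correct(stim, anchor)
        np.testing.assert_allclose(out.diameter_mm, 0.0, atol=1e-12)

    def test_constant_offset_recovered(self):
        anchor = make_trace(np.full(2400, 5.0))
        stim = make_trace(np.full(2400, 4.0))
        out = baseline_correct(stim, anchor)
        np.testing.assert_allclose(out.diameter_mm, -1.0, atol=1e-12)
        assert out.meta["baseline_mm"] == pytest.approx(5.0)

    def test_baseline_uses_final_window_only(self):
        d = np.concatenate([np.full(1100, 7.0), np.full(1300, 5.0)])
        anchor = make_trace(d)  # 20 s at 120 Hz; final 10 s window all 5.0
        stim = make_trace(np.full(1200, 4.0))
        out = baseline_correct(stim, anchor, window_s=10.0)
        assert out.diameter_mm[0] == pytest.approx(-1.0, abs=1e-6)

    def test_short_anchor_rejected(self):
        anchor = make_trace(np.full(600, 5.0))  # 5 s
        stim = make_trace(np.full(600, 5.0))
        with pytest.raises(ValueError, match="baseline window"):
            baseline_correct(stim, anchor, window_s=10.0)


class TestExtractDiameter:
    def test_constant_trace(self):
        tr = make_trace(np.full(1200, 3.0))
        assert extract_diameter(tr, 5.0) == pytest.approx(3.0)

    def test_linear_ramp_midpoint(self):
        t = np.arange(12000) / 120.0
        tr = make_trace(2.0 + 0.01 * t)
        assert extract_diameter(tr, 60.0, window_s=1.0) == pytest.approx(2.6, abs=1e-3)

    def test_right_aligned_at_trace_end(self):
        t = np.arange(36000) / 120.0
        tr = make_trace(2.0 + 0.01 * t)
        # window [299, 300): mean of the ramp over the final second
        got = extract_diameter(tr, 300.0, window_s=1.0)
        expected = np.mean(2.0 + 0.01 * t[t >= 299.0 - 1e-9])
        assert got == pytest.approx(expected, abs=1e-9)

    def test_matches_direct_windowed_mean(self):
        rng = np.random.default_rng(5)
        d = 4.0 + rng.normal(0, 0.2, 12000)
        tr = make_trace(np.clip(d, 2, 8))
        t = tr.time_s
        sel = (t >= 59.5 - 1e-9) & (t <= 60.5 + 1e-9)
        assert extract_diameter(tr, 60.0) == pytest.approx(
            tr.diameter_mm[sel].mean(), abs=1e-12
        )

    def test_outside_trace_rejected(self):
        tr = make_trace(np.full(1200, 3.0))
        with pytest.raises(ValueError, match="outside"):
            extract_diameter(tr, 100.0)


class TestPredictionError:
    def test_zero_error(self):
        s = prediction_error(3.0, [3.0, 3.0])
        assert (s.mean_error_mm, s.sd_error_mm, s.n) == (0.0, 0.0, 2)

    def test_hand_arithmetic(self):
        s = prediction_error(3.0, [2.0, 4.0])
        assert s.mean_error_mm == pytest.approx(0.0)
        assert s.sd_error_mm == pytest.approx(math.sqrt(2.0))

    def test_sampling_distribution(self):
        rng = np.random.default_rng(11)
        measured = 3.0 + rng.normal(0.5, 0.1, 20)
        s = prediction_error(3.0, measured)
        se = s.sd_error_mm / math.sqrt(s.n)
        assert abs(s.mean_error_mm - (-0.5)) < 3 * se

    def test_subject_order_invariance(self):
        vals = [2.8, 3.4, 3.1, 2.9]
        a = prediction_error(3.0, vals)
        b = prediction_error(3.0, vals[::-1])
        assert a.mean_error_mm == b.mean_error_mm
        assert a.sd_error_mm == b.sd_error_mm

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            prediction_error(3.0, [])


class TestOffsetCorrection:
    def test_published_condition_means(self):
        corrected, offset = offset_correct([0.94, 0.71])
        assert offset == pytest.approx(0.825)
        assert corrected[0] == pytest.approx(0.115)
        assert round(corrected[0], 2) == 0.12
        assert corrected[1] == pytest.approx(-0.115)

    def test_equal_means_vanish(self):
        corrected, _ = offset_correct([0.4, 0.4, 0.4])
        np.testing.assert_allclose(corrected, 0.0, atol=1e-15)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        means=st.lists(
            st.floats(min_value=-5, max_value=5), min_size=2, max_size=8
        )
    )
    def test_corrected_means_center_to_zero(self, means):
        corrected, offset = offset_correct(means)
        assert corrected.sum() == pytest.approx(0.0, abs=1e-9)
        assert offset == pytest.approx(np.mean(means), abs=1e-12)


class TestRmAnova:
    TOY = np.array(
        [
            [5.0, 4.0, 3.0],
            [6.0, 5.0, 5.0],
            [4.0, 4.0, 2.0],
            [7.0, 5.0, 4.0],
            [6.0, 6.0, 3.0],
        ]
    )

    def test_agrees_with_definitional_oracle(self):
        res = rm_anova(self.TOY)
        oracle = brute_force_rm_anova(self.TOY)
        assert res.f_value == pytest.approx(oracle["f"], abs=1e-8)
        assert res.mauchly_w == pytest.approx(oracle["w"], abs=1e-8)
        assert res.mauchly_chi2 == pytest.approx(oracle["chi2"], abs=1e-8)
        assert res.gg_epsilon == pytest.approx(oracle["eps"], abs=1e-8)
        assert res.eta_sq == pytest.approx(oracle["eta_sq"], abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(4.0, 1.0, size=(5, 3)) + rng.normal(0, 1, size=(5, 1))
        res = rm_anova(x)
        oracle = brute_force_rm_anova(x)
        for got, want in [
            (res.f_value, oracle["f"]),
            (res.mauchly_w, oracle["w"]),
            (res.gg_epsilon, oracle["eps"]),
        ]:
            assert got == pytest.approx(want, abs=1e-8)

    def test_agrees_with_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        x = rng.normal(4.0, 0.8, size=(10, 4)) + np.array([0.0, 0.2, 0.5, 0.9])
        res = rm_anova(x, list("abcd"))
        n, k = x.shape
        df = pd.DataFrame(
            {
                "y": x.ravel(),
                "subj": np.repeat(np.arange(n), k),
                "cond": np.tile(list("abcd"), n),
            }
        )
        aov = pg.rm_anova(df, dv="y", within="cond", subject="subj",
                          detailed=True, effsize="n2")
        sph = pg.sphericity(df, dv="y", within="cond", subject="subj")
        eps = pg.epsilon(df, dv="y", within="cond", subject="subj", correction="gg")
        assert res.f_value == pytest.approx(float(aov.loc[0, "F"]), rel=1e-9)
        assert res.eta_sq == pytest.approx(float(aov.loc[0, "n2"]), rel=1e-9)
        assert res.mauchly_w == pytest.approx(float(sph.W), rel=1e-9)
        assert res.gg_epsilon == pytest.approx(float(eps), rel=1e-9)

    def test_two_conditions_reduce_to_paired_t(self):
        rng = np.random.default_rng(4)
        x = rng.normal(5.0, 1.0, size=(12, 2))
        res = rm_anova(x)
        t_stat, p = stats.ttest_rel(x[:, 0], x[:, 1])
        assert res.f_value == pytest.approx(t_stat**2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)
        assert res.gg_epsilon == 1.0
        assert res.mauchly_p == 1.0

    def test_subject_constant_shift_leaves_f_unchanged(self):
        x = self.TOY.copy()
        ref = rm_anova(x).f_value
        x[2] += 100.0
        assert rm_anova(x).f_value == pytest.approx(ref, rel=1e-9)

    def test_epsilon_one_keeps_df(self):
        res = rm_anova(self.TOY)
        n, k = self.TOY.shape
        if not res.epsilon_applied:
            assert (res.df1, res.df2) == (k - 1, (n - 1) * (k - 1))

    def test_bonferroni_pairwise(self):
        res = rm_anova(self.TOY, ["c1", "c2", "c3"])
        assert len(res.pairwise) == 3
        combos = list(itertools.combinations(range(3), 2))
        for pc, (i, j) in zip(res.pairwise, combos):
            t_stat, p = stats.ttest_rel(self.TOY[:, i], self.TOY[:, j])
            assert pc.t == pytest.approx(float(t_stat), rel=1e-10)
            assert pc.p_bonferroni == pytest.approx(min(float(p) * 3, 1.0), rel=1e-10)
            assert pc.mean_diff_mm == pytest.approx(
                float(np.mean(self.TOY[:, i] - self.TOY[:, j])), rel=1e-12
            )

    def test_missing_cells_rejected(self):
        x = self.TOY.copy()
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova(x)

    def test_epsilon_bounds(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, size=(6, 4))
            res = rm_anova(x)
            assert 1.0 / 3.0 - 1e-12 <= res.gg_epsilon <= 1.0
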