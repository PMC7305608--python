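import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pelletome as pt
from pelletome import ValidationError
from pelletome.differential import METHOD_NORM, METHOD_RAW
from tests.conftest import make_manifest


class TestWelchT:
    def test_identical_samples(self):
        res = pt.welch_t([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_hand_computed_example(self):
        res = pt.welch_t([1, 2, 3, 4], [2, 3, 4, 5])
        assert res.t == pytest.approx(-1.0954451, abs=1e-6)
        assert res.df == pytest.approx(6.0, abs=1e-9)
        assert res.p == pytest.approx(0.3153336, abs=1e-4)

    def test_scale_invariance(self):
        a = pt.welch_t([1.0, 2.0, 5.0], [2.0, 4.0, 4.5])
        b = pt.welch_t([7.0, 14.0, 35.0], [14.0, 28.0, 31.5])
        assert a.t == pytest.approx(b.t, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)

    def test_zero_variance_conventions(self):
        assert pt.welch_t([2, 2, 2], [2, 2, 2]).p == 1.0
        assert pt.welch_t([2, 2, 2], [3, 3, 3]).p == 0.0

    @given(st.integers(min_value=0, max_value=2**31))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_agrees_with_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(2, 12))
        y = rng.normal(loc=rng.normal(), size=rng.integers(2, 12))
        mine = pt.welch_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert mine.t == pytest.approx(ref.statistic, abs=1e-8)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-8)


class TestWilcoxonRankSum:
    def test_exact_enumeration_small_case(self):
        # 6 equally likely rank assignments; observed is the most extreme
        assert pt.wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_exchangeable_samples_give_one(self):
        assert pt.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == 1.0

    def test_label_swap_symmetry(self):
        x, y = [1.5, 2.5, 9.0], [3.0, 4.0, 5.0, 6.0]
        assert pt.wilcoxon_rank_sum(x, y) == pytest.approx(pt.wilcoxon_rank_sum(y, x))

    def test_all_tied_gives_one(self):
        assert pt.wilcoxon_rank_sum([5, 5, 5], [5, 5, 5, 5]) == 1.0

    @given(st.integers(min_value=0, max_value=2**31))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_approximation_agrees_with_scipy(self, seed):
        rng = np.random.default_rng(seed)
        # force the approximation path: combined n > 12
        x = rng.normal(size=rng.integers(5, 10))
        y = rng.normal(loc=0.5, size=rng.integers(8, 12))
        mine = pt.wilcoxon_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert mine == pytest.approx(min(1.0, ref.pvalue), abs=1e-8)

    @given(st.integers(min_value=0, max_value=2**31))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_exact_close_to_approximation_at_n12(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(1.0, 13.0))[:6]
        y = np.setdiff1d(np.arange(1.0, 13.0), x)
        exact = pt.wilcoxon_rank_sum(x, y)
        ranks = stats.rankdata(np.concatenate([x, y]))
        u1 = ranks[:6].sum() - 21
        z = (u1 - 18 - 0.5 * np.sign(u1 - 18)) / np.sqrt(6 * 6 * 13 / 12)
        approx = min(1.0, 2 * stats.norm.sf(abs(z)))
        assert abs(exact - approx) < 0.02


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        out = pt.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert pt.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_out_of_range_raises(self):
        with pytest.raises(ValidationError):
            pt.bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_adjusted_at_least_raw_and_matches_step_up_oracle(self, pvals):
        out = pt.bh_adjust(pvals)
        p = np.asarray(pvals)
        assert (out >= p - 1e-12).all()
        assert (out <= 1.0 + 1e-12).all()
        # independent step-up oracle
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        assert np.allclose(out, adj, atol=1e-12)


class TestMethod1:
    def _setup(self, control_counts, disease_counts, n=4):
        manifest = make_manifest(("control", "AD"), n_subjects=n)
        pel_c = manifest.samples(group="control", fraction="pellet")
        pel_d = manifest.samples(group="AD", fraction="pellet")
        frame = pd.DataFrame(
            1, index=["TARGET", "FLAT"], columns=manifest.sample_ids
        )
        frame.loc["TARGET", pel_c] = control_counts
        frame.loc["TARGET", pel_d] = disease_counts
        return pt.CountMatrix(frame.astype(np.int64)), manifest

    def test_plain_ratio_of_means(self):
        counts, manifest = self._setup([2, 2, 2, 2], [12, 12, 12, 12])
        rec = pt.method1_rank(counts, manifest).set_index("protein_id")
        assert rec.loc["TARGET", "ratio"] == pytest.approx(6.0)
        assert rec.loc["TARGET", "method"] == METHOD_RAW

    def test_zero_control_mean_uses_pseudo_guard(self):
        counts, manifest = self._setup([0, 0, 0, 0], [20, 20, 20, 20])
        rec = pt.method1_rank(counts, manifest).set_index("protein_id")
        assert rec.loc["TARGET", "ratio"] == pytest.approx(5.0)  # (20+5)/(0+5)

    def test_identical_groups_are_null(self):
        counts, manifest = self._setup([4, 7, 1, 9], [4, 7, 1, 9])
        rec = pt.method1_rank(counts, manifest).set_index("protein_id")
        assert rec.loc["TARGET", "ratio"] == pytest.approx(1.0)
        assert rec.loc["TARGET", "p_welch"] == pytest.approx(1.0)

    def test_single_replicate_group_raises(self):
        counts, manifest = self._setup([3], [3], n=1)
        with pytest.raises(ValidationError, match=">= 2"):
            pt.method1_rank(counts, manifest)

    def test_row_order_invariance(self, small_dataset):
        ds = small_dataset
        a = pt.method1_rank(ds.counts, ds.manifest).set_index("protein_id")
        shuffled = pt.CountMatrix(ds.counts.counts.iloc[::-1])
        b = pt.method1_rank(shuffled, ds.manifest).set_index("protein_id")
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


class TestMethod2:
    def test_forced_arithmetic(self):
        manifest = make_manifest(("control", "AD"), n_subjects=3)
        ratios = pd.DataFrame(
            {"C1": [1.0], "C2": [1.1], "C3": [0.9], "AD1": [2.0], "AD2": [2.1], "AD3": [1.9]},
            index=["A"],
        )
        rec = pt.method2_rank(ratios, manifest).iloc[0]
        assert rec["log_fc"] == pytest.approx(1.0)
        assert rec["ratio"] == pytest.approx(2.0)
        assert rec["method"] == METHOD_NORM

    def test_equal_groups_are_null(self):
        manifest = make_manifest(("control", "AD"), n_subjects=2)
        ratios = pd.DataFrame({"C1": [1.0], "C2": [2.0], "AD1": [1.0], "AD2": [2.0]}, index=["A"])
        rec = pt.method2_rank(ratios, manifest).iloc[0]
        assert rec["log_fc"] == 0.0
        assert rec["p_welch"] == 1.0

    def test_too_few_subjects_raises(self):
        manifest = make_manifest(("control", "AD"), n_subjects=2)
        ratios = pd.DataFrame({"C1": [1.0], "C2": [2.0], "AD1": [1.5]}, index=["A"])
        with pytest.raises(ValidationError):
            pt.method2_rank(ratios, manifest)


class TestCallSignificant:
    @pytest.mark.parametrize(
        "q,log_fc,expected",
        [
            (0.04, 0.6, True),
            (0.04, 0.4, False),  # both conditions required
            (0.05, 2.0, False),  # strict inequality on alpha
            (0.01, 0.5, False),  # strict inequality on the fold threshold
            (0.01, -0.8, True),  # absolute fold change
        ],
    )
    def test_thresholds(self, q, log_fc, expected):
        records = pd.DataFrame({"protein_id": ["x"], "log_fc": [log_fc], "q_welch": [q]})
        out = pt.call_significant(records, pt.SignificanceConfig())
        assert bool(out["significant"].iloc[0]) is expected
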