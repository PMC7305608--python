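import numpy as np
import pandas as pd
import pytest

import pelletome as pt
from pelletome import ValidationError
from pelletome.pca import PCAResult, _robust_distances
from tests.conftest import make_manifest


def _centered(rng, n_prot=120, n_sub=10):
    ratios = pd.DataFrame(
        rng.normal(size=(n_prot, n_sub)),
        index=[f"P{i}" for i in range(n_prot)],
        columns=[f"S{j}" for j in range(n_sub)],
    )
    return pt.center_ratios(ratios)


class TestPCA:
    def test_reconstruction_with_all_components(self, rng):
        centered = _centered(rng)
        res = pt.pca_on_ratios(centered)
        recon = res.scores @ res.loadings.T
        assert np.max(np.abs(recon - centered.to_numpy().T)) < 1e-8

    def test_total_variance_conserved(self, rng):
        centered = _centered(rng)
        res = pt.pca_on_ratios(centered)
        X = centered.to_numpy().T
        assert res.scores.var(axis=0, ddof=1).sum() == pytest.approx(
            X.var(axis=0, ddof=1).sum(), rel=1e-10
        )

    def test_variance_explained_non_increasing(self, rng):
        res = pt.pca_on_ratios(_centered(rng))
        assert (np.diff(res.variance_explained) <= 1e-12).all()
        assert res.variance_explained.sum() <= 1 + 1e-9

    def test_duplicate_subjects_have_equal_scores(self, rng):
        centered = _centered(rng, n_sub=6)
        centered["S1"] = centered["S0"]
        centered = pt.center_ratios(centered)
        res = pt.pca_on_ratios(centered)
        assert np.allclose(res.scores[0], res.scores[1], atol=1e-8)

    def test_groups_separate_along_pc1_with_large_effect(self):
        ds = pt.simulate_pelletome(
            pt.SimulationConfig(n_per_group=6, n_proteins=500, effect_log2=2.0, seed=11)
        )
        pairing = pt.validate_pairing(ds.manifest, ds.counts)
        centered = pt.center_ratios(
            pt.insolubility_ratio(pt.normalize_counts(ds.counts), pairing)
        )
        res = pt.pca_on_ratios(centered)
        group_of = ds.manifest.group_of_subject()
        pc1 = {s: res.scores[i, 0] for i, s in enumerate(res.subject_ids)}
        ad = [v for s, v in pc1.items() if group_of[s] == "AD"]
        ctl = [v for s, v in pc1.items() if group_of[s] == "control"]
        # complete separation of the clusters along PC1
        assert max(min(ad), min(ctl)) > min(max(ad), max(ctl)) or (
            min(ad) > max(ctl) or min(ctl) > max(ad)
        )

    def test_excess_components_clipped_with_warning(self, rng):
        with pytest.warns(UserWarning, match="clipped"):
            res = pt.pca_on_ratios(_centered(rng, n_sub=4), n_components=10)
        assert res.scores.shape[1] == 4


class TestFlagOutliers:
    def test_zero_spread_flags_nothing(self):
        scores = np.zeros((6, 2))
        res = PCAResult(tuple("abcdef"), scores, np.zeros((10, 2)), np.array([0.0, 0.0]))
        with pytest.warns(UserWarning, match="zero MAD"):
            reports = pt.flag_outliers(res)
        assert not any(r.flagged for r in reports)

    def test_infinite_k_flags_nothing(self, rng):
        centered = _centered(rng)
        reports = pt.flag_outliers(pt.pca_on_ratios(centered), k=np.inf)
        assert not any(r.flagged for r in reports)

    def test_subject_order_and_scale_invariance(self, rng):
        centered = _centered(rng)
        rep_a = pt.flag_outliers(pt.pca_on_ratios(centered))
        shuffled = centered[list(reversed(centered.columns))]
        rep_b = pt.flag_outliers(pt.pca_on_ratios(shuffled))
        rep_c = pt.flag_outliers(pt.pca_on_ratios(centered * 7.5))
        dist_a = {r.subject_id: r.robust_distance for r in rep_a}
        dist_b = {r.subject_id: r.robust_distance for r in rep_b}
        dist_c = {r.subject_id: r.robust_distance for r in rep_c}
        for s in dist_a:
            assert dist_a[s] == pytest.approx(dist_b[s], abs=1e-8)
            assert dist_a[s] == pytest.approx(dist_c[s], abs=1e-8)

    def test_planted_outlier_recovered(self):
        ds = pt.simulate_outlier(
            pt.SimulationConfig(n_proteins=400, seed=5, outlier_subject=True)
        )
        pairing = pt.validate_pairing(ds.manifest, ds.counts)
        centered = pt.center_ratios(
            pt.insolubility_ratio(pt.normalize_counts(ds.counts), pairing)
        )
        reports = pt.flag_outliers(pt.pca_on_ratios(centered))
        flagged = {r.subject_id for r in reports if r.flagged}
        assert flagged == {ds.outlier_subject}

    def test_robust_distance_definition(self):
        scores = np.array([[0.0], [1.0], [-1.0], [0.5], [-0.5], [30.0]])
        d = _robust_distances(scores, n_pcs=1)
        med = np.median(scores[:, 0])
        mad = np.median(np.abs(scores[:, 0] - med))
        assert d[5] == pytest.approx(abs(30.0 - med) / (1.4826 * mad))


class TestExcludeSubjects:
    def _reports(self, subjects, flagged):
        return [
            pt.pca.OutlierReport(s, 10.0 if s in flagged else 0.0, s in flagged, 5.0)
            for s in subjects
        ]

    def test_no_flags_is_identity(self, rng):
        ratios = _centered(rng, n_sub=4)
        out = pt.exclude_subjects(ratios, self._reports(ratios.columns, set()))
        pd.testing.assert_frame_equal(out, ratios)

    def test_one_flag_removes_one_column(self):
        manifest = make_manifest(("control", "AD"), n_subjects=8)
        subjects = manifest.subject_ids
        ratios = pd.DataFrame(np.zeros((3, 16)), columns=subjects)
        out = pt.exclude_subjects(ratios, self._reports(subjects, {"AD6"}), manifest)
        assert out.shape[1] == 15
        assert "AD6" not in out.columns
        assert sum(c.startswith("AD") for c in out.columns) == 7

    def test_flagging_whole_group_raises(self):
        manifest = make_manifest(("control", "AD"), n_subjects=2)
        subjects = manifest.subject_ids
        ratios = pd.DataFrame(np.zeros((3, 4)), columns=subjects)
        with pytest.raises(ValidationError, match="AD"):
            pt.exclude_subjects(ratios, self._reports(subjects, {"AD1", "AD2"}), manifest)
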