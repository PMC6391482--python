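"""Target extraction and agreement statistics against brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from vsimetry.stats import (
    TargetRecord,
    bland_altman,
    build_report,
    correlate,
    extract_target,
    group_compare,
    paired_t,
)


def brute_force_sphere(volume, affine, center, radius):
    """Naive triple-loop sphere membership, the oracle for extract_target."""
    vals = []
    for i in range(volume.shape[0]):
        for j in range(volume.shape[1]):
            for k in range(volume.shape[2]):
                xyz = affine[:3, :3] @ [i, j, k] + affine[:3, 3]
                if np.linalg.norm(xyz - np.asarray(center)) <= radius:
                    vals.append(volume[i, j, k])
    return np.array(vals)


class TestExtractTarget:
    affine = np.diag([2.0, 2.0, 3.0, 1.0])

    def test_uniform_map(self):
        vol = np.full((10, 10, 6), 3.7)
        value, n = extract_target(vol, self.affine, (10.0, 10.0, 9.0), 5.0)
        oracle = brute_force_sphere(vol, self.affine, (10.0, 10.0, 9.0), 5.0)
        assert value == 3.7 and n == oracle.size > 1

    def test_tiny_radius_selects_single_voxel(self):
        vol = np.arange(60.0).reshape(5, 4, 3)
        value, n = extract_target(vol, self.affine, (4.0, 2.0, 3.0), 0.5)
        assert n == 1 and value == vol[2, 1, 1]

    def test_two_valued_plane_median_matches_brute_force(self):
        vol = np.where(np.arange(12)[:, None, None] < 6, 1.0, 5.0) \
            * np.ones((12, 12, 8))
        center, radius = (11.0, 12.0, 12.0), 6.0
        value, n = extract_target(vol, self.affine, center, radius)
        oracle = brute_force_sphere(vol, self.affine, center, radius)
        assert n == oracle.size
        assert value == np.median(oracle)

    def test_empty_sphere_rejected(self):
        with pytest.raises(ValueError, match="no valid voxels"):
            extract_target(np.ones((4, 4, 4)), self.affine, (500.0, 0.0, 0.0), 5.0)

    def test_nan_voxels_excluded(self):
        vol = np.full((6, 6, 4), 2.0)
        vol[2, 2, 1] = np.nan
        value, _ = extract_target(vol, self.affine, (4.0, 4.0, 3.0), 4.0)
        assert value == 2.0


class TestBlandAltman:
    def test_identical_series(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.mean_difference == ba.loa_low == ba.loa_high == 0.0

    def test_constant_offset_zero_variance(self):
        ba = bland_altman([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        assert ba.mean_difference == -1.0
        assert ba.loa_low == ba.loa_high == -1.0

    def test_hand_arithmetic_example(self):
        # d = {0, -1, -2}: mean -1, sample SD 1, LoA -1 +/- 1.96
        ba = bland_altman([0.0, 0.0, 0.0], [0.0, 1.0, 2.0])
        assert ba.mean_difference == pytest.approx(-1.0)
        assert ba.sd == pytest.approx(1.0)
        assert ba.loa_low == pytest.approx(-2.96)
        assert ba.loa_high == pytest.approx(0.96)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=2, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_loa_identity(self, pairs):
        """LoA are exactly mean +/- 1.96 * sample SD of the differences."""
        x, y = (np.array(v) for v in zip(*pairs))
        ba = bland_altman(x, y)
        d = x - y
        assert ba.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1),
                                           abs=1e-9)
        assert ba.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1),
                                            abs=1e-9)
        assert ba.loa_low <= ba.mean_difference <= ba.loa_high


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert correlate(x, -x)[0] == pytest.approx(-1.0)

    def test_p_value_matches_t_distribution(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 26))
        r, p = correlate(x, y)
        t = r * np.sqrt((26 - 2) / (1 - r**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 24), rel=1e-10)

    def test_cohort_scale_example(self):
        # r = 0.49 at n = 26 is significant at about p = 0.011
        t = 0.49 * np.sqrt(24 / (1 - 0.49**2))
        assert 2 * sps.t.sf(t, 24) == pytest.approx(0.011, abs=0.001)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0])

    @given(a=st.floats(0.1, 10.0), b=st.floats(-100.0, 100.0))
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=(2, 20))
        r0, p0 = correlate(x, y)
        r1, p1 = correlate(a * x + b, y)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert p1 == pytest.approx(p0, abs=1e-9)


class TestGroupCompare:
    def test_u_matches_brute_force_count(self):
        """U equals the pairwise-win count (with half for ties), n1=n2=3."""
        a, b = [1.0, 4.0, 6.0], [2.0, 3.0, 5.0]
        res = group_compare(np.array(a + b),
                            np.array(["x"] * 3 + ["y"] * 3))
        wins = sum(0.5 if u == v else float(u > v)
                   for u, v in itertools.product(a, b))
        assert res["u"] == wins

    def test_complete_separation(self):
        res = group_compare(np.array([10.0, 11.0, 12.0, 1.0, 2.0, 3.0]),
                            np.array(["hi"] * 3 + ["lo"] * 3))
        assert res["u"] in (9.0, 0.0)
        # smallest achievable two-sided exact p at n1=n2=3 is 2/20
        assert res["p"] == pytest.approx(0.1, abs=1e-9)

    def test_group_validation(self):
        with pytest.raises(ValueError):
            group_compare(np.ones(3), np.array(["a", "a", "a"]))

    def test_paired_t_degenerate_cases(self):
        assert paired_t([1.0, 2.0], [1.0, 2.0])[1] == 1.0
        assert paired_t([2.0, 3.0], [1.0, 2.0])[1] == 0.0

    def test_shapiro_reported_per_group(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=20)
        res = group_compare(vals, np.array(["a"] * 10 + ["b"] * 10))
        for g in res["groups"]:
            assert 0 <= res["shapiro"][g]["p"] <= 1


class TestBuildReport:
    def test_perfect_caliber_agreement(self):
        from vsimetry.synthetic import make_paired_cohort
        recs, _ = make_paired_cohort(n_targets=26, rho_caliber=1.0, seed=0)
        report, _ = build_report(recs)
        assert report.pearson["vsi_mri_vs_caliber"]["r"] == pytest.approx(1.0,
                                                                          abs=1e-9)

    def test_too_few_targets_refused(self):
        recs = [TargetRecord(target_id=str(i), grade="III", rcbv=1.0, adc=1.0,
                             vsi_mri=10.0, density=40.0, vsi_histo=11.0)
                for i in range(2)]
        with pytest.raises(ValueError):
            build_report(recs)

    def test_incomplete_targets_excluded_and_logged(self):
        from vsimetry.synthetic import make_paired_cohort
        recs, _ = make_paired_cohort(n_targets=10, seed=1)
        recs[3].vsi_histo = float("nan")
        report, df = build_report(recs)
        assert report.excluded == ["T03"]
        assert report.n_targets == 9 and len(df) == 9

    def test_report_matches_independent_recomputation(self):
        """Every reported statistic is re-derived directly with scipy."""
        from vsimetry.synthetic import make_paired_cohort
        recs, _ = make_paired_cohort(n_targets=26, seed=12)
        report, df = build_report(recs)
        d = df["vsi_histo"].to_numpy() - df["vsi_mri"].to_numpy()
        assert report.bland_altman.mean_difference == pytest.approx(d.mean())
        assert report.bland_altman.loa_high == pytest.approx(
            d.mean() + 1.96 * d.std(ddof=1))
        r, p = sps.pearsonr(df["rcbv"], df["density"])
        assert report.pearson["rcbv_vs_density"]["r"] == pytest.approx(r)
        assert report.pearson["rcbv_vs_density"]["p"] == pytest.approx(p)
        t, tp = sps.ttest_rel(df["vsi_histo"], df["vsi_mri"])
        assert report.t_p == pytest.approx(tp)
        first, second = report.grade_tests["rcbv"]["groups"]
        g3 = df[df.grade == first]["rcbv"]
        g4 = df[df.grade == second]["rcbv"]
        u, up = sps.mannwhitneyu(g3, g4, alternative="two-sided")
        assert report.grade_tests["rcbv"]["u"] == pytest.approx(u)
        assert report.grade_tests["rcbv"]["p"] == pytest.approx(up)
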