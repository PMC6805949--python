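"""Phantom generator: digitisation accuracy, cohort sampling, clinical rules."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oculomorph.morphometry import compute_volume, measure_eye
from oculomorph.phantom import (
    EyePhantomSpec,
    VisualFieldMap,
    assign_groups,
    classify_visual_field,
    default_correlation,
    default_group_params,
    make_eye_mask,
    masks_from_cohort,
    sample_cohort,
)


def analytic_ellipsoid_volume(a, b, c):
    return 4.0 / 3.0 * np.pi * a * b * c


class TestMakeEyeMask:
    def test_sphere_volume_matches_analytic(self, sphere_mask):
        vol = compute_volume(sphere_mask)
        expected = analytic_ellipsoid_volume(11.6, 11.6, 11.6)
        assert abs(vol - expected) / expected < 0.015

    def test_ellipsoid_ground_truth_diameters(self, myopic_ellipsoid_mask):
        lm = myopic_ellipsoid_mask.landmarks
        # apex-to-posterior-pole distance is the anteroposterior diameter
        assert np.linalg.norm(lm["apex"] - lm["disk"]) == pytest.approx(25.6, abs=1e-9)

    def test_zero_bump_is_exact_ellipsoid(self):
        base = EyePhantomSpec(11.0, 10.5, 10.0, rotation=(10, -5, 3))
        bumped = dataclasses.replace(base, bump_amplitude=0.0,
                                     bump_direction=(0, -1, -1))
        a = make_eye_mask(base)
        b = make_eye_mask(bumped)
        assert np.array_equal(a.data, b.data)

    def test_bump_adds_material_in_bump_direction_only(self):
        spec = EyePhantomSpec(11.0, 11.0, 11.0, grid_shape=(44, 44, 44))
        bumped = dataclasses.replace(spec, bump_amplitude=1.2,
                                     bump_direction=(0.0, -1.0, 0.0))
        plain = make_eye_mask(spec).data
        with_bump = make_eye_mask(bumped).data
        assert (with_bump & ~plain).sum() > 0
        assert not (plain & ~with_bump).any()

    def test_invalid_specs_raise(self):
        with pytest.raises(ValueError, match="invalid spec"):
            make_eye_mask(EyePhantomSpec(-1.0, 10.0, 10.0))
        with pytest.raises(ValueError, match="grid too small"):
            make_eye_mask(EyePhantomSpec(11.6, 11.6, 11.6, grid_shape=(20, 20, 20)))

    def test_volume_error_shrinks_with_voxel_refinement(self, rng):
        """Mean digitisation error over random shapes drops as voxels shrink."""
        mean_errors = []
        for vox in (1.4, 0.7, 0.35):
            errs = []
            for _ in range(8):
                a, b, c = rng.uniform(10, 13, 3)
                ctr = tuple(rng.uniform(-0.5, 0.5, 3) * vox)
                m = make_eye_mask(EyePhantomSpec(a, b, c, center=ctr,
                                                 voxel_size=vox))
                expected = analytic_ellipsoid_volume(a, b, c)
                errs.append(abs(m.volume_mm3() - expected) / expected)
            mean_errors.append(np.mean(errs))
        assert mean_errors[0] > mean_errors[1] > mean_errors[2]


class TestSampleCohort:
    def test_default_group_sizes(self, default_cohort):
        sizes = default_cohort.groupby("group").size()
        assert sizes["control"] == 30
        assert sizes["myopia"] == 13
        assert sizes["glaucoma"] == 33
        assert sizes["glaucoma_myopia"] == 51
        assert sizes["ppg"] == 27
        assert len(default_cohort) == 154

    def test_fixed_seed_reproducible(self):
        a = sample_cohort(seed=11)
        b = sample_cohort(seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_sd_degenerate(self):
        gp = dataclasses.replace(default_group_params()[0], n_eyes=8)
        gp = dataclasses.replace(gp, sds={v: 0.0 for v in gp.sds})
        df = sample_cohort([gp], seed=0)
        for var, mean in gp.means.items():
            assert np.allclose(df[var], mean)

    def test_control_marginals_are_gaussian(self):
        """KS non-rejection for a group far from the truncation bounds."""
        gp = dataclasses.replace(default_group_params()[0], n_eyes=5000)
        df = sample_cohort([gp], seed=3)
        for var in ("volume", "axial", "age"):
            stat = sps.kstest(df[var], "norm",
                              args=(gp.means[var], gp.sds[var]))
            assert stat.pvalue > 0.01, var

    def test_replicate_mean_volume_matches_target(self):
        """Control volume mean over replicates within 2 SE of 6182.3 mm^3."""
        gp = default_group_params()[0]
        means = [sample_cohort([gp], seed=s)["volume"].mean()
                 for s in range(200)]
        se = gp.sds["volume"] / np.sqrt(gp.n_eyes * len(means))
        assert abs(np.mean(means) - 6182.3) < 2 * se + 1e-9

    def test_copula_recovers_spearman_target(self):
        gp = dataclasses.replace(default_group_params()[0], n_eyes=1000)
        df = sample_cohort([gp], seed=5)
        rho = sps.spearmanr(df["volume"], df["etiv"]).statistic
        assert abs(rho - 0.40) < 0.05

    def test_subject_sharing_and_eligibility(self, default_cohort):
        per_subj = default_cohort.groupby("subject_id")
        assert (per_subj.size() <= 2).all()
        for var in ("age", "height", "etiv", "sex"):
            assert (per_subj[var].nunique() == 1).all(), var
        assert (default_cohort["se"] > -8.0).all()

    def test_invalid_correlation_rejected(self):
        bad = default_correlation().copy()
        bad.loc["volume", "axial"] = 0.99
        bad.loc["axial", "volume"] = 0.99
        bad.loc["volume", "transverse"] = 0.99
        bad.loc["transverse", "volume"] = 0.99
        bad.loc["axial", "transverse"] = -0.9
        bad.loc["transverse", "axial"] = -0.9
        with pytest.raises(ValueError, match="invalid correlation spec"):
            sample_cohort(correlation=bad, seed=0)


class TestMasksFromCohort:
    def test_empty_table_gives_empty_set(self, default_cohort):
        assert masks_from_cohort(default_cohort.iloc[0:0]) == {}

    def test_missing_ground_truth_rejected(self, default_cohort):
        broken = default_cohort.head(3).drop(columns=["true_axial"])
        with pytest.raises(ValueError, match="incomplete record"):
            masks_from_cohort(broken)

    def test_spherical_record_measures_isotropic(self, default_cohort):
        """Spherical ground truth recovers anisotropy 1.00 downstream.

        A single 0.7 mm digitisation carries ~1 % staircase noise on the
        ratio, so the check averages over rotation seeds, as the cohort-level
        statistic does over eyes.
        """
        rec = default_cohort.head(1).copy()
        rec["true_axial"] = 23.2
        rec["true_transverse"] = 23.2
        ratios = []
        for seed in range(6):
            (mask,) = masks_from_cohort(rec, seed=seed).values()
            ratios.append(measure_eye(mask).anisotropy)
        assert np.mean(ratios) == pytest.approx(1.00, abs=0.01)

    def test_rotation_does_not_change_volume(self, default_cohort):
        rec = default_cohort.head(1).copy()
        rec["true_axial"] = 24.6
        rec["true_transverse"] = 23.8
        vols = [compute_volume(next(iter(masks_from_cohort(rec, seed=s).values())))
                for s in (1, 2)]
        assert abs(vols[0] - vols[1]) / vols[0] < 0.015

    def test_glaucoma_masks_carry_bump(self, default_cohort):
        rec = default_cohort[default_cohort["group"] == "glaucoma"].head(1).copy()
        rec["true_axial"] = rec["true_transverse"] = 24.0
        (bumped,) = masks_from_cohort(rec, seed=9).values()
        (plain,) = masks_from_cohort(rec, seed=9, bump_amplitude=0.0).values()
        assert bumped.data.sum() > plain.data.sum()


# ---------------------------------------------------------------------------
# Anderson-Patella visual-field classification
# ---------------------------------------------------------------------------

def brute_force_classify(cat, upper, ght=False, psd=False):
    """Independent oracle: BFS cluster search per hemifield."""
    if ght or psd:
        return "glaucomatous"
    rows, cols = cat.shape

    def clusters(points):
        points = set(points)
        seen, out = set(), []
        for p in points:
            if p in seen:
                continue
            stack, comp = [p], []
            seen.add(p)
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for q in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
                    if q in points and q not in seen:
                        seen.add(q)
                        stack.append(q)
            out.append(comp)
        return out

    for hemi in (True, False):
        pts5 = [(r, c) for r in range(rows) for c in range(cols)
                if cat[r, c] >= 1 and upper[r, c] == hemi]
        for comp in clusters(pts5):
            if len(comp) >= 3 and any(cat[r, c] == 2 for r, c in comp):
                return "glaucomatous"
        pts1 = [(r, c) for r in range(rows) for c in range(cols)
                if cat[r, c] == 2 and upper[r, c] == hemi]
        for comp in clusters(pts1):
            if len(comp) >= 2:
                return "glaucomatous"
    return "normal"


class TestClassifyVisualField:
    def test_all_normal_points(self):
        vf = VisualFieldMap(np.zeros((4, 4), dtype=int))
        assert classify_visual_field(vf) == "normal"

    def test_three_point_cluster_with_one_sub1pct(self):
        cat = np.zeros((4, 4), dtype=int)
        cat[0, 0] = cat[0, 1] = 1
        cat[1, 0] = 2
        assert classify_visual_field(VisualFieldMap(cat)) == "glaucomatous"

    def test_three_point_cluster_without_sub1pct_is_normal(self):
        cat = np.zeros((4, 4), dtype=int)
        cat[0, 0] = cat[0, 1] = cat[1, 0] = 1
        assert classify_visual_field(VisualFieldMap(cat)) == "normal"

    def test_two_adjacent_sub1pct_points(self):
        cat = np.zeros((4, 4), dtype=int)
        cat[2, 1] = cat[2, 2] = 2
        assert classify_visual_field(VisualFieldMap(cat)) == "glaucomatous"

    def test_cluster_split_across_hemifields_is_normal(self):
        # three <5% points 4-connected only across the hemifield border
        cat = np.zeros((4, 4), dtype=int)
        cat[1, 0] = 2
        cat[2, 0] = cat[3, 0] = 1
        upper = np.zeros((4, 4), dtype=bool)
        upper[:2] = True
        vf = VisualFieldMap(cat, upper=upper)
        assert classify_visual_field(vf) == "normal"

    @pytest.mark.parametrize("flag", ["ght_outside_normal", "psd_beyond_95"])
    def test_secondary_criteria_flags(self, flag):
        vf = VisualFieldMap(np.zeros((4, 4), dtype=int), **{flag: True})
        assert classify_visual_field(vf) == "glaucomatous"

    def test_matches_brute_force_on_random_grids(self, rng):
        upper = np.zeros((3, 3), dtype=bool)
        upper[:2] = True
        for _ in range(300):
            cat = rng.integers(0, 3, size=(3, 3))
            vf = VisualFieldMap(cat, upper=upper)
            assert classify_visual_field(vf) == brute_force_classify(cat, upper)


class TestAssignGroups:
    def make_table(self, se, glaucoma=False, ppg=False):
        return pd.DataFrame({"se": [se], "glaucoma": [glaucoma], "ppg": [ppg]})

    @pytest.mark.parametrize("se,glaucoma,ppg,expected", [
        (-5.3, False, False, "myopia"),
        (-3.00, False, False, "control"),     # strictly "worse than" -3
        (-2.99, True, False, "glaucoma"),
        (-5.58, True, False, "glaucoma_myopia"),
        (-1.88, False, True, "ppg"),
    ])
    def test_labels(self, se, glaucoma, ppg, expected):
        out = assign_groups(self.make_table(se, glaucoma, ppg))
        assert out["group"].iloc[0] == expected

    def test_high_myopia_excluded(self):
        out = assign_groups(self.make_table(-8.5))
        assert len(out) == 0

    def test_missing_se_rejected(self):
        with pytest.raises(ValueError, match="incomplete record"):
            assign_groups(pd.DataFrame({"se": [np.nan], "glaucoma": [False],
                                        "ppg": [False]}))
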