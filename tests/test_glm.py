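"""Design construction, first/second-level fits, clustering, smoothing."""

import numpy as np
import pytest
from scipy import stats

import physiofmri as pf
from physiofmri.core import BoldImage
from physiofmri import glm as G


@pytest.fixture(scope="module")
def events():
    return pf.gen_event_design(seed=1, start_s=10.0)


@pytest.fixture(scope="module")
def design216(events):
    return G.build_design(events, 216, 2.04, model=1)


class TestHrf:
    def test_zero_at_onset(self):
        assert G.canonical_hrf(np.array([0.0]))[0] == 0.0

    def test_peak_between_4_and_6_seconds(self):
        t = np.arange(0, 32, 0.01)
        h = G.canonical_hrf(t)
        assert 4.0 <= t[np.argmax(h)] <= 6.0
        assert h.max() == pytest.approx(1.0, abs=1e-6)

    def test_positive_integral_with_undershoot(self):
        t = np.arange(0, 32, 0.01)
        h = G.canonical_hrf(t)
        assert np.trapezoid(h, t) > 0
        assert h[(t > 12) & (t < 20)].min() < 0


class TestDesign:
    def test_model1_columns(self, design216):
        names = design216.column_names
        assert names[:2] == ["CC", "IC"]
        assert sum(n.startswith("dct") for n in names) == 6  # 2*216*2.04/128
        assert names[-1] == "intercept"
        assert not any("x" in n for n in names)

    def test_model2_adds_modulated_columns(self, events):
        rng = np.random.default_rng(0)
        d = G.build_design(events, 216, 2.04, model=2,
                           modulator=rng.standard_normal(len(events)))
        assert "CCxscr" in d.column_names and "ICxscr" in d.column_names
        assert "CC" in d.column_names  # main effects retained

    def test_motion_columns_appended(self, events):
        motion = np.zeros((216, 6)) + np.arange(216)[:, None] * 1e-3
        d = G.build_design(events, 216, 2.04, model=1, motion=motion)
        assert sum(n.startswith("motion") for n in d.column_names) == 6

    def test_constant_modulator_gives_zero_column(self, events):
        d = G.build_design(events, 216, 2.04, model=3,
                           modulator=np.full(len(events), 7.0))
        assert np.allclose(d.column("CCxpdr"), 0.0)
        assert np.allclose(d.column("ICxpdr"), 0.0)
        assert d.rank_deficient

    def test_modulator_linearity_after_centering(self, events):
        rng = np.random.default_rng(1)
        m = rng.standard_normal(len(events))
        d1 = G.build_design(events, 216, 2.04, model=3, modulator=m)
        d2 = G.build_design(events, 216, 2.04, model=3, modulator=2 * m)
        assert np.allclose(d2.column("ICxpdr"), 2 * d1.column("ICxpdr"))

    def test_modulator_centered_orthogonal_to_sticks_preconvolution(self, events):
        rng = np.random.default_rng(2)
        m = rng.standard_normal(len(events))
        for cond in ("CC", "IC"):
            sel = events.conditions == cond
            centered = m[sel] - m[sel].mean()
            assert np.ones(sel.sum()) @ centered == pytest.approx(0.0, abs=1e-10)

    def test_modulator_required_iff_model_2_or_3(self, events):
        with pytest.raises(ValueError):
            G.build_design(events, 216, 2.04, model=2)
        with pytest.raises(ValueError):
            G.build_design(events, 216, 2.04, model=1,
                           modulator=np.zeros(len(events)))

    def test_modulator_length_mismatch_rejected(self, events):
        with pytest.raises(ValueError):
            G.build_design(events, 216, 2.04, model=2, modulator=np.zeros(3))


class TestFirstLevel:
    def test_whitening_at_rho_zero_is_identity(self, rng):
        A = rng.standard_normal((30, 3))
        assert np.allclose(G._ar1_whiten(A, 0.0), A)

    def test_white_noise_fit_equals_plain_ols(self, design216, rng):
        """On white-noise data the AR(1) route reproduces plain OLS betas."""
        y = rng.standard_normal((216, 50))
        bold = BoldImage(y.T.reshape(50, 1, 1, 216), np.eye(4), 2.04)
        res = G.fit_first_level(bold, design216)
        assert abs(res.ar1_rho) < 0.02
        ols = np.linalg.pinv(design216.values) @ y
        # rho-hat is near but not exactly 0; compare through the same filter
        resw = G.fit_first_level(bold, design216, ar1=False)
        assert np.allclose(resw.betas.reshape(50, -1).T, ols, atol=1e-8)

    def test_noiseless_contrast_recovery(self, noiseless_clean_session):
        """True betas 1 (CC) and 2 (IC): fitted interference contrast is
        1.0 to within numerical precision."""
        s = noiseless_clean_session
        trim = s.bold.discard_initial(4)
        ev = s.events.shifted(-4 * s.bold.tr_s)
        design = G.build_design(ev, trim.n_volumes, trim.tr_s, model=1)
        res = G.fit_first_level(trim, design, ar1=False)
        con, t = G.interference_contrast(res)
        for v in s.truth.active_voxel_set:
            assert con[tuple(v)] == pytest.approx(1.0, abs=1e-6)

    def test_active_voxel_t_dominates_in_noiseless_session(
            self, noiseless_clean_session):
        s = noiseless_clean_session
        trim = s.bold.discard_initial(4)
        ev = s.events.shifted(-4 * s.bold.tr_s)
        design = G.build_design(ev, trim.n_volumes, trim.tr_s, model=1)
        res = G.fit_first_level(trim, design, ar1=False)
        con, t = G.interference_contrast(res)
        active = np.zeros(trim.grid, dtype=bool)
        for v in s.truth.active_voxel_set:
            active[tuple(v)] = True
        assert np.nanmin(np.where(active, t, np.nan)) > np.nanmax(
            np.where(active, np.nan, np.abs(t)))

    def test_pooled_rho_recovers_ar1_coefficient(self, design216):
        """Simulated AR(1) noise at rho 0.4, 216 volumes: the pooled
        estimate lands within 0.05 across 20 seeds."""
        rhos = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            e = rng.standard_normal((216, 300))
            y = np.empty_like(e)
            y[0] = e[0] / np.sqrt(1 - 0.16)
            for t in range(1, 216):
                y[t] = 0.4 * y[t - 1] + e[t]
            bold = BoldImage(y.T.reshape(300, 1, 1, 216), np.eye(4), 2.04)
            rhos.append(G.fit_first_level(bold, design216).ar1_rho)
        assert all(abs(r - 0.4) < 0.05 for r in rhos)

    def test_contrast_antisymmetry_under_label_swap(self, design216, rng):
        y = 100 + rng.standard_normal((216, 20))
        bold = BoldImage(y.T.reshape(20, 1, 1, 216), np.eye(4), 2.04)
        res = G.fit_first_level(bold, design216, ar1=False)
        con_fwd, _ = res.contrast({"IC": 1.0, "CC": -1.0})
        con_rev, _ = res.contrast({"CC": 1.0, "IC": -1.0})
        assert np.allclose(con_fwd, -con_rev, equal_nan=True)

    def test_row_mismatch_rejected(self, design216, rng):
        bold = BoldImage(rng.standard_normal((2, 2, 1, 100)), np.eye(4), 2.04)
        with pytest.raises(ValueError):
            G.fit_first_level(bold, design216)


class TestTypeICalibration:
    def test_null_voxel_false_positive_rate(self, design216):
        """10,000 white-noise voxels: the rate of t beyond the one-sided
        p < 0.005 critical value stays within 3 binomial SE of nominal."""
        rng = np.random.default_rng(77)
        y = rng.standard_normal((216, 10_000))
        bold = BoldImage(y.T.reshape(100, 100, 1, 216), np.eye(4), 2.04)
        res = G.fit_first_level(bold, design216)
        _, t = G.interference_contrast(res)
        rate = float(np.mean(t.ravel() > stats.t.ppf(0.995, res.df)))
        se = np.sqrt(0.005 * 0.995 / 10_000)
        assert rate == pytest.approx(0.005, abs=3 * se)


class TestSecondLevel:
    def test_identical_condition_maps_give_zero_t(self, rng):
        maps = [rng.standard_normal((4, 4, 4)) for _ in range(5)]
        t, df = G.second_level_paired(maps, [m.copy() for m in maps])
        assert df == 4
        assert np.allclose(t, 0.0)

    def test_matches_scipy_paired_oracle(self, rng):
        cc = [rng.standard_normal((3, 3, 3)) for _ in range(8)]
        ic = [rng.standard_normal((3, 3, 3)) for _ in range(8)]
        t, df = G.second_level_paired(cc, ic)
        ref = stats.ttest_rel(np.stack(ic), np.stack(cc), axis=0)
        assert np.allclose(t, ref.statistic, atol=1e-10)

    def test_group_effect_power(self):
        """11 subjects with a Cohen's d = 1.5 effect at active voxels:
        those voxels exceed the p < 0.005 threshold in at least 9/10 seeds."""
        hits = 0
        active = (2, 2, 2)
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            cc = [rng.standard_normal((5, 5, 5)) for _ in range(11)]
            ic = []
            for m in cc:
                d = rng.standard_normal((5, 5, 5))
                d[active] += 1.5
                ic.append(m + d)
            t, df = G.second_level_paired(cc, ic)
            if t[active] > stats.t.ppf(0.995, df):
                hits += 1
        assert hits >= 9

    def test_subject_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            G.second_level_paired([np.zeros((2, 2, 2))] * 4,
                                  [np.zeros((2, 2, 2))] * 5)


def flood_fill_components(binary):
    """Brute-force 26-connectivity labeling by breadth-first search."""
    binary = np.asarray(binary, dtype=bool)
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    for start in zip(*np.nonzero(binary)):
        if labels[start]:
            continue
        current += 1
        queue = [start]
        labels[start] = current
        while queue:
            x, y, z = queue.pop()
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if (0 <= p[0] < binary.shape[0] and 0 <= p[1] < binary.shape[1]
                        and 0 <= p[2] < binary.shape[2]
                        and binary[p] and not labels[p]):
                    labels[p] = current
                    queue.append(p)
    return labels, current


class TestClusterThreshold:
    def _tmap_with_blob(self, size=30):
        t = np.zeros((12, 12, 12))
        filled = 0
        for x in range(12):
            for y in range(12):
                for z in range(12):
                    if filled < size:
                        t[2 + x % 4, 2 + y % 4, 2 + (filled // 16)] = 5.0
                        filled += 1
        # ensure a single connected 30-voxel blob
        t[:] = 0.0
        coords = [(x, y, z) for z in (4, 5) for x in range(4, 8)
                  for y in range(4, 8)][:size]
        for c in coords:
            t[c] = 5.0
        return t

    def test_single_blob_reported_with_size(self):
        t = self._tmap_with_blob(30)
        table = G.cluster_threshold(t, df=10, voxel_p=0.005, extent=12)
        assert len(table) == 1
        assert table.rows.iloc[0]["size_voxels"] == 30
        assert table.rows.iloc[0]["peak_t"] == 5.0

    def test_extent_rule_removes_small_clusters(self):
        t = self._tmap_with_blob(30)
        table = G.cluster_threshold(t, df=10, voxel_p=0.005, extent=31)
        assert len(table) == 0

    def test_no_suprathreshold_voxels_is_empty_not_error(self):
        table = G.cluster_threshold(np.zeros((5, 5, 5)), df=10)
        assert len(table) == 0

    def test_labeling_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            vol = rng.random((10, 10, 10)) < 0.25
            ours, n_ours = G._connected_clusters(vol)
            ref, n_ref = flood_fill_components(vol)
            assert n_ours == n_ref
            ours_sizes = sorted(np.bincount(ours.ravel())[1:])
            ref_sizes = sorted(np.bincount(ref.ravel())[1:])
            assert ours_sizes == ref_sizes

    def test_auto_extent_uses_permutation_estimate(self, rng):
        diffs = rng.standard_normal((8, 6, 6, 6))
        t = G.paired_t_map(diffs)
        table = G.cluster_threshold(t, df=7, extent="auto", subject_diffs=diffs,
                                    n_permutations=50, seed=1)
        assert table.extent_k >= 1


class TestAtlasOverlap:
    def test_cluster_inside_mask(self):
        cluster = np.zeros((6, 6, 6), bool)
        cluster[2:4, 2:4, 2:4] = True
        count, frac = G.atlas_overlap(cluster, np.ones((6, 6, 6), bool))
        assert (count, frac) == (8, 1.0)

    def test_disjoint_gives_zero(self):
        cluster = np.zeros((6, 6, 6), bool)
        cluster[0, 0, 0] = True
        mask = np.zeros((6, 6, 6), bool)
        mask[5, 5, 5] = True
        assert G.atlas_overlap(cluster, mask) == (0, 0.0)

    def test_half_in_half_out(self):
        cluster = np.zeros((10, 4, 4), bool)
        cluster[0:10, 0, 0] = True
        mask = np.zeros((10, 4, 4), bool)
        mask[0:5, :, :] = True
        count, frac = G.atlas_overlap(cluster, mask)
        assert (count, frac) == (5, 0.5)

    def test_nearest_resampling_identity_affines(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:5, 2:5, 2:5] = True
        out = G.resample_mask_nearest(mask, np.eye(4), (8, 8, 8), np.eye(4))
        assert np.array_equal(out, mask)

    def test_resampling_respects_scaling_affine(self):
        # atlas at 1 mm, target at 2 mm: voxel (i) maps to atlas voxel (2i)
        mask = np.zeros((8, 8, 8), bool)
        mask[0:4, 0:4, 0:4] = True
        target_aff = np.diag([2.0, 2.0, 2.0, 1.0])
        out = G.resample_mask_nearest(mask, np.eye(4), (4, 4, 4), target_aff)
        assert out[0, 0, 0] and out[1, 1, 1] and not out[2, 2, 2]


class TestSmoothing:
    def test_fwhm_to_sigma_value(self):
        assert G.fwhm_to_sigma(4.0) == pytest.approx(1.699, abs=0.001)

    def test_constant_image_unchanged(self):
        bold = BoldImage(np.full((6, 6, 6, 4), 3.0),
                         np.diag([1.4, 1.4, 1.4, 1.0]), 2.04)
        out = G.gaussian_smooth(bold, 4.0)
        assert np.allclose(out.data, 3.0)

    def test_delta_kernel_mass_is_one(self):
        img = np.zeros((21, 21, 21))
        img[10, 10, 10] = 1.0
        out = G.gaussian_smooth(img, 4.0, voxel_sizes_mm=np.array([1.4] * 3))
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_missing_voxel_sizes_rejected(self):
        with pytest.raises(ValueError):
            G.gaussian_smooth(np.zeros((4, 4, 4)), 4.0)
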