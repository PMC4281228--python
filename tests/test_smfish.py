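"""smFISH detection, scoring, threshold equalization, and spot assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

import colonymap as cm
from colonymap.grid import GridSpec
from colonymap.images import LabelMatrix
from colonymap.smfish import _margin_stats, initial_threshold
from colonymap.synthetic import SmfishParams, _stamp_gaussian3d, generate_smfish_stack

PX = 0.13


def psf_stack(amps_positions, shape=(11, 64, 64), background=10.0):
    vol = np.zeros(shape)
    for amp, (z, y, x) in amps_positions:
        _stamp_gaussian3d(vol, z, y, x, amp, 1.6, 1.3)
    return vol + background


class TestPreprocess:
    def test_constant_background_maps_to_zero(self):
        out = cm.preprocess_stack(np.full((5, 40, 40), 17.0), 3, 1.3)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_single_psf_peak_within_one_px(self):
        vol = psf_stack([(50, (5.3, 20.6, 30.2))])
        out = cm.preprocess_stack(vol, 3, 1.3)
        z, y, x = np.unravel_index(np.argmax(out), out.shape)
        assert abs(z - 5.3) <= 1 and abs(y - 20.6) <= 1 and abs(x - 30.2) <= 1

    def test_smooth_gradient_does_not_shift_peak(self):
        vol_flat = psf_stack([(50, (5.3, 20.6, 30.2))])
        ramp = np.linspace(0, 30, 64)[None, None, :] * np.ones((11, 64, 1))
        vol_grad = vol_flat + ramp
        p1 = np.unravel_index(np.argmax(cm.preprocess_stack(vol_flat, 3, 1.3)), vol_flat.shape)
        p2 = np.unravel_index(np.argmax(cm.preprocess_stack(vol_grad, 3, 1.3)), vol_grad.shape)
        assert p1 == p2

    def test_small_opening_radius_warns(self):
        with pytest.warns(UserWarning, match="erase"):
            cm.preprocess_stack(np.zeros((3, 16, 16)), 1, 1.3)

    def test_too_few_planes_rejected(self):
        with pytest.raises(ValueError):
            cm.preprocess_stack(np.zeros((2, 16, 16)), 3, 1.3)


class TestDetect:
    def test_zero_stack_empty(self):
        out = cm.detect_candidates(np.zeros((5, 32, 32)), np.zeros((5, 32, 32)))
        assert out.empty

    def test_planted_spots_top_ranked(self):
        grid = GridSpec(1, 1, 150, 150, 0)
        p = SmfishParams(n_spots=50, amplitude=40, amplitude_sigma_log=0.0,
                         background_in_colony=25, background_outside=25,
                         min_spot_separation_px=8.0)
        fields, truth = generate_smfish_stack(p, grid, seed=8)
        stack = fields[0].channel("fish")
        filt = cm.preprocess_stack(stack, 3, 1.3)
        cands = cm.detect_candidates(filt, stack)
        assert len(cands) >= 50
        top = cands.nlargest(50, "statistic")
        d, _ = cKDTree(top[["z_px", "y_px", "x_px"]].to_numpy()).query(
            truth[["z_px", "y_px", "x_px"]].to_numpy()
        )
        assert (d <= 1.8).all()  # within 1 px per axis of every truth spot

    def test_two_close_spots_distinct(self):
        vol = psf_stack([(50, (5, 30, 25)), (50, (5, 30, 35))])  # 10 px apart
        filt = cm.preprocess_stack(vol, 3, 1.3)
        cands = cm.detect_candidates(filt, vol)
        top = cands.nlargest(2, "statistic")
        xs = sorted(top.x_px)
        assert abs(xs[0] - 25) <= 1 and abs(xs[1] - 35) <= 1


class TestStatistic:
    def test_quadratic_scaling_with_amplitude(self):
        def stat(amp):
            vol = psf_stack([(amp, (5.2, 30.4, 30.6))])
            filt = cm.preprocess_stack(vol, 3, 1.3)
            pos = np.unravel_index(np.argmax(filt), filt.shape)
            return cm.spot_statistic(vol, filt, pos)

        assert stat(100) / stat(50) == pytest.approx(4.0, rel=0.10)

    def test_sharp_psf_beats_broad_blob(self):
        vol_sharp = psf_stack([(50, (5, 30, 30))])
        vol_broad = np.full((11, 64, 64), 10.0)
        _stamp_gaussian3d(vol_broad, 5, 30, 30, 50, 3.2, 3.9)  # 3x wider
        s_sharp = cm.spot_statistic(
            vol_sharp, cm.preprocess_stack(vol_sharp, 5, 1.3), (5, 30, 30)
        )
        s_broad = cm.spot_statistic(
            vol_broad, cm.preprocess_stack(vol_broad, 5, 1.3), (5, 30, 30)
        )
        assert s_sharp > s_broad

    def test_noise_and_spots_separable_by_single_threshold(self):
        # ROC of the statistic at SNR ~6: planted spots vs noise candidates
        grid = GridSpec(1, 1, 150, 150, 0)
        p = SmfishParams(n_spots=40, amplitude=32, amplitude_sigma_log=0.0,
                         background_in_colony=25, background_outside=25,
                         min_spot_separation_px=8.0)
        fields, truth = generate_smfish_stack(p, grid, seed=12)
        stack = fields[0].channel("fish")
        cands = cm.detect_candidates(cm.preprocess_stack(stack, 3, 1.3), stack)
        d, _ = cKDTree(truth[["z_px", "y_px", "x_px"]].to_numpy()).query(
            cands[["z_px", "y_px", "x_px"]].to_numpy()
        )
        is_spot = d <= 1.8
        assert is_spot.sum() >= 38
        from sklearn.metrics import roc_auc_score

        auc = roc_auc_score(is_spot, cands.statistic)
        assert auc >= 0.99

    def test_non_maximum_position_rejected(self):
        vol = psf_stack([(50, (5, 30, 30))])
        filt = cm.preprocess_stack(vol, 3, 1.3)
        with pytest.raises(ValueError, match="maximum"):
            cm.spot_statistic(vol, filt, (5, 27, 30))  # on the spot's flank


class TestMarginCounts:
    @staticmethod
    def _cands(rows):
        return pd.DataFrame(rows, columns=["z_px", "y_px", "x_px", "statistic",
                                           "intensity", "field_x", "field_y"])

    def test_zero_threshold_counts_all(self):
        grid = GridSpec(2, 1, 100, 100, 20)
        c = self._cands([(5, 10, 5, 3.0, 1, 0, 0), (5, 50, 95, 2.0, 1, 0, 0)])
        f = cm.margin_counts(c, grid, 0.0)
        assert f == dict(top=1, bottom=0, left=1, right=1)

    def test_infinite_threshold_counts_zero(self):
        grid = GridSpec(2, 1, 100, 100, 20)
        c = self._cands([(5, 10, 5, 3.0, 1, 0, 0)])
        f = cm.margin_counts(c, grid, np.inf)
        assert all(v == 0 for v in f.values())

    def test_hand_placed_right_margin(self):
        grid = GridSpec(2, 1, 100, 100, 20)
        rows = [(5, 30, 85, s, 1, 0, 0) for s in (1.0, 2.0, 3.0)]
        f = cm.margin_counts(self._cands(rows), grid, 0.5)
        assert f["right"] == 3

    def test_zero_overlap_rejected(self):
        grid = GridSpec(2, 1, 100, 100, 0)
        with pytest.raises(ValueError):
            cm.margin_counts(self._cands([]), grid, 1.0)


class TestEqualization:
    def test_identical_fields_constant_s_optimal(self):
        grid = GridSpec(2, 1, 160, 160, 40)
        p = SmfishParams(n_spots=80, shot_noise=False, read_noise_sd=0.0,
                         background_in_colony=20, background_outside=20)
        fields, _ = generate_smfish_stack(p, grid, seed=3)
        cands = pd.concat(
            [cm.detect_candidates(cm.preprocess_stack(f.channel("fish"), 3, 1.3),
                                  f.channel("fish"), field_x=f.field_x,
                                  field_y=f.field_y) for f in fields],
            ignore_index=True,
        )
        tm = cm.equalize_thresholds(cands, grid)
        # noiseless identical margins: the initial constant S is already exact
        assert tm.objective == 0.0

    def test_gain_mismatch_resolved_to_brute_force_optimum(self):
        grid = GridSpec(2, 1, 160, 160, 40)
        p = SmfishParams(n_spots=120, amplitude=50, amplitude_sigma_log=0.35,
                         background_in_colony=20, background_outside=20)
        fe = cm.FieldEffects(gain=np.array([[1.0, 0.5]]))
        fields, _ = generate_smfish_stack(p, grid, seed=5, field_effects=fe)
        cands = pd.concat(
            [cm.detect_candidates(cm.preprocess_stack(f.channel("fish"), 3, 1.3),
                                  f.channel("fish"), field_x=f.field_x,
                                  field_y=f.field_y) for f in fields],
            ignore_index=True,
        )
        tm = cm.equalize_thresholds(cands, grid, norm=2)
        assert tm.s[0, 1] < tm.s[0, 0]  # dimmer field gets the lower threshold
        assert tm.objective == 0.0
        # exhaustive search over both fields' breakpoint grids
        pf = {
            (fx, fy): _margin_stats(
                cands[(cands.field_x == fx) & (cands.field_y == fy)], grid
            )
            for fx, fy in grid.iter_fields()
        }
        best = np.inf
        for sa in _breakpoints(pf[(0, 0)], tm.s0):
            for sb in _breakpoints(pf[(1, 0)], tm.s0):
                e = cm.margin_error(pf, grid, np.array([[sa, sb]]), 2)
                best = min(best, e)
        assert tm.objective == best

    def test_descent_never_worse_than_initial(self):
        rng = np.random.default_rng(0)
        grid = GridSpec(3, 2, 120, 120, 30)
        rows = []
        for fx, fy in grid.iter_fields():
            n = rng.integers(30, 60)
            rows.append(pd.DataFrame(dict(
                z_px=rng.integers(1, 8, n), y_px=rng.integers(0, 120, n),
                x_px=rng.integers(0, 120, n),
                statistic=rng.lognormal(1 + 0.3 * fx, 1.0, n),
                intensity=1.0, field_x=fx, field_y=fy,
            )))
        cands = pd.concat(rows, ignore_index=True)
        for norm in (1, 2):
            tm = cm.equalize_thresholds(cands, grid, norm=norm)
            assert tm.objective <= tm.objective_initial

    def test_margin_count_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        grid = GridSpec(2, 1, 100, 100, 20)
        c = pd.DataFrame(dict(
            z_px=0, y_px=rng.integers(0, 100, 200), x_px=rng.integers(0, 100, 200),
            statistic=rng.lognormal(0, 1, 200), intensity=1.0, field_x=0, field_y=0,
        ))
        prev = None
        for s in np.linspace(0, 10, 25):
            f = cm.margin_counts(c, grid, s)
            if prev is not None:
                assert all(f[k] <= prev[k] for k in f)
            prev = f

    def test_no_candidates_rejected(self):
        grid = GridSpec(2, 1, 100, 100, 20)
        empty = pd.DataFrame(columns=["z_px", "y_px", "x_px", "statistic",
                                      "intensity", "field_x", "field_y"])
        with pytest.raises(ValueError):
            cm.equalize_thresholds(empty, grid)


def _breakpoints(margins, s0):
    vals = np.unique(np.concatenate([margins[k] for k in margins]))
    hi = (vals.max() if vals.size else s0) * 1.001 + 1.0
    return np.unique(np.concatenate([vals, [s0, hi]]))


class TestColonyMask:
    def test_mask_recovers_colony_iou(self):
        scene = cm.generate_colony_scene(
            cm.SceneParams(n_colonies=1, cells_per_colony=30, scene_width_um=60,
                           scene_height_um=60, colony_radius_um=20,
                           pixel_size_um=PX, cell_diameter_um=6.0,
                           periphery_fraction=0.0),
            seed=2,
        )
        h, w = scene.shape_px
        grid = GridSpec(1, 1, w, h, 0)
        p = SmfishParams(spots_per_cell=10, background_in_colony=40,
                         background_outside=5)
        fields, _ = generate_smfish_stack(p, grid, seed=2, scene=scene)
        mask = cm.colony_mask_from_background(fields[0].channel("fish"))
        truth = scene.colony_mask > 0
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.8

    def test_blank_stack_empty_mask(self):
        assert not cm.colony_mask_from_background(np.zeros((5, 40, 40))).any()

    def test_mask_stable_under_added_spots(self):
        scene = cm.generate_colony_scene(
            cm.SceneParams(n_colonies=1, cells_per_colony=30, scene_width_um=60,
                           scene_height_um=60, colony_radius_um=20,
                           pixel_size_um=PX, cell_diameter_um=6.0,
                           periphery_fraction=0.0),
            seed=2,
        )
        h, w = scene.shape_px
        grid = GridSpec(1, 1, w, h, 0)
        base = SmfishParams(spots_per_cell=0, background_in_colony=40,
                            background_outside=5, shot_noise=False,
                            read_noise_sd=0.0)
        spotty = SmfishParams(spots_per_cell=10, background_in_colony=40,
                              background_outside=5, shot_noise=False,
                              read_noise_sd=0.0)
        f0, _ = generate_smfish_stack(base, grid, seed=2, scene=scene)
        f1, _ = generate_smfish_stack(spotty, grid, seed=2, scene=scene)
        m0 = cm.colony_mask_from_background(f0[0].channel("fish"))
        m1 = cm.colony_mask_from_background(f1[0].channel("fish"))
        assert (m0 != m1).mean() < 0.01


class TestAssignment:
    def test_single_nucleus_gets_all_spots(self):
        lab = np.zeros((60, 60), np.int32)
        lab[28:33, 28:33] = 1
        mask = np.zeros((60, 60), bool)
        mask[10:50, 10:50] = True
        rng = np.random.default_rng(0)
        spots = pd.DataFrame(dict(
            z_px=0.0, y_px=rng.uniform(12, 48, 10), x_px=rng.uniform(12, 48, 10),
            statistic=1.0,
        ))
        assigned, _ = cm.assign_spots_to_cells(spots, LabelMatrix(lab, PX), mask)
        assert (assigned.cell_id == 1).all()
        assert cm.per_cell_counts(assigned).loc[1] == 10

    def test_midway_spot_ties_to_lower_label(self):
        lab = np.zeros((40, 80), np.int32)
        lab[18:23, 18:23] = 1
        lab[18:23, 58:63] = 2
        mask = np.ones((40, 80), bool)
        spots = pd.DataFrame(dict(z_px=[0.0], y_px=[20.0], x_px=[40.0], statistic=[1.0]))
        assigned, _ = cm.assign_spots_to_cells(spots, LabelMatrix(lab, PX), mask)
        assert assigned.cell_id.iloc[0] == 1

    def test_spot_outside_mask_unassigned(self):
        lab = np.zeros((40, 40), np.int32)
        lab[18:23, 18:23] = 1
        mask = np.zeros((40, 40), bool)
        mask[10:30, 10:30] = True
        spots = pd.DataFrame(dict(z_px=[0.0], y_px=[2.0], x_px=[2.0], statistic=[1.0]))
        assigned, _ = cm.assign_spots_to_cells(spots, LabelMatrix(lab, PX), mask)
        assert assigned.cell_id.iloc[0] == 0

    def test_interior_spot_counts_match_truth(self):
        # planted spots around nuclei: counts recovered for interior spots
        rng = np.random.default_rng(3)
        lab = np.zeros((120, 120), np.int32)
        centers = [(30, 30), (30, 90), (90, 30), (90, 90)]
        for i, (cy, cx) in enumerate(centers, 1):
            lab[cy - 4 : cy + 5, cx - 4 : cx + 5] = i
        mask = np.ones((120, 120), bool)
        rows = []
        truth_counts = {}
        for i, (cy, cx) in enumerate(centers, 1):
            k = rng.poisson(40)
            truth_counts[i] = k
            for _ in range(k):
                rows.append(dict(
                    z_px=0.0, y_px=cy + rng.uniform(-12, 12),
                    x_px=cx + rng.uniform(-12, 12), statistic=1.0,
                ))
        spots = pd.DataFrame(rows)
        assigned, _ = cm.assign_spots_to_cells(spots, LabelMatrix(lab, PX), mask)
        counts = cm.per_cell_counts(assigned)
        for i in truth_counts:
            assert counts.loc[i] == truth_counts[i]


class TestMatchAcrossFields:
    def test_margin_duplicate_merged(self):
        grid = GridSpec(2, 1, 100, 100, 20)
        spots = pd.DataFrame(dict(
            z_px=[4.0, 4.0], y_px=[50.0, 50.2], x_px=[90.0, 10.3],
            statistic=[5.0, 4.0], intensity=[1, 1],
            field_x=[0, 1], field_y=[0, 0],
        ))
        out = cm.match_spots_across_fields(spots, grid, radius_px=2.0)
        assert len(out) == 1
        assert out.statistic.iloc[0] == 5.0  # higher-statistic instance kept

    def test_distant_spots_not_merged(self):
        grid = GridSpec(2, 1, 100, 100, 20)
        spots = pd.DataFrame(dict(
            z_px=[4.0, 4.0], y_px=[50.0, 60.0], x_px=[90.0, 10.0],
            statistic=[5.0, 4.0], intensity=[1, 1],
            field_x=[0, 1], field_y=[0, 0],
        ))
        out = cm.match_spots_across_fields(spots, grid, radius_px=2.0)
        assert len(out) == 2

    def test_global_count_recovered_on_grid(self):
        grid = GridSpec(2, 2, 130, 130, 40)
        p = SmfishParams(n_spots=150, amplitude=45, amplitude_sigma_log=0.1,
                         background_in_colony=25, background_outside=25,
                         min_spot_separation_px=6.0)
        fields, truth = generate_smfish_stack(p, grid, seed=6)
        cands = pd.concat(
            [cm.detect_candidates(cm.preprocess_stack(f.channel("fish"), 3, 1.3),
                                  f.channel("fish"), field_x=f.field_x,
                                  field_y=f.field_y) for f in fields],
            ignore_index=True,
        )
        tm = cm.equalize_thresholds(cands, grid)
        out = cm.match_spots_across_fields(cands, grid, radius_px=2.0, thresholds=tm)
        n_true = truth.id.nunique()
        assert abs(len(out) - n_true) <= 0.05 * n_true
        # no duplicates: kept spots pairwise farther than the merge radius
        pts = out[["region_y_px", "region_x_px"]].to_numpy()
        d, _ = cKDTree(pts).query(pts, k=2)
        assert (d[:, 1] > 2.0).all()
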