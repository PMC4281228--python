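"""Colony/nucleus segmentation and feature extraction against closed forms."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

import colonymap as cm
from colonymap.images import FieldImage, LabelMatrix
from colonymap.segmentation import NucleiParams
from colonymap.synthetic import SceneParams
from conftest import grid_covering

PX = 0.65


def _disc(shape, cy, cx, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestSegmentColonies:
    def test_two_blobs_recovered_with_high_iou(self):
        scene = cm.generate_colony_scene(
            SceneParams(n_colonies=2, cells_per_colony=120, scene_width_um=620,
                        scene_height_um=320, colony_radius_um=85.0,
                        periphery_fraction=0.0),
            seed=2,
        )
        grid = grid_covering(scene, 1, 1, 0)
        fields = cm.render_fields(scene, grid, noise=False)
        labels = cm.segment_colonies(fields[0].channel("dna"), PX)
        assert labels.n_objects == 2
        h, w = scene.shape_px
        seg = labels.data[:h, :w]
        for cid in (1, 2):
            truth = scene.colony_mask == cid
            best = max(
                _iou(seg == l, truth) for l in labels.labels
            )
            assert best >= 0.75  # blurred boundary; bulk overlap required

    def test_uniform_image_zero_colonies(self):
        labels = cm.segment_colonies(np.full((100, 100), 7.0), PX)
        assert labels.n_objects == 0

    def test_min_area_filter(self):
        img = np.zeros((200, 200))
        img[_disc(img.shape, 60, 60, 40)] = 100.0   # big blob
        img[_disc(img.shape, 160, 160, 5)] = 100.0  # speck
        labels = cm.segment_colonies(img, PX, sigma_px=2.0, min_area_um2=500.0)
        assert labels.n_objects == 1


def _iou(a, b):
    return (a & b).sum() / max((a | b).sum(), 1)


class TestSegmentNuclei:
    def test_isolated_nuclei_recovered(self):
        # well-separated synthetic nuclei: count and centroid accuracy
        scene = cm.generate_colony_scene(
            SceneParams(n_colonies=1, cells_per_colony=20, scene_width_um=260,
                        scene_height_um=260, min_separation_frac=1.6,
                        periphery_fraction=0.0),
            seed=3,
        )
        grid = grid_covering(scene, 1, 1, 0)
        f = cm.render_fields(scene, grid, noise=False)[0]
        labels = cm.segment_nuclei(f)
        assert labels.n_objects == 20
        cents = np.array(
            ndimage.center_of_mass(labels.data > 0, labels.data, labels.labels)
        ) * PX
        truth = scene.cells[["y_um", "x_um"]].to_numpy()
        d, _ = cKDTree(cents).query(truth)
        assert (d <= 1.0 * PX + 1e-6).all()  # centroid error <= 1 px

    def test_touching_pair_split_by_watershed(self):
        # two nuclei overlapping by ~20% of a diameter are split in two
        f = _two_nuclei_field(overlap_frac=0.2)
        labels = cm.segment_nuclei(f)
        assert labels.n_objects == 2

    def test_empty_field_zero_labels(self):
        f = FieldImage({"dna": np.zeros((64, 64))}, 0, 0, PX)
        assert cm.segment_nuclei(f).n_objects == 0

    def test_recall_precision_on_sparse_fields(self):
        # matched by centroid <= 3 um at low-to-moderate packing
        scene = cm.generate_colony_scene(
            SceneParams(n_colonies=2, cells_per_colony=60, scene_width_um=450,
                        scene_height_um=450, min_separation_frac=1.3),
            seed=11,
        )
        grid = grid_covering(scene, 1, 1, 0)
        f = cm.render_fields(scene, grid)[0]
        labels = cm.segment_nuclei(f)
        cents = np.array(
            ndimage.center_of_mass(labels.data > 0, labels.data, labels.labels)
        ) * PX
        truth = scene.cells[["y_um", "x_um"]].to_numpy()
        d_t, _ = cKDTree(cents).query(truth)
        d_m, _ = cKDTree(truth).query(cents)
        assert (d_t <= 3.0).mean() >= 0.95  # recall
        assert (d_m <= 3.0).mean() >= 0.95  # precision


def _two_nuclei_field(overlap_frac: float) -> FieldImage:
    d_um = 12.0
    sep_um = d_um * (1 - overlap_frac)
    img = np.zeros((96, 96))
    sig = d_um / PX / 4
    for cx_um in (25.0, 25.0 + sep_um):
        cy, cx = 30.0 / PX, cx_um / PX
        yy, xx = np.mgrid[0:96, 0:96]
        q = ((yy - cy) / sig) ** 2 + ((xx - cx) / sig) ** 2
        g = 100 * np.exp(-0.5 * q)
        g[q > 4] = 0
        img += g
    return FieldImage({"dna": img}, 0, 0, PX)


class TestExtractFeatures:
    def test_uniform_disc_closed_form(self):
        lab = np.zeros((64, 64), np.int32)
        lab[_disc(lab.shape, 32, 32, 10)] = 1
        chan = {"dna": np.where(lab > 0, 5.0, 0.0)}
        (rec,) = cm.extract_features(LabelMatrix(lab, PX), chan)
        area_px = lab.sum()
        assert rec.area_px == area_px
        assert rec.area_um2 == pytest.approx(np.pi * 100 * PX**2, rel=0.05)
        assert rec.mean["dna"] == pytest.approx(5.0)
        assert rec.integrated["dna"] == pytest.approx(5.0 * area_px)
        assert rec.eccentricity < 0.15
        assert rec.perimeter_um == pytest.approx(2 * np.pi * 10 * PX, rel=0.05)

    def test_intensity_linearity_shape_invariance(self):
        lab = np.zeros((64, 64), np.int32)
        lab[_disc(lab.shape, 32, 32, 8)] = 1
        rng = np.random.default_rng(0)
        img = rng.uniform(1, 10, lab.shape)
        (r1,) = cm.extract_features(LabelMatrix(lab, PX), {"c": img})
        (r2,) = cm.extract_features(LabelMatrix(lab, PX), {"c": 2 * img})
        assert r2.integrated["c"] == pytest.approx(2 * r1.integrated["c"])
        assert r2.mean["c"] == pytest.approx(2 * r1.mean["c"])
        assert r2.area_um2 == r1.area_um2
        assert r2.eccentricity == r1.eccentricity

    def test_ellipse_eccentricity(self):
        # 2:1 axis ratio -> e = sqrt(1 - 1/4) ~ 0.866
        lab = np.zeros((120, 120), np.int32)
        yy, xx = np.mgrid[0:120, 0:120]
        lab[((yy - 60) / 20) ** 2 + ((xx - 60) / 40) ** 2 <= 1] = 1
        (rec,) = cm.extract_features(LabelMatrix(lab, PX), {})
        assert rec.eccentricity == pytest.approx(0.866, abs=0.01)

    def test_shape_mismatch_rejected(self):
        lab = LabelMatrix(np.zeros((10, 10), np.int32), PX)
        with pytest.raises(ValueError, match="shape"):
            cm.extract_features(lab, {"c": np.zeros((5, 5))})


class TestColonyFeatures:
    def test_disc_max_edge_distance(self):
        r_um = 50.0
        r_px = r_um / PX
        n = int(2 * r_px + 20)
        lab = np.zeros((n, n), np.int32)
        lab[_disc(lab.shape, n // 2, n // 2, r_px)] = 1
        (rec,) = cm.colony_features(LabelMatrix(lab, PX))
        assert rec.max_edge_distance_um == pytest.approx(r_um, rel=0.03)

    def test_annulus_max_edge_distance_is_half_ring_width(self):
        n, r_out, r_in = 200, 80, 40
        lab = np.zeros((n, n), np.int32)
        lab[_disc(lab.shape, 100, 100, r_out) & ~_disc(lab.shape, 100, 100, r_in)] = 1
        (rec,) = cm.colony_features(LabelMatrix(lab, PX))
        # brute-force oracle: max over mask pixels of min distance to background
        ys, xs = np.nonzero(lab)
        bg = np.column_stack(np.nonzero(lab == 0))
        d, _ = cKDTree(bg).query(np.column_stack([ys, xs]))
        assert rec.max_edge_distance_um == pytest.approx(d.max() * PX, abs=PX)
        assert rec.max_edge_distance_um == pytest.approx((r_out - r_in) / 2 * PX, rel=0.1)

    def test_two_colonies_two_records(self):
        lab = np.zeros((100, 100), np.int32)
        lab[_disc(lab.shape, 25, 25, 10)] = 1
        lab[_disc(lab.shape, 75, 75, 12)] = 2
        recs = cm.colony_features(LabelMatrix(lab, PX))
        assert [r.colony_id for r in recs] == [1, 2]

    def test_max_edge_distance_bounded_by_bbox(self):
        rng = np.random.default_rng(4)
        blob = ndimage.gaussian_filter(rng.standard_normal((150, 150)), 12) > 0.02
        lab, _ = ndimage.label(blob)
        for rec in cm.colony_features(LabelMatrix(lab.astype(np.int32), PX)):
            mask = lab == rec.colony_id
            ys, xs = np.nonzero(mask)
            side = min(ys.max() - ys.min() + 1, xs.max() - xs.min() + 1)
            assert rec.max_edge_distance_um <= (side / 2 + 1) * PX


class TestScaleEquivariance:
    def test_doubling_pixel_size_doubles_lengths_quadruples_areas(self):
        lab = np.zeros((64, 64), np.int32)
        lab[_disc(lab.shape, 32, 32, 10)] = 1
        (r1,) = cm.extract_features(LabelMatrix(lab, PX), {})
        (r2,) = cm.extract_features(LabelMatrix(lab, 2 * PX), {})
        assert r2.perimeter_um == pytest.approx(2 * r1.perimeter_um)
        assert r2.area_um2 == pytest.approx(4 * r1.area_um2)
        assert r2.area_px == r1.area_px


class TestDensityLinearity:
    def test_integrated_dna_tracks_cell_count_in_windows(self):
        # windowed integrated DNA intensity vs segmented count: near-linear
        scene = cm.generate_colony_scene(
            SceneParams(n_colonies=2, cells_per_colony=150, scene_width_um=500,
                        scene_height_um=500), seed=6,
        )
        grid = grid_covering(scene, 1, 1, 0)
        f = cm.render_fields(scene, grid, noise=False)[0]
        labels = cm.segment_nuclei(f)
        img = f.channel("dna")
        w = 100
        counts, sums = [], []
        for y0 in range(0, img.shape[0] - w, w):
            for x0 in range(0, img.shape[1] - w, w):
                win = labels.data[y0 : y0 + w, x0 : x0 + w]
                counts.append(len(np.unique(win[win > 0])))
                sums.append(img[y0 : y0 + w, x0 : x0 + w].sum())
        counts, sums = np.array(counts), np.array(sums)
        assert counts.max() >= 10  # wide density range sampled
        r = np.corrcoef(counts, sums)[0, 1]
        assert r >= 0.9
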