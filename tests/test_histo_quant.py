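"""Tests for puncta/synapse contact metrics, soma coverage and membrane ribbons."""

import numpy as np
import pytest
from scipy import ndimage

from sliceglia.histo_quant import (
    detect_puncta,
    identify_synapses,
    membrane_intensity,
    microglia_contact,
    segment_microglia,
    soma_metrics,
    synaptic_density,
    systematic_random_subset,
)
from sliceglia.simulate import simulate_puncta_scene


def _disk_image(centers, radius=3, shape=(128, 128), amplitude=200.0, background=10.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, background)
    for r0, c0 in centers:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = amplitude
    return img


class TestDetectPuncta:
    def test_blank_image_yields_no_puncta(self):
        labels, centroids = detect_puncta(np.full((64, 64), 7.0))
        assert labels.max() == 0
        assert centroids == []

    def test_scene_puncta_all_detected(self):
        scene, truth = simulate_puncta_scene(
            n_synapses=0, n_orphan_pre=30, seed=0, shape=(512, 512)
        )
        labels, centroids = detect_puncta(scene.pre_channel)
        assert len(centroids) == 30

    def test_interior_hole_filled_into_single_component(self):
        img = _disk_image([(30, 30)], radius=8)
        img[30, 30] = 10.0  # punch a hole
        labels, centroids = detect_puncta(img)
        assert len(centroids) == 1
        # the filled, eroded punctum must still cover the hole position
        assert labels[30, 30] == 1


class TestSynapseRule:
    def _labels(self, gap):
        """Two 1-px-wide bars, ``gap`` empty pixel columns apart."""
        pre = np.zeros((20, 40), dtype=int)
        post = np.zeros((20, 40), dtype=int)
        pre[8:12, 8:12] = 1
        post[8:12, 12 + gap : 16 + gap] = 1
        return pre, post

    def test_overlapping_masks_form_a_synapse(self):
        pre, post = self._labels(gap=-1)  # one column of overlap
        assert len(identify_synapses(pre, post)) == 1

    def test_adjacent_masks_form_a_synapse(self):
        pre, post = self._labels(gap=0)
        assert len(identify_synapses(pre, post)) == 1

    def test_masks_three_pixels_apart_do_not(self):
        pre, post = self._labels(gap=3)
        assert identify_synapses(pre, post) == []


class TestContactRule:
    def _scene(self, gap_px):
        """A synapse pair and a microglia block whose nearest pixel centre is
        ``gap_px`` pixels from the synapse."""
        pre = np.zeros((40, 60), dtype=int)
        post = np.zeros((40, 60), dtype=int)
        pre[18:22, 10:14] = 1
        post[18:22, 14:18] = 1
        mg = np.zeros((40, 60), dtype=bool)
        mg[18:22, 17 + gap_px : 24 + gap_px] = True
        return pre, post, mg

    @pytest.mark.parametrize("gap_px,expected", [(3, True), (5, False)])
    def test_200nm_rule_exact_at_50nm_pixels(self, gap_px, expected):
        pre, post, mg = self._scene(gap_px)
        records = identify_synapses(pre, post)
        records = microglia_contact(records, pre, post, mg, pixel_size=50.0)
        assert records[0].contacted_by_microglia is expected
        assert records[0].min_dist_px == pytest.approx(gap_px)

    def test_missing_pixel_size_rejected(self):
        pre, post, mg = self._scene(3)
        records = identify_synapses(pre, post)
        with pytest.raises(ValueError, match="pixel_size"):
            microglia_contact(records, pre, post, mg)

    def test_pipeline_recovers_truth_on_simulated_scenes(self):
        tp = fp = fn = contact_ok = 0
        for seed in range(4):
            scene, truth = simulate_puncta_scene(
                n_synapses=20, n_orphan_pre=5, n_orphan_post=5,
                microglia_geometry=[(60, 60, 18), (180, 180, 18), (60, 180, 18)],
                seed=seed,
            )
            pre_l, _ = detect_puncta(scene.pre_channel)
            post_l, _ = detect_puncta(scene.post_channel)
            mg = segment_microglia(scene.microglia_channel)
            records = identify_synapses(pre_l, post_l)
            records = microglia_contact(records, pre_l, post_l, mg, pixel_size=50.0)
            matched = set()
            for rec in records:
                mid = (
                    (rec.pre_centroid[0] + rec.post_centroid[0]) / 2,
                    (rec.pre_centroid[1] + rec.post_centroid[1]) / 2,
                )
                d2 = (truth.events.row - mid[0]) ** 2 + (truth.events.col - mid[1]) ** 2
                if d2.min() < 9.0:
                    tp += 1
                    matched.add(d2.idxmin())
                    if rec.contacted_by_microglia == truth.events.contacted[d2.idxmin()]:
                        contact_ok += 1
                else:
                    fp += 1
            fn += truth.n - len(matched)
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        assert precision >= 0.9
        assert recall >= 0.9
        assert contact_ok / tp >= 0.9


class TestSystematicRandomSubset:
    def test_requesting_all_items_returns_all(self):
        items = list(range(17))
        assert systematic_random_subset(items, 17, seed=0) == items

    def test_constant_stride_from_seeded_start(self):
        items = list(range(100))
        subset = systematic_random_subset(items, 10, seed=1)
        strides = np.diff(subset)
        assert len(subset) == 10
        np.testing.assert_array_equal(strides, 10)

    def test_same_seed_same_subset(self):
        items = list(range(57))
        assert systematic_random_subset(items, 8, seed=5) == systematic_random_subset(
            items, 8, seed=5
        )

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            systematic_random_subset([1, 2, 3], 4)


class TestSynapticDensity:
    def test_zero_image_gives_zero(self):
        out = synaptic_density(np.zeros((20, 20)), [(0, 0, 10, 10)])
        assert out[0]["integrated_density"] == 0.0

    def test_uniform_intensity_times_area(self):
        out = synaptic_density(np.full((20, 20), 3.0), [(2, 2, 5, 4)])
        assert out[0]["integrated_density"] == pytest.approx(3.0 * 20)
        assert out[0]["density_per_px"] == pytest.approx(3.0)

    def test_doubling_roi_doubles_integrated_density(self):
        img = np.full((30, 30), 2.5)
        small, large = synaptic_density(img, [(0, 0, 10, 10), (0, 0, 10, 20)])
        assert large["integrated_density"] == pytest.approx(
            2 * small["integrated_density"]
        )

    def test_out_of_bounds_roi_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            synaptic_density(np.zeros((10, 10)), [(5, 5, 10, 10)])


def _square_outline(r0, c0, side):
    pts = [
        (r0, c0), (r0, c0 + side), (r0 + side, c0 + side), (r0 + side, c0), (r0, c0),
    ]
    return np.array(pts, dtype=float)


class TestSomaMetrics:
    PIXEL_UM = 0.1  # 100 nm pixels

    def test_no_microglia_means_zero_coverage(self):
        outline = _square_outline(10, 10, 20)
        record = soma_metrics(
            [outline], [np.zeros((50, 50), dtype=bool)],
            pixel_size_um=self.PIXEL_UM, section_thickness=0.3,
        )
        assert record.coverage_percent == 0.0
        assert not record.contacted

    def test_one_fully_wrapped_section_of_three_gives_a_third(self):
        outline = _square_outline(10, 10, 20)
        wrapped = np.ones((50, 50), dtype=bool)
        empty = np.zeros((50, 50), dtype=bool)
        record = soma_metrics(
            [outline] * 3, [wrapped, empty, empty],
            pixel_size_um=self.PIXEL_UM, section_thickness=0.3,
        )
        assert record.coverage_percent == pytest.approx(100.0 / 3, rel=1e-6)
        assert record.contacted

    def test_contact_arc_below_half_micron_not_contacted(self):
        # microglia touches only a 0.3 µm stretch (3 px at 100 nm)
        outline = _square_outline(10, 10, 20)
        mg = np.zeros((50, 50), dtype=bool)
        mg[8:10, 14:17] = True  # adjacent to the top edge, 3 px long
        record = soma_metrics(
            [outline], [mg], pixel_size_um=self.PIXEL_UM, section_thickness=0.3,
        )
        assert record.covered_surface > 0.0
        assert not record.contacted

    def test_coverage_monotone_under_microglia_dilation(self):
        rng = np.random.default_rng(0)
        outline = _square_outline(10, 10, 25)
        mg = np.zeros((60, 60), dtype=bool)
        mg[rng.random((60, 60)) < 0.05] = True
        base = soma_metrics([outline], [mg], self.PIXEL_UM, 0.3)
        grown = soma_metrics(
            [outline], [ndimage.binary_dilation(mg)], self.PIXEL_UM, 0.3
        )
        assert 0.0 <= base.coverage_percent <= grown.coverage_percent <= 100.0

    def test_open_outline_rejected(self):
        pts = _square_outline(5, 5, 10)[:-1]
        with pytest.raises(ValueError, match="open outline"):
            soma_metrics([pts], [np.zeros((30, 30), dtype=bool)], 0.1, 0.3)


class TestMembraneIntensity:
    def test_uniform_image_gives_intensity_times_ribbon_width(self):
        img = np.full((200, 200), 3.0)
        polyline = np.array([[100.0, 40.0], [100.0, 160.0]])
        out = membrane_intensity(polyline, img, pixel_size_nm=50.0)
        assert out["intensity_per_length_nm"] == pytest.approx(3.0 * 500.0, rel=0.05)

    def test_per_length_value_independent_of_length(self):
        img = np.full((200, 400), 2.0)
        short = membrane_intensity(
            np.array([[100.0, 50.0], [100.0, 150.0]]), img, pixel_size_nm=50.0
        )
        long = membrane_intensity(
            np.array([[100.0, 50.0], [100.0, 350.0]]), img, pixel_size_nm=50.0
        )
        assert long["intensity_per_length_nm"] == pytest.approx(
            short["intensity_per_length_nm"], rel=0.05
        )

    def test_ribbon_outside_image_rejected(self):
        img = np.zeros((50, 50))
        polyline = np.array([[2.0, 2.0], [2.0, 48.0]])
        with pytest.raises(ValueError, match="outside"):
            membrane_intensity(polyline, img, pixel_size_nm=50.0)

    def test_default_width_is_500_nm(self):
        import inspect

        assert inspect.signature(membrane_intensity).parameters["width_nm"].default == 500.0
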