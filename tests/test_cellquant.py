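"""Per-cell power, contact gating, and positivity in the culture model."""

import numpy as np
import pytest
from scipy import ndimage

import exoquant as eq
from exoquant import cellquant as cq
from exoquant.stack import BinaryMask, CellLabelMap, ContractError
from exoquant.synthetic import UptakeSceneSpec, generate_uptake_scene


def _ring_image(shape, centers, radius=8, thickness=2, level=150.0):
    img = np.zeros(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cy, cx in centers:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        img[(d2 <= radius**2) & (d2 > (radius - thickness) ** 2)] = level
    return img


class TestLabelCells:
    def test_blank_channel_yields_zero_cells(self):
        with pytest.warns(UserWarning):
            cells = cq.label_cells_from_ctb(np.zeros((64, 64)))
        assert cells.n_cells == 0

    def test_three_rings_three_filled_labels(self):
        centers = [(20, 20), (20, 60), (60, 40)]
        img = _ring_image((80, 80), centers)
        cells = cq.label_cells_from_ctb(img, min_area_px=20)
        assert cells.n_cells == 3
        # filled interiors: each label area close to the full disc area
        disc_area = np.pi * 8**2
        areas = np.bincount(cells.labels.ravel())[1:]
        assert np.all(np.abs(areas - disc_area) / disc_area < 0.35)

    def test_touching_rings_merge_into_one_label(self):
        # two rings sharing a boundary arc become one 8-connected component
        img = _ring_image((64, 96), [(32, 32), (32, 47)])
        cells = cq.label_cells_from_ctb(img, min_area_px=20)
        assert cells.n_cells == 1

    def test_border_cells_excluded_by_default(self):
        img = _ring_image((64, 64), [(5, 32), (40, 32)])
        cells = cq.label_cells_from_ctb(img, min_area_px=20)
        assert cells.n_cells == 1
        cells_all = cq.label_cells_from_ctb(img, min_area_px=20, exclude_border=False)
        assert cells_all.n_cells == 2


class TestContactFilter:
    def _one_cell(self, shape=(40, 60), top=10, bottom=20, left=10, right=20):
        labels = np.zeros(shape, np.int32)
        labels[top:bottom, left:right] = 1
        return CellLabelMap(labels)

    def test_empty_adipocyte_mask_all_false(self):
        cells = self._one_cell()
        assert not cq.contact_filter(cells, np.zeros((40, 60), bool)).any()

    def test_overlap_is_contact_at_radius_zero(self):
        cells = self._one_cell()
        mask = np.zeros((40, 60), bool)
        mask[15:30, 15:40] = True
        assert cq.contact_filter(cells, mask, radius_px=0).all()

    def test_gap_of_three_pixels_needs_radius_three(self):
        # cell occupies columns 10..19; nearest mask pixel at column 22 is
        # 3 px away from the cell edge
        cells = self._one_cell()
        mask = np.zeros((40, 60), bool)
        mask[10:20, 22:30] = True
        assert not cq.contact_filter(cells, mask, radius_px=1)[0]
        assert cq.contact_filter(cells, mask, radius_px=3)[0]

    @pytest.mark.parametrize("radii", [(0, 1), (1, 3), (3, 8)])
    def test_monotone_in_radius(self, radii, rng):
        labels = np.zeros((64, 64), np.int32)
        for i, (cy, cx) in enumerate([(10, 10), (30, 40), (52, 14), (50, 52)]):
            labels[cy - 4 : cy + 4, cx - 4 : cx + 4] = i + 1
        cells = CellLabelMap(labels)
        mask = rng.random((64, 64)) > 0.98
        small = cq.contact_filter(cells, mask, radius_px=radii[0])
        large = cq.contact_filter(cells, mask, radius_px=radii[1])
        assert np.all(large | ~small)  # contact set never shrinks


class TestCellPower:
    def test_zero_signal_all_zero(self):
        labels = CellLabelMap(np.ones((10, 10), np.int32))
        assert np.all(cq.cell_power(labels, np.zeros((10, 10))) == 0)

    def test_uniform_cell_power_arithmetic(self):
        labels = np.zeros((20, 20), np.int32)
        labels[:5, :10] = 1  # 50 pixels
        signal = np.where(labels == 1, 20.0, 0.0)
        assert cq.cell_power(CellLabelMap(labels), signal)[0] == 1000.0

    def test_additive_over_partition_and_label_permutation(self, rng):
        labels = rng.integers(0, 4, (32, 32)).astype(np.int32)
        signal = rng.uniform(0, 10, (32, 32))
        powers = cq.cell_power(CellLabelMap(labels), signal)
        # total over labels equals masked total
        assert np.isclose(powers.sum(), signal[labels > 0].sum())
        # permuting label ids permutes powers: old label i -> new label perm[i]
        perm = np.array([0, 3, 1, 2])
        permuted = cq.cell_power(CellLabelMap(perm[labels].astype(np.int32)), signal)
        for old, new in [(1, 3), (2, 1), (3, 2)]:
            assert np.isclose(permuted[new - 1], powers[old - 1])

    def test_uptake_scene_truths_recovered_exactly(self):
        truths = np.array([100.0, 0.0, 250.0])
        stack, truth = generate_uptake_scene(truths, [False, False, False], seed=5)
        cells = cq.label_cells_from_ctb(stack["CtB"])
        powers = cq.cell_power(cells, stack["Alexa546"])
        centers = np.round(truth.macrophage_centers).astype(int)
        label_at = cells.labels[centers[:, 0], centers[:, 1]]
        assert (label_at > 0).all()
        assert np.array_equal(powers[label_at - 1], truth.true_power)


class TestRegionPower:
    def test_full_frame_equals_global_sum(self, rng):
        signal = rng.uniform(0, 5, (16, 16))
        assert cq.region_power(np.ones((16, 16), bool), signal) == pytest.approx(signal.sum())

    def test_disjoint_rois_additive(self, rng):
        signal = rng.uniform(0, 5, (16, 16))
        a = np.zeros((16, 16), bool)
        b = np.zeros((16, 16), bool)
        a[:8], b[8:] = True, True
        assert cq.region_power(a, signal) + cq.region_power(b, signal) == pytest.approx(
            cq.region_power(a | b, signal)
        )

    def test_empty_roi_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert cq.region_power(np.zeros((8, 8), bool), np.ones((8, 8))) == 0.0

    def test_annular_roi_recovers_painted_deposition(self):
        # paint a deposition band on an adipocyte perimeter and sum it back
        yy, xx = np.mgrid[:64, :64]
        d2 = (yy - 32) ** 2 + (xx - 32) ** 2
        band = (d2 <= 20**2) & (d2 > 17**2)
        signal = np.where(band, 12.5, 0.0)
        assert cq.region_power(BinaryMask(band), signal) == pytest.approx(12.5 * band.sum())


class TestPositivity:
    def test_fixed_threshold_fraction(self):
        res = cq.positivity(np.array([0.0, 0.0, 10.0, 10.0]), rule="fixed", threshold=5.0)
        assert res.fraction == 0.5

    def test_all_below_threshold(self):
        res = cq.positivity(np.array([1.0, 2.0]), rule="fixed", threshold=5.0)
        assert res.fraction == 0.0

    def test_adaptive_rule_requires_control(self):
        with pytest.raises(ContractError):
            cq.positivity(np.array([1.0]), rule="mad", control_powers=np.array([]))

    def test_adaptive_rule_recovers_mixture_fraction(self, rng):
        # two-population mixture: 60% positive cells well above control
        n = 200
        positive = rng.random(n) < 0.6
        powers = np.where(positive, rng.normal(500, 50, n), rng.normal(20, 5, n))
        control = rng.normal(20, 5, 300)
        res = cq.positivity(powers, rule="mad", control_powers=control, k=3.0)
        # binomial 95% CI around 0.6 at n=200
        se = np.sqrt(0.6 * 0.4 / n)
        assert abs(res.fraction - 0.6) < 1.96 * se + 1e-9


class TestSurfaceLamp1Culture:
    def test_blank_lamp1_channel_all_zero(self):
        ctb = _ring_image((80, 80), [(25, 25), (55, 55)])
        stack = eq.ChannelStack({"CtB": ctb, "LAMP1": np.zeros((80, 80))})
        cells, powers = cq.surface_lamp1_culture(stack, min_area_px=20)
        assert cells.n_cells == 2
        assert np.all(powers == 0)

    def test_surface_ring_totals_recovered_exactly(self):
        ctb = _ring_image((80, 80), [(25, 25), (55, 55)])
        lamp = _ring_image((80, 80), [(25, 25)], radius=7, level=40.0)
        stack = eq.ChannelStack({"CtB": ctb, "LAMP1": lamp})
        cells, powers = cq.surface_lamp1_culture(stack, min_area_px=20)
        centers = {tuple(np.round(ndimage.center_of_mass(cells.labels == i)).astype(int)): i for i in cells.ids}
        p1 = powers[centers[(25, 25)] - 1]
        assert p1 == pytest.approx(lamp.sum())  # ring inside the filled cell
        assert powers[centers[(55, 55)] - 1] == 0.0

    def test_condition_fold_recovered_from_scenes(self, rng):
        # apoptotic-condition cells painted at ~5x control LAMP-1
        shape = (160, 160)
        centers_a = [(30, 30), (30, 90), (90, 30), (90, 90), (130, 130)]
        medians = {}
        for cond, level in (("control", 20.0), ("apoptotic", 100.0)):
            ctb = _ring_image(shape, centers_a)
            lamp = _ring_image(shape, centers_a, radius=7, level=level)
            lamp = np.clip(lamp + rng.normal(0, 2.0, shape), 0, None)
            stack = eq.ChannelStack({"CtB": ctb, "LAMP1": lamp})
            _, powers = cq.surface_lamp1_culture(stack, min_area_px=20)
            medians[cond] = np.median(powers)
        ratio = medians["apoptotic"] / medians["control"]
        assert ratio == pytest.approx(5.0, rel=0.15)


class TestContactGatingPipeline:
    def test_contact_pattern_propagates_to_filter(self):
        pattern = [True, False, True, False]
        truths = np.array([50.0, 60.0, 70.0, 80.0])
        stack, truth = generate_uptake_scene(truths, pattern, seed=9)
        cells = cq.label_cells_from_ctb(stack["CtB"])
        adip = cq.adipocyte_mask_from_channel(stack["Alexa546"])
        flags = cq.contact_filter(cells, adip, radius_px=3)
        centers = np.round(truth.macrophage_centers).astype(int)
        label_at = cells.labels[centers[:, 0], centers[:, 1]]
        assert (label_at > 0).all()
        assert np.array_equal(flags[label_at - 1], np.asarray(pattern))

    def test_bafilomycin_style_uptake_abolition_detected(self):
        from exoquant.experiments import uptake_experiment

        rng = np.random.default_rng(77)
        truths_ctrl = rng.lognormal(np.log(300.0), 0.5, 30)
        truths_baf = np.zeros(30)
        res = uptake_experiment(13, truths_ctrl, truths_baf, noise_sd=5.0, background_level=10.0)
        assert res["p_value"] < 0.01
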