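import numpy as np
import pytest
from scipy.spatial.distance import cdist
from skimage.filters import gaussian
from skimage.measure import label as cc_label, regionprops

from fishq.io_formats import MISPProfile
from fishq.nuclei import (
    LabelMask,
    NucleusObject,
    border_slope_score,
    circularity,
    filter_nucleus,
    segment_nuclei,
)
from fishq.preprocess import DAPI, ChannelImage
from conftest import disk_image


class TestCircularity:
    def test_square_closed_form(self):
        # n x n square: 4*pi*n^2 / (4n)^2 = pi/4
        for n in (5, 20, 100):
            assert circularity(n * n, 4.0 * n) == pytest.approx(np.pi / 4)

    def test_rasterized_disk_is_round(self):
        img = disk_image((64, 64), (32, 32), 20, fg=1, bg=0)
        rp = regionprops(cc_label(img))[0]
        assert circularity(rp.area, rp.perimeter) >= 0.90

    def test_thin_rectangle_is_elongated(self):
        # 1x100 strip, closed-form perimeter 202: 4*pi*100/202^2 ~ 0.031
        assert circularity(100, 202.0) == pytest.approx(0.0308, abs=1e-3)
        assert circularity(100, 202.0) < 0.10

    def test_clamped_at_one(self):
        assert circularity(1000, 10.0) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            circularity(0, 10.0)
        with pytest.raises(ValueError):
            circularity(10, 0.0)


class TestBorderSlope:
    def _disk_mask(self, shape, center, radius):
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2

    def test_uniform_image_scores_zero(self):
        img = ChannelImage(np.full((40, 40), 120, np.uint8), 8, DAPI)
        mask = self._disk_mask((40, 40), (20, 20), 10)
        assert border_slope_score(img, mask) == 0.0

    def test_sharp_edge_beats_blurred_edge(self):
        sharp = disk_image((80, 80), (40, 40), 15, fg=200, bg=10)
        blurred = gaussian(sharp.astype(float), 4, preserve_range=True)
        mask = self._disk_mask((80, 80), (40, 40), 15)
        s_sharp = border_slope_score(ChannelImage(sharp, 8, DAPI), mask)
        s_blur = border_slope_score(
            ChannelImage(np.rint(blurred).astype(np.uint8), 8, DAPI), mask
        )
        assert s_sharp > s_blur > 0

    def test_invariant_to_constant_offset(self):
        img = disk_image((60, 60), (30, 30), 12, fg=150, bg=20)
        mask = self._disk_mask((60, 60), (30, 30), 12)
        a = border_slope_score(ChannelImage(img, 8, DAPI), mask)
        b = border_slope_score(ChannelImage(img + 50, 8, DAPI), mask)
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_mask_rejected(self):
        img = ChannelImage(np.zeros((10, 10), np.uint8), 8, DAPI)
        with pytest.raises(ValueError):
            border_slope_score(img, np.zeros((10, 10), bool))


def _obj(eqr=15.0, area=700, circ=0.9, slope=0.1):
    return NucleusObject(
        label=1, centroid=(50.0, 50.0), area_px2=area, perimeter_px=100.0,
        equivalent_radius_px=eqr, circularity=circ, border_slope=slope,
        mean_interior_intensity=100.0,
    )


class TestFilterNucleus:
    def test_all_bounds_met_accepted(self, default_profile):
        assert filter_nucleus(_obj(), default_profile) == (True, None)

    def test_low_circularity_rejected(self, default_profile):
        ok, reason = filter_nucleus(_obj(circ=0.5), default_profile)
        assert (ok, reason) == (False, "circularity")

    def test_ordering_radius_reported_before_circularity(self, default_profile):
        # radius out of [8, 30] and circularity failing: radius wins
        ok, reason = filter_nucleus(
            _obj(eqr=40.0, area=2000, circ=0.5), default_profile
        )
        assert (ok, reason) == (False, "radius")

    def test_area_checked_after_radius(self, default_profile):
        ok, reason = filter_nucleus(_obj(area=5000), default_profile)
        assert (ok, reason) == (False, "area")

    def test_border_slope_last(self, default_profile):
        ok, reason = filter_nucleus(_obj(slope=0.0), default_profile)
        assert (ok, reason) == (False, "border_slope")


class TestSegmentNuclei:
    def test_blank_image_gives_no_objects(self, default_profile):
        img = ChannelImage(np.zeros((128, 128), np.uint8), 8, DAPI)
        mask, objs = segment_nuclei(img, default_profile)
        assert objs == [] and mask.n_labels == 0

    def test_twelve_planted_disks_recovered(self, default_profile):
        """12 well-separated round nuclei within profile bounds are all
        accepted with centroids within 2 px of the planted centers."""
        h = w = 384
        centers = [(64 + 96 * i, 64 + 96 * j) for i in range(3) for j in range(4)]
        img = np.full((h, w), 10, np.uint8)
        yy, xx = np.mgrid[:h, :w]
        for cy, cx in centers:
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 14**2] = 200
        img = np.rint(gaussian(img.astype(float), 1.5, preserve_range=True)).astype(np.uint8)
        mask, objs = segment_nuclei(ChannelImage(img, 8, DAPI), default_profile)
        accepted = [o for o in objs if o.accepted]
        assert len(accepted) == 12
        d = cdist(np.array(centers, float), np.array([o.centroid for o in accepted]))
        assert d.min(axis=1).max() <= 2.0

    def test_bright_streak_rejected_for_circularity(self):
        """An elongated bright streak whose size passes the radius/area
        bounds is rejected on circularity, the first criterion it fails; a
        1-px-wide streak never even survives mask regularization."""
        profile = MISPProfile(
            nucleus_radius_px=(1.0, 40.0), nucleus_area_px2=(50.0, 3000.0),
            min_circularity=0.75, min_border_slope=0.0,
        )
        h = w = 256
        img = np.full((h, w), 10, np.uint8)
        yy, xx = np.mgrid[:h, :w]
        img[(yy - 60) ** 2 + (xx - 60) ** 2 <= 14**2] = 200   # one round nucleus
        img[178:183, 60:140] = 200                            # 5 x 80 streak
        img[220:221, 60:140] = 200                            # 1 x 80 hairline
        mask, objs = segment_nuclei(ChannelImage(img, 8, DAPI), profile)
        streaks = [o for o in objs if abs(o.centroid[0] - 180) < 5]
        assert len(streaks) == 1
        assert streaks[0].accepted is False
        assert streaks[0].reject_reason == "circularity"
        # direct computation confirms the streak is far from round
        assert streaks[0].circularity < profile.min_circularity
        # the hairline is denoised away before candidacy
        assert not any(abs(o.centroid[0] - 220) < 5 for o in objs)

    def test_border_touching_object_rejected(self, default_profile):
        img = np.full((128, 128), 10, np.uint8)
        yy, xx = np.mgrid[:128, :128]
        img[(yy - 0) ** 2 + (xx - 64) ** 2 <= 14**2] = 200   # clipped at top edge
        img[(yy - 70) ** 2 + (xx - 64) ** 2 <= 14**2] = 200  # interior control
        mask, objs = segment_nuclei(ChannelImage(img, 8, DAPI), default_profile)
        by_pos = sorted(objs, key=lambda o: o.centroid[0])
        assert by_pos[0].reject_reason == "border"
        assert by_pos[1].accepted

    def test_label_partition(self, quantified_core):
        """Sum of object areas equals the count of nonzero mask pixels."""
        result, _ = quantified_core
        assert sum(o.area_px2 for o in result.nuclei) == int(
            (result.mask.labels > 0).sum()
        )
        labels = np.unique(result.mask.labels)
        labels = labels[labels > 0]
        np.testing.assert_array_equal(labels, np.arange(1, len(labels) + 1))

    def test_deterministic(self, sim_core, default_profile):
        _, stacks, _ = sim_core
        from fishq.preprocess import extended_focus, local_contrast_enhance
        dapi = local_contrast_enhance(extended_focus(stacks[DAPI], "local_sharpness"))
        m1, o1 = segment_nuclei(dapi, default_profile)
        m2, o2 = segment_nuclei(dapi, default_profile)
        np.testing.assert_array_equal(m1.labels, m2.labels)
        assert o1 == o2

    def test_raising_min_circularity_never_increases_accepted(self, sim_core):
        _, stacks, _ = sim_core
        from fishq.preprocess import extended_focus, local_contrast_enhance
        dapi = local_contrast_enhance(extended_focus(stacks[DAPI], "local_sharpness"))
        counts = []
        for mc in (0.5, 0.75, 0.9, 0.97):
            profile = MISPProfile(min_circularity=mc)
            _, objs = segment_nuclei(dapi, profile)
            counts.append(sum(o.accepted for o in objs))
        assert counts == sorted(counts, reverse=True)
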