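"""Cup ellipse fitting, vessel clustering and the four-cluster composition."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import odatlas as od
from odatlas.representation import (
    DEFAULT_LEVELS,
    LABEL_CUP,
    LABEL_RIM,
    LABEL_VESSEL,
    decode_levels,
    encode_labels,
)


@pytest.fixture(scope="module")
def phantom192():
    return od.render_phantom(od.PhantomSpec(patch_size=192, noise_sd=0.0)), \
        od.PhantomSpec(patch_size=192)


class TestCupEllipse:
    def test_recovers_known_cup(self, phantom192):
        ph, spec = phantom192
        ell = od.fit_cup_ellipse(ph.patch, ph.disc_mask)
        assert np.hypot(ell.center[0] - spec.cup.center[0],
                        ell.center[1] - spec.cup.center[1]) < 2.0
        a_true = max(spec.cup.semi_axes)
        b_true = min(spec.cup.semi_axes)
        assert abs(ell.semi_axes[0] - a_true) < 2.0
        assert abs(ell.semi_axes[1] - b_true) < 2.0

    def test_center_robust_to_noise(self):
        errs = []
        for seed in range(10):
            spec = od.PhantomSpec(patch_size=192, noise_sd=0.05, seed=seed)
            ph = od.render_phantom(spec)
            ell = od.fit_cup_ellipse(ph.patch, ph.disc_mask)
            errs.append(np.hypot(ell.center[0] - spec.cup.center[0],
                                 ell.center[1] - spec.cup.center[1]))
        assert np.median(errs) < 4.0

    def test_flat_patch_rejected(self):
        disc = np.zeros((64, 64), dtype=bool)
        disc[16:48, 16:48] = True
        with pytest.raises(ValueError):
            od.fit_cup_ellipse(np.full((64, 64, 3), 0.5), disc)

    def test_axes_ordered_and_inside_disc(self, phantom192):
        ph, _ = phantom192
        ell = od.fit_cup_ellipse(ph.patch, ph.disc_mask)
        assert ell.semi_axes[1] <= ell.semi_axes[0]
        assert not np.any(ell.mask(ph.disc_mask.shape) & ~ph.disc_mask)


class TestVesselKmeans:
    def test_recovers_vessels_in_od_region(self):
        spec = od.PhantomSpec(patch_size=192, noise_sd=0.02, seed=1)
        ph = od.render_phantom(spec)
        mask = od.segment_vessels_kmeans(ph.patch, ph.disc_mask, seed=0)
        ys, xs = np.nonzero(ph.disc_mask)
        r = int(0.1 * 0.5 * max(np.ptp(xs), np.ptp(ys)))
        region = ndi.binary_dilation(ph.disc_mask, iterations=r)
        a, b = mask & region, ph.vessel_mask & region
        dice = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert dice > 0.9

    def test_no_vessels_near_empty_inside_disc(self):
        spec = od.PhantomSpec(patch_size=192, vessels=[], noise_sd=0.02, seed=2)
        ph = od.render_phantom(spec)
        mask = od.segment_vessels_kmeans(ph.patch, ph.disc_mask, seed=0)
        assert (mask & ph.disc_mask).sum() < 0.01 * ph.disc_mask.sum()

    def test_deterministic_for_fixed_seed(self):
        spec = od.PhantomSpec(patch_size=96, noise_sd=0.02, seed=3)
        ph = od.render_phantom(spec)
        m1 = od.segment_vessels_kmeans(ph.patch, ph.disc_mask, seed=5)
        m2 = od.segment_vessels_kmeans(ph.patch, ph.disc_mask, seed=5)
        assert np.array_equal(m1, m2)


class TestVesselAverageModel:
    def test_identical_masks_give_binary_map(self):
        ph = od.render_phantom(od.PhantomSpec(patch_size=96, noise_sd=0.0))
        masks = [ph.vessel_mask.copy() for _ in range(3)]
        prob, model = od.build_vessel_average_model(masks, ph.disc_mask)
        assert set(np.unique(prob)) <= {0.0, 1.0}
        assert np.array_equal(prob > 0.5, ph.vessel_mask)

    def test_all_empty_masks_give_zero_map(self):
        ph = od.render_phantom(od.PhantomSpec(patch_size=96, noise_sd=0.0))
        masks = [np.zeros_like(ph.vessel_mask) for _ in range(3)]
        prob, _ = od.build_vessel_average_model(masks, ph.disc_mask)
        assert np.all(prob == 0)

    def test_rare_branch_filtered(self, vessel_population):
        # an extra branch present in only 30% of subjects must not survive
        # the 75% frequency threshold
        prob = vessel_population["prob"]
        simplified = od.simplify_vessel_model(prob)
        from odatlas.synthetic import _vessel_distance

        m = prob.shape[0]
        extra = (np.array([[0.46 * m, 0.50 * m], [0.62 * m, 0.40 * m],
                           [0.80 * m, 0.32 * m]]), max(2.0, 0.022 * m))
        extra_region = _vessel_distance(m, [extra]) < 0.0
        # ignore the junction with the shared branches near the disc center
        far = extra_region.copy()
        far[:, :int(0.55 * m)] = False
        assert not np.any(simplified & far)


class TestSimplifyVesselModel:
    def test_strictly_above_threshold(self):
        prob = np.array([[0.74, 0.75, 0.76]])
        assert list(od.simplify_vessel_model(prob, 0.75)[0]) == [False, False, True]

    def test_degenerate_maps(self):
        assert not od.simplify_vessel_model(np.zeros((8, 8))).any()
        assert od.simplify_vessel_model(np.ones((8, 8))).all()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        prob = rng.random((32, 32))
        low = od.simplify_vessel_model(prob, 0.5)
        high = od.simplify_vessel_model(prob, 0.8)
        assert np.all(low[high])   # high-threshold mask is a subset


class TestRegisterModelToSubject:
    def test_identical_masks_unchanged(self):
        ph = od.render_phantom(od.PhantomSpec(patch_size=96, noise_sd=0.0))
        out = od.register_model_to_subject(ph.vessel_mask, ph.vessel_mask)
        inter = (out & ph.vessel_mask).sum()
        dice = 2 * inter / (out.sum() + ph.vessel_mask.sum())
        assert dice > 0.98

    def test_translated_subject_recovered(self):
        ph = od.render_phantom(od.PhantomSpec(patch_size=96, noise_sd=0.0))
        shift = np.zeros((2, 96, 96))
        shift[1] = 3.0
        subject = od.warp(ph.vessel_mask.astype(float), shift) > 0.5
        out = od.register_model_to_subject(ph.vessel_mask, subject)
        dice = 2 * (out & subject).sum() / (out.sum() + subject.sum())
        assert dice > 0.95

    def test_empty_subject_warns_and_returns_model(self):
        model = np.zeros((32, 32), dtype=bool)
        model[10:20, 15:18] = True
        with pytest.warns(UserWarning):
            out = od.register_model_to_subject(model, np.zeros_like(model))
        assert np.array_equal(out, model)


class TestFourCluster:
    def test_labels_partition_patch(self, phantom192):
        ph, _ = phantom192
        fc = od.compose_four_cluster(ph.disc_mask, ph.cup_mask, ph.vessel_mask)
        counts = np.bincount(fc.labels.ravel(), minlength=4)
        assert counts.sum() == ph.patch.shape[0] * ph.patch.shape[1]
        assert all(counts[1:] > 0)

    def test_vessel_priority_over_cup(self, phantom192):
        ph, _ = phantom192
        fc = od.compose_four_cluster(ph.disc_mask, ph.cup_mask, ph.vessel_mask)
        crossing = ph.vessel_mask & ph.cup_mask & ph.disc_mask
        if crossing.any():
            assert np.all(fc.labels[crossing] == LABEL_VESSEL)
        only_cup = ph.cup_mask & ~ph.vessel_mask
        assert np.all(fc.labels[only_cup] == LABEL_CUP)

    def test_no_vessels_gives_three_clusters(self, phantom192):
        ph, _ = phantom192
        fc = od.compose_four_cluster(ph.disc_mask, ph.cup_mask,
                                     np.zeros_like(ph.vessel_mask))
        assert LABEL_VESSEL not in np.unique(fc.labels)

    def test_cup_outside_disc_clipped_with_warning(self):
        disc = np.zeros((64, 64), dtype=bool)
        disc[20:44, 20:44] = True
        cup = np.zeros_like(disc)
        cup[30:60, 30:60] = True
        with pytest.warns(UserWarning):
            fc = od.compose_four_cluster(disc, cup, np.zeros_like(disc))
        assert not np.any((fc.labels == LABEL_CUP) & ~disc)

    def test_encoding_round_trip_lossless(self, phantom192):
        ph, _ = phantom192
        fc = od.compose_four_cluster(ph.disc_mask, ph.cup_mask, ph.vessel_mask)
        scalar = encode_labels(fc.labels, DEFAULT_LEVELS)
        assert np.array_equal(decode_levels(scalar, DEFAULT_LEVELS), fc.labels)
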