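"""Detection-chain tests: DoG oracle, shadow linking, Gaussian fits, filters."""

import numpy as np
import pytest
from scipy.signal import convolve2d
from scipy.spatial import cKDTree

from bcdquant import spotdetect, synthgen
from bcdquant.spotdetect import (
    Candidate,
    DoGParams,
    FilterCriteria,
    FittedParticle,
    apply_filters,
    detect,
    dog_filter,
    find_candidates,
    fit_particle,
    joint_fit,
    link_shadows,
)


def _discrete_dog_kernel(params: DoGParams) -> np.ndarray:
    """Independent construction of the balanced DoG kernel (truncate=4)."""

    def gauss2d(sigma):
        r = int(4 * sigma + 0.5)
        x = np.arange(-r, r + 1)
        k1 = np.exp(-(x**2) / (2 * sigma**2))
        k1 /= k1.sum()
        return np.outer(k1, k1)

    kc = gauss2d(params.center_radius_px)
    ks = gauss2d(params.surround_radius_px)
    pad = (ks.shape[0] - kc.shape[0]) // 2
    kc = np.pad(kc, pad)
    return kc - ks


def _elliptical_gaussian(shape, xc, yc, rx, ry, theta, amp, offset):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - xc) * ct + (yy - yc) * st
    yr = -(xx - xc) * st + (yy - yc) * ct
    return offset + amp * np.exp(-(xr**2 / (2 * rx**2) + yr**2 / (2 * ry**2)))


class TestDoGFilter:
    def test_zero_response_to_constant(self):
        out = dog_filter(np.full((40, 40), 123.4))
        assert np.max(np.abs(out)) < 1e-9

    def test_impulse_response_matches_kernel(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = dog_filter(img)
        kernel = _discrete_dog_kernel(DoGParams())
        assert out[20, 20] == pytest.approx(kernel[kernel.shape[0] // 2, kernel.shape[1] // 2], rel=1e-6)

    def test_matches_brute_force_convolution(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (48, 48))
        out = dog_filter(img)
        kernel = _discrete_dog_kernel(DoGParams())
        brute = convolve2d(img, kernel, mode="same", boundary="symm")
        # interior: boundary handling differs slightly between implementations
        assert np.allclose(out[12:-12, 12:-12], brute[12:-12, 12:-12], atol=1e-8)

    def test_spot_response_linear_in_amplitude(self):
        resp = []
        for A in (50.0, 200.0):
            img = _elliptical_gaussian((31, 31), 15, 15, 1.1, 1.1, 0.0, A, 0.0)
            resp.append(dog_filter(img).max())
        assert resp[1] / resp[0] == pytest.approx(4.0, rel=1e-6)


class TestFindCandidates:
    def test_empty_on_zero_stack(self):
        assert find_candidates(np.zeros((3, 32, 32))) == []

    def test_bright_spot_spans_slices(self, blasto_model):
        p = synthgen.ParticleTruth(0, 60.0, 40.0, 6.0, 0.2, 0.0, 10, 15000.0)
        spec = synthgen.RenderSpec(background_photons=0, background_modulation=0, poisson=False)
        stack = synthgen.render_stack([p], blasto_model, spec, shape=(12, 80, 120))
        filt = spotdetect.dog_filter_stack(stack)
        cands = find_candidates(filt)
        zs = sorted(c.z_slice for c in cands)
        assert len(cands) >= 3
        assert all(abs(c.x_px - 60) <= 1 and abs(c.y_px - 40) <= 1 for c in cands)
        assert zs == list(range(min(zs), max(zs) + 1))

    def test_noise_knee_in_threshold_sweep(self):
        """Candidate counts explode below a knee and vanish above it."""
        rng = np.random.default_rng(5)
        noise = rng.poisson(100, (6, 128, 128)).astype(float)
        filt = np.stack([dog_filter(sl) for sl in noise])
        counts = [
            len(find_candidates(filt, DoGParams(threshold=t)))
            for t in (0.5, 2.0, 10.0, 150.0)
        ]
        assert counts[0] > 50 * max(counts[2], 1)
        assert counts[3] == 0

    def test_sorted_brightest_first(self):
        filt = np.zeros((1, 20, 20))
        filt[0, 5, 5] = 10.0
        filt[0, 14, 14] = 30.0
        cands = find_candidates(filt, DoGParams(threshold=5))
        assert [c.dog_value for c in cands] == [30.0, 10.0]


class TestLinkShadows:
    def test_vertical_column_collapses(self):
        cands = [
            Candidate(10, 10, 5, 100.0),
            Candidate(10, 10, 4, 60.0),
            Candidate(10, 10, 6, 55.0),
        ]
        out = link_shadows(cands)
        assert len(out) == 1
        c, n_shadows = out[0]
        assert c.z_slice == 5 and n_shadows == 2

    def test_distant_particles_not_cross_linked(self):
        cands = sorted(
            [
                Candidate(10, 10, 5, 100.0),
                Candidate(10, 10, 6, 50.0),
                Candidate(20, 10, 5, 90.0),
                Candidate(20, 10, 4, 45.0),
            ],
            key=lambda c: -c.dog_value,
        )
        out = link_shadows(cands)
        assert len(out) == 2
        assert sorted((c.x_px, ns) for c, ns in out) == [(10, 1), (20, 1)]

    def test_single_slice_candidate_has_no_shadows(self):
        out = link_shadows([Candidate(5, 5, 3, 42.0)])
        assert out == [(Candidate(5, 5, 3, 42.0), 0)]
        particle = FittedParticle(5, 5, 3, 1.1, 1.1, 0, 1.0, 10.0, n_shadows=0)
        accepted, counts = apply_filters([particle])
        assert not accepted and counts["shadows"] == 1


class TestFitParticle:
    def test_noise_free_round_trip(self):
        truth = dict(xc=4.3, yc=4.6, rx=1.2, ry=1.0, theta=0.0, amp=100.0, offset=10.0)
        patch = _elliptical_gaussian((9, 9), truth["xc"], truth["yc"], truth["rx"],
                                     truth["ry"], truth["theta"], truth["amp"], truth["offset"])
        f = fit_particle(patch, 4, 5)
        assert f.x_c == pytest.approx(truth["xc"], abs=1e-3)
        assert f.y_c == pytest.approx(truth["yc"], abs=1e-3)
        assert f.r_x == pytest.approx(truth["rx"], abs=1e-3)
        assert f.r_y == pytest.approx(truth["ry"], abs=1e-3)
        assert f.amplitude == pytest.approx(truth["amp"], abs=0.1)
        assert f.offset == pytest.approx(truth["offset"], abs=0.1)

    def test_flat_patch_rejected_by_amplitude_filter(self):
        f = fit_particle(np.full((9, 9), 10.0), 4, 4)
        assert f.amplitude < 1.0
        accepted, counts = apply_filters([f], FilterCriteria(min_shadows=0))
        assert not accepted

    def test_circular_spot_zero_eccentricity(self):
        patch = _elliptical_gaussian((9, 9), 4.0, 4.0, 1.2, 1.2, 0.0, 80.0, 5.0)
        f = fit_particle(patch, 4, 4)
        assert f.eccentricity < 1e-6

    def test_major_minor_ordering(self):
        patch = _elliptical_gaussian((9, 9), 4.0, 4.0, 0.9, 1.6, 0.3, 80.0, 5.0)
        f = fit_particle(patch, 4, 4)
        assert f.r_x >= f.r_y
        assert -np.pi / 2 <= f.theta < np.pi / 2


class TestJointFit:
    def _pair_patch(self, amps=(100.0, 60.0), sep=3.0):
        shape = (13, 13)
        patch = _elliptical_gaussian(shape, 5.0, 6.0, 1.1, 1.1, 0.0, amps[0], 8.0)
        patch += _elliptical_gaussian(shape, 5.0 + sep, 6.0, 1.1, 1.1, 0.0, amps[1], 0.0)
        return patch

    def test_joint_beats_single_on_overlapping_pair(self):
        patch = self._pair_patch()
        fits = joint_fit(patch, [(5.0, 6.0), (8.0, 6.0)])
        fits.sort(key=lambda f: -f.amplitude)
        assert len(fits) == 2
        assert fits[0].amplitude == pytest.approx(100.0, rel=0.10)
        assert fits[1].amplitude == pytest.approx(60.0, rel=0.10)
        # independent single fits on the same patch are biased upward
        s0 = fit_particle(patch, 5.0, 6.0)
        s1 = fit_particle(patch, 8.0, 6.0)
        joint_err = abs(fits[0].amplitude - 100) + abs(fits[1].amplitude - 60)
        single_err = abs(s0.amplitude - 100) + abs(s1.amplitude - 60)
        assert joint_err < single_err

    def test_duplicate_candidates_merged(self):
        patch = _elliptical_gaussian((11, 11), 5.0, 5.0, 1.1, 1.1, 0.0, 90.0, 5.0)
        fits = joint_fit(patch, [(5.0, 5.0), (5.2, 5.0)])
        assert len(fits) == 1

    def test_far_apart_equals_single_fits(self):
        shape = (11, 25)
        patch = _elliptical_gaussian(shape, 5.0, 5.0, 1.1, 1.1, 0.0, 100.0, 8.0)
        patch += _elliptical_gaussian(shape, 19.0, 5.0, 1.1, 1.1, 0.0, 70.0, 0.0)
        fits = sorted(joint_fit(patch, [(5.0, 5.0), (19.0, 5.0)]), key=lambda f: f.x_c)
        s0 = fit_particle(patch[:, :11], 5.0, 5.0)
        assert fits[0].amplitude == pytest.approx(s0.amplitude, rel=0.02)
        assert fits[0].r_x == pytest.approx(s0.r_x, abs=0.05)


class TestApplyFilters:
    def _particle(self, **kw):
        base = dict(x_c=4, y_c=4, z_slice=3, r_x=1.2, r_y=1.1, theta=0.0,
                    offset=10.0, amplitude=50.0, n_shadows=1)
        base.update(kw)
        return FittedParticle(**base)

    @pytest.mark.parametrize(
        "kw,reason",
        [
            (dict(r_y=0.5), "radius"),
            (dict(r_x=3.0), "radius"),
            (dict(amplitude=5.0), "amplitude"),
            (dict(n_shadows=0), "shadows"),
        ],
    )
    def test_rejections(self, kw, reason):
        accepted, counts = apply_filters([self._particle(**kw)])
        assert not accepted
        assert counts[reason] == 1

    def test_all_criteria_met_accepted(self):
        accepted, counts = apply_filters([self._particle()])
        assert len(accepted) == 1 and counts["accepted"] == 1


class TestDetect:
    def test_noise_only_stack_yields_nothing(self, blasto_model):
        spec = synthgen.RenderSpec(seed=1)
        stack = synthgen.render_stack([], blasto_model, spec, shape=(10, 128, 128))
        table = detect(stack)
        assert int(table.accepted.sum()) == 0

    def test_precision_recall_on_separated_spots(self, separated_spots):
        """>=95% precision and recall on well-separated high-SNR spots."""
        particles, stack = separated_spots
        table = detect(stack)
        acc = table[table.accepted]
        truth = np.array([[p.x_px, p.y_px] for p in particles])
        det = acc[["x_c", "y_c"]].to_numpy()
        d_td, idx = cKDTree(truth).query(det)
        matched = d_td < 2.0
        precision = matched.mean()
        recall = len(set(idx[matched])) / len(particles)
        assert precision >= 0.95
        assert recall >= 0.95

    def test_eccentricity_concentrates_near_zero(self, separated_spots):
        _, stack = separated_spots
        acc = detect(stack).query("accepted")
        assert np.median(acc.eccentricity) < 0.15

    def test_intensity_definition_and_conservation(self, separated_spots):
        particles, stack = separated_spots
        acc = detect(stack).query("accepted")
        assert np.allclose(acc.intensity, acc.amplitude * acc.r_x * acc.r_y)
        sigma = 1.1
        truth_total = sum(p.photon_amplitude for p in particles) * sigma**2
        assert acc.intensity.sum() == pytest.approx(truth_total, rel=0.15)

    def test_intensity_dog_linear_correspondence(self, separated_spots):
        _, stack = separated_spots
        acc = detect(stack).query("accepted")
        r = np.corrcoef(acc.intensity, acc.dog_value)[0, 1]
        assert r > 0.95

    def test_shadow_counts_track_brightness(self, separated_spots):
        _, stack = separated_spots
        acc = detect(stack).query("accepted")
        bright = acc[acc.amplitude >= acc.amplitude.quantile(0.9)]
        assert (bright.n_shadows >= 2).mean() > 0.9
        assert acc.n_shadows.median() >= 1

    def test_diameter_near_three_pixels(self, separated_spots):
        """Mean reported diameter ~3 px for the default PSF (sigma 1.1)."""
        _, stack = separated_spots
        acc = detect(stack).query("accepted")
        assert acc.diameter.mean() == pytest.approx(2.355 * 1.1, rel=0.1)
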