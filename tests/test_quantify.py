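"""Hip normalization, autofluorescence, SNR and the biodistribution table."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.stats import spearmanr

import nirquant as nq
from nirquant import (
    CohortVariation,
    NIRImage,
    NoiseModel,
    PhantomTruth,
    QuantConfig,
    RegionSpec,
    biodistribution,
    estimate_autofluorescence,
    generate_cohort,
    generate_phantom,
    hip_normalize,
    mean_intensity,
    quantify_frame,
    snr,
)
from nirquant.errors import (
    DegenerateBackgroundError,
    EmptyRegionError,
    NormalizationError,
    ValidationError,
)


def loop_mean_sd(pixels, mask):
    """Naive pixel-loop oracle for mean and population SD."""
    vals = [float(pixels[i, j]) for i in range(pixels.shape[0])
            for j in range(pixels.shape[1]) if mask[i, j]]
    n = len(vals)
    m = sum(vals) / n
    var = sum((v - m) ** 2 for v in vals) / n
    return m, math.sqrt(var), n


class TestMeanIntensity:
    def test_constant_region(self):
        img = NIRImage(np.full((20, 20), 7.0))
        mask = np.zeros((20, 20), dtype=bool)
        mask[3:9, 3:9] = True
        assert mean_intensity(img, mask) == (7.0, 0.0, 36)

    def test_four_pixel_hand_computation(self):
        px = np.zeros((20, 20))
        px[0, :4] = [1, 2, 3, 4]
        mask = np.zeros((20, 20), dtype=bool)
        mask[0, :4] = True
        m, sd, n = mean_intensity(NIRImage(px), mask)
        assert (m, n) == (2.5, 4)
        assert sd == pytest.approx(math.sqrt(1.25))

    def test_matches_pixel_loop_oracle(self, rng):
        from tests.conftest import random_image, random_mask
        for _ in range(5):
            img = random_image(rng, integral=True)
            mask = random_mask(rng)
            m, sd, n = mean_intensity(img, mask)
            om, osd, on = loop_mean_sd(img.pixels, mask)
            assert (m, n) == (om, on)
            assert sd == pytest.approx(osd, rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyRegionError):
            mean_intensity(NIRImage(np.ones((20, 20))),
                           np.zeros((20, 20), dtype=bool))


class TestHipNormalize:
    def _img_with_hip(self, hip_value):
        px = np.full((20, 20), 10.0)
        hip = np.zeros((20, 20), dtype=bool)
        hip[12:16, 12:16] = True
        px[hip] = hip_value
        return NIRImage(px), hip

    def test_factor_and_resulting_level(self):
        img, hip = self._img_with_hip(50.0)
        normed, f = hip_normalize(img, hip, reference_level=100.0)
        assert f == pytest.approx(2.0)
        assert normed.pixels[hip].mean() == pytest.approx(100.0)

    def test_identity_when_already_at_reference(self):
        img, hip = self._img_with_hip(100.0)
        normed, f = hip_normalize(img, hip, reference_level=100.0)
        assert f == 1.0
        assert np.array_equal(normed.pixels, img.pixels)

    def test_invariant_to_global_scale(self, rng):
        px = rng.gamma(2.0, 30.0, size=(24, 24)) + 1.0
        hip = np.zeros((24, 24), dtype=bool)
        hip[4:9, 4:9] = True
        a, _ = hip_normalize(NIRImage(px), hip)
        b, _ = hip_normalize(NIRImage(px * 7.3), hip)
        assert np.max(np.abs(a.pixels - b.pixels)) / a.pixels.max() < 1e-12

    def test_zero_hip_rejected(self):
        px = np.full((20, 20), 1.0)
        hip = np.zeros((20, 20), dtype=bool)
        hip[0, 0] = True
        px[0, 0] = 0.0
        with pytest.raises(NormalizationError):
            hip_normalize(NIRImage(px), hip)


class TestAutofluorescence:
    def test_constant_control(self):
        px = np.full((20, 20), 5.0)
        body = np.ones((20, 20), dtype=bool)
        hip = np.zeros((20, 20), dtype=bool)
        hip[2:6, 2:6] = True
        a = estimate_autofluorescence(NIRImage(px), body, hip,
                                      reference_level=100.0)
        assert a == pytest.approx(100.0)

    def test_phantom_control_recovers_reference_level(self, default_truth):
        """On a pre-injection control the normalized body level equals R,
        since the hip carries only autofluorescence; body-edge blur is
        excluded with an erosion margin."""
        ctrl, regs = generate_phantom(
            dataclasses.replace(default_truth, seed=77), 0.0
        )
        a = estimate_autofluorescence(
            ctrl, regs.body_mask, regs.mask("hip_ref"),
            reference_level=100.0, edge_margin=8,
        )
        assert a == pytest.approx(100.0, rel=0.02)

    def test_exvivo_mode_plain_mean(self):
        px = np.full((20, 20), 3.5)
        lung = np.zeros((20, 20), dtype=bool)
        lung[5:15, 5:15] = True
        assert estimate_autofluorescence(NIRImage(px), lung) == 3.5


class TestSnr:
    def _setup(self, roi_level, bg_values):
        px = np.zeros((20, 20))
        roi = np.zeros((20, 20), dtype=bool)
        bg = np.zeros((20, 20), dtype=bool)
        roi[2:6, 2:6] = True
        px[roi] = roi_level
        bg[10, :len(bg_values)] = True
        px[10, :len(bg_values)] = bg_values
        return NIRImage(px), roi, bg

    def test_autofluorescence_only_roi_scores_zero(self):
        img, roi, bg = self._setup(100.0, [98.0, 102.0, 99.0, 101.0])
        assert snr(img, roi, bg, autofluorescence=100.0) == pytest.approx(0.0)
        assert snr(img, roi, bg, autofluorescence=100.0,
                   mode="mean_ratio") == pytest.approx(0.0)

    def test_noise_sd_arithmetic(self):
        img, roi, bg = self._setup(110.0, [98.0, 102.0, 98.0, 102.0])
        # bg SD = 2, roi mean - A = 10
        assert snr(img, roi, bg, autofluorescence=100.0) == pytest.approx(5.0)

    def test_negative_snr_reported_not_clipped(self):
        img, roi, bg = self._setup(90.0, [98.0, 102.0, 98.0, 102.0])
        assert snr(img, roi, bg, autofluorescence=100.0) == pytest.approx(-5.0)

    def test_zero_background_sd_raises(self):
        img, roi, bg = self._setup(110.0, [100.0, 100.0])
        with pytest.raises(DegenerateBackgroundError):
            snr(img, roi, bg, autofluorescence=100.0)

    def test_overlapping_masks_rejected(self):
        img, roi, _ = self._setup(110.0, [98.0, 102.0])
        with pytest.raises(ValidationError):
            snr(img, roi, roi, autofluorescence=100.0)

    def test_cohort_mean_near_noise_free_value(self, default_truth):
        """With subject geometry fixed, the noisy cohort mean lands close to
        the noise-free pipeline value."""
        img0, regs0 = generate_phantom(default_truth.with_noise_off(), 1.0)
        ref = {s.roi_name: s.snr for s in quantify_frame(img0, regs0)}["tumor"]
        novar = CohortVariation(center_jitter_px=0)
        frames = generate_cohort(default_truth, 5, [1.0], seed=31,
                                 variation=novar)
        got = biodistribution(frames).summary_value("tumor", 1.0)
        assert got == pytest.approx(ref, rel=0.15)


class TestBiodistribution:
    def test_row_and_summary_counts(self, default_truth):
        frames = generate_cohort(default_truth, 5, [1.0, 2.0, 4.0], seed=3)
        table = biodistribution(frames)
        # 6 quantified ROIs (hip_ref excluded) x 5 subjects x 3 timepoints
        assert len(table.measurements) == 90
        assert len(table.summary) == 18
        assert set(table.summary.n) == {5}

    def test_tumor_outranks_liver_at_every_timepoint(self, default_truth):
        frames = generate_cohort(default_truth, 5, [1.0, 2.0, 4.0], seed=3)
        table = biodistribution(frames)
        for t in (1.0, 2.0, 4.0):
            assert table.summary_value("tumor", t) > \
                table.summary_value("liver", t)

    def test_tumor_snr_plateau_1_to_4h(self, default_truth):
        frames = generate_cohort(default_truth, 5, [1.0, 2.0, 4.0], seed=3)
        table = biodistribution(frames)
        s1 = table.summary_value("tumor", 1.0)
        s4 = table.summary_value("tumor", 4.0)
        assert abs(s4 - s1) / s1 < 0.15

    def test_global_luminosity_invariance(self, default_frame):
        img, regs = default_frame
        base = {s.roi_name: s.snr for s in quantify_frame(img, regs)}
        for c in (0.1, 3.0, 10.0):
            scaled = {s.roi_name: s.snr
                      for s in quantify_frame(img.scaled(c), regs)}
            for roi, v in base.items():
                assert abs(scaled[roi] - v) <= 1e-9 * abs(v)

    def test_snr_monotone_in_tumor_amplitude_noise_free(self, default_truth):
        base = default_truth.with_noise_off()
        vals = []
        for amp in (15.0, 30.0, 45.0, 60.0, 75.0):
            img, regs = generate_phantom(base.with_tumor_amplitude(amp), 1.0)
            vals.append({s.roi_name: s.snr
                         for s in quantify_frame(img, regs)}["tumor"])
        assert np.all(np.diff(vals) > 0)

    def test_modes_rank_isolated_rois_identically(self):
        """noise_sd and mean_ratio agree on ROI ranking for well-separated
        regions with equal-width annuli (noise-free)."""
        # Four identical discs ring a central bright structure whose scattered
        # light provides every annulus with the same background; only the disc
        # amplitudes differ, so both SNR readings must order them identically.
        regions = [
            RegionSpec("gut", "disc", (70, 70), (10, 10), c_max=30.0, k_in=3.0),
            RegionSpec("roi_a", "disc", (42, 70), (5, 5), c_max=4.0, k_in=3.0),
            RegionSpec("roi_b", "disc", (98, 70), (5, 5), c_max=12.0, k_in=3.0),
            RegionSpec("roi_c", "disc", (70, 42), (5, 5), c_max=28.0, k_in=3.0),
            RegionSpec("roi_d", "disc", (70, 98), (5, 5), c_max=60.0, k_in=3.0),
            RegionSpec("hip_ref", "disc", (95, 95), (5, 5), c_max=0.0),
        ]
        truth = PhantomTruth(
            image_shape=(144, 144), body_center=(70, 70),
            body_radii=(65, 70), regions=regions, noise=NoiseModel.off(),
        )
        rois = ["roi_a", "roi_b", "roi_c", "roi_d"]
        img, regs = generate_phantom(truth, 1.0)
        by_sd = {s.roi_name: s.snr for s in quantify_frame(
            img, regs, QuantConfig(rois=rois))}
        by_mr = {s.roi_name: s.snr for s in quantify_frame(
            img, regs, QuantConfig(snr_mode="mean_ratio", rois=rois))}
        names = sorted(by_sd)
        rho = spearmanr([by_sd[n] for n in names],
                        [by_mr[n] for n in names]).statistic
        assert rho == pytest.approx(1.0)

    def test_failing_frame_dropped_not_fatal(self, default_truth):
        frames = list(generate_cohort(default_truth, 2, [1.0], seed=3))
        img, regs = frames[0]
        # strip hip_ref from one frame: its rows are dropped with a warning
        lm = regs.label_map.copy()
        lm[regs.mask("hip_ref")] = 0
        names = {k: v for k, v in regs.names.items() if v != "hip_ref"}
        broken = nq.RegionSet(lm, names, regs.aux_masks)
        table = biodistribution([(img, broken), frames[1]])
        assert set(table.measurements.subject_id) == {"m2"}

    def test_empty_input_gives_empty_table(self):
        table = biodistribution([])
        assert table.measurements.empty and table.summary.empty
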