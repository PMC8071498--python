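"""Forward model rendering and cohort simulation."""

import numpy as np
import pytest

from fingermark.calibration import fit_calibration, invert, series_from_measurements
from fingermark.color import measure
from fingermark.image_io import rectangle_mask
from fingermark.synthetic import (
    DEFAULT_STANDARD_CONCENTRATIONS,
    CohortConfig,
    ForwardModel,
    generate_cohort,
    generate_standard_series,
    noise_free,
    render_detection_window,
    sample_print_concentrations,
    write_cohort,
)

QUIET = ForwardModel(pixel_noise_sd=0.0)


def window_metrics(image, model=QUIET, tint=True):
    """Measure the known window rectangle (module-level oracle path)."""
    mask = rectangle_mask(image.shape[:2], *model.window)
    return measure(image, mask, tint=tint)


class TestRenderDetectionWindow:
    @pytest.mark.parametrize(
        "conc, expected_sat",
        [
            (0.0, 5.0),  # intercept alone
            (120.0, 83.0),  # 5 + 0.65 * 120
            (1000.0, 100.0),  # clamped at full saturation
        ],
    )
    def test_noise_free_window_saturation(self, conc, expected_sat):
        img = render_detection_window(conc, QUIET, seed=0)
        assert window_metrics(img).mean_saturation == pytest.approx(
            expected_sat, abs=0.5
        )

    def test_window_is_red_before_tint_and_background_clean(self):
        img = render_detection_window(60, QUIET, seed=0)
        x, y, w, h = QUIET.window
        window = img[y : y + h, x : x + w]
        assert np.all(window[..., 0] == 255)
        assert np.array_equal(window[..., 1], window[..., 2])  # pure red hue
        outside = img.copy()
        outside[y : y + h, x : x + w] = 255
        assert np.all(outside == 255)

    def test_deterministic_for_fixed_seed(self):
        a = render_detection_window(60, ForwardModel(), seed=42)
        b = render_detection_window(60, ForwardModel(), seed=42)
        assert np.array_equal(a, b)
        c = render_detection_window(60, ForwardModel(), seed=43)
        assert not np.array_equal(a, c)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            render_detection_window(-1, QUIET)

    def test_monotone_in_concentration_without_noise(self):
        grid = np.linspace(0, (100 - 5) / 0.65, 25)
        sats = [
            window_metrics(render_detection_window(c, QUIET)).mean_saturation
            for c in grid
        ]
        assert np.all(np.diff(sats) >= 0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"image_size": (0, 90)},
            {"window": (100, 0, 60, 40)},  # outside bounds
            {"slope": 0.0},
            {"intercept": -1.0},
            {"window": (0, 0, 1, 1)},  # < 1% of image area
        ],
    )
    def test_invalid_forward_models(self, kwargs):
        with pytest.raises(ValueError):
            ForwardModel(**kwargs)


class TestSamplePrintConcentrations:
    def test_zero_variance_returns_exact_means(self):
        cfg = CohortConfig(sd_print_female=0.0, sd_print_male=0.0)
        for sex, mu in (("female", 94.8), ("male", 54.0)):
            donors = sample_print_concentrations(cfg, sex, 5, seed=0)
            assert all(v == mu for prints in donors for v in prints)

    def test_law_of_large_numbers_female(self):
        cfg = CohortConfig(between_fraction=0.0, prints_per_donor=1)
        donors = sample_print_concentrations(cfg, "female", 10_000, seed=7)
        values = np.array([v for prints in donors for v in prints])
        assert abs(values.mean() - 94.8) < 3 * 29.3 / np.sqrt(10_000)

    def test_between_fraction_one_makes_prints_identical_within_donor(self):
        cfg = CohortConfig(between_fraction=1.0, prints_per_donor=3)
        donors = sample_print_concentrations(cfg, "male", 10, seed=1)
        for prints in donors:
            assert len(set(prints)) == 1

    def test_values_truncated_at_zero(self):
        cfg = CohortConfig(mu_male=1.0, sd_print_male=50.0)
        donors = sample_print_concentrations(cfg, "male", 200, seed=3)
        values = [v for prints in donors for v in prints]
        assert min(values) >= 0.0
        assert any(v == 0.0 for v in values)  # truncation actually happened

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError, match="unknown sex"):
            sample_print_concentrations(CohortConfig(), "other", 1)

    def test_reproducible_under_seed(self):
        cfg = CohortConfig()
        a = sample_print_concentrations(cfg, "female", 5, seed=9)
        b = sample_print_concentrations(cfg, "female", 5, seed=9)
        assert a == b


class TestGenerateCohort:
    def test_blind_study_design_counts(self):
        """11 female + 4 male donors at 3 prints each give 33 + 12 prints."""
        donors = generate_cohort(CohortConfig(), 11, 4, QUIET, seed=0)
        by_sex = {"female": 0, "male": 0}
        for d in donors:
            by_sex[d.sex] += len(d.prints)
        assert by_sex == {"female": 33, "male": 12}
        assert all(
            [p.finger for p in d.prints] == ["index", "middle", "ring"]
            for d in donors
        )

    def test_identity_settings_match_direct_rendering(self):
        cfg = CohortConfig(lifting_efficiency=1.0, powder_artifact_fraction=0.0)
        donors = generate_cohort(cfg, 1, 0, QUIET, seed=5)
        p = donors[0].prints[0]
        sat = window_metrics(p.image).mean_saturation
        assert sat == pytest.approx(
            QUIET.target_saturation(p.concentration_true), abs=0.5
        )

    def test_lifting_efficiency_halves_recovered_concentration(self):
        calib = fit_calibration(
            series_from_measurements(
                DEFAULT_STANDARD_CONCENTRATIONS,
                [
                    window_metrics(img)
                    for _, img in generate_standard_series(QUIET, seed=0)
                ],
            )
        )

        def recovered_mean(lifting):
            cfg = CohortConfig(lifting_efficiency=lifting)
            donors = generate_cohort(cfg, 50, 0, QUIET, seed=11)
            values = [
                invert(calib, window_metrics(p.image).mean_saturation).value
                for d in donors
                for p in d.prints
            ]
            return np.mean(values)

        full = recovered_mean(1.0)
        half = recovered_mean(0.5)
        assert half == pytest.approx(full / 2, rel=0.05)

    def test_powder_overwrites_window_fraction_with_dark_speckle(self):
        cfg = CohortConfig(powder_artifact_fraction=0.2, sd_print_female=0.0)
        donors = generate_cohort(cfg, 1, 0, QUIET, seed=2)
        img = donors[0].prints[0].image
        x, y, w, h = QUIET.window
        window = img[y : y + h, x : x + w]
        dark = np.all(window <= 30, axis=-1)
        assert dark.sum() == round(0.2 * w * h)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(), 0, 0, QUIET, seed=0)

    def test_seed_determinism_byte_identical_images(self):
        a = generate_cohort(CohortConfig(), 2, 1, ForwardModel(), seed=21)
        b = generate_cohort(CohortConfig(), 2, 1, ForwardModel(), seed=21)
        for da, db in zip(a, b):
            assert da.donor_id == db.donor_id and da.sex == db.sex
            for pa, pb in zip(da.prints, db.prints):
                assert pa.concentration_true == pb.concentration_true
                assert np.array_equal(pa.image, pb.image)


class TestStandardSeries:
    def test_default_series_has_six_images(self):
        pairs = generate_standard_series(QUIET, seed=0)
        assert len(pairs) == 6
        assert [c for c, _ in pairs] == list(DEFAULT_STANDARD_CONCENTRATIONS)

    def test_endpoint_saturations_match_forward_model(self):
        pairs = generate_standard_series(QUIET, [0, 100], seed=0)
        sats = [window_metrics(img).mean_saturation for _, img in pairs]
        assert sats[0] == pytest.approx(5.0, abs=0.5)
        assert sats[1] == pytest.approx(5.0 + 100 * 0.65, abs=0.5)

    def test_duplicate_only_concentrations_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            generate_standard_series(QUIET, [50, 50])


class TestRoundTrip:
    @pytest.mark.parametrize("noise_sd", [0.0, 2.0])
    def test_render_measure_invert_recovers_concentration(self, noise_sd):
        """|invert(fit(series), measure(render(C))) - C| <= 3 µM."""
        model = ForwardModel(pixel_noise_sd=noise_sd)
        pairs = generate_standard_series(model, seed=0)
        calib = fit_calibration(
            series_from_measurements(
                [c for c, _ in pairs], [window_metrics(img) for _, img in pairs]
            )
        )
        for c in DEFAULT_STANDARD_CONCENTRATIONS:
            img = render_detection_window(c, model, seed=int(c))
            est = invert(calib, window_metrics(img).mean_saturation)
            assert abs(est.value - c) <= 3.0


class TestWriteCohort:
    def test_manifest_and_images_written(self, tmp_path):
        donors = generate_cohort(CohortConfig(), 2, 1, QUIET, seed=0)
        manifest = write_cohort(donors, tmp_path / "out", image_format="png")
        lines = manifest.read_text().strip().splitlines()
        assert lines[0] == "donor_id,sex,finger,concentration_true,image_path"
        assert len(lines) == 1 + 9  # 3 donors x 3 prints
        for line in lines[1:]:
            rel = line.split(",")[-1]
            assert (tmp_path / "out" / rel).exists()

    def test_unknown_format_rejected(self, tmp_path):
        donors = generate_cohort(CohortConfig(), 1, 0, QUIET, seed=0)
        with pytest.raises(ValueError, match="format"):
            write_cohort(donors, tmp_path, image_format="bmp")


def test_cohort_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(between_fraction=1.5)
    with pytest.raises(ValueError):
        CohortConfig(lifting_efficiency=0.0)
    with pytest.raises(ValueError):
        CohortConfig(powder_artifact_fraction=0.5)
    with pytest.raises(ValueError):
        CohortConfig(prints_per_donor=0)
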