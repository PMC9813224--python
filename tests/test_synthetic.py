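"""Generator correctness: axes, peak tables, spectra, cohorts, maps, AFP."""

import numpy as np
import pandas as pd
import pytest

import ramanhisto as rh
from ramanhisto.core import SpectralAxis, make_axis
from ramanhisto.profiles import TissueClassProfile, combine_profiles
from ramanhisto.synthetic import (
    ZERO_BASELINE,
    BaselineParams,
    CohortConfig,
    generate_afp,
    generate_cohort,
    generate_map,
    generate_spectrum,
    generate_zstack,
    pure_spectrum,
)

FING = rh.FINGERPRINT_AXIS


class TestAxis:
    @pytest.mark.parametrize(
        "start,stop,n,spacing",
        [
            (500, 2000, 889, 1500 / 888),
            (0, 1, 2, 1.0),
            (2000, 3400, 701, 2.0),
        ],
    )
    def test_uniform_grid_including_endpoints(self, start, stop, n, spacing):
        ax = make_axis(start, stop, n)
        grid = ax.grid
        assert len(grid) == n
        assert grid[0] == start and grid[-1] == stop
        assert np.allclose(np.diff(grid), spacing)
        assert np.all(np.diff(grid) > 0)

    @pytest.mark.parametrize("bad", [(2000, 500, 10), (500, 500, 10), (500, 2000, 1)])
    def test_invalid_axis_rejected(self, bad):
        with pytest.raises(ValueError):
            make_axis(*bad)


class TestPeakTables:
    def test_fingerprint_table_has_19_bands_on_axis(self, peaks):
        assert len(peaks) == 19
        assert all(500 <= p.center <= 2000 for p in peaks)
        named = {749, 1212, 1393, 1547, 1586, 1602, 1637, 1003, 1156, 1519,
                 1081, 1130, 1304, 674, 974, 1336, 1356, 835}
        assert named <= {p.center for p in peaks}

    def test_carotenoid_assignment(self, peaks):
        by_center = {p.center: p for p in peaks}
        for c in (1003, 1156, 1519):
            assert "carotenoid" in by_center[c].assignment

    def test_configurable_19th_band(self):
        table = rh.default_peak_table(extra_center=1440.0)
        assert 1440.0 in {p.center for p in table}
        assert len(table) == 19

    def test_highwavenumber_table(self):
        table = rh.highwavenumber_peak_table()
        assert len(table) == 4
        assert all(2000 <= p.center <= 3400 for p in table)
        protein = [p.center for p in table if "protein" in p.assignment]
        lipid = [p.center for p in table if "lipid" in p.assignment]
        assert protein == [2930.0]
        assert sorted(lipid) == [2855.0, 2885.0, 3007.0]


class TestGenerateSpectrum:
    def test_single_peak_identity(self):
        axis = make_axis(900, 1100, 201)
        peak = rh.PeakDefinition(center=1000.0, base_amplitude=5.0)
        profile = TissueClassProfile("x", {1000.0: 2.0}, global_scale=3.0)
        spec = generate_spectrum(profile, [peak], axis, patient_effect=0.5)
        assert spec.intensities.argmax() == axis.index_of(1000.0)
        assert spec.intensities.max() == pytest.approx(5.0 * 2.0 * 3.0 * 0.5)

    def test_paracancer_dominates_cancer_at_every_band(self, profiles, peaks):
        para = pure_spectrum(profiles["paracancer"], peaks, FING)
        for subtype in ("HCC", "ICC"):
            cancer = pure_spectrum(profiles[subtype], peaks, FING)
            idx = [FING.index_of(p.center) for p in peaks]
            assert np.all(para[idx] > cancer[idx])

    def test_integral_matches_analytic_gaussian_area(self, peaks, profiles):
        spec = pure_spectrum(profiles["paracancer"], peaks, FING)
        integral = np.trapezoid(spec, FING.grid)
        sigma = 12.0 / (2 * np.sqrt(2 * np.log(2)))
        analytic = sum(p.base_amplitude * sigma * np.sqrt(2 * np.pi) for p in peaks)
        assert integral == pytest.approx(analytic, rel=0.01)

    def test_off_axis_peak_rejected(self):
        axis = make_axis(900, 1100, 101)
        with pytest.raises(ValueError):
            generate_spectrum(
                TissueClassProfile("x"), [rh.PeakDefinition(center=2000.0)], axis
            )

    def test_noise_and_baseline_reproducible_from_seed(self, profiles, peaks):
        a = generate_spectrum(profiles["HCC"], peaks, FING, rng=5, noise_sd=10,
                              baseline=BaselineParams())
        b = generate_spectrum(profiles["HCC"], peaks, FING, rng=5, noise_sd=10,
                              baseline=BaselineParams())
        assert np.array_equal(a.intensities, b.intensities)
        assert np.all(a.intensities >= 0)


class TestCohort:
    def test_default_study_design(self):
        cfg = CohortConfig()
        assert cfg.n_patients == 120 and cfg.n_hcc == 98 and cfg.n_icc == 22
        assert cfg.spectra_per_sample == 50
        # 120 pairs x 2 samples x 50 spectra = 12,000 without generating them all

    def test_small_cohort_structure(self, small_cohort):
        meta = small_cohort.meta
        assert len(small_cohort) == 12 * 2 * 10
        assert meta["sample_id"].nunique() == 24
        assert meta[meta.subtype == "HCC"]["patient_id"].nunique() == 9
        assert meta[meta.subtype == "ICC"]["patient_id"].nunique() == 3
        # every patient contributes exactly one cancer and one paracancer sample
        per_patient = meta.groupby("patient_id")["tissue"].nunique()
        assert (per_patient == 2).all()
        # patient intensity factor is shared across a patient's spectra
        assert (meta.groupby("patient_id")["patient_effect"].nunique() == 1).all()

    def test_minimal_cohort(self):
        cfg = CohortConfig(n_patients=1, n_hcc=1, n_icc=0, spectra_per_sample=1, seed=0)
        ds = generate_cohort(cfg)
        assert len(ds) == 2
        assert ds.meta["patient_id"].nunique() == 1

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(n_patients=10, n_hcc=5, n_icc=4))

    def test_bit_identical_replication_from_seed(self):
        cfg = CohortConfig(n_patients=4, n_hcc=3, n_icc=1, spectra_per_sample=3, seed=9)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert np.array_equal(a.X, b.X)
        pd.testing.assert_frame_equal(a.meta, b.meta)


@pytest.fixture(scope="module")
def class_means(peaks, profiles):
    rng = np.random.default_rng(123)
    means = {}
    for label in ("paracancer", "HCC", "ICC", "early_stage", "advanced_stage"):
        if label in ("early_stage", "advanced_stage"):
            profile = combine_profiles(profiles["HCC"], profiles[label])
        else:
            profile = profiles[label]
        block = np.vstack([
            generate_spectrum(
                profile, peaks, FING,
                patient_effect=float(np.exp(rng.normal(0, 0.15))),
                rng=rng, noise_sd=12.0, baseline=ZERO_BASELINE,
            ).intensities
            for _ in range(1000)
        ])
        means[label] = block.mean(axis=0)
    return means


class TestClassContrasts:
    """Mean spectra over many generated spectra honour the class orderings."""

    def _at(self, spectrum, centers):
        return np.array([spectrum[FING.index_of(c)] for c in centers])

    def test_paracancer_above_cancer_at_all_19_bands(self, class_means, peaks):
        centers = [p.center for p in peaks]
        for cancer in ("HCC", "ICC"):
            assert np.all(
                self._at(class_means["paracancer"], centers)
                > self._at(class_means[cancer], centers)
            )

    def test_subtype_contrast(self, class_means):
        up = [1003, 1156, 1519]
        down = [749, 974, 1304, 1356, 1393, 1586]
        assert np.all(self._at(class_means["ICC"], up) > self._at(class_means["HCC"], up))
        assert np.all(self._at(class_means["ICC"], down) < self._at(class_means["HCC"], down))

    def test_stage_contrast(self, class_means):
        up = [1003, 1156, 1519, 1130, 749, 1547]
        down = [674, 974, 835]
        early, adv = class_means["early_stage"], class_means["advanced_stage"]
        assert np.all(self._at(early, up) > self._at(adv, up))
        assert np.all(self._at(early, down) < self._at(adv, down))


class TestMaps:
    def test_single_component_noiseless_identity(self, profiles, peaks):
        layout = np.zeros((4, 5), dtype=int)
        m = generate_map([profiles["paracancer"]], layout, FING, noise_sd=0.0)
        expected = pure_spectrum(profiles["paracancer"], peaks, FING)
        assert np.allclose(m.cube, expected[None, None, :])

    def test_soft_layout_mixes_linearly(self, profiles, peaks):
        frac = np.zeros((2, 2, 2))
        frac[..., 0] = [[1.0, 0.5], [0.0, 0.25]]
        frac[..., 1] = 1.0 - frac[..., 0]
        m = generate_map([profiles["paracancer"], profiles["HCC"]], frac, FING, noise_sd=0.0)
        s0 = pure_spectrum(profiles["paracancer"], peaks, FING)
        s1 = pure_spectrum(profiles["HCC"], peaks, FING)
        assert np.allclose(m.cube[0, 1], 0.5 * s0 + 0.5 * s1)
        assert np.allclose(m.cube[1, 1], 0.25 * s0 + 0.75 * s1)

    def test_map_geometry_and_ground_truth(self, margin_phantom):
        assert margin_phantom.shape == (25, 25)
        assert margin_phantom.pixel_size == 2.0  # 50 x 50 um field at 2 um steps
        gt = margin_phantom.ground_truth
        assert gt["fractions"].shape == (25, 25, 2)
        assert np.allclose(gt["fractions"].sum(axis=2), 1.0)
        # noiseless cube is exactly the fraction-weighted mixture of the truth
        mixed = gt["fractions"] @ gt["pure_spectra"]
        assert np.allclose(margin_phantom.cube, mixed)

    def test_layout_label_mismatch_rejected(self, profiles):
        layout = np.full((3, 3), 5)
        with pytest.raises(ValueError):
            generate_map([profiles["paracancer"]], layout, FING)


class TestZStack:
    def test_default_six_planes_5um(self, margin_phantom):
        stack = generate_zstack(margin_phantom)
        assert stack.n_planes == 6
        assert stack.z_spacing == 5.0
        assert stack.cube.shape == (6, 25, 25, FING.n_points)

    def test_no_attenuation_copies_planes(self, margin_phantom):
        stack = generate_zstack(margin_phantom, depth_attenuation=1.0, noise_sd=0.0)
        for z in range(stack.n_planes):
            assert np.array_equal(stack.cube[z], margin_phantom.cube)

    def test_geometric_intensity_decay(self, margin_phantom):
        stack = generate_zstack(margin_phantom, depth_attenuation=0.5, noise_sd=0.0)
        base = stack.cube[0].mean()
        for p in range(stack.n_planes):
            assert stack.cube[p].mean() == pytest.approx(0.5**p * base)


class TestAFP:
    @pytest.mark.parametrize("rate,expect", [(0.0, 0), (1.0, 92)])
    def test_degenerate_rates(self, rate, expect):
        cfg = CohortConfig(n_patients=92, n_hcc=92, n_icc=0, spectra_per_sample=1, seed=3)
        cohort = generate_cohort(cfg)
        table = generate_afp(cohort, positive_rate_hcc=rate, rng=1)
        assert int((table["afp_ng_ml"] > 200).sum()) == expect

    def test_expected_positive_count_matches_rate(self):
        cfg = CohortConfig(n_patients=92, n_hcc=92, n_icc=0, spectra_per_sample=1, seed=3)
        cohort = generate_cohort(cfg)
        rng = np.random.default_rng(7)
        counts = [
            int((generate_afp(cohort, 25 / 92, rng=rng)["afp_ng_ml"] > 200).sum())
            for _ in range(200)
        ]
        # binomial(92, 25/92): mean 25, sd ~4.3; the mean of 200 replicates
        # has sd ~0.3, so a 1-unit tolerance is ~3 sigma
        assert np.mean(counts) == pytest.approx(25, abs=1.0)

    def test_requires_hcc_patients(self):
        cfg = CohortConfig(n_patients=2, n_hcc=0, n_icc=2, spectra_per_sample=1, seed=0)
        with pytest.raises(ValueError):
            generate_afp(generate_cohort(cfg), rng=0)
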