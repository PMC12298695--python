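"""Generator behaviour: determinism, composition arithmetic, mixing algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbfp.errors import ConfigurationError, GridError, ParameterError
from herbfp.synthetic import (
    DEFAULT_RATIOS,
    GeneratorConfig,
    MatrixProfile,
    PeakSpec,
    TriturationDesign,
    generate_blank,
    generate_paired_blocks,
    generate_reference,
    generate_study,
    make_trituration,
    random_profiles,
    render_peaks,
)

NOISELESS = GeneratorConfig(noise_scale=0.0, noise_floor=0.0, points_per_min=40)


class TestPeakSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"retention_time": 5.0, "width": 0.0, "height": 1.0, "mz": 100.0},
            {"retention_time": 5.0, "width": 0.05, "height": -1.0, "mz": 100.0},
            {"retention_time": 5.0, "width": 0.05, "height": 1.0, "mz": 30.0},
            {"retention_time": 5.0, "width": 0.05, "height": 1.0, "mz": 2500.0},
        ],
    )
    def test_invalid_peaks_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            PeakSpec(**kwargs)

    def test_matrix_profile_needs_a_peak(self):
        with pytest.raises(ConfigurationError):
            MatrixProfile(matrix_id="m", peaks=(), baseline_level=1.0)


class TestReference:
    def test_deterministic_under_seed(self):
        a = generate_reference(seed=1, n_signature_peaks=5, config=NOISELESS)
        b = generate_reference(seed=1, n_signature_peaks=5, config=NOISELESS)
        assert np.array_equal(a.intensities, b.intensities)
        assert np.array_equal(a.masses, b.masses)

    def test_seed_sensitivity(self):
        a = generate_reference(seed=1, config=NOISELESS)
        b = generate_reference(seed=2, config=NOISELESS)
        rts_a = sorted(p.retention_time for p in a.metadata["peaks"])
        rts_b = sorted(p.retention_time for p in b.metadata["peaks"])
        assert rts_a != rts_b

    def test_noiseless_local_maxima_count_matches_peaks(self):
        n = 5
        fp = generate_reference(seed=1, n_signature_peaks=n, config=NOISELESS)
        sig = fp.intensities
        d = np.diff(sig)
        apex = (d[:-1] > 0) & (d[1:] <= 0) & (sig[1:-1] > NOISELESS.reference_baseline + 0.5)
        assert int(apex.sum()) == n

    def test_too_few_signature_peaks_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_reference(seed=1, n_signature_peaks=2, config=NOISELESS)

    def test_bad_instrument_config_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(points_per_min=0)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(run_start=5.0, run_end=5.0)


class TestBlank:
    def test_noiseless_blank_reconstructs_profile(self):
        grid = NOISELESS.time_grid()
        peaks = (
            PeakSpec(retention_time=4.0, width=0.1, height=50.0, mz=400.0),
            PeakSpec(retention_time=8.0, width=0.2, height=20.0, mz=900.0),
        )
        profile = MatrixProfile(matrix_id="m1", peaks=peaks, baseline_level=3.0)
        fp = generate_blank(profile, seed=0, config=NOISELESS)
        expected = np.full(grid.size, 3.0)
        for p in peaks:
            expected += p.height * np.exp(-0.5 * ((grid - p.retention_time) / p.width) ** 2)
        assert np.max(np.abs(fp.intensities - expected)) == pytest.approx(0.0, abs=1e-12)
        assert fp.metadata["class"] == 2

    def test_distinct_profiles_are_not_identical(self):
        profiles = random_profiles(3, seed=0, config=NOISELESS)
        a = generate_blank(profiles[0], seed=0, config=NOISELESS)
        b = generate_blank(profiles[1], seed=0, config=NOISELESS)
        corr = np.corrcoef(a.intensities, b.intensities)[0, 1]
        assert corr < 1.0

    def test_zero_peaks_zero_noise_gives_flat_baseline(self):
        grid = NOISELESS.time_grid()
        intensity, mass = render_peaks([], baseline=4.5, grid=grid)
        assert np.all(intensity == 4.5)
        assert np.all(mass == 0.0)


class TestTrituration:
    def _pair(self):
        profiles = random_profiles(2, seed=3, config=NOISELESS)
        blank = generate_blank(profiles[0], seed=0, config=NOISELESS)
        ref = generate_reference(seed=1, config=NOISELESS)
        return blank, ref

    def test_half_ratio_is_exact_average(self):
        blank, ref = self._pair()
        trit = make_trituration(blank, ref, ratio=0.5, config=NOISELESS)
        expected = 0.5 * (blank.intensities + ref.intensities)
        assert np.max(np.abs(trit.intensities - expected)) == pytest.approx(0.0, abs=1e-12)
        assert trit.metadata["class"] == 1

    def test_small_ratio_approaches_blank(self):
        blank, ref = self._pair()
        trit = make_trituration(blank, ref, ratio=1e-9, config=NOISELESS)
        assert np.allclose(trit.intensities, blank.intensities, rtol=1e-6, atol=1e-4)

    def test_correlation_with_reference_increases_in_ratio(self):
        blank, ref = self._pair()
        cors = []
        for r in DEFAULT_RATIOS:
            trit = make_trituration(blank, ref, ratio=r, config=NOISELESS)
            cors.append(np.corrcoef(trit.intensities, ref.intensities)[0, 1])
        assert all(b > a for a, b in zip(cors, cors[1:]))

    def test_invalid_ratio_rejected(self):
        blank, ref = self._pair()
        for r in (0.0, 1.0, -0.2, 1.7):
            with pytest.raises(ParameterError):
                make_trituration(blank, ref, ratio=r, config=NOISELESS)

    def test_mismatched_grids_rejected(self):
        blank, _ = self._pair()
        other = generate_reference(seed=1, config=GeneratorConfig(points_per_min=37))
        with pytest.raises(GridError):
            make_trituration(blank, other, ratio=0.5)

    def test_mass_channel_tracks_dominant_component(self):
        blank, ref = self._pair()
        trit = make_trituration(blank, ref, ratio=0.5, config=NOISELESS)
        ref_part = 0.5 * ref.intensities
        blank_part = 0.5 * blank.intensities
        expected = np.where(ref_part >= blank_part, ref.masses, blank.masses)
        assert np.array_equal(trit.masses, expected)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(ratio=st.floats(min_value=0.01, max_value=0.99))
    def test_convex_combination_for_any_ratio(self, ratio):
        blank, ref = self._pair()
        trit = make_trituration(blank, ref, ratio=ratio, config=NOISELESS)
        expected = ratio * ref.intensities + (1 - ratio) * blank.intensities
        assert np.max(np.abs(trit.intensities - expected)) < 1e-10


class TestStudy:
    def test_default_study_composition(self, small_config):
        ds = generate_study(config=small_config)
        roles = ds.manifest["role"].value_counts()
        assert len(ds) == 67
        assert roles["trituration"] == 55
        assert roles["blank"] == 11
        assert roles["reference"] == 1
        y = ds.classes()
        assert (y == 1).sum() == 56
        assert (y == 2).sum() == 11

    def test_small_design_arithmetic(self):
        design = TriturationDesign(n_matrices=2, ratios=(1 / 10, 1 / 2), seed=0)
        ds = generate_study(design, config=NOISELESS)
        assert len(ds) == 2 * 2 + 2 + 1

    def test_study_is_deterministic(self, small_design, small_config):
        a = generate_study(small_design, config=small_config)
        b = generate_study(small_design, config=small_config)
        for fa, fb in zip(a.fingerprints, b.fingerprints):
            assert np.array_equal(fa.intensities, fb.intensities)
            assert np.array_equal(fa.masses, fb.masses)
        assert a.manifest.equals(b.manifest)

    def test_triturations_carry_their_matrix_and_ratio(self, small_study, small_design):
        trits = small_study.manifest[small_study.manifest["role"] == "trituration"]
        assert set(np.round(trits["ratio"], 6)) == {round(r, 6) for r in small_design.ratios}
        assert trits["matrix_id"].nunique() == small_design.n_matrices


class TestPairedBlocks:
    def test_blocks_share_samples_and_classes(self, small_design, small_config):
        a, b = generate_paired_blocks(small_design, config_a=small_config)
        ids_a = [fp.sample_id for fp in a.fingerprints]
        ids_b = [fp.sample_id for fp in b.fingerprints]
        assert ids_a == ids_b
        assert np.array_equal(a.classes(), b.classes())

    def test_blocks_have_different_grids(self, small_design, small_config):
        a, b = generate_paired_blocks(small_design, config_a=small_config)
        assert len(a.fingerprints[0]) != len(b.fingerprints[0])
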