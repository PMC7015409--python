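"""Synthetic storage-trial generator: trajectories, noise, determinism."""

import dataclasses

import numpy as np
import pytest

from phytoshelf import (
    StudyDesign,
    TrajectorySpec,
    default_trajectories,
    fit_linear,
    fit_quadratic,
    generate,
    mean_response,
    noise_free,
    to_series,
)
from phytoshelf.exceptions import ConfigurationError
from phytoshelf.simulate import FLAT, NEGATIVE_LINEAR, POSITIVE_QUADRATIC


class TestDefaultTrajectories:
    def test_tropical_cua_uses_printed_parabola(self):
        spec = default_trajectories()[("cuA", 52, "tropical")]
        assert spec.shape == POSITIVE_QUADRATIC
        assert spec.coefficients == (-0.0594, 0.2275, 0.3876)

    def test_chilled_cua_declines_linearly(self):
        spec = default_trajectories()[("cuA", 52, "chilled")]
        assert spec.shape == NEGATIVE_LINEAR
        assert spec.coefficients[0] < 0

    def test_high_drying_temperature_cells_are_flat_near_zero(self):
        trajs = default_trajectories()
        for cell, spec in trajs.items():
            if cell[1] == 100:
                assert spec.shape == FLAT
                assert 0 <= spec.coefficients[0] <= 0.2

    def test_cub_cells_are_positive_quadratic(self):
        trajs = default_trajectories()
        for cond in ("tropical", "chilled"):
            spec = trajs[("cuB", 52, cond)]
            assert spec.shape == POSITIVE_QUADRATIC
            a, b, _ = spec.coefficients
            assert a < 0 < b

    def test_cub_tropical_shelf_life_extrapolates_beyond_grid(self):
        a, b, _ = default_trajectories()[("cuB", 52, "tropical")].coefficients
        assert -b / a > 5  # x3 beyond the observed log3 range


class TestTrajectorySpecValidation:
    @pytest.mark.parametrize(
        "shape, coef",
        [
            (POSITIVE_QUADRATIC, (0.1, 0.2, 0.3)),  # a must be < 0
            (POSITIVE_QUADRATIC, (-0.1, -0.2, 0.3)),  # b must be > 0
            (NEGATIVE_LINEAR, (0.1, 0.3)),  # slope must be < 0
            (FLAT, (-0.5,)),  # level must be >= 0
            ("cubic", (1.0, 1.0, 1.0, 1.0)),
        ],
    )
    def test_invalid_specs_rejected(self, shape, coef):
        with pytest.raises(ConfigurationError):
            TrajectorySpec(shape, coef)


class TestMeanResponse:
    QUAD = TrajectorySpec(POSITIVE_QUADRATIC, (-0.0594, 0.2275, 0.3876))

    def test_intercept_is_initial_concentration(self):
        assert mean_response(self.QUAD, 0.0) == pytest.approx(0.3876)

    def test_vertex_value(self):
        # c - b^2/(4a) evaluated at the vertex x = -b/(2a) = 1.9149
        assert mean_response(self.QUAD, 1.9149) == pytest.approx(0.6054, abs=1e-3)

    def test_flat_is_constant(self):
        spec = TrajectorySpec(FLAT, (0.1,))
        assert mean_response(spec, 0.0) == mean_response(spec, 4.7) == 0.1

    def test_clipped_at_zero(self):
        spec = TrajectorySpec(NEGATIVE_LINEAR, (-1.0, 0.5))
        assert mean_response(spec, 3.0) == 0.0

    def test_negative_x_rejected(self):
        with pytest.raises(ValueError):
            mean_response(self.QUAD, -0.1)


class TestGenerate:
    def test_default_sample_count(self, noisy_samples):
        assert len(noisy_samples) == 2 * 2 * 2 * 6 * 10  # 480

    def test_noise_free_replicates_equal_mean_response(self, noise_free_samples):
        trajs = default_trajectories()
        for (comp, temp, cond), grp in noise_free_samples.groupby(
            ["compound", "drying_temp_C", "condition"]
        ):
            spec = trajs[(comp, temp, cond)]
            for _, row in grp.iterrows():
                from phytoshelf import encode_time

                mu = mean_response(spec, encode_time(row.time_weeks))
                assert row.concentration_ug_per_ml == pytest.approx(mu, abs=1e-12)

    def test_same_seed_is_byte_identical(self):
        a = generate(StudyDesign(seed=3)).to_csv(index=False)
        b = generate(StudyDesign(seed=3)).to_csv(index=False)
        assert a == b

    def test_different_seeds_differ(self):
        a = generate(StudyDesign(seed=3))
        b = generate(StudyDesign(seed=4))
        assert not np.allclose(
            a["concentration_ug_per_ml"], b["concentration_ug_per_ml"]
        )

    def test_concentrations_never_negative_and_clips_counted(self):
        df = generate(StudyDesign(seed=0, noise_sd=2.0))
        assert (df["concentration_ug_per_ml"] >= 0).all()
        assert df.attrs["n_clipped"] > 0

    def test_cell_draws_invariant_under_design_subsetting(self):
        full = generate(StudyDesign(seed=5))
        sub = generate(StudyDesign(seed=5, compounds=("cuB",)))
        cell = lambda df: df[
            (df.compound == "cuB") & (df.drying_temp_C == 52) & (df.condition == "chilled")
        ]["concentration_ug_per_ml"].to_numpy()
        assert np.array_equal(cell(full), cell(sub))

    def test_missing_trajectory_is_configuration_error(self):
        trajs = default_trajectories()
        del trajs[("cuB", 100, "chilled")]
        with pytest.raises(ConfigurationError):
            generate(StudyDesign(seed=0), trajs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(time_frames_weeks=(0.0, 3.0, 3.0)),  # not strictly increasing
            dict(time_frames_weeks=(-1.0, 3.0)),
            dict(n_replicates=1),
            dict(noise_sd=-0.1),
        ],
    )
    def test_invalid_design_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            StudyDesign(seed=0, **kwargs)


class TestFitRecovery:
    """Noise-free data refits to the generating coefficients exactly."""

    def test_quadratic_cells_recover_generating_coefficients(self, noise_free_samples):
        trajs = default_trajectories()
        for cell in [("cuA", 52, "tropical"), ("cuB", 52, "tropical"), ("cuB", 52, "chilled")]:
            series = to_series(noise_free_samples, cell, "per_time_means")
            model = fit_quadratic(series)
            a, b, c = trajs[cell].coefficients
            assert model.a == pytest.approx(a, abs=1e-9)
            assert model.b == pytest.approx(b, abs=1e-9)
            assert model.c == pytest.approx(c, abs=1e-9)
            assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_linear_cell_recovers_generating_coefficients(self, noise_free_samples):
        series = to_series(noise_free_samples, ("cuA", 52, "chilled"), "per_time_means")
        model = fit_linear(series)
        slope, intercept = default_trajectories()[("cuA", 52, "chilled")].coefficients
        assert model.slope == pytest.approx(slope, abs=1e-9)
        assert model.intercept == pytest.approx(intercept, abs=1e-9)


def test_noise_free_helper_zeroes_noise():
    d = noise_free(StudyDesign(seed=0))
    assert d.noise_sd == 0.0 and d.ph_jitter_sd == 0.0
    assert dataclasses.replace(d, noise_sd=0.23).noise_sd == 0.23
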