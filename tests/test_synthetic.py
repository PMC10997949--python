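"""Synthetic tap-observation generator: determinism, calibration, structure."""

import numpy as np
import pytest

from swss_hrt import (
    GeneratorParams,
    calibrate_noise_sd,
    generate_observations,
    linfit,
    observations_to_frame,
    sample_demands,
    study_layout_fixtures,
    validate_topology,
)
from swss_hrt.errors import CalibrationError, InvalidDemandError
from swss_hrt.synthetic import assign_bands, band_of_monthly


class TestDemandSampling:
    def test_deterministic_per_seed(self):
        floors = list(range(6, 20))
        for _ in range(2):
            rng = np.random.default_rng(7)
            bands = assign_bands(floors, rng)
            d = sample_demands(floors, bands, rng)
        rng = np.random.default_rng(7)
        bands2 = assign_bands(floors, rng)
        d2 = sample_demands(floors, bands2, rng)
        assert d == d2 and bands == bands2

    def test_band_supports(self):
        floors = list(range(100))
        rng = np.random.default_rng(1)
        bands = {f: ("low" if f < 50 else "high") for f in floors}
        d = sample_demands(floors, bands, rng)
        assert all(1.0 <= d[f] <= 5.0 for f in floors[:50])
        assert all(10.0 <= d[f] <= 14.0 for f in floors[50:])

    def test_low_band_mean(self):
        floors = list(range(10_000))
        rng = np.random.default_rng(3)
        d = sample_demands(floors, {f: "low" for f in floors}, rng)
        # uniform(1, 5) has mean 3; MC error ~ 3*sd/sqrt(n) ~ 0.035
        assert np.mean(list(d.values())) == pytest.approx(3.0, abs=0.05)

    def test_empty_floor_set_rejected(self):
        with pytest.raises(InvalidDemandError):
            sample_demands([], {}, np.random.default_rng(0))


class TestNoiseCalibration:
    def test_algebraic_identity_at_half(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        sd = calibrate_noise_sd(2.0, x, 0.5)
        assert sd**2 == pytest.approx(4.0 * np.var(x), rel=1e-12)

    def test_perfect_r2_limit(self):
        x = np.array([1.0, 2.0, 3.0])
        assert calibrate_noise_sd(1.0, x, 1 - 1e-12) == pytest.approx(0.0, abs=1e-5)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7])
    def test_target_outside_unit_interval(self, bad):
        with pytest.raises(CalibrationError):
            calibrate_noise_sd(1.0, [1.0, 2.0], bad)

    def test_constant_design_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_noise_sd(1.0, [2.0, 2.0, 2.0], 0.5)

    def test_large_n_sample_r2_hits_target(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(4.0, 12.0, size=10_000)
        slope, target = 0.3, 0.63
        sd = calibrate_noise_sd(slope, x, target)
        y = slope * x + rng.normal(0, sd, size=len(x))
        _, _, r2 = linfit(x, y)
        assert r2 == pytest.approx(target, abs=0.02)


class TestGenerateObservations:
    def test_byte_identical_tables_per_seed(self, office):
        params = GeneratorParams(seed=42)
        a = observations_to_frame(generate_observations(office, params))
        b = observations_to_frame(generate_observations(office, params))
        assert a.to_csv(index=False) == b.to_csv(index=False)
        c = observations_to_frame(
            generate_observations(office, GeneratorParams(seed=43))
        )
        assert a.to_csv(index=False) != c.to_csv(index=False)

    def test_zero_noise_gives_exact_linear_response(self, office):
        params = GeneratorParams(seed=0, noise_sd_16s=0.0)
        df = observations_to_frame(generate_observations(office, params))
        _, _, r2 = linfit(df.hrt_h, df.log10_16s)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(
            df.log10_16s, params.intercept_16s + params.slope_16s * df.hrt_h
        )

    def test_pumped_zone_has_higher_16s(self, office):
        # beta > 0 and systematically longer retention on the pumped upper
        # zone pushes its mean log abundance above the gravity zone's
        params = GeneratorParams(seed=5)
        df = observations_to_frame(generate_observations(office, params))
        means = df.groupby("supply_label")["log10_16s"].mean()
        assert means["swss-second"] > means["swss-first"]

    def test_bands_consistent_with_labels(self, office):
        df = observations_to_frame(
            generate_observations(office, GeneratorParams(seed=9))
        )
        assert set(df.consumption_band) <= {"low", "high"}
        assert (df.fe >= 0).all() and (df.zn >= 0).all() and (df.cu >= 0).all()

    def test_metal_levels_track_pipe_material(self):
        office, residential = study_layout_fixtures()
        df_o = observations_to_frame(
            generate_observations(office, GeneratorParams(seed=21))
        )
        df_r = observations_to_frame(
            generate_observations(residential, GeneratorParams(seed=21))
        )
        assert df_o.zn.mean() > df_r.zn.mean()   # galvanized steel sheds Zn
        assert df_r.cu.mean() > df_o.cu.mean()   # brass fittings shed Cu

    def test_slope_recovery_is_unbiased(self, residential):
        floors = list(range(3, 34))
        true_beta = GeneratorParams().slope_16s
        est = []
        for rep in range(150):
            obs = generate_observations(
                residential, GeneratorParams(seed=1_000 + rep), floors=floors
            )
            df = observations_to_frame(obs)
            s, _, _ = linfit(df.hrt_h, df.log10_16s)
            est.append(s)
        est = np.asarray(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - true_beta) < 2 * se + 1e-12


class TestStudyLayouts:
    def test_zone_ranges(self):
        office, residential = study_layout_fixtures()
        assert [z.served_floors for z in office.zones] == [(6, 23), (24, 34)]
        assert [z.served_floors for z in residential.zones] == [(3, 30), (31, 45)]

    def test_both_layouts_validate(self):
        for topo in study_layout_fixtures():
            assert validate_topology(topo) == []

    def test_band_classifier(self):
        assert band_of_monthly(3.0) == "low"
        assert band_of_monthly(12.0) == "high"
        assert band_of_monthly(7.5) == "other"
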