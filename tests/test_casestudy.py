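"""Two-site closed forms, decoding-time coarse-graining and calibration."""

import numpy as np
import pytest

from rfmnet import (
    DecodingProfile,
    NetworkSpec,
    PoolFunction,
    RateProfile,
    approx_tpr,
    calibrate_pool_coupling,
    coarse_grain_rates,
    invert_total_density,
    solve_equilibrium,
    spectral_steady_state,
    sweep_experiment,
    synthesize_decoding_times,
    total_density_identity,
    two_site_closed_forms,
)


class TestTwoSiteClosedForms:
    def test_unit_parameter(self):
        ss = two_site_closed_forms(1.0)
        golden = (1.0 + np.sqrt(5.0)) / 2.0
        assert ss.sigma == pytest.approx(golden, abs=1e-12)
        assert ss.e1 == pytest.approx(golden - 1.0, abs=1e-7)
        assert ss.e2 == pytest.approx(2.0 - golden, abs=1e-7)

    def test_production_rate_is_inverse_square_root(self):
        for c in (0.05, 0.7, 3.0, 40.0):
            ss = two_site_closed_forms(c)
            assert ss.R == pytest.approx(ss.sigma ** -2, rel=1e-14)

    def test_flooded_limit(self):
        ss = two_site_closed_forms(1e-8)
        assert ss.e1 == pytest.approx(1.0, abs=1e-6)
        assert ss.e2 == pytest.approx(0.5, abs=1e-6)

    def test_agrees_with_spectral_solver(self, homogeneous_two_site):
        """c = e_z**-0.5 maps the pool-fed chain onto the closed forms."""
        for c in np.geomspace(0.01, 100.0, 100):
            ss = two_site_closed_forms(c)
            eq = spectral_steady_state(homogeneous_two_site, u=c ** -2.0)
            np.testing.assert_allclose([ss.e1, ss.e2], eq.e, atol=1e-10)
            assert ss.R == pytest.approx(eq.R, abs=1e-10)

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError):
            two_site_closed_forms(0.0)


class TestDensityIdentity:
    def test_unit_point(self):
        ss = two_site_closed_forms(1.0)
        assert total_density_identity(1.0, 1) == pytest.approx(1.0 + ss.e1 + ss.e2)
        assert total_density_identity(1.0, 1) == pytest.approx(2.0, abs=1e-12)

    def test_inversion_reaches_the_saturation_value(self):
        """At s=50 and very many chains, total production sits at s/2 = 25."""
        m, s = 10 ** 5, 50.0
        c = invert_total_density(s, m)
        tpr = m * two_site_closed_forms(c).e2
        assert tpr == pytest.approx(25.0, rel=1e-3)

    def test_matches_network_equilibrium_solver(self, homogeneous_two_site):
        for m, s in ((1, 2.0), (10, 50.0), (1000, 50.0)):
            c = invert_total_density(s, m)
            eq = solve_equilibrium(
                NetworkSpec.identical(homogeneous_two_site, PoolFunction.linear(1.0), m, s)
            )
            assert c ** -2.0 == pytest.approx(eq.e_z, abs=1e-9 * s)


class TestApproxTpr:
    @pytest.mark.parametrize(
        "m, s, expected",
        [(100, 50.0, 5000.0 / 201.0), (1, 0.003, 0.001), (10 ** 6, 50.0, 24.9999875)],
    )
    def test_values(self, m, s, expected):
        assert approx_tpr(m, s) == pytest.approx(expected, rel=1e-9)

    def test_relative_error_vanishes_for_many_chains(self):
        s = 50.0
        errs = []
        for m in (10, 100, 1000, 10000):
            c = invert_total_density(s, m)
            exact = m * two_site_closed_forms(c).e2
            errs.append(abs(exact - approx_tpr(m, s)) / exact)
        assert np.all(np.diff(errs) < 0)
        assert errs[-1] < errs[0] / 100.0  # error scales like 1/m


class TestDecodingSynthesis:
    def test_deterministic_for_fixed_seed(self):
        a = synthesize_decoding_times(200, seed=42)
        b = synthesize_decoding_times(200, seed=42)
        np.testing.assert_array_equal(a.times, b.times)

    def test_site_count_for_120_codons(self):
        profile = synthesize_decoding_times(120, seed=0, group_size=10)
        assert profile.n_sites == 12

    def test_zero_scale_gives_constant_times(self):
        profile = synthesize_decoding_times(30, seed=0, sigma=0.0, mean_time=0.2)
        np.testing.assert_allclose(profile.times, 0.2)

    def test_first_group_size_partitioning(self):
        """145 codons with a 24-codon first group and 25-codon groups gives
        six sites, the last absorbing the remaining 21 codons."""
        profile = synthesize_decoding_times(
            145, seed=1, group_size=25, first_group_size=24
        )
        groups = profile.groups()
        assert [g.size for g in groups] == [24, 25, 25, 25, 25, 21]

    @pytest.mark.parametrize("bad", [{"n_codons": 0}, {"mean_time": -1.0}, {"law": "pareto"}])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = {"n_codons": 10, "seed": 0}
        kwargs.update(bad)
        with pytest.raises(ValueError):
            synthesize_decoding_times(**kwargs)


class TestCoarseGraining:
    def test_uniform_times(self):
        profile = DecodingProfile(np.full(25, 0.1), group_size=10)
        np.testing.assert_allclose(coarse_grain_rates(profile), [1.0, 1.0, 2.0])

    def test_rates_are_reciprocal_group_sums(self):
        rng = np.random.default_rng(0)
        times = rng.uniform(0.05, 0.5, 47)
        profile = DecodingProfile(times, group_size=10)
        rates = coarse_grain_rates(profile)
        sums = [g.sum() for g in profile.groups()]
        np.testing.assert_allclose(rates, 1.0 / np.asarray(sums))

    def test_normalization_hits_the_target_exactly(self):
        profile = synthesize_decoding_times(145, seed=5)
        rates = coarse_grain_rates(profile, target_mean_rate=10.0)
        sizes = np.array([g.size for g in profile.groups()])
        assert np.mean(rates * sizes) == pytest.approx(10.0, abs=1e-12)

    def test_scale_consistency(self):
        profile = synthesize_decoding_times(60, seed=2)
        scaled = DecodingProfile(profile.times * 3.0, group_size=profile.group_size)
        np.testing.assert_allclose(
            coarse_grain_rates(scaled), coarse_grain_rates(profile) / 3.0, rtol=1e-12
        )
        # normalized rates are invariant to a global time rescale
        np.testing.assert_allclose(
            coarse_grain_rates(scaled, target_mean_rate=10.0),
            coarse_grain_rates(profile, target_mean_rate=10.0),
            rtol=1e-12,
        )

    def test_full_profile_with_initiation_rate(self):
        profile = synthesize_decoding_times(50, seed=3)
        rp = coarse_grain_rates(profile, target_mean_rate=10.0, lambda0=0.8)
        assert isinstance(rp, RateProfile)
        assert rp.lambda0 == 0.8
        assert rp.n == profile.n_sites


class TestCalibration:
    def test_homogeneous_chain(self, homogeneous_two_site):
        """With all elongation rates 1, calibration pins c*e_z to exactly 1."""
        res = calibrate_pool_coupling(homogeneous_two_site, m=1, s=10.0)
        assert abs(res.c * res.e_z_at_c - 1.0) < 1e-8
        assert res.residual < 1e-10

    def test_initiation_is_the_bottleneck(self, yeast_profile):
        res = calibrate_pool_coupling(yeast_profile, m=20, s=100.0)
        effective = yeast_profile.lambda0 * res.c * res.e_z_at_c
        assert effective <= res.target + 1e-9
        assert res.residual < 1e-8

    def test_scaling_initiation_rate_leaves_the_product_pinned(self, homogeneous_two_site):
        """The defining equation fixes lambda0*c*e_z to min(lambda_1..n),
        whatever lambda0 is."""
        doubled = RateProfile((2.0, 1.0, 1.0))
        r1 = calibrate_pool_coupling(homogeneous_two_site, m=2, s=8.0)
        r2 = calibrate_pool_coupling(doubled, m=2, s=8.0)
        assert 1.0 * r1.c * r1.e_z_at_c == pytest.approx(r1.target, abs=1e-9)
        assert 2.0 * r2.c * r2.e_z_at_c == pytest.approx(r2.target, abs=1e-9)

    def test_too_few_ribosomes_is_infeasible(self, homogeneous_two_site):
        """If s/m is below the chain density at the bottleneck point, no c
        can raise the effective initiation rate to min(lambda_1..n)."""
        with pytest.raises(ArithmeticError, match="infeasible"):
            calibrate_pool_coupling(homogeneous_two_site, m=1, s=0.5, c_max=1e6)

    def test_calibrated_slope_matches_starved_limit(self, homogeneous_two_site):
        """With the calibrated c, TPR/e_z tends to c*m*lambda0 as s shrinks."""
        m = 3
        res = calibrate_pool_coupling(homogeneous_two_site, m=m, s=30.0)
        slope = res.c * m * homogeneous_two_site.lambda0
        ratios = []
        for s in (1.0, 0.1, 0.01):
            eq = solve_equilibrium(
                NetworkSpec.identical(homogeneous_two_site, PoolFunction.linear(res.c), m, s)
            )
            ratios.append(eq.TPR / eq.e_z)
        errors = np.abs(np.array(ratios) - slope)
        assert np.all(np.diff(errors) < 0)
        assert errors[-1] < 0.01 * slope


class TestSweepExperiment:
    def test_shrinking_density_approaches_slope_from_below(self, yeast_profile):
        m = 10
        slope = 0.1678 * m

        def builder(s):
            return NetworkSpec.identical(yeast_profile, PoolFunction.linear(1.0), m, float(s))

        table = sweep_experiment(builder, vary="s", grid=[20.0, 5.0, 1.0, 0.2, 0.05])
        ratio = table["tpr_over_ez"].to_numpy()
        assert np.all(ratio < slope)
        assert np.all(np.diff(ratio) > 0)  # sorted by m/s: larger m/s, closer

    def test_growing_copy_number_drains_the_pool(self, homogeneous_two_site):
        def builder(m):
            return NetworkSpec.identical(
                homogeneous_two_site, PoolFunction.linear(1.0), int(m), 50.0
            )

        table = sweep_experiment(builder, vary="m", grid=[1, 10, 100, 1000])
        assert np.all(np.diff(table["e_z"]) < 0)

    def test_single_point_grid(self, homogeneous_two_site, tmp_path):
        out = tmp_path / "sweep.csv"
        table = sweep_experiment(
            lambda m: NetworkSpec.identical(
                homogeneous_two_site, PoolFunction.linear(1.0), int(m), 5.0
            ),
            vary="m",
            grid=[4],
            out=str(out),
        )
        assert len(table) == 1
        assert out.exists()
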