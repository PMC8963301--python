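"""Wright-Fisher expected spectra, DFE fitting, and DFE-corrected alpha."""

import math

import numpy as np
import pytest
from scipy import integrate

from parthenopop.dfe import (
    DemographyModel, DFEModel, ExpectedSFSEngine, alpha_from_dfe,
    bootstrap_dfe, class_lrt, discretize_dfe, estimate_theta_site,
    expected_sfs, fit_demography, fit_dfe, fixation_rate_ratio,
)
from parthenopop.sfs import SFS
from parthenopop.sim import fast_tables


def diffusion_sfs_oracle(S: float, n: int) -> np.ndarray:
    """Independent oracle: Wright's stationary frequency spectrum for genic
    selection, f(x) ~ (1 - e^{-S(1-x)}) / (x(1-x)(1-e^{-S})), integrated
    against binomial sampling."""

    def density(x):
        if S == 0:
            return 1.0 / x
        return -np.expm1(-S * (1 - x)) / (x * (1 - x) * -np.expm1(-S))

    out = np.zeros(n - 1)
    for i in range(1, n):
        val, _ = integrate.quad(
            lambda x: density(x) * math.comb(n, i) * x**i * (1 - x) ** (n - i),
            1e-9, 1 - 1e-9, limit=200,
        )
        out[i - 1] = val
    return out


class TestExpectedSFS:
    def test_neutral_equilibrium_one_over_i(self):
        # discretization error scales ~1/N_ref; within 1% at the convergence
        # check size
        vec = ExpectedSFSEngine(DemographyModel(N_ref=400), 20).sfs_for_S(0.0)
        i = np.arange(1, 20)
        assert np.all(np.abs(vec * i - 1.0) < 0.01)

    def test_strongly_deleterious_concentrates_in_singletons(self):
        eng = ExpectedSFSEngine(DemographyModel(), 20)
        got = eng.sfs_for_S(-100.0)
        oracle = diffusion_sfs_oracle(-100.0, 20)
        assert got[0] / got.sum() == pytest.approx(oracle[0] / oracle.sum(), abs=0.02)
        assert got[0] / got.sum() > 0.85

    def test_matches_diffusion_oracle_across_effects(self):
        eng = ExpectedSFSEngine(DemographyModel(N_ref=200), 12)
        for S in (-0.5, -5.0, -30.0):
            got = eng.sfs_for_S(S)
            oracle = diffusion_sfs_oracle(S, 12)
            np.testing.assert_allclose(
                got / got.sum(), oracle / oracle.sum(), atol=0.012
            )

    def test_folding_linearity(self):
        dem = DemographyModel()
        unfolded = expected_sfs(dem, 12, -3.0)
        folded = expected_sfs(dem, 12, -3.0, folded=True)
        manual = SFS(n=12, counts=unfolded).fold().counts
        np.testing.assert_allclose(folded, manual)

    def test_nonnegative_finite(self):
        dem = DemographyModel(ratio=2.0, t2=0.2)
        model = DFEModel("gamma", {"mean": 500.0, "shape": 0.4})
        vec = expected_sfs(dem, 10, model)
        assert np.all(vec >= 0) and np.all(np.isfinite(vec))

    def test_sample_size_exceeding_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            ExpectedSFSEngine(DemographyModel(N_ref=10), 30)

    def test_stronger_selection_never_increases_nonsingleton_share(self):
        eng = ExpectedSFSEngine(DemographyModel(), 20)
        shares = []
        for s_abs in (0.1, 1.0, 5.0, 20.0, 80.0, 300.0):
            v = eng.sfs_for_S(-s_abs)
            shares.append(v[1:].sum() / v.sum())
        assert all(a >= b - 1e-12 for a, b in zip(shares[:-1], shares[1:]))


class TestDiscretize:
    def quad_oracle(self, model: DFEModel):
        """Independent adaptive-quadrature oracle over the |S| density."""
        mean, shape = model.params["mean"], model.params["shape"]
        scale = mean / shape
        from scipy.stats import gamma as gdist

        def pdf(x):
            return gdist.pdf(x, a=shape, scale=scale)

        edges_S = [0.0, 2.0, 20.0, 200.0, np.inf]
        props = []
        for lo, hi in zip(edges_S[:-1], edges_S[1:]):
            hi_eff = min(hi, mean / shape * 200 + 1000)
            val, _ = integrate.quad(pdf, lo, hi_eff, limit=400)
            props.append(val)
        props[-1] = max(0.0, 1.0 - sum(props[:-1]))
        return props

    @pytest.mark.parametrize(
        "mean,shape", [(1000.0, 0.3), (10.0, 0.5), (0.01, 1.0), (2000.0, 0.3)]
    )
    def test_gamma_bins_match_quadrature_oracle(self, mean, shape):
        model = DFEModel("gamma", {"mean": mean, "shape": shape})
        got = discretize_dfe(model)
        want = self.quad_oracle(model)
        assert sum(got) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_neutral_spike(self):
        model = DFEModel("spike", {"s_values": (1e-12,), "weights": (1.0,)})
        assert discretize_dfe(model)[0] == pytest.approx(1.0)

    def test_spike_on_bin_edge_goes_to_upper_bin(self):
        # |S| = 2 is Ne*s = 1, the lower edge of the second bin
        model = DFEModel("spike", {"s_values": (2.0,), "weights": (1.0,)})
        props = discretize_dfe(model)
        assert props[1] == pytest.approx(1.0)

    def test_step_family_normalizes(self):
        model = DFEModel("step", {"edges": (0.0, 2.0, 200.0), "weights": (0.3, 0.7)})
        props = discretize_dfe(model)
        assert sum(props) == pytest.approx(1.0, abs=1e-9)
        assert props[0] == pytest.approx(0.3, abs=1e-9)


class TestAlphaFromDFE:
    def test_all_neutral_limit(self):
        model = DFEModel("spike", {"s_values": (1e-10,), "weights": (1.0,)})
        D_N, D_S, L_N, L_S = 80, 40, 900.0, 300.0
        alpha, omega = alpha_from_dfe(model, D_N, D_S, L_N, L_S)
        assert alpha == pytest.approx(1 - D_S * L_N / (D_N * L_S), abs=1e-6)

    def test_fully_lethal_limit(self):
        model = DFEModel("spike", {"s_values": (1e6,), "weights": (1.0,)})
        alpha, _ = alpha_from_dfe(model, 80, 40, 900.0, 300.0)
        assert alpha == pytest.approx(1.0, abs=1e-4)

    def test_undefined_divergence(self):
        model = DFEModel("gamma", {"mean": 10.0, "shape": 0.5})
        with pytest.raises(ValueError):
            alpha_from_dfe(model, 80, 0, 900.0, 300.0)

    def test_fixation_rate_ratio_limits(self):
        assert fixation_rate_ratio(0.0) == 1.0
        assert fixation_rate_ratio(-10.0) == pytest.approx(10 / (math.e**10 - 1))
        # beneficial: rate approaches S
        assert fixation_rate_ratio(20.0) == pytest.approx(20.0, rel=1e-6)


class TestFitDemography:
    def test_equilibrium_recovered_with_flag(self):
        rng = np.random.default_rng(0)
        eng = ExpectedSFSEngine(DemographyModel(N_ref=50), 20)
        expected = 5000.0 * eng.sfs_for_S(0.0) / eng.sfs_for_S(0.0).sum()
        obs = rng.poisson(expected).astype(float)
        dem = fit_demography(SFS(n=20, counts=obs), N_ref=50,
                             ratio_bounds=(0.2, 5.0), t2_bounds=(0.05, 1.0),
                             grid_points=4)
        assert dem.is_equilibrium

    def test_expansion_recovered_within_twofold(self):
        rng = np.random.default_rng(1)
        true = DemographyModel(ratio=4.0, t2=0.3, N_ref=50)
        eng = ExpectedSFSEngine(true, 20)
        shape = eng.sfs_for_S(0.0)
        obs = rng.poisson(20000.0 * shape / shape.sum()).astype(float)
        dem = fit_demography(SFS(n=20, counts=obs), N_ref=50,
                             ratio_bounds=(0.2, 8.0), t2_bounds=(0.05, 1.0),
                             grid_points=4)
        assert not dem.is_equilibrium
        assert 2.0 <= dem.ratio <= 8.0


class TestFitDFE:
    def test_all_neutral_data_mass_in_first_bin(self):
        rng = np.random.default_rng(3)
        dem = DemographyModel()
        eng = ExpectedSFSEngine(dem, 20)
        neutral = eng.sfs_for_S(0.0)
        obs = rng.poisson(50.0 * neutral).astype(float)
        theta = estimate_theta_site(SFS(n=20, counts=obs), 1.0, dem)
        fit = fit_dfe(SFS(n=20, counts=obs), dem, "gamma", theta_N=theta)
        assert fit.bin_proportions[0] > 0.9

    def test_gamma_recovery_on_generator_data(self):
        dfe = DFEModel("gamma", {"mean": 2000.0, "shape": 0.3})
        tables, sfs_N, sfs_S = fast_tables(
            dfe, 0.0, n_genes=120, theta_site=0.011, T=0.1, n=40, seed=5,
            L_N=760.0, L_S=240.0,
        )
        dem = DemographyModel()
        theta = estimate_theta_site(sfs_S.fold(), 240.0 * 120, dem)
        fit = fit_dfe(sfs_N.fold(), dem, "gamma", theta_N=theta * 760.0 * 120)
        assert fit.model.params["shape"] == pytest.approx(0.3, abs=0.08)

    def test_lrt_identical_classes_null(self):
        dfe = DFEModel("gamma", {"mean": 100.0, "shape": 0.5})
        _, sfs_N, sfs_S = fast_tables(dfe, 0.0, 60, 0.01, 0.1, 20, seed=9)
        dem = DemographyModel()
        half = sfs_N.counts / 2.0
        fit_joint = fit_dfe(sfs_N, dem, "gamma")
        fit_a = fit_dfe(SFS(20, half), dem, "gamma")
        fit_b = fit_dfe(SFS(20, half), dem, "gamma")
        chi2, df, p = class_lrt(fit_joint, fit_a, fit_b)
        assert df == 2
        assert p > 0.2

    def test_lrt_rejects_mismatched_family(self):
        dfe = DFEModel("gamma", {"mean": 100.0, "shape": 0.5})
        _, sfs_N, _ = fast_tables(dfe, 0.0, 30, 0.01, 0.1, 20, seed=9)
        dem = DemographyModel()
        f1 = fit_dfe(sfs_N, dem, "gamma")
        f2 = fit_dfe(sfs_N, dem, "lognormal")
        with pytest.raises(ValueError, match="family"):
            class_lrt(f1, f2, f2)


class TestBootstrapDFE:
    def test_single_replicate_degenerates_to_point(self):
        dfe = DFEModel("gamma", {"mean": 50.0, "shape": 0.5})
        _, sfs_N, sfs_S = fast_tables(dfe, 0.0, 40, 0.01, 0.2, 20, seed=2)
        dem = DemographyModel()
        out = bootstrap_dfe(sfs_N, sfs_S, dem, 50, 60, 750.0, 250.0, B=1, seed=4)
        assert out["alpha_ci"][0] == out["alpha_ci"][1]

    def test_seeded_reproducibility(self):
        dfe = DFEModel("gamma", {"mean": 50.0, "shape": 0.5})
        _, sfs_N, sfs_S = fast_tables(dfe, 0.0, 40, 0.01, 0.2, 20, seed=2)
        dem = DemographyModel()
        a = bootstrap_dfe(sfs_N, sfs_S, dem, 50, 60, 750.0, 250.0, B=8, seed=4)
        b = bootstrap_dfe(sfs_N, sfs_S, dem, 50, 60, 750.0, 250.0, B=8, seed=4)
        assert a["alpha_ci"] == b["alpha_ci"]
        assert a["bin_ci"] == b["bin_ci"]
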