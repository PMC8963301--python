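"""MK-framework estimators: naive, Fisher/FDR, multigene ML, asymptotic."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parthenopop.alignment import MKTable
from parthenopop.mk import (
    asymptotic_mk, bootstrap_welch, fdr_correct, gene_mk_test,
    naive_alpha, naive_alpha_from_counts, permutation_test_omega_a,
    welch_ml_fit, welch_model_selection,
)
from parthenopop.sfs import SFS


def table(P_N, P_S, D_N, D_S, gene_id="g", label="control", L_N=750.0, L_S=250.0):
    return MKTable(gene_id, P_N, P_S, D_N, D_S, L_N, L_S, label)


class TestNaive:
    def test_formula_examples(self):
        r = naive_alpha_from_counts(5, 20, 10, 20)
        assert r.alpha == pytest.approx(0.5)
        assert r.adaptive_count == pytest.approx(5.0)
        # neutral expectation
        assert naive_alpha_from_counts(10, 20, 10, 20).alpha == pytest.approx(0.0)
        # excess polymorphism gives a negative estimate
        assert naive_alpha_from_counts(15, 20, 10, 20).alpha == pytest.approx(-0.5)

    def test_undefined_cases_reported_missing(self):
        assert naive_alpha_from_counts(5, 20, 0, 20).alpha is None
        assert naive_alpha_from_counts(5, 0, 10, 20).alpha is None

    @given(
        P_N=st.integers(0, 100), P_S=st.integers(1, 100),
        D_N=st.integers(1, 100), D_S=st.integers(0, 100),
        k=st.integers(2, 20),
    )
    @settings(max_examples=60, deadline=None)
    def test_scale_invariance(self, P_N, P_S, D_N, D_S, k):
        a1 = naive_alpha_from_counts(P_N, P_S, D_N, D_S).alpha
        a2 = naive_alpha_from_counts(k * P_N, k * P_S, k * D_N, k * D_S).alpha
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_omega_a_uses_site_opportunities(self):
        r = naive_alpha(
            [table(5, 20, 10, 20, L_N=1000.0, L_S=500.0)]
        )
        # omega_a = alpha * (D_N/L_N)/(D_S/L_S)
        assert r.omega_a == pytest.approx(0.5 * (10 / 1000) / (20 / 500))


def exact_two_sided_fisher(a, b, c, d):
    """Oracle: exhaustive hypergeometric enumeration with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(n, c1)
    probs = {k: comb(r1, k) * comb(r2, c1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestFisherFDR:
    @pytest.mark.parametrize(
        "cells",
        [(0, 10, 10, 10), (5, 10, 10, 20), (3, 7, 9, 2), (1, 1, 1, 1),
         (12, 3, 4, 11), (0, 0, 10, 10), (8, 2, 0, 5), (2, 9, 7, 3)],
    )
    def test_matches_exhaustive_enumeration(self, cells):
        P_N, P_S, D_N, D_S = cells
        t = table(P_N, P_S, D_N, D_S)
        got = gene_mk_test(t)
        tab = np.array([[P_N, P_S], [D_N, D_S]])
        if (tab.sum(0) == 0).any() or (tab.sum(1) == 0).any():
            assert got == 1.0
        else:
            assert got == pytest.approx(exact_two_sided_fisher(P_N, P_S, D_N, D_S), abs=1e-9)

    @given(
        P_N=st.integers(0, 12), P_S=st.integers(0, 12),
        D_N=st.integers(0, 12), D_S=st.integers(0, 12),
    )
    @settings(max_examples=80, deadline=None)
    def test_enumeration_property_totals_le_40(self, P_N, P_S, D_N, D_S):
        t = table(P_N, P_S, D_N, D_S)
        got = gene_mk_test(t)
        tab = np.array([[P_N, P_S], [D_N, D_S]])
        if (tab.sum(0) == 0).any() or (tab.sum(1) == 0).any():
            assert got == 1.0
        else:
            assert got == pytest.approx(exact_two_sided_fisher(P_N, P_S, D_N, D_S), abs=1e-9)

    def test_proportional_table_p_one(self):
        assert gene_mk_test(table(5, 10, 10, 20)) == pytest.approx(1.0)

    def test_bh_stepup_hand_computed(self):
        q = fdr_correct([0.01, 0.02, 0.04])
        assert np.allclose(q, [0.03, 0.03, 0.04])


def _welch_generator(n_genes, alpha, T, seed, theta_scale=0.02):
    """Counts drawn from the multigene Poisson model itself."""
    rng = np.random.default_rng(seed)
    tables = []
    for g in range(n_genes):
        L_S, L_N = 300.0, 900.0
        theta = theta_scale * rng.lognormal(0, 0.5)
        f = rng.uniform(0.05, 0.5)
        mu = [theta * L_S, f * theta * L_N, T * theta * L_S,
              f * T * theta * L_N / (1 - alpha)]
        P_S, P_N, D_S, D_N = rng.poisson(mu)
        tables.append(table(int(P_N), int(P_S), int(D_N), int(D_S), gene_id=f"g{g}"))
    return tables


class TestWelchML:
    def test_single_gene_profile_equals_naive(self):
        t = table(5, 20, 10, 20)
        m = welch_ml_fit([t], alpha_structure="single")
        assert m.alpha["*"] == pytest.approx(0.5, abs=1e-3)

    def test_alpha_recovery_within_bootstrap_ci(self):
        tables = _welch_generator(200, alpha=0.4, T=2.0, seed=42)
        m = welch_ml_fit(tables, alpha_structure="single")
        ci = bootstrap_welch(tables, alpha_structure="single", B=200, seed=1)
        lo, hi = ci["control"]
        assert lo <= 0.4 <= hi
        assert abs(m.alpha["*"] - 0.4) < 0.15

    def test_neutral_data_small_delta_aic(self):
        tables = _welch_generator(150, alpha=0.0, T=2.0, seed=7)
        free = welch_ml_fit(tables, alpha_structure="single")
        zero = welch_ml_fit(tables, alpha_structure="zero")
        # nested models: freeing alpha can only increase the likelihood
        assert free.logL >= zero.logL - 1e-6
        assert abs(free.AIC - zero.AIC) < 4.0

    def test_model_selection_weights_sum_to_one(self):
        tables = _welch_generator(40, alpha=0.2, T=1.5, seed=3)
        models = welch_model_selection(
            tables, alpha_structures=("zero", "single"), f_structures=("per-gene",)
        )
        assert sum(m.akaike_weight for m in models) == pytest.approx(1.0)
        assert models[0].AIC <= models[1].AIC

    def test_bootstrap_deterministic_under_seed(self):
        tables = _welch_generator(30, alpha=0.2, T=1.5, seed=9)
        ci1 = bootstrap_welch(tables, alpha_structure="single", B=50, seed=5)
        ci2 = bootstrap_welch(tables, alpha_structure="single", B=50, seed=5)
        assert ci1 == ci2

    def test_single_gene_class_ci_collapses_with_warning(self):
        tables = _welch_generator(10, alpha=0.2, T=1.5, seed=2)
        lone = table(3, 10, 5, 10, gene_id="lone", label="immune")
        with pytest.warns(UserWarning, match="single gene"):
            bootstrap_welch(tables + [lone], alpha_structure="per-class", B=5, seed=0)


class TestAsymptoticMK:
    def _flat_spectra(self, n=40, ratio=0.5):
        i = np.arange(1, n)
        syn = 1000.0 / i
        non = ratio * syn
        sN = SFS(n=n, counts=non, site_class="nonsynonymous")
        sS = SFS(n=n, counts=syn, site_class="synonymous")
        return sN, sS

    def test_flat_ratio_recovers_naive_alpha(self):
        sN, sS = self._flat_spectra(ratio=0.5)
        D_N, D_S = 100, 50
        fit = asymptotic_mk(sN, sS, D_N, D_S)
        naive = 1 - (D_S / D_N) * 0.5
        assert fit.alpha_asymptotic == pytest.approx(naive, abs=1e-6)

    def test_empty_synonymous_bins_dropped(self):
        n = 40
        i = np.arange(1, n)
        syn = 1000.0 / i
        syn[i / n >= 0.9] = 0.0  # empty the top bins
        non = 0.5 * syn
        fit = asymptotic_mk(
            SFS(n=n, counts=non, site_class="nonsynonymous"),
            SFS(n=n, counts=syn, site_class="synonymous"),
            100, 50,
        )
        assert fit.n_bins_used >= 10
        assert np.isfinite(fit.alpha_asymptotic)

    def test_requires_unfolded(self):
        sN, sS = self._flat_spectra()
        with pytest.raises(ValueError):
            asymptotic_mk(sN.fold(), sS, 10, 10)

    def test_rare_allele_excess_extrapolates_above_naive(self):
        # deleterious-like excess of rare nonsynonymous variants pulls the
        # naive estimate down; the x->1 extrapolation recovers most of it
        n = 40
        i = np.arange(1, n)
        x = i / n
        syn = 1000.0 / i
        non = 0.5 * syn * (1 + 3.0 * np.exp(-20 * x))
        D_N, D_S = 100, 50
        fit = asymptotic_mk(
            SFS(n=n, counts=non, site_class="nonsynonymous"),
            SFS(n=n, counts=syn, site_class="synonymous"),
            D_N, D_S,
        )
        from parthenopop.mk import naive_alpha_from_counts

        naive = naive_alpha_from_counts(non.sum(), syn.sum(), D_N, D_S).alpha
        assert fit.alpha_asymptotic > naive
        assert fit.alpha_asymptotic == pytest.approx(1 - 0.5 * 0.5, abs=0.05)


class TestPermutationOmegaA:
    def test_identical_groups_null(self):
        a = _welch_generator(40, alpha=0.1, T=1.5, seed=11)
        b = _welch_generator(40, alpha=0.1, T=1.5, seed=12)
        out = permutation_test_omega_a(a, b, B=200, seed=0)
        assert out["p_value"] > 0.05
        assert out["interpretive"]

    def test_shifted_group_detected(self):
        a = _welch_generator(60, alpha=0.0, T=1.5, seed=13)
        b = _welch_generator(60, alpha=0.6, T=1.5, seed=14)
        out = permutation_test_omega_a(a, b, B=300, seed=0)
        assert out["p_value"] < 0.05

    def test_seeded_determinism(self):
        a = _welch_generator(20, alpha=0.1, T=1.5, seed=15)
        b = _welch_generator(20, alpha=0.3, T=1.5, seed=16)
        assert (permutation_test_omega_a(a, b, B=100, seed=2)
                == permutation_test_omega_a(a, b, B=100, seed=2))
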