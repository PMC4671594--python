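"""Transmission law, loess smoothing, error-fraction estimation,
rare-variant validation and saturation projections."""

import numpy as np
import pandas as pd
import pytest

from rareherit import (
    SimConfig,
    duo_reference_maf,
    estimate_error_fraction,
    expected_transmission,
    fit_quadratic,
    fit_saturation,
    loess_fit,
    observed_transmission,
    pooled_transmission,
    quadratic_projection,
    saturation_resample,
    simulate_genotypes,
    simulate_pedigree,
    unrelated_pairs,
    validate_rare_variants,
)
from rareherit.duos import _validation_matrix, control_band, make_maf_bins

from conftest import make_pedigree, make_variant_table


class TestExpectedTransmission:
    def test_printed_values(self):
        assert expected_transmission(0.0) == 0.5
        assert expected_transmission(0.5) == 0.75
        assert expected_transmission(0.02) == pytest.approx(0.51)

    def test_affine_with_half_slope(self):
        m = np.linspace(0, 0.5, 11)
        np.testing.assert_allclose(expected_transmission(m), 0.5 + 0.5 * m)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            expected_transmission(-0.01)
        with pytest.raises(ValueError):
            expected_transmission(0.6)


class TestObservedTransmission:
    def test_handcrafted_proportions(self):
        # sire het at sites 0,1,2; son carries at 0 and 2 only
        G = np.array([[1, 1, 1, 0], [1, 0, 2, 1]], dtype=np.int8)
        vt = make_variant_table(G, sample_ids=["sire", "son"])
        maf = np.array([0.1, 0.1, 0.1, 0.1])
        out = observed_transmission(vt, [("sire", "son")], np.array([0.0, 0.5]),
                                    maf=maf, alt_freq=maf)
        assert out["n_sire_het"].iloc[0] == 3
        assert out["proportion"].iloc[0] == pytest.approx(2 / 3)

    def test_empty_denominator_flagged_nan(self):
        G = np.array([[0, 0], [1, 1]], dtype=np.int8)
        vt = make_variant_table(G, sample_ids=["sire", "son"])
        out = observed_transmission(
            vt, [("sire", "son")], np.array([0.0, 0.5]), maf=np.array([0.1, 0.1])
        )
        assert np.isnan(out["proportion"].iloc[0])

    def test_missing_member_errors_with_id(self):
        vt = make_variant_table(np.zeros((2, 2)), sample_ids=["a", "b"])
        with pytest.raises(KeyError, match="ghost"):
            observed_transmission(vt, [("a", "ghost")], np.array([0.0, 0.5]),
                                  maf=np.array([0.1, 0.1]))

    def test_error_free_simulation_matches_theory(self):
        """Pooled transmission within 3 binomial SE of 0.5 + 0.5*MAF."""
        cfg = SimConfig(n_founders=300, n_generations=2, n_sires_per_gen=30,
                        n_sons_per_sire=1, n_variants=6000, error_rate=0.0, seed=2)
        ped = simulate_pedigree(cfg)
        vt = simulate_genotypes(ped, cfg)
        maf = duo_reference_maf(vt, ped.duos)
        bins = make_maf_bins(maf, n_bins=5)
        pooled = pooled_transmission(observed_transmission(vt, ped.duos, bins, maf=maf))
        exp = expected_transmission(pooled["mean_maf"].to_numpy())
        se = np.sqrt(exp * (1 - exp) / pooled["n_sire_het"].to_numpy())
        assert np.all(np.abs(pooled["proportion"].to_numpy() - exp) < 3 * se)


class TestLoess:
    def test_constant_reproduced_exactly(self):
        x = np.linspace(0, 1, 30)
        _, fit = loess_fit(x, np.full(30, 0.5), span=0.3)
        np.testing.assert_allclose(fit, 0.5, atol=1e-12)

    def test_linear_reproduced(self):
        x = np.linspace(0, 1, 40)
        y = 0.2 + 0.6 * x
        grid, fit = loess_fit(x, y, span=0.4)
        np.testing.assert_allclose(fit, 0.2 + 0.6 * grid, atol=1e-6)

    def test_larger_span_is_smoother(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 1, 200))
        y = 1 / (1 + np.exp(-10 * (x - 0.5))) + rng.normal(0, 0.1, 200)
        grid = np.linspace(0.05, 0.95, 60)
        _, f_small = loess_fit(x, y, span=0.2, grid=grid)
        _, f_large = loess_fit(x, y, span=0.9, grid=grid)
        curvature = lambda f: np.sum(np.abs(np.diff(f, 2)))
        assert curvature(f_large) < curvature(f_small)

    def test_matches_statsmodels_on_linear_signal(self):
        """Independent smoother cross-check where both are unbiased."""
        from statsmodels.nonparametric.smoothers_lowess import lowess

        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 1, 150))
        y = 1.0 + 2.0 * x + rng.normal(0, 0.05, 150)
        grid = x
        _, mine = loess_fit(x, y, span=0.5, grid=grid)
        theirs = lowess(y, x, frac=0.5, return_sorted=False)
        assert np.mean(np.abs(mine - theirs)) < 0.05

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            loess_fit(np.arange(5), np.arange(5))


class TestControlBand:
    def test_identical_pairs_zero_width(self):
        rng = np.random.default_rng(3)
        maf = np.linspace(0.02, 0.48, 400)
        G = rng.binomial(2, maf, size=(2, 400)).astype(np.int8)
        # two pairs built from duplicated animals: identical curves
        G4 = np.vstack([G, G])
        vt = make_variant_table(G4, sample_ids=["a", "b", "c", "d"])
        bins = np.linspace(0.0, 0.5, 12)
        band = control_band(vt, [("a", "b"), ("c", "d")], bins, maf=maf, alt_freq=maf)
        np.testing.assert_allclose(band["lower"], band["upper"], atol=1e-12)

    def test_related_curve_above_unrelated_band_at_low_maf(self):
        cfg = SimConfig(n_founders=400, n_generations=2, n_sires_per_gen=30,
                        n_sons_per_sire=1, n_variants=8000, error_rate=0.0, seed=6)
        ped = simulate_pedigree(cfg)
        vt = simulate_genotypes(ped, cfg)
        controls = unrelated_pairs(ped, 10, seed=1)
        maf = duo_reference_maf(vt, ped.duos + controls)
        bins = make_maf_bins(maf, n_bins=10)
        grid = np.linspace(0.01, 0.09, 20)
        band = control_band(vt, controls, bins, grid=grid, maf=maf)
        duo_df = observed_transmission(vt, ped.duos, bins, maf=maf)
        pooled = pooled_transmission(duo_df).dropna(subset=["proportion"])
        _, duo_fit = loess_fit(pooled["mean_maf"], pooled["proportion"],
                               span=0.5, grid=grid)
        assert np.all(duo_fit > band["upper"].to_numpy())
        # band center tracks the Hardy-Weinberg carrier probability 1-(1-m)^2
        hw = 1 - (1 - grid) ** 2
        assert np.all(np.abs(band["center"].to_numpy() - hw) < 0.1)


class TestErrorFraction:
    def test_observed_equals_expected_gives_zero(self):
        m = np.array([0.005, 0.1])
        assert np.all(estimate_error_fraction(expected_transmission(m), m) == 0)

    def test_half_expected_gives_half(self):
        m = np.array([0.005, 0.02])
        obs = 0.5 * expected_transmission(m)
        np.testing.assert_allclose(estimate_error_fraction(obs, m), 0.5)

    def test_clipped_to_unit_interval(self):
        m = np.array([0.01])
        assert estimate_error_fraction(np.array([0.9]), m)[0] == 0.0
        assert estimate_error_fraction(np.array([0.0]), m)[0] == 1.0


class TestValidateRareVariants:
    def _vt(self):
        # site 0: only the sire carries (spurious); site 1: sire and son het;
        # site 2: common site (not rare)
        G = np.zeros((300, 3), dtype=np.int8)
        G[0, 0] = 1
        G[0, 1], G[1, 1] = 1, 1
        G[:150, 2] = 1
        return make_variant_table(G)

    def test_sire_only_carrier_not_validated(self):
        validated = validate_rare_variants(self._vt(), [("s0", "s1")])
        assert list(validated["pos"]) == [2000]

    def test_het_het_duo_validated(self):
        validated = validate_rare_variants(self._vt(), [("s0", "s1")], strict_het=True)
        assert list(validated["pos"]) == [2000]

    def test_monotone_in_duos(self):
        cfg = SimConfig(n_founders=100, n_generations=2, n_sires_per_gen=10,
                        n_sons_per_sire=2, n_variants=2000, seed=8)
        ped = simulate_pedigree(cfg)
        vt = simulate_genotypes(ped, cfg)
        small = validate_rare_variants(vt, ped.duos[:5])
        full = validate_rare_variants(vt, ped.duos)
        assert set(map(tuple, small.values)) <= set(map(tuple, full.values))

    def test_validated_fraction_matches_enumeration_oracle(self):
        """P(duo co-carries) from enumerating sire/dam genotype combinations."""
        q = 0.1
        rows = [(f"f{i}", None, None) for i in range(6)]
        rows += [(f"son{i}", f"f{2*i}", f"f{2*i+1}") for i in range(3)]
        ped = make_pedigree(rows, duos=[(f"f{2*i}", f"son{i}") for i in range(3)])
        cfg = SimConfig(n_founders=6, n_generations=1, n_sires_per_gen=1,
                        n_sons_per_sire=1, n_variants=4000, seed=10)
        vt = simulate_genotypes(ped, cfg, founder_freqs=np.full(4000, q))
        # closed form: sire Binom(2,q); son carries iff sire transmits or dam does
        p_duo = 0.0
        for gs, pr in ((1, 2 * q * (1 - q)), (2, q * q)):
            p_son = 1 - (1 - gs / 2) * (1 - q) ** 2 * 1.0 if gs == 2 else None
            # P(son >= 1 copy) = 1 - P(no copy from sire) * P(no copy from dam)
            p_no_sire = 1 - gs / 2
            p_no_dam = (1 - q) ** 2 + 2 * q * (1 - q) * 0.5
            p_duo += pr * (1 - p_no_sire * p_no_dam)
        expected = 1 - (1 - p_duo) ** 3
        M = _validation_matrix(vt, ped.duos, np.arange(vt.n_sites), strict_het=False)
        observed = M.any(axis=0).mean()
        se = np.sqrt(expected * (1 - expected) / vt.n_sites)
        assert abs(observed - expected) < 3 * se


@pytest.fixture(scope="module")
def pop():
    cfg = SimConfig(n_founders=150, n_generations=2, n_sires_per_gen=12,
                    n_sons_per_sire=2, n_variants=3000, seed=12)
    ped = simulate_pedigree(cfg)
    vt = simulate_genotypes(ped, cfg)
    return ped, vt


class TestSaturation:
    def test_full_set_replicates_identical(self, pop):
        ped, vt = pop
        sat = saturation_resample(vt, ped.duos, n_replicates=10, seed=0)
        full = sat[sat["n_duos"] == len(ped.duos)]["count"]
        assert full.nunique() == 1

    def test_nested_subsets_monotone(self, pop):
        """Union over a growing duo set can only add validated variants."""
        ped, vt = pop
        counts = [len(validate_rare_variants(vt, ped.duos[:k]))
                  for k in range(1, len(ped.duos) + 1)]
        assert np.all(np.diff(counts) >= 0)

    def test_mean_counts_increase_overall(self, pop):
        ped, vt = pop
        sat = saturation_resample(vt, ped.duos, n_replicates=30, seed=1)
        means = sat.groupby("n_duos")["count"].mean().to_numpy()
        assert means[-1] >= means[0]
        assert np.polyfit(np.arange(means.size), means, 1)[0] > 0

    def test_deterministic_given_seed(self, pop):
        ped, vt = pop
        a = saturation_resample(vt, ped.duos, n_replicates=5, seed=3)
        b = saturation_resample(vt, ped.duos, n_replicates=5, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestQuadraticFit:
    def test_vertex_ceiling_projections(self):
        assert quadratic_projection(108432, 80557, -926).duos_needed == 44
        assert quadratic_projection(653, 775, -6.7).duos_needed == 58

    def test_exact_parabola_recovered(self):
        x = np.repeat(np.arange(1, 11), 3)
        y = 5.0 + 3.0 * x - 0.1 * x**2
        fit = fit_quadratic(pd.DataFrame({"n_duos": x, "count": y}))
        assert fit.a == pytest.approx(5.0, abs=1e-9)
        assert fit.b == pytest.approx(3.0, abs=1e-9)
        assert fit.c == pytest.approx(-0.1, abs=1e-9)

    def test_non_concave_flagged(self):
        fit = quadratic_projection(1.0, 2.0, 0.5)
        assert fit.duos_needed is None and fit.projected_max is None


class TestSaturationFit:
    @staticmethod
    def _counts(T, k, n_max=38, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        n = np.arange(1, n_max + 1)
        y = T * (1 - np.exp(-k * n)) + rng.normal(0, noise, n.size)
        return pd.DataFrame({"n_duos": n, "count": y})

    def test_recovers_T_within_5_percent(self):
        fit = fit_saturation(self._counts(1000, 0.05, noise=5.0))
        assert abs(fit.T - 1000) / 1000 < 0.05

    def test_near_saturated_regime(self):
        fit = fit_saturation(self._counts(1000, 0.5, noise=1.0))
        assert abs(fit(38) - 1000) / 1000 < 0.01

    def test_constant_counts_degenerate_saturation(self):
        df = pd.DataFrame({"n_duos": np.arange(1, 11), "count": np.full(10, 200.0)})
        fit = fit_saturation(df)
        np.testing.assert_allclose(fit(np.arange(1, 11)), 200.0, rtol=0.01)

    def test_agrees_with_quadratic_on_observed_range(self):
        """Two parametric families track each other loosely on saturating data."""
        counts = self._counts(1000, 0.06, noise=10.0, seed=5)
        sat = fit_saturation(counts)
        quad = fit_quadratic(counts)
        n = np.arange(5, 39)
        q = quad.a + quad.b * n + quad.c * n**2
        assert np.all(np.abs(q - sat(n)) / sat(n) < 0.25)
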