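"""Generator correctness: pedigree structure, Mendelian gene drop,
variance-share calibration, and the false-heterozygote error process."""

import numpy as np
import pandas as pd
import pytest

from rareherit import (
    SimConfig,
    assign_effects_and_phenotypes,
    inject_sequencing_errors,
    simulate_genotypes,
    simulate_pedigree,
    unrelated_pairs,
)
from rareherit.config import ConfigurationError
from rareherit.simulate import inject_false_heterozygotes, sample_maf_spectrum

from conftest import make_pedigree


def test_minimal_pedigree_has_one_duo():
    cfg = SimConfig(n_founders=2, n_generations=1, n_sires_per_gen=1,
                    n_sons_per_sire=1, n_variants=10, seed=0)
    ped = simulate_pedigree(cfg)
    assert len(ped.ids) >= 3
    assert len(ped.duos) == 1
    sire, son = ped.duos[0]
    assert ped.parents(son)[0] == sire


@pytest.mark.parametrize("seed", [0, 1])
def test_every_nonfounder_has_both_parents_in_table(seed):
    cfg = SimConfig(n_founders=30, n_generations=3, n_sires_per_gen=5,
                    n_sons_per_sire=2, n_variants=10, seed=seed)
    ped = simulate_pedigree(cfg)
    ids = set(ped.ids)
    founders = set(ped.founders())
    for _, row in ped.records.iterrows():
        if row["id"] in founders:
            assert pd.isna(row["sire"]) and pd.isna(row["dam"])
        else:
            assert row["sire"] in ids and row["dam"] in ids
    assert len(ped.duos) >= cfg.n_sires_per_gen * cfg.n_sons_per_sire


def test_pedigree_deterministic_under_seed():
    cfg = SimConfig(seed=42, n_variants=10)
    a, b = simulate_pedigree(cfg), simulate_pedigree(cfg)
    pd.testing.assert_frame_equal(a.records, b.records)
    assert a.duos == b.duos


def test_invalid_counts_rejected():
    with pytest.raises(ConfigurationError):
        SimConfig(n_founders=0)
    with pytest.raises(ConfigurationError):
        SimConfig(h2=0.0)
    with pytest.raises(ConfigurationError):
        SimConfig(variance_shares={"common": 0.9, "uncommon": 0.0,
                                   "rare": 0.0, "untyped_polygenic": 0.0})


def test_fixed_allele_stays_fixed():
    cfg = SimConfig(n_founders=10, n_generations=2, n_sires_per_gen=2,
                    n_sons_per_sire=2, n_variants=5, seed=1)
    ped = simulate_pedigree(cfg)
    vt = simulate_genotypes(ped, cfg, founder_freqs=np.zeros(5))
    assert np.all(vt.genotypes == 0)


def test_gene_drop_is_mendelian_consistent(tiny_pop):
    """Child dosage bounded by parental homozygosity at every site."""
    ped, vt = tiny_pop["ped"], tiny_pop["vt"]
    idx = {a: k for k, a in enumerate(vt.sample_ids)}
    founders = set(ped.founders())
    for _, row in ped.records.iterrows():
        if row["id"] in founders:
            continue
        child = vt.genotypes[idx[row["id"]]]
        gs = vt.genotypes[idx[row["sire"]]]
        gd = vt.genotypes[idx[row["dam"]]]
        lower = (gs == 2).astype(int) + (gd == 2).astype(int)
        upper = 2 - (gs == 0).astype(int) - (gd == 0).astype(int)
        assert np.all(child >= lower) and np.all(child <= upper)


def test_founder_frequency_binomial_oracle():
    """Mean founder ALT frequency within 3 SE of the target p = 0.3."""
    cfg = SimConfig(n_founders=2000, n_generations=1, n_sires_per_gen=1,
                    n_sons_per_sire=1, n_variants=50, seed=3)
    ped = simulate_pedigree(cfg)
    vt = simulate_genotypes(ped, cfg, founder_freqs=np.full(50, 0.3))
    founder_rows = [vt.sample_index(a) for a in ped.founders()]
    mean_freq = vt.genotypes[founder_rows].mean() / 2
    se = np.sqrt(0.3 * 0.7 / (2 * len(founder_rows) * 50))
    assert abs(mean_freq - 0.3) < 3 * se


def test_frequency_conserved_across_generations():
    """Regression of final-generation frequency on founder frequency has slope ~1."""
    cfg = SimConfig(n_founders=200, n_generations=3, n_sires_per_gen=30,
                    n_sons_per_sire=3, n_variants=3000, seed=5)
    ped = simulate_pedigree(cfg)
    vt = simulate_genotypes(ped, cfg)
    final_gen = [a for a in ped.ids if a.startswith(f"G{cfg.n_generations}")]
    rows = [vt.sample_index(a) for a in final_gen]
    f_final = vt.genotypes[rows].mean(axis=0) / 2
    f0 = vt.founder_freqs
    slope, intercept = np.polyfit(f0, f_final, 1)
    # SE of the OLS slope from the residuals
    resid = f_final - (slope * f0 + intercept)
    se = np.sqrt(resid.var() / (len(f0) * f0.var()))
    assert abs(slope - 1.0) < 3 * se


def test_maf_spectrum_is_rare_heavy():
    cfg = SimConfig(n_founders=100, n_variants=20000, seed=0)
    rng = np.random.default_rng(0)
    p = sample_maf_spectrum(20000, cfg, rng)
    assert p.min() >= 1 / 200 and p.max() <= 0.5
    frac_rare = np.mean(np.minimum(p, 1 - p) < 0.01)
    assert 0.1 < frac_rare < 0.35


def test_zero_rare_share_gives_zero_rare_variance(tiny_cfg):
    ped = simulate_pedigree(tiny_cfg)
    vt = simulate_genotypes(ped, tiny_cfg)
    cfg = SimConfig(**{**tiny_cfg.to_dict(),
                       "variance_shares": {"common": 0.9, "uncommon": 0.0,
                                           "rare": 0.0, "untyped_polygenic": 0.1}})
    _, truth, _ = assign_effects_and_phenotypes(vt, ped, cfg)
    assert truth["variances"]["rare"] == 0.0


def test_realized_shares_match_config(tiny_pop, tiny_cfg):
    truth = tiny_pop["truth"]
    sigma_a2 = tiny_cfg.h2 * tiny_cfg.phenotypic_variance
    for label, share in tiny_cfg.variance_shares.items():
        assert abs(truth["variances"][label] - share * sigma_a2) < 1e-6


def test_untyped_causals_are_hidden(tiny_pop):
    vt, vt_visible, truth = tiny_pop["vt"], tiny_pop["vt_visible"], tiny_pop["truth"]
    hidden = set(truth["causal_sites"]["untyped_polygenic"])
    assert hidden
    assert hidden.isdisjoint(set(vt_visible.sites["pos"]))
    assert vt.n_sites - vt_visible.n_sites == len(hidden)


def test_no_residual_phenotype_equals_genetic_value(tiny_cfg):
    ped = simulate_pedigree(tiny_cfg)
    vt = simulate_genotypes(ped, tiny_cfg)
    cfg = SimConfig(**{**tiny_cfg.to_dict(), "h2": 1.0,
                       "weight_distribution": {"shape": 2.0, "scale": 2.0, "min": 1e9}})
    phen, truth, _ = assign_effects_and_phenotypes(vt, ped, cfg)
    cor = np.corrcoef(phen.values, truth["total_genetic_value"])[0, 1]
    assert cor > 0.999


def test_phenotypes_deterministic(tiny_cfg):
    ped = simulate_pedigree(tiny_cfg)
    vt = simulate_genotypes(ped, tiny_cfg)
    p1, _, _ = assign_effects_and_phenotypes(vt, ped, tiny_cfg)
    p2, _, _ = assign_effects_and_phenotypes(vt, ped, tiny_cfg)
    np.testing.assert_array_equal(p1.values, p2.values)
    np.testing.assert_array_equal(p1.weights, p2.weights)


def test_positive_share_with_no_eligible_sites_errors():
    ped = make_pedigree([("a", None, None), ("b", None, None)])
    from conftest import make_variant_table
    vt = make_variant_table([[0, 0, 0], [0, 0, 0]], sample_ids=["a", "b"])
    cfg = SimConfig(n_founders=2, n_generations=1, n_sires_per_gen=1,
                    n_sons_per_sire=1, n_variants=3, seed=0)
    with pytest.raises(ConfigurationError):
        assign_effects_and_phenotypes(vt, ped, cfg)


class TestSequencingErrors:
    def test_zero_rate_is_identity(self, tiny_pop, tiny_cfg):
        cfg = SimConfig(**{**tiny_cfg.to_dict(), "error_rate": 0.0})
        out = inject_sequencing_errors(tiny_pop["vt_visible"], cfg)
        np.testing.assert_array_equal(out.genotypes, tiny_pop["vt_visible"].genotypes)

    def test_rate_one_flips_every_monomorphic_zero(self):
        cfg = SimConfig(n_founders=10, n_generations=1, n_sires_per_gen=1,
                        n_sons_per_sire=1, n_variants=4, error_rate=1.0, seed=0)
        ped = simulate_pedigree(cfg)
        vt = simulate_genotypes(ped, cfg, founder_freqs=np.zeros(4))
        out = inject_sequencing_errors(vt, cfg)
        assert np.all(out.genotypes == 1)

    def test_flip_count_binomial_oracle(self):
        cfg = SimConfig(n_founders=50, n_generations=1, n_sires_per_gen=1,
                        n_sons_per_sire=1, n_variants=200, error_rate=0.02,
                        n_spurious_sites=0, seed=9)
        ped = simulate_pedigree(cfg)
        vt = simulate_genotypes(ped, cfg, founder_freqs=np.zeros(200))
        out = inject_sequencing_errors(vt, cfg)
        n_slots = vt.genotypes.size  # all-zero table: every slot eligible
        flips = int((out.genotypes != vt.genotypes).sum())
        expect = 0.02 * n_slots
        se = np.sqrt(n_slots * 0.02 * 0.98)
        assert abs(flips - expect) <= 3 * se

    def test_input_table_untouched_and_spurious_appended(self, tiny_pop, tiny_cfg):
        vt = tiny_pop["vt_visible"]
        before = vt.genotypes.copy()
        cfg = SimConfig(**{**tiny_cfg.to_dict(), "n_spurious_sites": 7})
        out = inject_sequencing_errors(vt, cfg)
        np.testing.assert_array_equal(vt.genotypes, before)
        assert out.n_sites == vt.n_sites + 7
        spurious = out.genotypes[:, vt.n_sites:]
        assert set(np.unique(spurious)) <= {0, 1}

    def test_calibrated_false_het_fraction(self):
        """inject_false_heterozygotes hits the requested false/total het ratio."""
        rng = np.random.default_rng(4)
        G = rng.choice([0, 1], p=[0.9, 0.1], size=(200, 2000)).astype(np.int8)
        from conftest import make_variant_table
        vt = make_variant_table(G)
        true_het = int((G == 1).sum())
        out = inject_false_heterozygotes(
            vt, np.arange(200), np.ones(2000, dtype=bool), 0.5,
            np.random.default_rng(5),
        )
        false_het = int((out.genotypes == 1).sum()) - true_het
        ratio = false_het / (true_het + false_het)
        assert abs(ratio - 0.5) < 0.02


def test_unrelated_pairs_are_disjoint_founders(tiny_pop):
    ped = tiny_pop["ped"]
    pairs = unrelated_pairs(ped, 5, seed=1)
    founders = set(ped.founders())
    seen = set()
    for a, b in pairs:
        assert a in founders and b in founders
        assert a not in seen and b not in seen
        seen |= {a, b}
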