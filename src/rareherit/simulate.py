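"""Synthetic population generator.

Emulates the data structure of a dairy-cattle sequence study: a
multi-generation sire pedigree with sequenced sire-son duos, gene-dropped
genotypes from a rare-heavy founder site-frequency spectrum, daughter-trait-
deviation phenotypes with per-animal residual weights, additive genetic
variance split across MAF classes (with an "untyped polygenic" share carried
by causal sites hidden from the genotype table), and false-heterozygote
sequencing errors concentrated at rare and monomorphic sites.

All randomness flows from ``SimConfig.seed``; each stage draws from an
independent, reproducible substream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimConfig
from .datatypes import MISSING, Pedigree, PhenotypeSet, VariantTable

# substream tags so that successive stages never share a generator state
_PEDIGREE, _GENOTYPES, _EFFECTS, _ERRORS = 1, 2, 3, 4


def _rng(tag: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([tag, seed])


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Simulate a multi-generation pedigree with sequenced sire-son duos.

    Founders (generation 0, unknown parents) are split equally into males
    and females.  In each later generation, ``n_sires_per_gen`` sires are
    drawn from the previous generation's males and each produces
    ``n_sons_per_sire`` sons and as many daughters, with dams drawn at
    random from the previous generation's females.  The sire-son pairs of
    the final generation are flagged as the available sequenced duos
    (``n_sires_per_gen * n_sons_per_sire`` of them; 38 under the defaults).
    """
    rng = _rng(_PEDIGREE, config.seed)
    rows: list[tuple] = []
    males: list[str] = []
    females: list[str] = []
    for k in range(config.n_founders):
        sex = "M" if k % 2 == 0 else "F"
        animal = f"G0{sex}{k:04d}"
        rows.append((animal, None, None, sex))
        (males if sex == "M" else females).append(animal)

    duos: list[tuple[str, str]] = []
    for gen in range(1, config.n_generations + 1):
        if len(males) < config.n_sires_per_gen:
            raise ConfigurationError(
                f"generation {gen}: need {config.n_sires_per_gen} sires but only "
                f"{len(males)} males are available; increase n_founders"
            )
        if not females:
            raise ConfigurationError(f"generation {gen}: no dams available")
        sires = list(rng.choice(males, size=config.n_sires_per_gen, replace=False))
        new_males: list[str] = []
        new_females: list[str] = []
        last_gen = gen == config.n_generations
        for s_idx, sire in enumerate(sires):
            for c_idx in range(config.n_sons_per_sire):
                dam = females[rng.integers(len(females))]
                son = f"G{gen}M{s_idx:03d}{c_idx:02d}"
                rows.append((son, sire, dam, "M"))
                new_males.append(son)
                if last_gen:
                    duos.append((sire, son))
                dam = females[rng.integers(len(females))]
                daughter = f"G{gen}F{s_idx:03d}{c_idx:02d}"
                rows.append((daughter, sire, dam, "F"))
                new_females.append(daughter)
        males, females = new_males, new_females

    records = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"])
    return Pedigree(records=records, duos=duos)


def unrelated_pairs(pedigree: Pedigree, n_pairs: int, seed: int = 0) -> list[tuple[str, str]]:
    """Disjoint founder pairs, used as the unrelated control sample."""
    founders = pedigree.founders()
    if len(founders) < 2 * n_pairs:
        raise ConfigurationError(
            f"{n_pairs} unrelated pairs need {2 * n_pairs} founders, "
            f"pedigree has {len(founders)}"
        )
    rng = np.random.default_rng([17, seed])
    chosen = rng.choice(founders, size=2 * n_pairs, replace=False)
    return [(chosen[2 * k], chosen[2 * k + 1]) for k in range(n_pairs)]


def sample_maf_spectrum(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw founder allele frequencies from the configured spectrum.

    The 'neutral' default has density proportional to 1/p on
    [1/(2*n_founders), 0.5], a rare-heavy spectrum in which roughly a third
    of sites fall below MAF 0.01 for typical founder counts.  The 'beta'
    option draws Beta(a, b) and folds to the minor-allele range.
    """
    p_min = 1.0 / (2.0 * config.n_founders)
    p_max = 0.5
    shape = config.maf_spectrum.get("shape", "neutral")
    if shape == "neutral":
        u = rng.uniform(size=n)
        return p_min * (p_max / p_min) ** u
    if shape == "beta":
        params = config.maf_spectrum.get("params", {})
        a = params.get("a", 0.5)
        b = params.get("b", 0.5)
        p = rng.beta(a, b, size=n)
        p = np.minimum(p, 1.0 - p)
        return np.clip(p, p_min, p_max)
    raise ConfigurationError(f"unknown maf_spectrum shape {shape!r}")


def simulate_genotypes(
    pedigree: Pedigree,
    config: SimConfig,
    founder_freqs: np.ndarray | None = None,
) -> VariantTable:
    """Gene-drop genotypes through the pedigree.

    Founder genotypes are Binomial(2, p_k) per site; every non-founder
    receives one allele from each parent, Binomial(1, g_parent/2).  No
    genotyping errors are introduced here (see
    :func:`inject_sequencing_errors`).
    """
    rng = _rng(_GENOTYPES, config.seed)
    m = config.n_variants
    if founder_freqs is None:
        founder_freqs = sample_maf_spectrum(m, config, rng)
    else:
        founder_freqs = np.asarray(founder_freqs, dtype=float)
        if founder_freqs.shape != (m,):
            raise ConfigurationError("founder_freqs length must equal n_variants")

    ids = pedigree.ids
    index = {a: k for k, a in enumerate(ids)}
    G = np.zeros((len(ids), m), dtype=np.int8)
    for _, row in pedigree.records.iterrows():
        i = index[row["id"]]
        if pd.isna(row["sire"]) and pd.isna(row["dam"]):
            G[i] = rng.binomial(2, founder_freqs)
        else:
            # both parents known by pedigree construction
            gs = G[index[row["sire"]]]
            gd = G[index[row["dam"]]]
            G[i] = rng.binomial(1, gs / 2.0) + rng.binomial(1, gd / 2.0)

    pos = np.cumsum(rng.integers(1, 200, size=m))
    sites = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos.astype(int),
            "ref": "A",
            "alt": "C",
            "qual": np.round(np.clip(rng.normal(60.0, 20.0, m), 1.0, None), 1),
            "mq": np.round(np.clip(rng.normal(50.0, 8.0, m), 0.0, 60.0), 1),
            "dp": rng.poisson(30, m).astype(int),
        }
    )
    vt = VariantTable(sites=sites, genotypes=G, sample_ids=list(ids))
    vt.founder_freqs = founder_freqs  # kept for diagnostics/tests
    return vt


def _minor_dosage(genotypes: np.ndarray, alt_freq: np.ndarray) -> np.ndarray:
    """Dosage of the minor allele (flips sites where ALT is the major allele)."""
    flip = alt_freq > 0.5
    g = genotypes.astype(float)
    g[:, flip] = 2.0 - g[:, flip]
    return g


def assign_effects_and_phenotypes(
    vt: VariantTable,
    pedigree: Pedigree,
    config: SimConfig,
    maf_rare: float = 0.01,
    maf_uncommon_upper: float = 0.05,
):
    """Draw class-stratified causal effects and phenotypes.

    Per MAF class with a positive variance share, ``n_causal_per_class``
    causal sites are drawn, standard-normal effects assigned, and the class
    genetic values rescaled so the realized variance equals
    ``share * h2 * phenotypic_variance`` exactly.  The untyped-polygenic
    share is carried by causal sites *removed* from the returned
    VariantTable, so only pedigree information can recover it.  Residuals
    are N(0, sigma_e^2 / w_i) with weights from a shifted Gamma.

    Returns
    -------
    (phenotypes, truth, vt_visible)
        ``truth`` maps class -> realized genetic variance plus the total
        genetic values and causal site positions, for recovery tests;
        ``vt_visible`` is the table with untyped causal sites removed.
    """
    rng = _rng(_EFFECTS, config.seed)
    n = vt.n_samples
    f = vt.alt_frequency()
    maf = np.minimum(f, 1.0 - f)
    poly = maf > 0
    classes = {
        "rare": poly & (maf < maf_rare),
        "uncommon": (maf >= maf_rare) & (maf < maf_uncommon_upper),
        "common": maf >= maf_uncommon_upper,
    }

    sigma_a2 = config.h2 * config.phenotypic_variance
    sigma_e2 = (1.0 - config.h2) * config.phenotypic_variance
    shares = config.variance_shares

    taken = np.zeros(vt.n_sites, dtype=bool)
    # untyped-polygenic causals come from the common pool (hidden afterwards)
    untyped_idx = np.array([], dtype=int)
    if shares.get("untyped_polygenic", 0.0) > 0:
        pool = np.flatnonzero(classes["common"])
        if pool.size == 0:
            raise ConfigurationError(
                "untyped_polygenic share > 0 but no common sites to hide"
            )
        untyped_idx = rng.choice(pool, size=min(config.n_causal_per_class, pool.size),
                                 replace=False)
        taken[untyped_idx] = True

    genetic_values: dict[str, np.ndarray] = {}
    causal_sites: dict[str, list[int]] = {}
    realized: dict[str, float] = {}

    def _class_value(idx: np.ndarray, target: float, label: str) -> np.ndarray:
        X = vt.genotypes[:, idx]
        if np.any(X == MISSING):
            raise ConfigurationError(f"missing genotypes at causal sites ({label})")
        beta = rng.normal(size=idx.size)
        g = X.astype(float) @ beta
        g -= g.mean()
        v = float(np.var(g))
        if v == 0.0:
            raise ConfigurationError(f"class {label!r}: causal sites carry no variation")
        return g * np.sqrt(target / v)

    for label in ("common", "uncommon", "rare"):
        share = shares.get(label, 0.0)
        if share == 0.0:
            genetic_values[label] = np.zeros(n)
            realized[label] = 0.0
            causal_sites[label] = []
            continue
        pool = np.flatnonzero(classes[label] & ~taken)
        if pool.size == 0:
            raise ConfigurationError(
                f"variance share for class {label!r} is positive but no eligible sites exist"
            )
        idx = rng.choice(pool, size=min(config.n_causal_per_class, pool.size),
                         replace=False)
        taken[idx] = True
        target = share * sigma_a2
        g = _class_value(idx, target, label)
        genetic_values[label] = g
        realized[label] = float(np.var(g))
        causal_sites[label] = sorted(vt.sites["pos"].iloc[idx].tolist())

    if untyped_idx.size > 0:
        target = shares["untyped_polygenic"] * sigma_a2
        g = _class_value(untyped_idx, target, "untyped_polygenic")
    else:
        g = np.zeros(n)
    genetic_values["untyped_polygenic"] = g
    realized["untyped_polygenic"] = float(np.var(g))
    causal_sites["untyped_polygenic"] = sorted(
        vt.sites["pos"].iloc[untyped_idx].tolist()
    )

    total_g = sum(genetic_values.values())

    wd = config.weight_distribution
    weights = wd.get("min", 1.0) + rng.gamma(wd.get("shape", 2.0),
                                             wd.get("scale", 2.0), size=n)
    residual = rng.normal(size=n) * np.sqrt(sigma_e2 / weights)
    y = total_g + residual

    phenotypes = PhenotypeSet(ids=list(vt.sample_ids), values=y, weights=weights,
                              trait_name="dtd")
    truth = {
        "variances": realized,
        "sigma_a2": sigma_a2,
        "sigma_e2": sigma_e2,
        "genetic_values": genetic_values,
        "total_genetic_value": total_g,
        "causal_sites": causal_sites,
    }
    vt_visible = vt.take_sites(~np.isin(np.arange(vt.n_sites), untyped_idx))
    return phenotypes, truth, vt_visible


def inject_sequencing_errors(
    vt: VariantTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> VariantTable:
    """Flip 0 -> 1 at rare/monomorphic sites and append spurious sites.

    Each homozygous-reference genotype at a site with MAF < 0.01 (including
    monomorphic sites) becomes a false heterozygote with probability
    ``config.error_rate``.  ``config.n_spurious_sites`` entirely spurious
    sites — true frequency zero, only error-generated heterozygotes — are
    appended at the end of the last chromosome.  The input table is not
    modified.
    """
    if rng is None:
        rng = _rng(_ERRORS, config.seed)
    if config.error_rate == 0.0:
        # no error process: identity (spurious sites would be all-zero too)
        return VariantTable(sites=vt.sites.copy(), genotypes=vt.genotypes.copy(),
                            sample_ids=list(vt.sample_ids))
    G = vt.genotypes.copy()
    f = vt.alt_frequency()
    maf = np.minimum(f, 1.0 - f)
    target = np.isnan(maf) | (maf < 0.01)
    if config.error_rate > 0 and target.any():
        sub = G[:, target]
        flips = (sub == 0) & (rng.uniform(size=sub.shape) < config.error_rate)
        sub[flips] = 1
        G[:, target] = sub
    sites = vt.sites.copy()

    if config.n_spurious_sites > 0:
        k = config.n_spurious_sites
        last_chrom = sites["chrom"].iloc[-1]
        last_pos = int(sites.loc[sites["chrom"] == last_chrom, "pos"].max())
        pos = last_pos + np.cumsum(rng.integers(1, 200, size=k))
        extra = pd.DataFrame(
            {
                "chrom": last_chrom,
                "pos": pos.astype(int),
                "ref": "A",
                "alt": "T",
                "qual": np.round(np.clip(rng.normal(60.0, 20.0, k), 1.0, None), 1),
                "mq": np.round(np.clip(rng.normal(50.0, 8.0, k), 0.0, 60.0), 1),
                "dp": rng.poisson(30, k).astype(int),
            }
        )
        spurious = (rng.uniform(size=(vt.n_samples, k)) < config.error_rate).astype(np.int8)
        sites = pd.concat([sites, extra], ignore_index=True)
        G = np.hstack([G, spurious])

    return VariantTable(sites=sites, genotypes=G, sample_ids=list(vt.sample_ids))


def inject_false_heterozygotes(
    vt: VariantTable,
    carrier_rows: list[int] | np.ndarray,
    site_mask: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
) -> VariantTable:
    """Make ``fraction`` of heterozygous calls among ``carrier_rows`` false.

    For each selected site, homozygous-reference genotypes of the carrier
    rows are flipped to heterozygous with a probability calibrated so that
    the expected ratio false-het / (true-het + false-het) equals
    ``fraction``.  Used to create data sets with a known per-bin error
    fraction for the transmission-based error estimator.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    G = vt.genotypes.copy()
    rows = np.asarray(carrier_rows, dtype=int)
    for j in np.flatnonzero(site_mask):
        col = G[rows, j]
        t = int((col == 1).sum())
        zeros = np.flatnonzero(col == 0)
        if t == 0 or zeros.size == 0 or fraction == 0.0:
            continue
        p_flip = min(1.0, t * fraction / ((1.0 - fraction) * zeros.size))
        flip = zeros[rng.uniform(size=zeros.size) < p_flip]
        col[flip] = 1
        G[rows, j] = col
    return VariantTable(sites=vt.sites.copy(), genotypes=G, sample_ids=list(vt.sample_ids))
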