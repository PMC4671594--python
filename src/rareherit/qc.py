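"""Variant quality control: hard filters, proximity rules, MAF classes, LD pruning.

The filter set mirrors standard multi-sample short-read calling practice:
multi-allelic sites, low QUAL / mapping quality, out-of-range depth, excess
opposing homozygotes in parent-offspring pairs (a Mendelian impossibility),
SNPs overlapping indels, and proximity conflicts resolved in favour of the
higher-QUAL site.  Sites are then classed as rare (MAF < 0.01), uncommon
(0.01 <= MAF < 0.05) or common (MAF >= 0.05) and near-duplicate sites
(genotypic r^2 > 0.999) are pruned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, VariantTable


@dataclass
class QCThresholds:
    min_qual: float = 20.0
    min_mq: float = 30.0
    min_dp: float = 10.0
    dp_upper_sd: float = 3.0          # upper cut: median(DP) + dp_upper_sd * SD(DP)
    max_opposing_hom_fraction: float = 0.10
    indel_indel_window: int = 10      # bp
    any_variant_window: int = 3       # bp
    ld_r2_max: float = 0.999
    ld_window_bp: int = 1_000_000
    maf_rare: float = 0.01
    maf_uncommon_upper: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_rare < self.maf_uncommon_upper <= 0.5):
            raise ValueError("need 0 < maf_rare < maf_uncommon_upper <= 0.5")


#: order in which filter rules are applied; removal counts use
#: first-failure attribution in this order.
FILTER_RULES = [
    "missing_qc_fields",
    "multi_allelic",
    "low_qual",
    "low_mq",
    "low_dp",
    "high_dp",
    "opposing_homozygotes",
    "snp_overlaps_indel",
]


def filter_sites(
    vt: VariantTable,
    duos: list[tuple[str, str]] | None = None,
    thresholds: QCThresholds | None = None,
) -> tuple[VariantTable, dict[str, int]]:
    """Apply the hard site filters; returns survivors and per-rule counts.

    A site failing several rules is counted once, under the first failing
    rule in :data:`FILTER_RULES` order.  Sites with missing QUAL/MQ/DP are
    removed under ``missing_qc_fields`` rather than silently passed.  The
    depth upper bound is median(DP) + 3*SD(DP) computed on the input table.
    """
    th = thresholds or QCThresholds()
    duos = duos or []
    sites = vt.sites
    n = len(sites)
    counts = {rule: 0 for rule in FILTER_RULES}
    if n == 0:
        return vt, counts

    qual = pd.to_numeric(sites["qual"], errors="coerce").to_numpy(dtype=float)
    mq = pd.to_numeric(sites["mq"], errors="coerce").to_numpy(dtype=float)
    dp = pd.to_numeric(sites["dp"], errors="coerce").to_numpy(dtype=float)
    dp_obs = dp[~np.isnan(dp)]
    dp_hi = np.inf
    if dp_obs.size:
        dp_hi = float(np.median(dp_obs) + th.dp_upper_sd * np.std(dp_obs))

    multi = sites["alt"].astype(str).str.contains(",").to_numpy()

    opp_frac = np.zeros(n)
    if duos:
        pairs = [(vt.sample_index(s), vt.sample_index(o)) for s, o in duos]
        opp = np.zeros(n)
        for si, oi in pairs:
            gs, go = vt.genotypes[si], vt.genotypes[oi]
            opp += ((gs == 0) & (go == 2)) | ((gs == 2) & (go == 0))
        opp_frac = opp / len(pairs)

    is_indel = vt.is_indel()
    # SNP sharing a bp position with an indel
    snp_on_indel = np.zeros(n, dtype=bool)
    key = sites["chrom"].astype(str) + ":" + sites["pos"].astype(str)
    indel_keys = set(key[is_indel])
    if indel_keys:
        snp_on_indel = (~is_indel) & key.isin(indel_keys).to_numpy()

    fails = {
        "missing_qc_fields": np.isnan(qual) | np.isnan(mq) | np.isnan(dp),
        "multi_allelic": multi,
        "low_qual": qual < th.min_qual,
        "low_mq": mq < th.min_mq,
        "low_dp": dp < th.min_dp,
        "high_dp": dp > dp_hi,
        "opposing_homozygotes": opp_frac > th.max_opposing_hom_fraction,
        "snp_overlaps_indel": snp_on_indel,
    }

    removed = np.zeros(n, dtype=bool)
    for rule in FILTER_RULES:
        mask = np.nan_to_num(fails[rule], nan=False).astype(bool) & ~removed
        counts[rule] = int(mask.sum())
        removed |= mask

    return vt.take_sites(~removed), counts


def proximity_filter(vt: VariantTable, thresholds: QCThresholds | None = None) -> VariantTable:
    """Remove the lower-QUAL member of proximal variant pairs.

    First pass: indels within ``indel_indel_window`` bp of another indel;
    second pass: any variant within ``any_variant_window`` bp of another
    variant.  QUAL ties remove the later site by position.
    """
    th = thresholds or QCThresholds()
    keep = np.ones(vt.n_sites, dtype=bool)
    is_indel = vt.is_indel()

    def _pass(window: int, eligible: np.ndarray) -> None:
        for _, grp in vt.sites.groupby("chrom", sort=False):
            idx = [i for i in grp.index if keep[i] and eligible[i]]
            survivors: list[int] = []
            for i in idx:
                pos_i = vt.sites.at[i, "pos"]
                qual_i = vt.sites.at[i, "qual"]
                while survivors:
                    j = survivors[-1]
                    if pos_i - vt.sites.at[j, "pos"] > window:
                        break
                    if vt.sites.at[j, "qual"] < qual_i:
                        keep[j] = False
                        survivors.pop()
                    else:
                        # lower (or tied) QUAL at the later position: drop i
                        keep[i] = False
                        break
                if keep[i]:
                    survivors.append(i)

    _pass(th.indel_indel_window, is_indel)
    _pass(th.any_variant_window, np.ones(vt.n_sites, dtype=bool))
    return vt.take_sites(keep)


def classify_maf(vt: VariantTable, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Per-site minor-allele frequency and class label.

    MAF is min(f, 1-f) of the ALT frequency over non-missing genotypes.
    Classes: monomorphic (MAF = 0, including all-missing sites, whose MAF
    is reported as 0), rare (0 < MAF < 0.01), uncommon (0.01 <= MAF < 0.05)
    and common (MAF >= 0.05); the boundaries are inclusive upward, so MAF
    exactly 0.01 is uncommon and exactly 0.05 common.
    """
    th = thresholds or QCThresholds()
    f = vt.alt_frequency()
    maf = np.minimum(f, 1.0 - f)
    maf = np.where(np.isnan(maf), 0.0, maf)
    labels = np.where(
        maf == 0.0,
        "monomorphic",
        np.where(
            maf < th.maf_rare,
            "rare",
            np.where(maf < th.maf_uncommon_upper, "uncommon", "common"),
        ),
    )
    return pd.DataFrame({"maf": maf, "maf_class": labels}, index=vt.sites.index)


def prune_ld(
    vt: VariantTable,
    thresholds: QCThresholds | None = None,
) -> tuple[VariantTable, int]:
    """Greedy left-to-right LD pruning within a bp window per chromosome.

    For each pair of retained sites within ``ld_window_bp`` whose genotype
    dosages have squared Pearson correlation > ``ld_r2_max``, the later site
    (by position) is removed.  Monomorphic / zero-variance sites are
    excluded up front and counted in the returned warning count.
    """
    th = thresholds or QCThresholds()
    G = vt.genotypes.astype(float)
    G[vt.genotypes == MISSING] = np.nan
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean, G)
    var = G.var(axis=0)
    zero_var = var == 0
    n_zero = int(zero_var.sum())

    keep = ~zero_var
    std = np.sqrt(np.where(zero_var, 1.0, var))
    Z = (G - G.mean(axis=0)) / std
    n = G.shape[0]

    for _, grp in vt.sites.groupby("chrom", sort=False):
        kept: list[int] = []
        for i in grp.index:
            if not keep[i]:
                continue
            pos_i = vt.sites.at[i, "pos"]
            while kept and pos_i - vt.sites.at[kept[0], "pos"] > th.ld_window_bp:
                kept.pop(0)
            if kept:
                r = Z[:, kept].T @ Z[:, i] / n
                if np.any(r * r > th.ld_r2_max):
                    keep[i] = False
                    continue
            kept.append(i)

    return vt.take_sites(keep), n_zero


def qc_report(counts: dict[str, int]) -> pd.DataFrame:
    """Per-rule removal counts as a (rule, count) table."""
    return pd.DataFrame({"rule": list(counts), "count": list(counts.values())})
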