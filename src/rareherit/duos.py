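"""Sire-son duo validation of rare variants.

A sire heterozygous for a site's minor allele transmits it to his son with
probability 0.5; the son can additionally receive the allele from his dam,
so under random mating the probability that the son carries at least one
copy is

    p(carrier son | het sire) = 0.5 * (1 - MAF) + MAF = 0.5 + 0.5 * MAF.

Genuine rare variants therefore reappear in the son at a rate near 0.5,
while false heterozygote calls (sequencing errors) do not, which makes the
deficit of observed vs expected transmission a per-MAF-bin estimate of the
error fraction.  The module also resamples duo subsets to trace how the
count of validated rare variants saturates with the number of duos, and
projects the duos needed via quadratic and exponential-saturation fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datatypes import MISSING, VariantTable
from .qc import QCThresholds, classify_maf


def expected_transmission(maf):
    """Theoretical carrier probability for the son given a heterozygous sire.

    ``0.5 * (1 - maf) + maf``: one half from the sire plus the chance the
    dam contributes a copy.  Affine in MAF with slope 0.5, range [0.5, 0.75]
    on the valid domain [0, 0.5].
    """
    arr = np.asarray(maf, dtype=float)
    if np.any(arr < 0) or np.any(arr > 0.5):
        raise ValueError("maf must lie in [0, 0.5]")
    out = 0.5 * (1.0 - arr) + arr
    return float(out) if np.isscalar(maf) else out


def make_maf_bins(maf: np.ndarray, n_bins: int = 25) -> np.ndarray:
    """Equal-count bin edges over (0, 0.5] from the polymorphic MAF values."""
    poly = np.asarray(maf, dtype=float)
    poly = poly[poly > 0]
    if poly.size == 0:
        raise ValueError("no polymorphic sites to bin")
    qs = np.quantile(poly, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    edges[0] = 0.0
    edges[-1] = 0.5
    return edges


def _minor_orientation(vt: VariantTable) -> np.ndarray:
    """True where ALT is the major allele (minor dosage = 2 - genotype)."""
    return vt.alt_frequency() > 0.5


def duo_reference_maf(vt: VariantTable, duos: list[tuple[str, str]]) -> np.ndarray:
    """Per-site MAF computed over animals outside every duo.

    Binning transmission observations by a MAF estimate that includes the
    duo members themselves is circular: a non-transmitted allele lowers the
    site's sample frequency, sorting exactly the non-transmitting sites
    into the lowest bins and biasing observed transmission downward there.
    Frequencies from the non-duo animals (the reference population) avoid
    this.  Falls back to the full sample when every animal is in a duo.
    """
    members = {a for pair in duos for a in pair}
    rows = [i for i, a in enumerate(vt.sample_ids) if a not in members]
    if not rows:
        f = vt.alt_frequency()
    else:
        g = vt.genotypes[rows]
        obs = g != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            f = np.where(n > 0, np.where(obs, g, 0).sum(axis=0) / (2 * n), np.nan)
    maf = np.minimum(f, 1.0 - f)
    return np.where(np.isnan(maf), 0.0, maf)


def observed_transmission(
    vt: VariantTable,
    duos: list[tuple[str, str]],
    bins: np.ndarray,
    maf: np.ndarray | None = None,
    alt_freq: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-duo, per-bin proportion of sire-het sites with a carrier son.

    Numerator: sites where the sire is heterozygous and the son carries at
    least one copy of the minor allele; denominator: sites where the sire
    is heterozygous (both genotypes observed).  A duo/bin with an empty
    denominator gets proportion NaN (flagged, never 0).
    """
    if maf is None:
        maf = classify_maf(vt)["maf"].to_numpy()
    maf = np.asarray(maf, dtype=float)
    bins = np.asarray(bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bin edges must be strictly ascending")
    # orient the minor allele by the same reference the MAF came from
    flip = _minor_orientation(vt) if alt_freq is None else np.asarray(alt_freq) > 0.5

    # bin index per site; polymorphic sites only
    bin_idx = np.digitize(maf, bins[1:-1], right=True)
    in_range = (maf > bins[0]) & (maf <= bins[-1])

    rows = []
    for d, (sire, son) in enumerate(duos):
        gs = vt.genotypes[vt.sample_index(sire)]
        go = vt.genotypes[vt.sample_index(son)]
        ok = (gs != MISSING) & (go != MISSING) & in_range
        sire_het = ok & (gs == 1)
        minor_go = np.where(flip, 2 - go, go)
        carrier = sire_het & (minor_go >= 1)
        for b in range(len(bins) - 1):
            sel = bin_idx == b
            denom = int((sire_het & sel).sum())
            numer = int((carrier & sel).sum())
            center = 0.5 * (bins[b] + bins[b + 1])
            rows.append(
                {
                    "duo": d,
                    "sire": sire,
                    "son": son,
                    "bin": b,
                    "bin_center": center,
                    # MAF where the observations actually sit (used for the
                    # theoretical expectation); midpoint when bin is empty
                    "mean_maf": float(maf[sire_het & sel].mean()) if denom else center,
                    "n_sire_het": denom,
                    "n_transmitted": numer,
                    "proportion": numer / denom if denom else np.nan,
                }
            )
    return pd.DataFrame(rows)


def pooled_transmission(per_duo: pd.DataFrame) -> pd.DataFrame:
    """Pool numerators/denominators across duos per MAF bin.

    ``mean_maf`` is the sire-het-weighted mean MAF across duos, so the
    theoretical expectation is evaluated where the observations sit.
    """
    per_duo = per_duo.assign(_w=per_duo["mean_maf"] * per_duo["n_sire_het"])
    g = per_duo.groupby("bin")
    out = g.agg(
        bin_center=("bin_center", "first"),
        n_sire_het=("n_sire_het", "sum"),
        n_transmitted=("n_transmitted", "sum"),
        _w=("_w", "sum"),
    ).reset_index()
    out["mean_maf"] = np.where(
        out["n_sire_het"] > 0, out["_w"] / out["n_sire_het"], out["bin_center"]
    )
    out = out.drop(columns="_w")
    out["proportion"] = np.where(
        out["n_sire_het"] > 0, out["n_transmitted"] / out["n_sire_het"], np.nan
    )
    return out


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.2,
    grid: np.ndarray | None = None,
    degree: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Locally weighted polynomial regression (tricube weights, degree 2).

    At each grid point, the ``span`` fraction of nearest data points gets
    tricube weights by distance and a weighted degree-2 polynomial is
    fitted; the fitted value at the grid point is returned.  Deterministic
    given inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 10:
        raise ValueError(f"loess needs >= 10 points, got {n}")
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 101)
    grid = np.asarray(grid, dtype=float)

    k = max(int(math.ceil(span * n)), degree + 2)
    k = min(k, n)
    fitted = np.empty(grid.size)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        order = np.argsort(d, kind="stable")[:k]
        dmax = d[order[-1]]
        if dmax == 0.0:
            fitted[i] = y[order].mean()
            continue
        w = (1.0 - np.minimum(d[order] / dmax, 1.0) ** 3) ** 3
        pos = w > 0
        xs, ys, ws = x[order][pos], y[order][pos], w[pos]
        deg = min(degree, len(np.unique(xs)) - 1)
        if deg < 1:
            fitted[i] = np.average(ys, weights=ws)
            continue
        # weighted LS in the centered monomial basis for conditioning
        B = np.vander(xs - x0, deg + 1, increasing=True)
        sw = np.sqrt(ws)
        coef, *_ = np.linalg.lstsq(B * sw[:, None], ys * sw, rcond=None)
        fitted[i] = coef[0]
    return grid, fitted


def control_band(
    vt: VariantTable,
    unrelated_pairs: list[tuple[str, str]],
    bins: np.ndarray,
    span: float = 0.2,
    grid: np.ndarray | None = None,
    mode: str = "minmax",
    quantiles: tuple[float, float] = (0.05, 0.95),
    maf: np.ndarray | None = None,
    alt_freq: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pointwise envelope of per-pair loess curves for unrelated controls.

    Each unrelated pair is scored with the same sire-het / carrier-"son"
    statistic; the band is the pointwise min-max (default) or quantile
    envelope across the per-pair smoothed curves.
    """
    if len(unrelated_pairs) < 2:
        raise ValueError("control band needs >= 2 unrelated pairs")
    per_pair = observed_transmission(vt, unrelated_pairs, bins, maf=maf, alt_freq=alt_freq)
    if grid is None:
        centers = per_pair["bin_center"].unique()
        grid = np.linspace(centers.min(), centers.max(), 101)
    curves = []
    for _, sub in per_pair.groupby("duo"):
        sub = sub.dropna(subset=["proportion"])
        _, fit = loess_fit(sub["bin_center"], sub["proportion"], span=span, grid=grid)
        curves.append(fit)
    curves = np.vstack(curves)
    if mode == "minmax":
        lower, upper = curves.min(axis=0), curves.max(axis=0)
    elif mode == "quantile":
        lower = np.quantile(curves, quantiles[0], axis=0)
        upper = np.quantile(curves, quantiles[1], axis=0)
    else:
        raise ValueError(f"unknown control-band mode {mode!r}")
    return pd.DataFrame(
        {"maf": grid, "lower": lower, "upper": upper, "center": curves.mean(axis=0)}
    )


def estimate_error_fraction(observed: np.ndarray, maf_bin_centers: np.ndarray) -> np.ndarray:
    """Per-bin fraction of sire-het calls behaving as non-transmissible.

    ``clip(1 - observed / expected, 0, 1)``: the relative deficit of
    observed transmission against the theoretical carrier probability.
    """
    observed = np.asarray(observed, dtype=float)
    exp = expected_transmission(np.asarray(maf_bin_centers, dtype=float))
    with np.errstate(invalid="ignore"):
        return np.clip(1.0 - observed / exp, 0.0, 1.0)


def _validation_matrix(
    vt: VariantTable,
    duos: list[tuple[str, str]],
    site_idx: np.ndarray,
    strict_het: bool,
) -> np.ndarray:
    """Boolean (n_duos, len(site_idx)): duo d validates site j."""
    flip = _minor_orientation(vt)[site_idx]
    M = np.zeros((len(duos), site_idx.size), dtype=bool)
    for d, (sire, son) in enumerate(duos):
        gs = vt.genotypes[vt.sample_index(sire), site_idx]
        go = vt.genotypes[vt.sample_index(son), site_idx]
        ok = (gs != MISSING) & (go != MISSING)
        if strict_het:
            M[d] = ok & (gs == 1) & (go == 1)
        else:
            ms = np.where(flip, 2 - gs, gs)
            mo = np.where(flip, 2 - go, go)
            M[d] = ok & (ms >= 1) & (mo >= 1)
    return M


def validate_rare_variants(
    vt: VariantTable,
    duos: list[tuple[str, str]],
    thresholds: QCThresholds | None = None,
    strict_het: bool = False,
    site_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Rare sites carried by both members of at least one duo.

    Default mode requires both sire and son to carry >= 1 copy of the minor
    allele; ``strict_het`` requires both to be heterozygous.  Returns the
    validated (chrom, pos) site list.
    """
    if not duos:
        raise ValueError("need at least one duo")
    classing = classify_maf(vt, thresholds)
    rare = (classing["maf_class"] == "rare").to_numpy()
    if site_mask is not None:
        rare &= np.asarray(site_mask, dtype=bool)
    idx = np.flatnonzero(rare)
    M = _validation_matrix(vt, duos, idx, strict_het)
    validated = idx[M.any(axis=0)]
    return vt.sites.iloc[validated][["chrom", "pos"]].reset_index(drop=True)


def saturation_resample(
    vt: VariantTable,
    duos: list[tuple[str, str]],
    n_replicates: int = 50,
    seed: int = 0,
    thresholds: QCThresholds | None = None,
    strict_het: bool = False,
    site_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Validated-variant counts for random duo subsets of every size.

    For each N in 1..len(duos), draws ``n_replicates`` subsets of N duos
    (without replacement within a subset) and counts the distinct rare
    variants validated by the subset.  Columns: n_duos, replicate, count.
    """
    if not duos:
        raise ValueError("need at least one duo")
    classing = classify_maf(vt, thresholds)
    rare = (classing["maf_class"] == "rare").to_numpy()
    if site_mask is not None:
        rare &= np.asarray(site_mask, dtype=bool)
    idx = np.flatnonzero(rare)
    M = _validation_matrix(vt, duos, idx, strict_het)
    rng = np.random.default_rng(seed)
    D = len(duos)
    rows = []
    for n_duos in range(1, D + 1):
        for rep in range(n_replicates):
            chosen = rng.choice(D, size=n_duos, replace=False)
            count = int(M[chosen].any(axis=0).sum())
            rows.append({"n_duos": n_duos, "replicate": rep, "count": count})
    return pd.DataFrame(rows)


@dataclass
class QuadraticFit:
    """y = a + b*N + c*N^2 with its vertex-based projection."""

    a: float
    b: float
    c: float
    duos_needed: int | None
    projected_max: float | None

    @property
    def concave(self) -> bool:
        return self.c < 0


def quadratic_projection(a: float, b: float, c: float) -> QuadraticFit:
    """Vertex projection for a fitted saturation quadratic.

    ``duos_needed`` is the ceiling of the vertex abscissa -b/(2c) — the
    minimum whole number of duos at which the fitted count stops growing —
    and ``projected_max`` the quadratic evaluated at the exact vertex.
    Non-concave fits (c >= 0) have no projection.
    """
    if c >= 0:
        return QuadraticFit(a, b, c, None, None)
    vertex = -b / (2.0 * c)
    y_max = a + b * vertex + c * vertex * vertex
    return QuadraticFit(a, b, c, int(math.ceil(vertex)), float(y_max))


def fit_quadratic(counts: pd.DataFrame, per_n_means: bool = False) -> QuadraticFit:
    """OLS quadratic of validated count on number of duos.

    Fits over all replicate points by default (matching the
    boxplot-plus-regression presentation); ``per_n_means`` fits on per-N
    mean counts instead.
    """
    if counts["n_duos"].nunique() < 3:
        raise ValueError("quadratic fit needs >= 3 distinct duo counts")
    if per_n_means:
        d = counts.groupby("n_duos")["count"].mean().reset_index()
        x, y = d["n_duos"].to_numpy(float), d["count"].to_numpy(float)
    else:
        x, y = counts["n_duos"].to_numpy(float), counts["count"].to_numpy(float)
    c, b, a = np.polyfit(x, y, 2)
    return quadratic_projection(float(a), float(b), float(c))


@dataclass
class SaturationFit:
    """y = T(1 - exp(-k N)): asymptotic total T and per-duo rate k."""

    T: float
    k: float

    def __call__(self, n):
        return self.T * (1.0 - np.exp(-self.k * np.asarray(n, dtype=float)))


def fit_saturation(counts: pd.DataFrame) -> SaturationFit:
    """Nonlinear least squares of per-N mean counts on T(1 - e^(-kN)).

    Initialization: T0 = 1.1 * max count, k0 from inverting the model at
    the mean count and mean N; trust-region reflective steps with positive
    bounds, relative tolerance 1e-8, iteration cap 500.
    """
    d = counts.groupby("n_duos")["count"].mean().reset_index()
    if len(d) < 3:
        raise ValueError("saturation fit needs >= 3 distinct duo counts")
    x = d["n_duos"].to_numpy(float)
    y = d["count"].to_numpy(float)
    if np.any(y <= 0):
        raise ValueError("saturation fit needs positive counts")
    T0 = 1.1 * y.max()
    ratio = min(np.mean(y) / T0, 1.0 - 1e-12)
    k0 = -math.log(1.0 - ratio) / np.mean(x)

    def resid(theta):
        T, k = theta
        return T * (1.0 - np.exp(-k * x)) - y

    sol = least_squares(
        resid,
        x0=[T0, k0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=1e-8,
        ftol=1e-8,
        gtol=1e-8,
        max_nfev=500,
    )
    if not sol.success:
        raise RuntimeError(
            f"saturation fit did not converge: {sol.message}; last iterate {sol.x}"
        )
    return SaturationFit(T=float(sol.x[0]), k=float(sol.x[1]))
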