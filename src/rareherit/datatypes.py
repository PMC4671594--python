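"""Core in-memory containers shared by every pipeline stage.

The package operates on four objects: a :class:`Pedigree` (id/sire/dam triples
with a birth order), a :class:`VariantTable` (per-site metadata plus an
animals x sites dosage matrix), a :class:`PhenotypeSet` (daughter trait
deviations with per-animal residual weights), and a
:class:`RelationshipMatrix` (genomic G or pedigree A).

Genotypes count copies of the ALT allele: 0, 1, 2, with ``MISSING`` (-1) for
no-calls.  Positions are 1-based (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

#: required columns of ``VariantTable.sites``
SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "mq", "dp"]


@dataclass
class Pedigree:
    """Pedigree as id/sire/dam records sorted parents-before-offspring.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``id``, ``sire``, ``dam`` (object/str; unknown parent is
        ``None``) and ``sex`` ('M'/'F') where known.  Row order is birth
        order.
    duos : list of (sire_id, son_id)
        Sequenced sire-son pairs available for transmission validation.
    """

    records: pd.DataFrame
    duos: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def ids(self) -> list[str]:
        return list(self.records["id"])

    @property
    def birth_order(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.records["id"])}

    def founders(self) -> list[str]:
        r = self.records
        mask = r["sire"].isna() & r["dam"].isna()
        return list(r.loc[mask, "id"])

    def parents(self, animal: str) -> tuple[str | None, str | None]:
        row = self.records.loc[self.records["id"] == animal].iloc[0]
        sire = row["sire"] if pd.notna(row["sire"]) else None
        dam = row["dam"] if pd.notna(row["dam"]) else None
        return sire, dam

    def validate(self) -> None:
        """Check acyclicity (parents precede offspring) and parent closure."""
        seen: set[str] = set()
        for _, row in self.records.iterrows():
            for parent in (row["sire"], row["dam"]):
                if pd.notna(parent) and parent not in seen:
                    raise ValueError(
                        f"parent {parent!r} of {row['id']!r} does not precede it "
                        "in birth order (or is absent from the pedigree)"
                    )
            if row["id"] in seen:
                raise ValueError(f"duplicate id {row['id']!r}")
            seen.add(row["id"])
        for sire, son in self.duos:
            if sire == son:
                raise ValueError(f"degenerate duo ({sire!r}, {son!r})")


@dataclass
class VariantTable:
    """Per-site metadata plus an animals x sites ALT-dosage matrix."""

    sites: pd.DataFrame
    genotypes: np.ndarray  # (n_animals, n_sites) int8, MISSING = -1
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        valid = np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotype entries must be in {0, 1, 2, missing}")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            # ties allowed: a SNP and an indel may share a bp position
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not sorted on {chrom}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, animal: str) -> int:
        try:
            return self.sample_ids.index(animal)
        except ValueError:
            raise KeyError(f"animal {animal!r} not in genotype table") from None

    def take_sites(self, mask_or_idx) -> "VariantTable":
        """Subset sites (boolean mask or integer index), preserving order."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return VariantTable(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[:, idx],
            sample_ids=list(self.sample_ids),
        )

    def alt_frequency(self) -> np.ndarray:
        """Per-site ALT allele frequency over non-missing genotypes (NaN if none)."""
        g = self.genotypes
        obs = g != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, np.where(obs, g, 0).sum(axis=0) / (2 * n), np.nan)

    def is_indel(self) -> np.ndarray:
        ref = self.sites["ref"].astype(str).str.len()
        alt = self.sites["alt"].astype(str).str.len()
        return ((ref > 1) | (alt > 1)).to_numpy()


@dataclass
class PhenotypeSet:
    """Daughter trait deviations with per-animal residual weights w_i >= 1."""

    ids: list[str]
    values: np.ndarray
    weights: np.ndarray
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.ids) == len(self.values) == len(self.weights)):
            raise ValueError("ids, values and weights must have equal length")
        if np.any(self.weights <= 0):
            raise ValueError("residual weights must be strictly positive")

    def subset(self, ids: list[str]) -> "PhenotypeSet":
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = [pos[i] for i in ids]
        return PhenotypeSet(list(ids), self.values[idx], self.weights[idx], self.trait_name)


@dataclass
class RelationshipMatrix:
    """Symmetric animal x animal additive-relationship matrix.

    ``kind`` is 'genomic' (marker-based G) or 'pedigree' (numerator A);
    ``source`` tags the variant class ('common', 'rare', ...) or 'pedigree'.
    """

    matrix: np.ndarray
    ids: list[str]
    kind: str
    source: str
    n_markers: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")

    def align(self, ids: list[str]) -> np.ndarray:
        """Return the matrix reordered/subset to ``ids``."""
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return self.matrix[np.ix_(idx, idx)]

    def cross(self, row_ids: list[str], col_ids: list[str]) -> np.ndarray:
        pos = {i: k for k, i in enumerate(self.ids)}
        ri = np.array([pos[i] for i in row_ids])
        ci = np.array([pos[i] for i in col_ids])
        return self.matrix[np.ix_(ri, ci)]
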