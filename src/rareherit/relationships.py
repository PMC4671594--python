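"""Genomic (G) and pedigree numerator (A) relationship matrices.

G follows the allele-frequency-standardized estimator of GREML practice:
off-diagonals are averages of (x_ik - 2p_k)(x_jk - 2p_k) / (2 p_k (1-p_k))
and the diagonal uses the distinct homozygosity-corrected form
1 + (x^2 - (1+2p)x + 2p^2) / (2p(1-p)), which has expectation 1 + F under
Hardy-Weinberg.  A is built by the tabular method from id/sire/dam records.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import MISSING, Pedigree, RelationshipMatrix, VariantTable


def build_grm(
    vt: VariantTable,
    freq_source: str | np.ndarray = "observed",
    yang_diagonal: bool = True,
    source: str = "genomic",
) -> RelationshipMatrix:
    """Genomic relationship matrix from an ALT-dosage table.

    Parameters
    ----------
    freq_source : "observed" or array of per-site ALT frequencies
        Frequencies p_k used for centering and scaling.
    yang_diagonal : bool
        Use the homozygosity-corrected diagonal (default); otherwise the
        plain cross-product diagonal.

    Missing genotypes are mean-imputed to 2 p_k (zero contribution after
    centering); the corrected diagonal is averaged over each animal's
    non-missing sites.  Monomorphic sites are an error — prune first.
    """
    m = vt.n_sites
    if m == 0:
        raise ValueError("cannot build a GRM from zero markers")
    if isinstance(freq_source, str):
        if freq_source != "observed":
            raise ValueError(f"unknown freq_source {freq_source!r}")
        p = vt.alt_frequency()
    else:
        p = np.asarray(freq_source, dtype=float)
        if p.shape != (m,):
            raise ValueError("frequency array length must equal number of sites")
    mono = ~((p > 0) & (p < 1))
    if mono.any():
        bad = vt.sites.loc[np.flatnonzero(mono)[:10], "pos"].tolist()
        raise ValueError(
            f"{int(mono.sum())} monomorphic site(s) in GRM input (first positions {bad})"
        )

    X = vt.genotypes.astype(float)
    missing = vt.genotypes == MISSING
    X[missing] = (2.0 * p)[np.where(missing)[1]]

    het = 2.0 * p * (1.0 - p)
    W = (X - 2.0 * p) / np.sqrt(het)
    G = (W @ W.T) / m

    if yang_diagonal:
        num = X * X - (1.0 + 2.0 * p) * X + 2.0 * p * p
        term = num / het
        term[missing] = np.nan
        m_i = (~missing).sum(axis=1)
        if np.any(m_i == 0):
            raise ValueError("an animal has no observed genotypes")
        diag = 1.0 + np.nansum(term, axis=1) / m_i
        np.fill_diagonal(G, diag)

    return RelationshipMatrix(
        matrix=G, ids=list(vt.sample_ids), kind="genomic", source=source, n_markers=m
    )


def build_nrm(pedigree: Pedigree) -> RelationshipMatrix:
    """Pedigree numerator relationship matrix by the tabular method.

    A_ij = 0.5 (A_{j,s(i)} + A_{j,d(i)}) for j preceding i, and
    A_ii = 1 + 0.5 A_{s(i),d(i)}; unknown parents contribute zero.
    Diagonals are 1 + F_i with F_i the inbreeding coefficient.
    """
    ids = pedigree.ids
    index = {a: k for k, a in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for _, row in pedigree.records.iterrows():
        i = index[row["id"]]
        s = index[row["sire"]] if pd.notna(row["sire"]) else None
        d = index[row["dam"]] if pd.notna(row["dam"]) else None
        if s is not None and d is not None:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            val = 0.0
            if s is not None:
                val += 0.5 * A[j, s]
            if d is not None:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return RelationshipMatrix(matrix=A, ids=list(ids), kind="pedigree", source="pedigree")


def write_grm_text(rm: RelationshipMatrix, prefix: str) -> None:
    """Lower-triangle text layout: index1, index2, n_markers, value (+ .id file)."""
    n = len(rm.ids)
    m = rm.n_markers or 0
    with open(f"{prefix}.grm.txt", "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{m}\t{rm.matrix[i, j]:.8g}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for animal in rm.ids:
            fh.write(f"{animal}\n")


def read_grm_text(prefix: str, kind: str = "genomic", source: str = "genomic") -> RelationshipMatrix:
    with open(f"{prefix}.grm.id") as fh:
        ids = [line.strip() for line in fh if line.strip()]
    n = len(ids)
    A = np.zeros((n, n))
    n_markers = 0
    with open(f"{prefix}.grm.txt") as fh:
        for line in fh:
            i, j, m, v = line.split()
            i, j = int(i) - 1, int(j) - 1
            A[i, j] = A[j, i] = float(v)
            n_markers = int(m)
    return RelationshipMatrix(matrix=A, ids=ids, kind=kind, source=source,
                              n_markers=n_markers or None)
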