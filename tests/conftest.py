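import numpy as np
import pandas as pd
import pytest

from rareherit import (
    SimConfig,
    Pedigree,
    VariantTable,
    assign_effects_and_phenotypes,
    simulate_genotypes,
    simulate_pedigree,
)


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    return SimConfig(
        n_founders=40,
        n_generations=2,
        n_sires_per_gen=8,
        n_sons_per_sire=2,
        n_variants=600,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_pop(tiny_cfg):
    """Small simulated population shared by read-only tests."""
    ped = simulate_pedigree(tiny_cfg)
    vt = simulate_genotypes(ped, tiny_cfg)
    phen, truth, vt_visible = assign_effects_and_phenotypes(vt, ped, tiny_cfg)
    return {"ped": ped, "vt": vt, "phen": phen, "truth": truth, "vt_visible": vt_visible}


def make_variant_table(
    genotypes,
    pos=None,
    qual=None,
    mq=None,
    dp=None,
    ref=None,
    alt=None,
    chrom="1",
    sample_ids=None,
) -> VariantTable:
    """Hand-built VariantTable with passing QC metadata by default."""
    G = np.asarray(genotypes, dtype=np.int8)
    n, m = G.shape
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "ref": ref if ref is not None else ["A"] * m,
            "alt": alt if alt is not None else ["C"] * m,
            "qual": qual if qual is not None else [50.0] * m,
            "mq": mq if mq is not None else [55.0] * m,
            "dp": dp if dp is not None else [30.0] * m,
        }
    )
    ids = sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]
    return VariantTable(sites=sites, genotypes=G, sample_ids=ids)


def make_pedigree(rows, duos=None) -> Pedigree:
    """rows: list of (id, sire, dam); parents-before-offspring order."""
    rec = pd.DataFrame(rows, columns=["id", "sire", "dam"])
    rec["sex"] = None
    return Pedigree(records=rec, duos=duos or [])
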