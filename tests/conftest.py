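import numpy as np
import pandas as pd
import pytest

from countgwas import (
    GenotypeMatrix,
    SimConfig,
    compute_grm,
    simulate_genotypes,
    simulate_phenotype_panel,
)


def make_genotypes(dosages, bp=None, chrom="1", impute_r2=1.0):
    """Hand-rolled GenotypeMatrix from a plain dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if bp is None:
        bp = np.arange(1, m + 1) * 1000
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"s{j + 1}" for j in range(m)],
            "chrom": chrom,
            "bp": bp,
            "ea": "A",
            "oa": "G",
            "impute_r2": impute_r2,
        }
    )
    return GenotypeMatrix(
        dosages=dosages, snp_map=snp_map, sample_ids=[f"i{k + 1}" for k in range(n)]
    )


def single_trait_config(n, m, h2, seed, **kw):
    return SimConfig(
        n_individuals=n,
        n_snps=m,
        block_size=kw.pop("block_size", 1),
        within_block_rho=kw.pop("within_block_rho", 0.0),
        timepoints=(8.0,),
        h2_by_timepoint=(h2,),
        rg_matrix=((1.0,),),
        re_matrix=((1.0,),),
        n_causal=kw.pop("n_causal", min(200, m)),
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def heritable_sim():
    """Shared moderately sized cohort with a strongly heritable trait."""
    cfg = single_trait_config(n=800, m=1200, h2=0.45, seed=101, n_causal=200)
    G = simulate_genotypes(cfg)
    panel = simulate_phenotype_panel(G, cfg)
    grm = compute_grm(G)
    return cfg, G, panel, grm


@pytest.fixture(scope="session")
def null_two_age_sim():
    """Small fully-null two-age cohort for permutation machinery tests."""
    cfg = SimConfig(
        n_individuals=400,
        n_snps=150,
        block_size=1,
        within_block_rho=0.0,
        chrom_length_bp=20_000_000,
        timepoints=(8.0, 17.0),
        h2_by_timepoint=(0.0, 0.0),
        rg_matrix=((1.0, 0.9), (0.9, 1.0)),
        re_matrix=((1.0, 0.5), (0.5, 1.0)),
        n_causal=0,
        seed=202,
    )
    G = simulate_genotypes(cfg)
    panel = simulate_phenotype_panel(G, cfg)
    return cfg, G, panel
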