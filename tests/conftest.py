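import numpy as np
import pytest

from rrgwas import RandomRegressionModel
from rrgwas.qc import minor_allele_frequency
from rrgwas.simulate import (
    SimConfig,
    gene_drop,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_sim():
    """Three-generation population, 180 individuals, mild missingness."""
    cfg = SimConfig(seed=42, n_founders=60, n_generations=2, n_snps=120, missing_rate=0.02)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def fitted_sim():
    """A 300-individual study with one planted QTN and its fitted null model.

    The QTN is the SNP with realized MAF closest to 0.3, carrying a constant
    age profile of 14 kg per allele copy.
    """
    cfg = SimConfig(seed=7, n_founders=100, n_generations=2, n_snps=200)
    rng_ped, rng_geno, rng_pheno = cfg.streams()
    ped = simulate_pedigree(cfg, rng_ped)
    genos = gene_drop(ped, cfg, rng_geno)
    mafs = np.array([minor_allele_frequency(genos.calls[:, j]) for j in range(genos.n_snps)])
    qtn = int(np.argmin(np.abs(mafs - 0.3)))
    cfg.qtns = [(qtn, np.array([14.0, 0.0]))]
    pheno, truth = simulate_phenotypes(ped, genos, cfg, rng_pheno)
    model = RandomRegressionModel(pheno, ped, order_fixed=3, order_additive=1, order_pe=1)
    results = model.fit()
    return {
        "cfg": cfg,
        "ped": ped,
        "genos": genos,
        "pheno": pheno,
        "truth": truth,
        "qtn_index": qtn,
        "qtn_id": genos.snps["snp_id"][qtn],
        "results": results,
    }
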