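"""Shared fixtures: small simulated populations and independent oracles."""

import numpy as np
import pandas as pd
import pytest

from hapdeficit import SimConfig
from hapdeficit.simulate import (PhasedGenotypeMatrix, simulate_population,
                                 power_scan_config)


def small_config(seed: int = 42, penetrance: float = 1.0) -> SimConfig:
    return SimConfig(n_founders=120, n_generations=3, n_sires_per_gen=8,
                     offspring_per_dam=2, n_snps=200, n_chromosomes=2,
                     map_length_cM_per_chr=2.0, risk_hap_freq=0.1,
                     penetrance=penetrance, trait_h2=0.4,
                     female_genotyping_rate=0.6, seed=seed)


def assoc_config(seed: int, hap_effect: float, n_chromosomes: int = 2,
                 n_snps: int = 300) -> SimConfig:
    """Fully genotyped two-generation population for association studies."""
    return SimConfig(n_founders=200, n_generations=2, n_sires_per_gen=12,
                     offspring_per_dam=2, n_snps=n_snps,
                     n_chromosomes=n_chromosomes,
                     # one 50-SNP window spans ~1 cM
                     map_length_cM_per_chr=(n_snps / n_chromosomes) / 50.0,
                     risk_hap_freq=0.15, penetrance=0.0, trait_h2=0.4,
                     hap_trait_effect=hap_effect,
                     female_genotyping_rate=1.0, sire_usage_decay=0.8,
                     seed=seed)


@pytest.fixture(scope="session")
def small_pop():
    """Lethal-haplotype population: ~480 animals, 200 SNPs."""
    return simulate_population(small_config())


@pytest.fixture(scope="session")
def null_pop():
    """Same population structure without lethality (penetrance 0)."""
    return simulate_population(small_config(penetrance=0.0))


@pytest.fixture(scope="session")
def power_pop():
    """Reference lethal scenario with >=20 expected homozygotes."""
    return simulate_population(power_scan_config(seed=7))


@pytest.fixture
def toy_genotypes():
    """Factory for hand-built phased matrices on one chromosome."""

    def build(haplotypes, chrom="1", bp_spacing=1000):
        haps = np.asarray(haplotypes, dtype=np.uint8)
        n, two, s = haps.shape
        snps = pd.DataFrame({
            "snp_id": [f"s{j}" for j in range(s)],
            "chrom": chrom,
            "pos": (np.arange(s) + 1) * bp_spacing,
            "cM": np.linspace(0, 1, s),
        })
        return PhasedGenotypeMatrix(
            animal_ids=[f"A{i}" for i in range(n)],
            snps=snps, haplotypes=haps, phase_known=True)

    return build


@pytest.fixture
def enum_tail():
    """Independent exhaustive-enumeration oracle for the Poisson-binomial
    lower tail P(X <= k); exact for n <= ~20."""

    def tail(pis, k):
        pis = np.asarray(pis, dtype=float)
        n = pis.size
        outcomes = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
        probs = np.where(outcomes == 1, pis, 1 - pis).prod(axis=1)
        return float(probs[outcomes.sum(axis=1) <= k].sum())

    return tail
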