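import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from twaskit.datatypes import GenotypePanel, SnpRecord, WeightSet
from twaskit.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=25, n_ref_individuals=400, snps_per_gene=10,
        set_size_range=(5, 10), n_sets=12, seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


def make_panel(dosages, chrom="1", alleles=None, bp0=1000, spacing=500):
    """Small hand-specified panel; dosages is individuals x SNPs."""
    dosages = np.asarray(dosages, dtype=np.int8)
    m = dosages.shape[1]
    if alleles is None:
        alleles = [("A", "G")] * m
    recs = [
        SnpRecord(snp_id=f"snp{j}", chrom=chrom, bp=bp0 + j * spacing,
                  a1=alleles[j][0], a2=alleles[j][1],
                  maf=float(min(dosages[:, j].mean() / 2,
                                1 - dosages[:, j].mean() / 2)))
        for j in range(m)
    ]
    return GenotypePanel(snps=recs, dosages=dosages)


@pytest.fixture
def toy_panel():
    """5 SNPs x 6 individuals with varied allele pairs (snp2 is A/T)."""
    rng = np.random.default_rng(42)
    dosages = rng.integers(0, 3, size=(6, 5))
    dosages[0] = [0, 1, 2, 1, 0]  # guard against monomorphic columns
    dosages[1] = [2, 0, 0, 2, 1]
    alleles = [("A", "G"), ("C", "T"), ("A", "T"), ("A", "C"), ("T", "G")]
    return make_panel(dosages, alleles=alleles)


def make_weight_set(gene_id="G1", chrom="1", start=1, end=2000,
                    snp_ids=None, a1=None, a2=None, w=None, cis_h2=0.2):
    snp_ids = snp_ids or ["snp0", "snp1"]
    m = len(snp_ids)
    return WeightSet(
        gene_id=gene_id, chrom=chrom, start=start, end=end,
        snp_ids=snp_ids, a1=a1 or ["A"] * m, a2=a2 or ["G"] * m,
        w=np.asarray(w if w is not None else np.ones(m), dtype=float),
        cis_h2=cis_h2,
    )
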