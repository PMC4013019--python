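import numpy as np
import pytest

from ecogrs import (ClineSpec, DiseaseModelSpec, GenotypeDataset, LDBlockSpec,
                    PopulationSpec, SnpRecord)
from ecogrs.synthio import default_snp_records, draw_population_panel


def make_dataset(dosage, phenotype=None, population=None, snps=None, **kw):
    """Small helper: wrap a dosage matrix into a GenotypeDataset."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if snps is None:
        snps = default_snp_records(m)
    return GenotypeDataset(
        samples=[f"s{i}" for i in range(n)], snps=snps, dosage=dosage,
        phenotype=None if phenotype is None else np.asarray(phenotype),
        population=None if population is None else np.asarray(population),
        **kw)


@pytest.fixture
def flat_cline():
    """12 SNPs at frequency 0.3 everywhere (no geographic structure)."""
    m = 12
    a = np.full(m, np.log(0.3 / 0.7))
    return ClineSpec(a=a, b=np.zeros(m), c=np.zeros(m))


@pytest.fixture
def small_panel(flat_cline):
    pops = [PopulationSpec(f"P{i}", 40.0 + 2 * i, 5.0 * i, 50) for i in range(4)]
    blocks = LDBlockSpec.uniform(flat_cline.n_snps, 4, 0.5)
    return draw_population_panel(pops, flat_cline, blocks, seed=11)
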