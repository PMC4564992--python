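import numpy as np
import pytest

from poescan import simulate
from poescan.pedio import FamilyUnit, GenotypeMatrix, SnpInfo


def make_matrix(dosages, ids=None, mafs=None, chrom="1"):
    """GenotypeMatrix from a plain dosage array (rows = individuals)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_ind, n_snp = dosages.shape
    if ids is None:
        ids = [f"I{i}" for i in range(n_ind)]
    if mafs is None:
        mafs = [0.25] * n_snp
    snps = [SnpInfo(f"snp{j+1}", chrom, (j + 1) * 1000, "2", "1", mafs[j])
            for j in range(n_snp)]
    return GenotypeMatrix(list(ids), snps, dosages)


def make_trio_unit(fid="F0", mother="M", father="P", child="C"):
    return FamilyUnit("trio", fid, child, mother_id=mother, father_id=father)


@pytest.fixture(scope="session")
def small_trio_dataset():
    """300 trios, 3 blocks of 8 SNPs, null model; shared across tests."""
    cfg = simulate.SimConfig(n_units=300, n_blocks=3, block_size=8,
                             causal_index=12, seed=11)
    return simulate.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_duo_dataset():
    """300 case-mother duos under the null."""
    cfg = simulate.SimConfig(n_units=300, unit_type="duo_mother",
                             n_blocks=3, block_size=8, causal_index=12,
                             seed=13)
    return simulate.simulate_dataset(cfg)
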