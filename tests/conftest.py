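import itertools

import numpy as np
import pytest

from episnet import GenotypeDataset


@pytest.fixture
def xor_dataset() -> GenotypeDataset:
    """Nine individuals, one per joint genotype (g_A, g_B) in {0,1,2}^2;
    the class is parity(g_A) XOR parity(g_B): 4 cases, 5 controls."""
    geno = np.array(list(itertools.product(range(3), repeat=2)),
                    dtype=np.int8)
    pheno = ((geno[:, 0] % 2) ^ (geno[:, 1] % 2)).astype(np.int8)
    return GenotypeDataset(snp_ids=["A", "B"], genotypes=geno,
                           phenotype=pheno)


@pytest.fixture
def toy_tsv(tmp_path):
    """3-individual, 2-SNP genotype file in the native TSV dialect."""
    path = tmp_path / "toy.tsv"
    path.write_text(
        "ID\tSTATUS\trs1\trs2\n"
        "s1\t1\t0\t2\n"
        "s2\t0\t1\t1\n"
        "s3\t1\t2\t0\n"
    )
    return path


def random_dataset(rng: np.random.Generator, n: int, m: int,
                   missing: float = 0.0) -> GenotypeDataset:
    """Random dataset with both classes guaranteed present."""
    geno = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing > 0:
        mask = rng.random((n, m)) < missing
        # keep at least one observed entry per column
        mask[rng.integers(0, n, size=m), np.arange(m)] = False
        geno[mask] = -1
    pheno = rng.integers(0, 2, size=n).astype(np.int8)
    pheno[0], pheno[1] = 0, 1
    return GenotypeDataset(snp_ids=[f"snp{j}" for j in range(m)],
                           genotypes=geno, phenotype=pheno)


# Printed degree distribution of the bladder-cancer network at t = 0.013
# (fractions p(d) over 319 vertices); used to reconstruct integer counts.
TABLE1_REAL_PD = {
    1: 0.677, 2: 0.201, 3: 0.0533, 4: 0.0345, 5: 0.0125,
    6: 1.25e-2, 8: 6.27e-3, 11: 3.13e-3,
}
TABLE1_N_VERTICES = 319
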