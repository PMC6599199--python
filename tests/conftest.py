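import numpy as np
import pandas as pd
import pytest

from polysweep.variants import AlleleCounts, VariantTable


def counts_from_haplotypes(hap: np.ndarray) -> AlleleCounts:
    """AlleleCounts for a fully-called phased haplotype matrix."""
    hap = np.asarray(hap)
    m = hap.sum(axis=1)
    n = np.full(len(m), hap.shape[1])
    gt = hap.reshape(hap.shape[0], -1, 2)
    het = (gt[..., 0] != gt[..., 1]).sum(axis=1)
    return AlleleCounts(
        m=m.astype(np.int64),
        n=n.astype(np.int64),
        n_het=het.astype(np.int64),
        n_called=np.full(len(m), hap.shape[1] // 2, dtype=np.int64),
    )


def make_table(
    chroms, positions, genotypes, depth=None, mapq=None, func_class=None,
    samples=None,
) -> VariantTable:
    """Small VariantTable from explicit arrays (genotypes: sites x samples x 2)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = genotypes.shape[:2]
    sites = pd.DataFrame(
        {
            "chrom": chroms if not isinstance(chroms, str) else [chroms] * n_sites,
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "depth": depth if depth is not None else [50] * n_sites,
            "mapq": mapq if mapq is not None else [60.0] * n_sites,
            "func_class": func_class
            if func_class is not None
            else ["synonymous"] * n_sites,
        }
    )
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return VariantTable(sites=sites, genotypes=genotypes, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
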