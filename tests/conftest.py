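import numpy as np
import pandas as pd
import pytest

from gestaltqtl import simdata


@pytest.fixture(scope="session")
def small_params():
    return simdata.SimParams(
        n_colonies=6, workers_per_colony=4, patrilines=(2, 4), n_loci=300,
        n_chromosomes=3, chrom_length_cM=60.0, n_traits=3, qtl_per_trait=1,
        pev=0.3, colony_env_var=0.2, gestalt_m=0.4, seed=42,
    )


@pytest.fixture(scope="session")
def small_sim(small_params):
    rng = np.random.default_rng(small_params.seed)
    pedigree, haps = simdata.simulate_colonies(small_params, rng=rng)
    traits, truth = simdata.simulate_traits(haps, pedigree, small_params, rng=rng)
    return pedigree, haps, traits, truth


@pytest.fixture(scope="session")
def fixture_dir(small_sim, tmp_path_factory):
    pedigree, haps, traits, truth = small_sim
    out = tmp_path_factory.mktemp("fixture")
    paths = simdata.write_fixture(pedigree, haps, traits, str(out),
                                  qtl_truth=truth, seed=7)
    return paths


def make_genotype_matrix(dosage, depth=None, colonies=None, ploidy=None,
                         chrom=None, bp=None):
    """Hand-built GenotypeMatrix for filter tests."""
    from gestaltqtl.variants import GenotypeMatrix

    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    depth = np.full((n, m), 12.0) if depth is None else np.asarray(depth, float)
    colonies = colonies if colonies is not None else ["C1"] * n
    ploidy = ploidy if ploidy is not None else [2] * n
    chrom = chrom if chrom is not None else ["chr1"] * m
    bp = bp if bp is not None else list(range(1, m + 1))
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{j + 1}" for j in range(m)],
            "chrom": chrom,
            "bp": bp,
            "ref": ["A"] * m,
            "alt": ["T"] * m,
            "biallelic_snp": [True] * m,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1}" for i in range(n)],
            "colony_id": colonies,
            "ploidy": ploidy,
        }
    )
    return GenotypeMatrix(dosage=dosage, depth=depth, loci=loci, samples=samples)
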