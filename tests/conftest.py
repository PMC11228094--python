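import numpy as np
import pytest

import pedigen as pg


@pytest.fixture(scope="session")
def small_cfg():
    """Tiny population: fast enough for per-operation tests."""
    return pg.SimConfig(
        n_founders=8, n_parent_generations=1, n_families=6,
        family_size_range=(4, 8), n_dual_families=2, n_chromosomes=4,
        chrom_length_bp=10_000_000, markers_per_platform=(120, 110),
        overlap_markers=5, missing_rate=(0.005, 0.016), recomb_rate=1.0,
        seed=11)


@pytest.fixture(scope="session")
def small_pop(small_cfg):
    return pg.simulate_population(small_cfg)


@pytest.fixture(scope="session")
def gwas_pop():
    """Medium-sized population with enough individuals for mixed models."""
    cfg = pg.SimConfig(seed=3, n_families=30, family_size_range=(8, 16))
    truth, ped, design = pg.simulate_population(cfg)
    geno = pg.GenotypeMatrix(truth.genotypes().astype(np.float32),
                             truth.individuals, truth.marker_map)
    geno = pg.filter_maf(geno, 0.025)
    return truth, ped, design, geno


def genotype_matrix_from_truth(truth):
    return pg.GenotypeMatrix(truth.genotypes().astype(np.float32),
                             truth.individuals, truth.marker_map)
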