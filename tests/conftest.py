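import dataclasses

import numpy as np
import pytest

import ldcall as lc
from ldcall.training import _init_model


def random_models(rng, n, K, Kp=None):
    """Random valid parental models for oracle comparisons."""
    maternal = _init_model(n, K, rng)
    paternal = _init_model(n, Kp if Kp is not None else K, rng)
    return lc.ParentalModels(maternal, paternal)


@pytest.fixture(scope="session")
def standard_fixture():
    """The standard synthetic study: mosaic panel, trained K=7 models, one
    panel-drawn individual, Poisson-6 and Poisson-20 Phred-20 read sets."""
    cfg = lc.SimConfig(
        n_snps=1000,
        n_panel_haplotypes=120,
        n_founders_true=10,
        recomb_switch_prob=0.01,
        mutation_flip_prob=0.005,
        mean_coverage=6.0,
        phred_dist=((20, 1.0),),
    )
    panel, founders = lc.simulate_panel(cfg, seed=1)
    result = lc.FounderHMM(panel, K=7).fit(seed=0)
    models = lc.ParentalModels.from_single(result.hmm)
    ss = np.random.SeedSequence(2).spawn(3)
    h, hp, g = lc.simulate_individual(panel, seed=ss[0])
    reads6 = lc.simulate_reads(g, cfg, seed=ss[1])
    cfg20 = dataclasses.replace(cfg, mean_coverage=20.0)
    reads20 = lc.simulate_reads(g, cfg20, seed=ss[2])
    return {
        "config": cfg,
        "panel": panel,
        "train_result": result,
        "models": models,
        "h": h,
        "hp": hp,
        "truth": g,
        "reads6": reads6,
        "reads20": reads20,
        "read_seed_spawn": ss,
    }


@pytest.fixture
def tiny_panel():
    """A 6-haplotype, 4-SNP panel with both alleles at every locus."""
    loci = [lc.SnpLocus(i, "1", 100 * (i + 1), "A", "G") for i in range(4)]
    haps = np.array(
        [
            [0, 1, 0, 1],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [1, 0, 1, 0],
            [0, 1, 1, 1],
            [1, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    return lc.HaplotypePanel(loci=loci, haplotypes=haps)
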