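import numpy as np
import pandas as pd
import pytest

from carnet.annotations import GeneModel, GenomicInterval, SuperEnhancer
from carnet.pairs import PAIR_COLUMNS
from carnet.simulate import SimConfig, make_annotations


def make_pairs(records):
    """Build a pair DataFrame from (rna_chrom, rs, re, dna_chrom, ds, de) tuples."""
    return pd.DataFrame(records, columns=PAIR_COLUMNS)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def annotations(sim_config):
    return make_annotations(sim_config)


@pytest.fixture
def toy_genes():
    return [
        GeneModel("GA", GenomicInterval("chr1", 50, 500)),
        GeneModel("GB", GenomicInterval("chr1", 90, 250)),
        GeneModel("GC", GenomicInterval("chr2", 1000, 2000)),
    ]


@pytest.fixture
def toy_ses():
    return [
        SuperEnhancer("SE_A", GenomicInterval("chr1", 100, 200)),
        SuperEnhancer("SE_B", GenomicInterval("chr1", 600, 700)),
        SuperEnhancer("SE_C", GenomicInterval("chr2", 1100, 1300)),
    ]
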