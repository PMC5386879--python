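import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from autozyg.sim import make_half_sib_pedigree
from autozyg.types import Marker, MarkerDataset


@pytest.fixture
def half_sib():
    return make_half_sib_pedigree()


@pytest.fixture
def half_sib_shared_dam():
    return make_half_sib_pedigree("dam")


def build_dataset(samples, chrom_pos, genotypes, alleles=("A", "B")):
    """Small dataset helper: chrom_pos is a list of (chrom, pos) pairs,
    genotypes a row-per-sample nested list with -1 for missing."""
    markers = [
        Marker(name=f"m{j + 1}", chrom=c, pos_bp=p, alleles=alleles)
        for j, (c, p) in enumerate(chrom_pos)
    ]
    return MarkerDataset(markers, samples, np.asarray(genotypes, dtype=np.int8))


@pytest.fixture
def dataset_builder():
    return build_dataset
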