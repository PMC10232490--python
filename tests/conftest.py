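import numpy as np
import pytest

from somascape.simulate import (
    default_immune_gene_sets,
    generate_genome,
    reference_signatures,
)


@pytest.fixture(scope="session")
def toy_genome():
    """Two 20 Mb chromosomes — enough structure for binning and centromeres."""
    return generate_genome(n_chrom=2, chrom_length=20_000_000, seed=11)


@pytest.fixture(scope="session")
def big_genome():
    """Single 100 Mb chromosome for kataegis window scans."""
    return generate_genome(n_chrom=1, chrom_length=100_000_000, seed=7)


@pytest.fixture(scope="session")
def ref_sigs():
    """Four sparse, well-separated synthetic reference signatures."""
    return reference_signatures(4, seed=5)


@pytest.fixture(scope="session")
def immune_sets():
    sets, lymphoid, myeloid = default_immune_gene_sets(seed=3)
    return sets, lymphoid, myeloid
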