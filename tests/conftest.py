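import numpy as np
import pytest

from polytetra.io_core import GenotypeMatrix


def make_gm(
    dosage,
    ploidy,
    pos=None,
    chrom="chr1",
    samples=None,
    ancestral_is_ref=None,
):
    """Small GenotypeMatrix builder for tests."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n_sites, n_samples = dosage.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    chroms = (
        np.array([chrom] * n_sites, dtype=object)
        if isinstance(chrom, str)
        else np.asarray(chrom, dtype=object)
    )
    return GenotypeMatrix(
        chrom=chroms,
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        dosage=dosage,
        ploidy=np.asarray(ploidy, dtype=np.int8),
        samples=list(samples),
        ancestral_is_ref=ancestral_is_ref,
    )


@pytest.fixture
def gm_builder():
    return make_gm
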