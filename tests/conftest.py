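import numpy as np
import pytest

from admixsv.core_io import GenomicInterval, PopulationPanel, SNVRecord, SVRecord
from admixsv.simpop import AdmixtureWave, SimConfig, simulate_cohort


def make_sv(id="sv1", chrom="chr1", start=1000, end=2000, svtype="DEL",
            genotypes=(0, 1, 2), length=None):
    iv = GenomicInterval(chrom, start, end)
    if length is None:
        length = end - start
    return SVRecord(id, iv, svtype, length, np.asarray(genotypes))


def make_snv(id="snv1", chrom="chr1", pos=1500, genotypes=(0, 1, 2)):
    return SNVRecord(id, chrom, pos, "A", "G", np.asarray(genotypes))


@pytest.fixture
def tiny_panel():
    return PopulationPanel(["s1", "s2", "s3"], ["ADMIXED"] * 3)


def small_config(seed=11, **overrides):
    """Desk-scale cohort for unit tests: fast but structurally complete."""
    kwargs = dict(
        seed=seed,
        n_sv=300, n_snv=200, n_genes=25,
        n_admixed=30, n_west=40, n_east=40, n_african=10,
        pop_size=80,
        waves=(AdmixtureWave(20, 0.5, 1.0), AdmixtureWave(8, 0.5, 0.3)),
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_cohort(small_config())
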