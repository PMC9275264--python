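import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rohscape.genotype_io import GenotypeTable, LocusMap

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_dataset(code_rows, spacing=100_000, chrom=1, start=1_000_000,
                 populations=None):
    """Build a single-chromosome dataset from rows of genotype codes
    (0 hom-ref, 1 het, 2 hom-alt, -1 missing), evenly spaced SNPs."""
    codes = np.asarray(code_rows, dtype=np.int8)
    if codes.ndim == 1:
        codes = codes.reshape(1, -1)
    n_samples, n_loci = codes.shape
    pos = start + spacing * np.arange(n_loci)
    lmap = LocusMap(
        np.full(n_loci, chrom),
        np.array([f"c{chrom}_s{i}" for i in range(n_loci)], dtype=object),
        pos,
        np.array(["A"] * n_loci, dtype=object),
        np.array(["C"] * n_loci, dtype=object),
    )
    samples = np.array([f"ind{i}" for i in range(n_samples)], dtype=object)
    pops = np.array(populations if populations is not None
                    else ["pop1"] * n_samples, dtype=object)
    return GenotypeTable(samples, pops, codes), lmap


def random_chromosome(rng, n=100, het_p=0.1, miss_p=0.02, span_bp=10_000_000):
    """One random sample x one chromosome, mimicking array genotypes."""
    codes = rng.choice([0, 2], size=n).astype(np.int8)
    codes[rng.random(n) < het_p] = 1
    codes[rng.random(n) < miss_p] = -1
    pos = np.sort(rng.choice(np.arange(1, span_bp + 1), size=n, replace=False))
    lmap = LocusMap(
        np.ones(n, dtype=int),
        np.array([f"s{i}" for i in range(n)], dtype=object), pos,
        np.array(["A"] * n, dtype=object), np.array(["C"] * n, dtype=object),
    )
    table = GenotypeTable(np.array(["x"], dtype=object),
                          np.array(["p"], dtype=object),
                          codes.reshape(1, -1))
    return table, lmap


@pytest.fixture
def rng():
    return np.random.default_rng(20220712)
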