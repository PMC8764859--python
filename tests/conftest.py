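import pytest

from pgtmosaic import (BiopsyTruth, CellKaryotype, CnEvent, GenomeModel,
                       NgsParams, SnpParams, simulate_embryo, simulate_mda)


@pytest.fixture(scope="session")
def genome():
    return GenomeModel.default()


@pytest.fixture(scope="session")
def genome_xx(genome):
    """XX-baseline calling genome: autosomes + X."""
    return genome.subset([str(i) for i in range(1, 23)] + ["X"])


@pytest.fixture(scope="session")
def flat_weights(genome):
    """Bias-free amplification (sigma 0 -> weights identically 1)."""
    return simulate_mda(genome, sigma_log=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_snp_params():
    return SnpParams(n_markers=40_000, sigma_lrr=0.0, sigma_baf=0.0,
                     nocall_prob=0.0)


@pytest.fixture(scope="session")
def noiseless_ngs_params():
    return NgsParams(deterministic=True, overdispersion=0.0,
                     gc_coeffs=(1.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def disomic_truth():
    return BiopsyTruth(((CellKaryotype.disomic(), 1.0),), n_cells=10)


def trisomy(chrom="21"):
    return CnEvent(chrom=chrom, scope="whole", direction="gain")


def monosomy(chrom="21"):
    return CnEvent(chrom=chrom, scope="whole", direction="loss")


@pytest.fixture(scope="session")
def default_noise_embryo(genome_xx):
    """One default-noise dual-platform render of a 60% 2q-loss mosaic."""
    ev = CnEvent(chrom="2", scope="q", direction="loss")
    truth = BiopsyTruth.from_fraction(ev, 0.6, n_cells=10)
    snp, ngs = simulate_embryo(truth, genome_xx, seed=11)
    return truth, snp, ngs
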