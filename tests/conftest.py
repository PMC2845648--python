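import numpy as np
import pytest

import recfst as rf
from recfst.panel import SnpPanel


@pytest.fixture
def toy_map():
    gm = rf.GeneticMap()
    gm.add_chromosome("chr1", np.array([1_000_000, 2_000_000, 3_000_000]), np.array([1.0, 2.0, 2.5]))
    return gm


@pytest.fixture
def flat_map_structure():
    """Constant 1 cM/Mb map on a 10 Mb chromosome with one centromere and
    telomeres at both ends."""
    gm = rf.GeneticMap()
    gm.add_chromosome("chr1", np.array([500_000, 3_500_000, 9_500_000]), np.array([0.5, 3.5, 9.5]))
    st = rf.ChromosomeStructure(
        lengths={"chr1": 10_000_000},
        centromeres={"chr1": [(4_000_000, 4_500_000)]},
        telomeres={"chr1": [(1, 100_000), (9_900_001, 10_000_000)]},
    )
    return gm, st


def make_panel(alt, n, pops=None, chrom=None, pos=None, rho=None, coding=None):
    """Build a small panel from (m, n_pops) count arrays."""
    alt = np.atleast_2d(np.asarray(alt))
    n = np.atleast_2d(np.asarray(n))
    m, k = alt.shape
    pops = pops or [f"pop{j + 1}" for j in range(k)]
    return SnpPanel(
        ids=[f"s{i + 1}" for i in range(m)],
        chrom=chrom if chrom is not None else ["chr1"] * m,
        pos=pos if pos is not None else np.arange(1, m + 1) * 1000,
        pops=pops,
        alt=alt,
        n=n,
        coding=coding,
        rho=rho,
        status=["ok"] * m,
    )


def balding_nichols_panel(rng, n_snps, c, n_chrom=100, n_pops=2, rho=None):
    """Direct BN draw (no map, no LD): the independent simulation oracle
    used against the synthetic_data module and the estimators."""
    c = np.broadcast_to(np.asarray(c, dtype=float), (n_snps,))
    p = rng.uniform(0.05, 0.95, n_snps)
    a, b = p * (1 - c) / c, (1 - p) * (1 - c) / c
    alt = np.empty((n_snps, n_pops), dtype=np.int64)
    for j in range(n_pops):
        freq = rng.beta(a, b)
        alt[:, j] = rng.binomial(n_chrom, freq)
    n = np.full((n_snps, n_pops), n_chrom, dtype=np.int64)
    return make_panel(alt, n, rho=rho)


@pytest.fixture(scope="session")
def sim_bundle():
    """Shared small simulated dataset: map, structure, 5,000-SNP panel."""
    rng = np.random.default_rng(42)
    gmap, structure = rf.simulate_genetic_map(
        {"chr1": 50_000_000, "chr2": 50_000_000}, rng=rng
    )
    truth = rf.SyntheticTruth(intercept=0.128, slope=-0.005, coding_frac=0.1)
    panel, truth, extras = rf.simulate_snp_panel(gmap, structure, truth, 5_000, rng=rng)
    return gmap, structure, panel, truth, extras
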