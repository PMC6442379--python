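"""Shared fixtures: toy genomes/matrices and one cached standard simulation."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from hicarch import correction, simulate, tads
from hicarch.fragments import FragmentBinMap, GenomeModel, fixed_width_bins
from hicarch.matrix import ContactMatrix


@pytest.fixture(scope="session")
def toy_genome() -> GenomeModel:
    return GenomeModel.from_dict({"chr1": 40_000})


@pytest.fixture(scope="session")
def toy_bins(toy_genome) -> FragmentBinMap:
    return fixed_width_bins(toy_genome, 1000)


def dense_matrix(dense: np.ndarray, bin_width: int = 1000,
                 chrom: str = "chr1") -> ContactMatrix:
    """Wrap a dense symmetric array as a one-chromosome ContactMatrix."""
    n = dense.shape[0]
    genome = GenomeModel.from_dict({chrom: n * bin_width})
    bins = fixed_width_bins(genome, bin_width)
    return ContactMatrix.from_dense(bins, dense)


@pytest.fixture()
def two_block_matrix() -> ContactMatrix:
    """40 bins of 1 kb; within-block contacts 10, between-block 1; the
    planted boundary sits at bin 20 (bp 20000)."""
    n = 40
    dense = np.ones((n, n))
    dense[:20, :20] = 10.0
    dense[20:, 20:] = 10.0
    return dense_matrix(dense)


@pytest.fixture(scope="session")
def standard_run():
    """One standard simulation (seed 0, cell A) with correction and border
    calls, shared by read-only tests."""
    params = simulate.SimulationParams(seed=0)
    truth = simulate.generate_truth(params)
    m = simulate.simulate_hic(truth, "A", seed=11)
    filt = correction.filter_bins(m, -np.inf, np.inf)
    balanced = correction.ice_correct(filt)
    track = tads.tad_separation_score(balanced.matrix)
    borders, tadset = tads.call_borders(track, balanced.matrix)
    return {"params": params, "truth": truth, "raw": m, "filtered": filt,
            "balanced": balanced, "track": track, "borders": borders,
            "tads": tadset}
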