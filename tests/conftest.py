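"""Shared fixtures: tiny hand-built datasets and session-scoped simulations."""

import numpy as np
import pytest

from sweepscan.dataio import HaplotypeDataset, PopulationPanel
from sweepscan.simulate import SimulationConfig, simulate_two_pop


def make_dataset(haps, positions, chrom="chr1", n_wild=None, chrom_length=None):
    """Build a HaplotypeDataset from a (n_hap, n_sites) 0/1 matrix.

    The first ``n_wild`` samples (default half) are labelled wild, the
    rest farm; n_hap must be even.
    """
    haps = np.asarray(haps, dtype=np.uint8)
    n_samples = haps.shape[0] // 2
    if n_wild is None:
        n_wild = n_samples // 2
    sample_ids = [f"w{i}" for i in range(n_wild)] + [f"f{i}" for i in range(n_samples - n_wild)]
    positions = np.asarray(positions, dtype=np.int64)
    return HaplotypeDataset(
        sample_ids=sample_ids,
        population_of_sample={s: ("wild" if s.startswith("w") else "farm") for s in sample_ids},
        chrom_names=[chrom],
        positions={chrom: positions},
        ref_alleles={chrom: np.full(len(positions), "A")},
        alt_alleles={chrom: np.full(len(positions), "C")},
        haplotypes={chrom: haps},
        chrom_lengths={chrom: chrom_length} if chrom_length else {},
    )


@pytest.fixture
def wf_panel():
    def _panel(ds):
        return PopulationPanel(
            populations={
                "wild": [s for s in ds.sample_ids if s.startswith("w")],
                "farm": [s for s in ds.sample_ids if s.startswith("f")],
            },
            reference="wild",
        )

    return _panel


@pytest.fixture(scope="session")
def sweep_sim():
    """One small sweep replicate: 1.5 Mb, sweep fixed mid-chromosome."""
    cfg = SimulationConfig(
        seed=9001,
        genome=[("chr1", 1_500_000)],
        sweep_loci=[("chr1", 725_000, 0.5)],
    )
    ds, truth = simulate_two_pop(cfg)
    panel = PopulationPanel(
        populations={
            "wild": [s for s in ds.sample_ids if s.startswith("w")],
            "farm": [s for s in ds.sample_ids if s.startswith("f")],
        },
        reference="wild",
    )
    return ds, truth, panel


@pytest.fixture(scope="session")
def null_sim():
    """Null dataset: one equilibrium pool split into two 10-diploid panels.

    generations_farm = 0 and no sweep loci, so the "farm" sample is just
    a second draw from the ancestral population — the permutation null
    of every differentiation statistic.
    """
    cfg = SimulationConfig(
        seed=77_001,
        genome=[("chr1", 5_000_000)],
        generations_farm=0,
        sweep_loci=[],
    )
    ds, truth = simulate_two_pop(cfg)
    panel = PopulationPanel(
        populations={
            "wild": [s for s in ds.sample_ids if s.startswith("w")],
            "farm": [s for s in ds.sample_ids if s.startswith("f")],
        },
        reference="wild",
    )
    return ds, panel
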