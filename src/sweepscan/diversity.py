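"""Windowed nucleotide diversity (pi) and the wild/farm diversity ratio.

Per-site diversity uses the unbiased pairwise estimator
``pi_site = c0 * c1 / C(n, 2)`` (the mean pairwise difference over the
n sampled haplotypes). Window pi divides the sum of site values by the
full window length in bp — the per-bp convention of windowed-diversity
tools — so windows with no SNPs have pi = 0 and the trailing partial
window on each chromosome is conservatively divided by the full nominal
window size.

The relative diversity of a test (farm) population against the reference
(wild) population in a window is ``pi_ref / pi_test``: values above 1
mean reduced diversity in the farm, the expected footprint of a sweep or
founder bottleneck. Windows with pi_test = 0 have no finite ratio and
are flagged undefined (excluded from empirical-p ranking).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dataio import HaplotypeDataset, PopulationPanel

logger = logging.getLogger(__name__)

__all__ = ["site_pi", "site_pi_array", "windowed_pi", "relative_diversity", "DEFAULT_WINDOW"]

DEFAULT_WINDOW = 50_000


def site_pi(count0: int, count1: int) -> float:
    """Per-site pairwise diversity from the two allele counts."""
    n = count0 + count1
    if n < 2:
        raise ValueError("site pi needs at least 2 haplotypes")
    return count0 * count1 / (n * (n - 1) / 2)


def site_pi_array(hapmatrix: np.ndarray) -> np.ndarray:
    """Vectorised per-site pi over a population's haplotype matrix."""
    n = hapmatrix.shape[0]
    if n < 2:
        raise ValueError("site pi needs at least 2 haplotypes")
    c1 = hapmatrix.sum(axis=0).astype(np.float64)
    return (n - c1) * c1 / (n * (n - 1) / 2)


def windowed_pi(
    ds: HaplotypeDataset,
    panel: PopulationPanel,
    window_size: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Per-population pi (per bp) over non-overlapping windows.

    Windows are anchored at position 1 on each chromosome; every window
    up to the chromosome's effective length is present even with zero
    SNPs. Columns: chrom, start, end (half-open, 1-based), n_snps, and
    one ``pi_<population>`` column per panel population.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    pops = list(panel.populations)
    rows = []
    for chrom in ds.chrom_names:
        pos = ds.positions[chrom]
        length = max(ds.effective_length(chrom), int(pos[-1]) if len(pos) else 1)
        n_windows = int(np.ceil(length / window_size))
        starts = 1 + window_size * np.arange(n_windows)
        # window index of each SNP
        widx = (pos - 1) // window_size if len(pos) else np.asarray([], dtype=np.int64)
        n_snps = np.bincount(widx, minlength=n_windows) if len(pos) else np.zeros(n_windows, int)
        pi_cols = {}
        for pop in pops:
            pi_sites = site_pi_array(ds.population_matrix(pop, chrom)) if len(pos) else np.array([])
            sums = (
                np.bincount(widx, weights=pi_sites, minlength=n_windows)
                if len(pos)
                else np.zeros(n_windows)
            )
            pi_cols[f"pi_{pop}"] = sums / window_size
        for w in range(n_windows):
            row = {
                "chrom": chrom,
                "start": int(starts[w]),
                "end": int(starts[w]) + window_size,
                "n_snps": int(n_snps[w]),
            }
            for pop in pops:
                row[f"pi_{pop}"] = pi_cols[f"pi_{pop}"][w]
            rows.append(row)
    return pd.DataFrame(rows)


def relative_diversity(
    pi_windows: pd.DataFrame,
    reference_pop: str,
    test_pop: str,
) -> pd.DataFrame:
    """Add ``ratio`` (pi_ref / pi_test) and ``defined`` columns.

    ``defined`` is False where pi_test = 0 (no finite ratio; those
    windows are excluded from empirical-p ranking and logged).
    """
    for pop in (reference_pop, test_pop):
        if f"pi_{pop}" not in pi_windows.columns:
            raise KeyError(f"population {pop!r} absent from pi window table")
    out = pi_windows.copy()
    pi_ref = out[f"pi_{reference_pop}"].to_numpy()
    pi_test = out[f"pi_{test_pop}"].to_numpy()
    defined = pi_test > 0
    ratio = np.full(len(out), np.nan)
    np.divide(pi_ref, pi_test, out=ratio, where=defined)
    out["ratio"] = ratio
    out["defined"] = defined
    n_undef = int((~defined).sum())
    if n_undef:
        logger.info("%d windows with pi_%s = 0 excluded from ratio ranking", n_undef, test_pop)
    return out
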