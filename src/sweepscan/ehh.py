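"""Extended haplotype homozygosity (EHH), integrated EHH, and XP-EHH.

EHH at extension distance x from a core SNP is the probability that two
haplotypes drawn at random from the sample are identical at every SNP
from the core out to x. Two tract conventions are supported: the
decay-curve API (:func:`ehh_at_core`) defaults to excluding the core
SNP from the identity tract, so EHH(0) = 1; the cross-population scan
defaults to the canonical construction that includes the core SNP, so
the curve starts at the core's haplotype homozygosity. Both use
whole-sample (allele-unpartitioned) EHH in each population.

iES is the area under the EHH decay curve against physical distance,
summed over the upstream and downstream directions. XP-EHH for a test
(farm) population against a reference (wild) population at a core SNP is

    ln( iES_test / iES_ref )

with both integrals taken over a shared support: the extension boundary
in each direction is where the EHH of the pooled two-population sample
drops below the cutoff (or where an inter-SNP gap exceeds ``max_gap``, or
the chromosome ends). Positive values mean unusually long haplotypes in
the test population — the signature of a recent sweep there. Raw ln
ratios are z-normalised genome-wide (in this pipeline, across per-bin
representative scores; see :mod:`sweepscan.scan`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import HaplotypeDataset, PopulationPanel

logger = logging.getLogger(__name__)

__all__ = [
    "EHHDecay",
    "ehh_at_core",
    "integrated_ehh",
    "xpehh_site",
    "xpehh_scan",
    "normalize_scores",
    "DEFAULT_CUTOFF",
    "DEFAULT_MAX_GAP",
    "IES_FLOOR",
]

DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP = 200_000
#: iES floor in bp; a population whose iES is at the floor at a core is
#: unscoreable there and the site is dropped (avoids infinite ln ratios).
IES_FLOOR = 1.0


@dataclass
class EHHDecay:
    """EHH decay curve away from a core site in one direction.

    ``offsets`` are nonnegative physical distances (bp) from the core,
    starting at 0 where EHH = 1; ``ehh`` is non-increasing.
    """

    core_site_index: int
    direction: str  # "upstream" (towards lower pos) or "downstream"
    offsets: np.ndarray
    ehh: np.ndarray


def _pair_fraction(counts: np.ndarray, n: int) -> float:
    """Fraction of the n(n-1)/2 haplotype pairs falling inside one class."""
    return float(np.sum(counts * (counts - 1)) / (n * (n - 1)))


def _refine(labels: np.ndarray, alleles: np.ndarray) -> tuple[np.ndarray, float]:
    """Split identity classes by the alleles at one more site; return EHH."""
    combined = labels * 2 + alleles
    _, inverse, counts = np.unique(combined, return_inverse=True, return_counts=True)
    return inverse.astype(np.int64), _pair_fraction(counts, len(combined))


def ehh_at_core(
    hapmatrix: np.ndarray,
    positions: np.ndarray,
    core_site: int,
    direction: str,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: int = DEFAULT_MAX_GAP,
    include_core: bool = False,
) -> EHHDecay:
    """EHH decay from a core SNP over one population's haplotype matrix.

    The curve is evaluated at each successive SNP moving away from the
    core. Extension stops after recording the first point where EHH drops
    below ``cutoff``, when the gap to the next SNP exceeds ``max_gap``,
    or at the chromosome end. By default the core site does not
    partition the sample (EHH(0) = 1 by convention); ``include_core``
    starts the tract at the core SNP instead, so the curve begins at the
    core's haplotype homozygosity.
    """
    n, m = hapmatrix.shape
    if n < 2:
        raise ValueError("EHH requires at least 2 haplotypes")
    if not 0 <= core_site < m:
        raise IndexError(f"core site {core_site} out of range")
    step = -1 if direction == "upstream" else 1
    if direction not in ("upstream", "downstream"):
        raise ValueError(f"direction must be 'upstream' or 'downstream', got {direction!r}")

    if include_core:
        col = hapmatrix[:, core_site].astype(np.int64)
        counts = np.bincount(col)
        labels = (np.cumsum(counts > 0) - 1)[col]
        offsets = [0.0]
        ehh_values = [_pair_fraction(counts, n)]
    else:
        labels = np.zeros(n, dtype=np.int64)
        offsets = [0.0]
        ehh_values = [1.0]
    j = core_site
    while True:
        nxt = j + step
        if nxt < 0 or nxt >= m:
            break
        if abs(int(positions[nxt]) - int(positions[j])) > max_gap:
            break
        labels, ehh = _refine(labels, hapmatrix[:, nxt].astype(np.int64))
        offsets.append(float(abs(int(positions[nxt]) - int(positions[core_site]))))
        ehh_values.append(ehh)
        j = nxt
        if ehh < cutoff:
            break
    return EHHDecay(
        core_site_index=core_site,
        direction=direction,
        offsets=np.asarray(offsets),
        ehh=np.asarray(ehh_values),
    )


def integrated_ehh(decay_up: EHHDecay, decay_down: EHHDecay) -> tuple[float, bool]:
    """Trapezoidal area under the two decay curves (bp * EHH).

    Returns ``(iES, scoreable)``; when neither direction has a flanking
    SNP the area collapses and the floor value is returned with
    ``scoreable=False``.
    """
    if decay_up.core_site_index != decay_down.core_site_index:
        raise ValueError("decay curves do not share a core site")
    area = 0.0
    for decay in (decay_up, decay_down):
        if len(decay.offsets) > 1:
            area += float(np.trapezoid(decay.ehh, decay.offsets))
    if area <= IES_FLOOR:
        return IES_FLOOR, False
    return area, True


def _walk_direction(
    pooled: np.ndarray,
    n_ref: int,
    positions: np.ndarray,
    core: int,
    step: int,
    cutoff: float,
    max_gap: int,
    include_core: bool = True,
) -> tuple[float, float]:
    """One-direction (area_ref, area_test) on pooled-EHH support.

    ``pooled`` holds the reference haplotypes in rows [:n_ref] and the
    test haplotypes after them. A single set of identity-class labels
    over the pooled sample is refined site by site; each population's
    EHH is the pair fraction of the labels restricted to its rows, since
    identity over a shared site set is inherited by any row subset.

    With ``include_core`` (the canonical cross-population construction)
    the identity tract includes the core SNP itself, so each curve
    starts at the core's haplotype homozygosity; a fixed difference
    between the populations then splits the reference sample at the
    core while leaving a swept test sample intact — the signal XP-EHH
    is designed to catch.
    """
    n, m = pooled.shape
    n_test = n - n_ref
    if include_core:
        combined = pooled[:, core]
        counts = np.bincount(combined)
        labels = (np.cumsum(counts > 0) - 1)[combined]
        ehh_pool = _pair_fraction(counts, n)
        ehh_ref = _pair_fraction(np.bincount(labels[:n_ref]), n_ref)
        ehh_test = _pair_fraction(np.bincount(labels[n_ref:]), n_test)
    else:
        labels = np.zeros(n, dtype=np.int64)
        ehh_pool = ehh_ref = ehh_test = 1.0
    area_ref = area_test = 0.0
    j = core
    core_pos = int(positions[core])
    while True:
        nxt = j + step
        if nxt < 0 or nxt >= m:
            break
        if abs(int(positions[nxt]) - int(positions[j])) > max_gap:
            break
        combined = labels * 2 + pooled[:, nxt]
        counts = np.bincount(combined)
        labels = (np.cumsum(counts > 0) - 1)[combined]
        prev_ref, prev_test = ehh_ref, ehh_test
        ehh_pool = _pair_fraction(counts[counts > 1], n)
        cnt_ref = np.bincount(labels[:n_ref])
        ehh_ref = _pair_fraction(cnt_ref, n_ref)
        cnt_test = np.bincount(labels[n_ref:])
        ehh_test = _pair_fraction(cnt_test, n_test)
        half = 0.5 * (abs(int(positions[nxt]) - core_pos) - abs(int(positions[j]) - core_pos))
        area_ref += half * (prev_ref + ehh_ref)
        area_test += half * (prev_test + ehh_test)
        j = nxt
        if ehh_pool < cutoff:  # pooled sample decayed: shared boundary
            break
    return area_ref, area_test


def xpehh_site(
    ds: HaplotypeDataset,
    panel: PopulationPanel,
    test_population: str,
    chrom: str,
    core_site: int,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: int = DEFAULT_MAX_GAP,
    include_core: bool = True,
) -> dict | None:
    """Unstandardised XP-EHH at one core SNP, or None if unscoreable."""
    ref_rows = ds.haplotype_rows(panel.reference)
    test_rows = ds.haplotype_rows(test_population)
    H = ds.haplotypes[chrom]
    pooled = np.ascontiguousarray(H[np.concatenate([ref_rows, test_rows])], dtype=np.int64)
    return _xpehh_core(
        pooled, len(ref_rows), ds.positions[chrom], chrom, core_site, cutoff, max_gap,
        include_core,
    )


def _xpehh_core(pooled, n_ref, positions, chrom, core_site, cutoff, max_gap,
                include_core=True):
    if n_ref < 2 or pooled.shape[0] - n_ref < 2:
        raise ValueError("both populations need >= 2 haplotypes")
    ies_ref = ies_test = 0.0
    for step in (-1, 1):
        a_ref, a_test = _walk_direction(
            pooled, n_ref, positions, core_site, step, cutoff, max_gap, include_core
        )
        ies_ref += a_ref
        ies_test += a_test
    if ies_ref <= IES_FLOOR or ies_test <= IES_FLOOR:
        return None
    return {
        "chrom": chrom,
        "pos": int(positions[core_site]),
        "site_index": core_site,
        "ies_ref": ies_ref,
        "ies_test": ies_test,
        "raw_lnratio": float(np.log(ies_test / ies_ref)),
    }


def xpehh_scan(
    ds: HaplotypeDataset,
    panel: PopulationPanel,
    test_population: str,
    chroms: list[str] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: int = DEFAULT_MAX_GAP,
    include_core: bool = True,
) -> pd.DataFrame:
    """Per-site unstandardised XP-EHH over whole chromosomes.

    Returns a DataFrame with columns chrom, pos, site_index, ies_ref,
    ies_test, raw_lnratio; unscoreable sites (either population's iES at
    the floor, or no flanking SNPs) are dropped and counted in the log.
    """
    ref_rows = ds.haplotype_rows(panel.reference)
    test_rows = ds.haplotype_rows(test_population)
    records = []
    n_dropped = 0
    for chrom in chroms if chroms is not None else ds.chrom_names:
        H = ds.haplotypes[chrom]
        pooled = np.ascontiguousarray(
            H[np.concatenate([ref_rows, test_rows])], dtype=np.int64
        )
        positions = ds.positions[chrom]
        for core in range(H.shape[1]):
            rec = _xpehh_core(
                pooled, len(ref_rows), positions, chrom, core, cutoff, max_gap, include_core
            )
            if rec is None:
                n_dropped += 1
            else:
                records.append(rec)
    if n_dropped:
        logger.info("dropped %d unscoreable core sites (iES at floor)", n_dropped)
    cols = ["chrom", "pos", "site_index", "ies_ref", "ies_test", "raw_lnratio"]
    return pd.DataFrame(records, columns=cols)


def normalize_scores(raw: np.ndarray) -> np.ndarray:
    """Genome-wide z-normalisation: (raw - mean) / sd (population sd)."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least 2 scores to normalise")
    sd = raw.std()
    if sd == 0:
        raise ValueError("degenerate score set: zero standard deviation")
    return (raw - raw.mean()) / sd
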