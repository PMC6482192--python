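"""Genome binning, empirical p-values, and candidate-region intersection.

The genome is tiled with non-overlapping 50 kb bins. Each bin's
representative XP-EHH is the maximum raw ln ratio over its SNPs; the
per-bin representatives are z-normalised genome-wide and ranked into
upper-tail empirical p-values, p_i = #{bins with value >= value_i} / N.
The wild/farm diversity ratio gets the same rank treatment. A bin is a
candidate selective-sweep region when it is significant (top alpha
fraction of ranked bins) for BOTH statistics; with distinct values that
is exactly the top floor(alpha * N) bins per statistic, implemented as
``p <= alpha`` on the >=-counting empirical p.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ehh import normalize_scores

__all__ = [
    "make_bins",
    "bin_index",
    "bin_representative_xpehh",
    "empirical_p",
    "attach_ratio",
    "intersect_candidates",
    "build_bin_table",
    "population_overlap",
    "DEFAULT_BIN_SIZE",
    "DEFAULT_ALPHA",
]

DEFAULT_BIN_SIZE = 50_000
DEFAULT_ALPHA = 0.05


def make_bins(chrom_lengths: dict[str, int], bin_size: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
    """Tile each chromosome with half-open 1-based bins [start, start+bin).

    The last bin may extend past the chromosome end (ceiling division);
    short scaffolds are binned like any chromosome.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise ValueError(f"{chrom}: length must be >= 1")
        for k in range(int(np.ceil(length / bin_size))):
            rows.append({"chrom": chrom, "start": 1 + k * bin_size, "end": 1 + (k + 1) * bin_size})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def bin_index(pos: np.ndarray, bin_size: int = DEFAULT_BIN_SIZE) -> np.ndarray:
    """0-based bin ordinal of each 1-based position."""
    return (np.asarray(pos) - 1) // bin_size


def bin_representative_xpehh(site_scores: pd.DataFrame, bins: pd.DataFrame) -> pd.DataFrame:
    """Fill per-bin ``xpehh_max`` (max raw ln ratio) and ``xpehh_norm``.

    Bins with no scored SNP keep NaN and are excluded from normalisation
    and ranking. Normalisation is over the per-bin representatives, so
    the z-scores refer to the genome-wide bin distribution.
    """
    out = bins.copy()
    out["xpehh_max"] = np.nan
    if len(site_scores):
        bin_size = int(out["end"].iloc[0] - out["start"].iloc[0])
        keyed = site_scores.assign(
            start=1 + bin_index(site_scores["pos"].to_numpy(), bin_size) * bin_size
        )
        per_bin = keyed.groupby(["chrom", "start"], sort=False)["raw_lnratio"].max().reset_index()
        missing = per_bin.merge(out[["chrom", "start"]], on=["chrom", "start"], how="left", indicator=True)
        if (missing["_merge"] != "both").any():
            bad = missing.loc[missing["_merge"] != "both"].iloc[0]
            raise ValueError(f"scored site in {bad['chrom']} bin start {bad['start']} maps to no bin")
        out = out.merge(per_bin.rename(columns={"raw_lnratio": "xpehh_max_"}), on=["chrom", "start"], how="left")
        out["xpehh_max"] = out.pop("xpehh_max_")
    scored = out["xpehh_max"].notna()
    out["xpehh_norm"] = np.nan
    if scored.sum() >= 2:
        out.loc[scored, "xpehh_norm"] = normalize_scores(out.loc[scored, "xpehh_max"].to_numpy())
    return out


def empirical_p(values: np.ndarray, tail: str = "upper") -> np.ndarray:
    """Rank-based tail probability: p_i = #{v_j >= v_i} / N (upper tail).

    Ties share the larger (conservative) p; p ranges over [1/N, 1] and is
    invariant under any order-preserving transform of the values.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empirical_p needs at least one value")
    if np.any(~np.isfinite(values)):
        raise ValueError("empirical_p requires finite values")
    if tail == "lower":
        values = -values
    elif tail != "upper":
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    order = np.sort(values)
    n_ge = values.size - np.searchsorted(order, values, side="left")
    return n_ge / values.size


def attach_ratio(bins: pd.DataFrame, ratio_windows: pd.DataFrame) -> pd.DataFrame:
    """Merge the diversity-ratio table onto the bin grid (same tiling)."""
    keep = ratio_windows[["chrom", "start", "ratio", "defined"]]
    out = bins.merge(keep, on=["chrom", "start"], how="left")
    out["pi_ratio"] = out.pop("ratio")
    out["defined"] = out["defined"].fillna(False).astype(bool)
    return out


def intersect_candidates(bins: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Empirical p for both statistics and the candidate intersection flag.

    A bin must be rankable in both statistics (a scored XP-EHH SNP and a
    defined diversity ratio) to be a candidate; candidacy is significance
    in both ranked tails at level alpha.
    """
    out = bins.copy()
    out["p_xpehh"] = np.nan
    out["p_ratio"] = np.nan
    ok_x = out["xpehh_max"].notna().to_numpy()
    if ok_x.any():
        out.loc[ok_x, "p_xpehh"] = empirical_p(out.loc[ok_x, "xpehh_max"].to_numpy())
    ok_r = (out["defined"] & out["pi_ratio"].notna()).to_numpy()
    if ok_r.any():
        out.loc[ok_r, "p_ratio"] = empirical_p(out.loc[ok_r, "pi_ratio"].to_numpy())
    out["is_candidate"] = (
        (out["p_xpehh"] <= alpha) & (out["p_ratio"] <= alpha)
    ).fillna(False)
    return out


def build_bin_table(
    site_scores: pd.DataFrame,
    ratio_windows: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Full bin table: representative XP-EHH, ratio, p-values, candidacy."""
    bins = make_bins(chrom_lengths, bin_size)
    bins = bin_representative_xpehh(site_scores, bins)
    bins = attach_ratio(bins, ratio_windows)
    return intersect_candidates(bins, alpha)


def population_overlap(candidate_bins_by_population: dict[str, set]) -> dict:
    """Shared / exclusive candidate-bin accounting across populations.

    Bins are identified by hashable keys (e.g. (chrom, start)); returns
    the all-population intersection, each population's exclusive set, and
    all pairwise intersections.
    """
    pops = list(candidate_bins_by_population)
    if not pops:
        raise ValueError("no populations given")
    sets = {p: set(candidate_bins_by_population[p]) for p in pops}
    shared_all = set.intersection(*sets.values())
    exclusive = {
        p: sets[p] - set().union(*(sets[q] for q in pops if q != p)) if len(pops) > 1 else sets[p]
        for p in pops
    }
    pairwise = {
        (p, q): sets[p] & sets[q] for i, p in enumerate(pops) for q in pops[i + 1 :]
    }
    return {"shared_all": shared_all, "exclusive": exclusive, "pairwise": pairwise}
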