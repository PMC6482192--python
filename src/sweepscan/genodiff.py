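"""Per-SNP genotype differentiation under five genetic models.

For each SNP, genotype counts in the test (farm) and reference (wild)
populations are collapsed into a contingency table under each model —
rows are populations, columns are genotype classes oriented by the
reference population's major allele ("homref" = homozygote for the
wild-major allele):

    dominant   2x2  (carriers = het + homalt, non-carriers = homref)
    recessive  2x2  (homalt, het + homref)
    allelic    2x2  (alt alleles = 2*homalt + het, ref = het + 2*homref)
    codominant 2x3  (homref, het, homalt)
    trend      2x3  (same table; Cochran-Armitage with dose weights 0,1,2)

Fisher's exact test covers the 2x2 models, Pearson chi-square (no
continuity correction, empty genotype columns dropped with df reduced)
the codominant model, and the Cochran-Armitage trend statistic (1 df)
the trend model. The minimum p over models is deliberately not corrected
for multiplicity: a locus is "differentiating" when min p < alpha under
at least one model AND it lies within a gene body or the 5 kb flank.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import HaplotypeDataset, PopulationPanel, genotype_count_matrix
from .scan import bin_index

__all__ = [
    "MODELS",
    "model_table",
    "fisher_exact_2x2",
    "chisq_2x3",
    "cochran_armitage",
    "scan_differentiated_loci",
    "DEFAULT_FLANK",
]

MODELS = ("dominant", "recessive", "codominant", "allelic", "trend")
DEFAULT_FLANK = 5_000


def model_table(counts_test, counts_ref, model: str) -> np.ndarray:
    """Collapse two genotype triples (homref, het, homalt) into a table.

    Rows are (test population, reference population); columns per model
    as in the module docstring. Cell totals are conserved (2x allele
    scale for the allelic model).
    """
    rows = []
    for n0, n1, n2 in (counts_test, counts_ref):
        if model == "dominant":
            rows.append([n1 + n2, n0])
        elif model == "recessive":
            rows.append([n2, n1 + n0])
        elif model == "allelic":
            rows.append([2 * n2 + n1, n1 + 2 * n0])
        elif model in ("codominant", "trend"):
            rows.append([n0, n1, n2])
        else:
            raise ValueError(f"unknown model {model!r}")
    return np.asarray(rows, dtype=np.int64)


@lru_cache(maxsize=200_000)
def _fisher_cached(a, b, c, d) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (sum of fixed-margin tables with point
    probability <= the observed table's)."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    if np.any(table < 0):
        raise ValueError("negative cell count")
    return _fisher_cached(*table.ravel().tolist())


@lru_cache(maxsize=200_000)
def _chisq_cached(cells: tuple) -> float:
    table = np.asarray(cells, dtype=np.float64).reshape(2, -1)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        return 1.0  # single occupied genotype class: no association testable
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def chisq_2x3(table) -> float:
    """Pearson chi-square p for a 2x3 genotype table, empty columns dropped."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 3):
        raise ValueError("chisq_2x3 requires a 2x3 table")
    if np.any(table.sum(axis=1) == 0):
        raise ValueError("a population row sums to zero")
    return _chisq_cached(tuple(table.ravel().tolist()))


def cochran_armitage(table, weights=(0.0, 1.0, 2.0)) -> float:
    """Cochran-Armitage trend test p for a 2x3 genotype table.

    The squared trend statistic is referred to chi-square with 1 df; it
    is invariant under affine transformation of the dose weights. Zero
    trend variance (all counts in one genotype column, or a monomorphic
    dose) returns p = 1.
    """
    t = np.asarray(table, dtype=np.float64)
    if t.shape[0] != 2 or t.shape[1] != len(weights):
        raise ValueError("cochran_armitage requires a 2xK table with K dose weights")
    w = np.asarray(weights, dtype=np.float64)
    r1, r2 = t.sum(axis=1)
    n = r1 + r2
    col = t.sum(axis=0)
    if r1 == 0 or r2 == 0 or n == 0:
        raise ValueError("a population row sums to zero")
    tstat = np.sum(w * (t[0] * r2 - t[1] * r1))
    var = r1 * r2 * (n * np.sum(w * w * col) - np.sum(w * col) ** 2) / n
    if var <= 0:
        return 1.0
    z2 = tstat * tstat / var
    return float(stats.chi2.sf(z2, df=1))


def _orient_triples(test_triples: np.ndarray, ref_triples: np.ndarray) -> tuple:
    """Flip per-site genotype triples so class 0 is the wild-major homozygote."""
    # alt-allele count in reference; flip where alt is the wild major
    ref_alt = 2 * ref_triples[:, 2] + ref_triples[:, 1]
    ref_total = 2 * ref_triples.sum(axis=1)
    flip = ref_alt * 2 > ref_total  # strict majority; ties keep REF orientation
    t = test_triples.copy()
    r = ref_triples.copy()
    t[flip] = t[flip, ::-1]
    r[flip] = r[flip, ::-1]
    return t, r


def scan_differentiated_loci(
    ds: HaplotypeDataset,
    panel: PopulationPanel,
    test_pop: str,
    genes: pd.DataFrame | None = None,
    candidate_bins: pd.DataFrame | None = None,
    alpha: float = 0.05,
    flank: int = DEFAULT_FLANK,
    bin_size: int = 50_000,
) -> pd.DataFrame:
    """All five model tests at every polymorphic SNP, with gene context.

    Sites monomorphic for the same allele in both populations are
    skipped (every model p would be 1). Returns one row per tested SNP:
    chrom, pos, p_<model> per model, p_min, in_genic_flank,
    in_candidate_bin, nearest_gene_id, differentiating.
    """
    records = []
    for chrom in ds.chrom_names:
        pos = ds.positions[chrom]
        if not len(pos):
            continue
        t_triples = genotype_count_matrix(ds, test_pop, chrom)
        r_triples = genotype_count_matrix(ds, panel.reference, chrom)
        # polymorphic in the combined sample
        alt = 2 * (t_triples[:, 2] + r_triples[:, 2]) + t_triples[:, 1] + r_triples[:, 1]
        total = 2 * (t_triples.sum(axis=1) + r_triples.sum(axis=1))
        poly = (alt > 0) & (alt < total)
        t_or, r_or = _orient_triples(t_triples, r_triples)

        gene_ctx = _gene_context(genes, chrom, pos, flank) if genes is not None else None
        cand_starts = None
        if candidate_bins is not None:
            sel = candidate_bins[
                (candidate_bins["chrom"] == chrom) & candidate_bins["is_candidate"]
            ]
            cand_starts = set(sel["start"].astype(int))

        for j in np.flatnonzero(poly):
            tt = tuple(int(x) for x in t_or[j])
            rr = tuple(int(x) for x in r_or[j])
            p = {
                "dominant": fisher_exact_2x2(model_table(tt, rr, "dominant")),
                "recessive": fisher_exact_2x2(model_table(tt, rr, "recessive")),
                "allelic": fisher_exact_2x2(model_table(tt, rr, "allelic")),
                "codominant": chisq_2x3(model_table(tt, rr, "codominant")),
                "trend": cochran_armitage(model_table(tt, rr, "trend")),
            }
            p_min = min(p.values())
            in_flank, nearest = (True, None) if gene_ctx is None else gene_ctx(int(pos[j]))
            in_cand = (
                cand_starts is not None
                and int(1 + bin_index(pos[j], bin_size) * bin_size) in cand_starts
            )
            records.append(
                {
                    "chrom": chrom,
                    "pos": int(pos[j]),
                    **{f"p_{m}": p[m] for m in MODELS},
                    "p_min": p_min,
                    "in_genic_flank": bool(in_flank),
                    "in_candidate_bin": bool(in_cand),
                    "nearest_gene_id": nearest,
                    "differentiating": bool(p_min < alpha and in_flank),
                }
            )
    cols = (
        ["chrom", "pos"]
        + [f"p_{m}" for m in MODELS]
        + ["p_min", "in_genic_flank", "in_candidate_bin", "nearest_gene_id", "differentiating"]
    )
    return pd.DataFrame(records, columns=cols)


def _gene_context(genes: pd.DataFrame, chrom: str, pos: np.ndarray, flank: int):
    """Closure answering (in ±flank of a gene?, nearest gene id) per position."""
    g = genes[genes["chrom"] == chrom].sort_values("start")
    if not len(g):
        return lambda p: (False, None)
    gs = g["start"].to_numpy()
    ge = g["end"].to_numpy()
    ids = g["id"].to_numpy()

    def query(p: int):
        dist = np.where(p < gs, gs - p, np.where(p > ge, p - ge, 0))
        i = int(np.argmin(dist))
        return bool(dist[i] <= flank), ids[i]

    return query
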