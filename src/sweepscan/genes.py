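"""Gene annotation I/O and gene-to-bin assignment.

Genes are 1-based inclusive intervals with unique ids, optional strand,
and an optional annotation-coverage fraction (the alignment coverage of
the gene's functional annotation; genes under the coverage threshold are
dropped from the export list intended for enrichment tools). BED input
(0-based half-open) is converted exactly; GFF3 is already 1-based
inclusive.

A candidate bin is represented by the genes overlapping it; a bin with
no overlapping gene falls back to the nearest gene on the chromosome by
edge distance, reporting both on a tie.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["read_gene_annotation", "genes_for_bins", "DEFAULT_COVERAGE_MIN"]

DEFAULT_COVERAGE_MIN = 0.70

_GENE_COLUMNS = ["id", "chrom", "start", "end", "strand", "coverage"]


def _finish(rows: list[dict]) -> pd.DataFrame:
    genes = pd.DataFrame(rows, columns=_GENE_COLUMNS)
    dup = genes["id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate gene id: {genes.loc[dup, 'id'].iloc[0]!r}")
    if (genes["start"] > genes["end"]).any():
        bad = genes[genes["start"] > genes["end"]].iloc[0]
        raise ValueError(f"gene {bad['id']!r}: start > end")
    return genes


def read_gene_annotation(path) -> pd.DataFrame:
    """Read gene intervals from BED or GFF3 into 1-based inclusive form.

    BED: columns chrom, start (0-based), end, name, [coverage fraction],
    [strand]; the optional 5th column is interpreted as the annotation
    coverage when it parses as a number in [0, 1]. GFF3: records of type
    ``gene``, id from ``ID=`` (or ``gene_id``), coverage from an optional
    ``annotation_coverage``/``coverage`` attribute.
    """
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        return _read_gff3(path)
    return _read_bed(path)


def _read_bed(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: BED gene record needs >= 4 columns")
            try:
                start0, end0 = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            coverage = np.nan
            if len(f) >= 5 and f[4] not in (".", ""):
                try:
                    val = float(f[4])
                    if 0.0 <= val <= 1.0:
                        coverage = val
                except ValueError:
                    pass
            strand = f[5] if len(f) >= 6 and f[5] in "+-" else "."
            rows.append(
                {
                    "id": f[3],
                    "chrom": f[0],
                    "start": start0 + 1,  # 0-based half-open -> 1-based inclusive
                    "end": end0,
                    "strand": strand,
                    "coverage": coverage,
                }
            )
    return _finish(rows)


def _read_gff3(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 record needs 9 columns")
            if f[2].lower() != "gene":
                continue
            try:
                start, end = int(f[3]), int(f[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}:{lineno}: gene record without ID attribute")
            coverage = np.nan
            for key in ("annotation_coverage", "coverage"):
                if key in attrs:
                    coverage = float(attrs[key])
                    break
            rows.append(
                {
                    "id": gid,
                    "chrom": f[0],
                    "start": start,
                    "end": end,
                    "strand": f[6] if f[6] in "+-" else ".",
                    "coverage": coverage,
                }
            )
    return _finish(rows)


def genes_for_bins(
    bins: pd.DataFrame,
    genes: pd.DataFrame,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
    apply_coverage_filter: bool = True,
) -> pd.DataFrame:
    """Assign genes to (candidate) bins: overlap first, nearest as fallback.

    For each bin (1-based half-open [start, end)) returns every gene whose
    interval overlaps it; when none does, the single nearest gene on the
    chromosome by edge distance (both genes on an exact tie). Genes whose
    annotation coverage is present and below ``coverage_min`` are excluded
    before assignment when ``apply_coverage_filter`` is set.

    Returns a long DataFrame: chrom, start, end, gene_id, relation
    ("overlap"/"nearest"), distance (0 for overlap).
    """
    usable = genes
    if apply_coverage_filter:
        keep = genes["coverage"].isna() | (genes["coverage"] >= coverage_min)
        usable = genes[keep]
    by_chrom = {c: g.sort_values("start").reset_index(drop=True) for c, g in usable.groupby("chrom")}

    out_rows = []
    for _, b in bins.iterrows():
        chrom, bs, be = b["chrom"], int(b["start"]), int(b["end"])
        g = by_chrom.get(chrom)
        if g is None or not len(g):
            logger.warning("no annotated genes on %s; bin %d-%d reported empty", chrom, bs, be)
            continue
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        overlap = (gs <= be - 1) & (ge >= bs)
        if overlap.any():
            for i in np.flatnonzero(overlap):
                out_rows.append(
                    {"chrom": chrom, "start": bs, "end": be,
                     "gene_id": g["id"].iloc[i], "relation": "overlap", "distance": 0}
                )
        else:
            # nearest by edge distance: gene fully left -> bs - ge; right -> gs - (be-1)
            dist = np.where(ge < bs, bs - ge, gs - (be - 1))
            dmin = dist.min()
            for i in np.flatnonzero(dist == dmin):
                out_rows.append(
                    {"chrom": chrom, "start": bs, "end": be,
                     "gene_id": g["id"].iloc[i], "relation": "nearest", "distance": int(dmin)}
                )
    return pd.DataFrame(out_rows, columns=["chrom", "start", "end", "gene_id", "relation", "distance"])
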