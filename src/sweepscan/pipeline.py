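"""End-to-end scan orchestration and cross-population overlap summaries.

`run_full_scan` runs, for each test (farm) population paired against the
reference (wild) population: the per-site XP-EHH scan, windowed
nucleotide diversity and the wild/farm ratio, the 50 kb bin table with
empirical p-values and candidate intersection, gene assignment for
candidate bins, and the five-model genotype-differentiation scan. All
results are written as TSV (header lines begin with ``#``) plus a
candidate BED and a JSON run manifest; reruns on identical inputs and
configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import pandas as pd

from . import __version__
from .dataio import HaplotypeDataset, PopulationPanel, read_panel, read_phased_vcf
from .diversity import relative_diversity, windowed_pi
from .ehh import xpehh_scan
from .genes import genes_for_bins, read_gene_annotation
from .genodiff import scan_differentiated_loci
from .scan import build_bin_table, population_overlap

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_scan", "summarize_overlap"]


@dataclasses.dataclass
class RunConfig:
    """Paths and parameters of a full scan run (defaults are the scan's
    published operating point: 50 kb bins, alpha 0.05, 5 kb gene flank,
    EHH cutoff 0.05, 200 kb max gap, 70% annotation-coverage floor)."""

    vcf: str
    panel: str
    outdir: str
    annotation: str | None = None
    reference_pop: str = "wild"
    test_pops: list[str] | None = None
    bin_size: int = 50_000
    alpha: float = 0.05
    flank: int = 5_000
    ehh_cutoff: float = 0.05
    max_gap: int = 200_000
    coverage_min: float = 0.70

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.10g")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_full_scan(config: RunConfig) -> dict:
    """Run the whole scan; returns the in-memory report bundle.

    The bundle maps each test population to its bin table, candidate
    bins, gene assignment and genotype-differentiation table, plus a
    cross-population overlap summary when there are >= 2 test
    populations.
    """
    os.makedirs(config.outdir, exist_ok=True)
    panel = read_panel(config.panel, reference=config.reference_pop)
    ds = read_phased_vcf(config.vcf, panel)
    test_pops = config.test_pops or panel.test_populations
    genes = read_gene_annotation(config.annotation) if config.annotation else None
    chrom_lengths = {c: ds.effective_length(c) for c in ds.chrom_names}

    pi = windowed_pi(ds, panel, window_size=config.bin_size)
    bundle: dict = {"populations": {}, "config": config}
    candidate_sets: dict[str, set] = {}
    gene_sets: dict[str, set] = {}

    for pop in test_pops:
        logger.info("scanning population %s against %s", pop, config.reference_pop)
        scores = xpehh_scan(
            ds, panel, pop, cutoff=config.ehh_cutoff, max_gap=config.max_gap
        )
        ratio = relative_diversity(pi, config.reference_pop, pop)
        bins = build_bin_table(
            scores, ratio, chrom_lengths, bin_size=config.bin_size, alpha=config.alpha
        )
        cand = bins[bins["is_candidate"]]
        gene_map = (
            genes_for_bins(cand, genes, coverage_min=config.coverage_min)
            if genes is not None
            else pd.DataFrame(columns=["chrom", "start", "end", "gene_id", "relation", "distance"])
        )
        diff = scan_differentiated_loci(
            ds,
            panel,
            pop,
            genes=genes,
            candidate_bins=bins,
            alpha=config.alpha,
            flank=config.flank,
            bin_size=config.bin_size,
        )
        pdir = os.path.join(config.outdir, pop)
        os.makedirs(pdir, exist_ok=True)
        _write_tsv(scores, os.path.join(pdir, "xpehh_sites.tsv"))
        _write_tsv(ratio, os.path.join(pdir, "pi_ratio.tsv"))
        _write_tsv(bins, os.path.join(pdir, "bins.tsv"))
        _write_tsv(gene_map, os.path.join(pdir, "candidate_genes.tsv"))
        _write_tsv(diff, os.path.join(pdir, "genotype_diff.tsv"))
        with open(os.path.join(pdir, "candidates.bed"), "w") as fh:
            for _, row in cand.iterrows():
                fh.write(
                    f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end']) - 1}\t"
                    f"candidate\t{row['xpehh_norm']:.6g}\n"
                )
        with open(os.path.join(pdir, "candidate_gene_list.txt"), "w") as fh:
            for gid in sorted(set(gene_map["gene_id"])):
                fh.write(gid + "\n")
        candidate_sets[pop] = {(c, int(s)) for c, s in zip(cand["chrom"], cand["start"])}
        gene_sets[pop] = set(gene_map["gene_id"])
        bundle["populations"][pop] = {
            "scores": scores,
            "ratio": ratio,
            "bins": bins,
            "genes": gene_map,
            "genotype_diff": diff,
        }

    if len(test_pops) >= 2:
        overlap = summarize_overlap(candidate_sets, gene_sets)
        bundle["overlap"] = overlap
        with open(os.path.join(config.outdir, "overlap.json"), "w") as fh:
            json.dump(_overlap_json(overlap), fh, indent=2, sort_keys=True)

    manifest = {
        "tool": "sweepscan",
        "version": __version__,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("vcf", "panel", "annotation", "outdir")
        },
        "inputs": {
            "vcf": {"path": config.vcf, "sha256": _sha256(config.vcf)},
            "panel": {"path": config.panel, "sha256": _sha256(config.panel)},
            **(
                {"annotation": {"path": config.annotation, "sha256": _sha256(config.annotation)}}
                if config.annotation
                else {}
            ),
        },
        "populations": {"reference": config.reference_pop, "tests": list(test_pops)},
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return bundle


def summarize_overlap(candidate_sets: dict[str, set], gene_sets: dict[str, set] | None = None):
    """Bin-level and gene-level sharing across >= 2 population scans."""
    if len(candidate_sets) < 2:
        raise ValueError("overlap summary needs at least 2 populations")
    out = {"bins": population_overlap(candidate_sets)}
    if gene_sets is not None:
        out["genes"] = population_overlap(gene_sets)
    return out


def _overlap_json(overlap: dict) -> dict:
    def conv(node):
        if isinstance(node, set):
            return sorted(str(x) for x in node)
        if isinstance(node, dict):
            return {str(k): conv(v) for k, v in node.items()}
        return node

    return conv(overlap)
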