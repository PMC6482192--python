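"""Phased haplotype data structures and VCF input/output.

The substrate of every statistic in this package is a matrix of phased,
complete, biallelic SNP alleles for two or more populations. Input is a
VCF 4.x file whose GT fields are all phased (``|`` separator) and complete
— the intended upstream is an imputation/phasing step, so missingness is a
contract violation rather than something to paper over (an explicit
``fill_major`` escape hatch exists for convenience).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationPanel",
    "HaplotypeDataset",
    "read_panel",
    "read_phased_vcf",
    "write_phased_vcf",
    "allele_counts",
    "genotype_counts",
]


class VcfContractError(ValueError):
    """Raised when a VCF record violates the phased-and-complete contract."""


@dataclass(frozen=True)
class PopulationPanel:
    """Sample-to-population assignment with a designated reference population.

    Parameters
    ----------
    populations
        Mapping population label -> list of sample identifiers.
    reference
        The label of the reference (wild) population; every other label is
        a test (farm) population.
    """

    populations: dict[str, list[str]]
    reference: str

    def __post_init__(self):
        if self.reference not in self.populations:
            raise ValueError(f"reference population {self.reference!r} not in panel")
        seen: set[str] = set()
        for label, samples in self.populations.items():
            dup = seen.intersection(samples)
            if dup:
                raise ValueError(f"samples assigned to more than one population: {sorted(dup)}")
            seen.update(samples)

    @property
    def test_populations(self) -> list[str]:
        return [p for p in self.populations if p != self.reference]

    @property
    def samples(self) -> list[str]:
        out: list[str] = []
        for label in self.populations:
            out.extend(self.populations[label])
        return out

    def population_of(self, sample: str) -> str:
        for label, samples in self.populations.items():
            if sample in samples:
                return label
        raise KeyError(sample)


def read_panel(path, reference: str) -> PopulationPanel:
    """Read a two-column ``sample<TAB>population`` assignment file."""
    populations: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>population', got {line!r}")
            sample, pop = parts
            populations.setdefault(pop, []).append(sample)
    return PopulationPanel(populations=populations, reference=reference)


@dataclass
class HaplotypeDataset:
    """Phased biallelic haplotype matrices keyed by chromosome.

    ``haplotypes[chrom]`` has one row per haplotype — two consecutive rows
    per diploid sample, in ``sample_ids`` order (left-of-bar then
    right-of-bar) — and one column per SNP, holding 0 (REF) or 1 (ALT).
    Positions are 1-based and strictly increasing within a chromosome.
    """

    sample_ids: list[str]
    population_of_sample: dict[str, str]
    chrom_names: list[str]
    positions: dict[str, np.ndarray]
    ref_alleles: dict[str, np.ndarray]
    alt_alleles: dict[str, np.ndarray]
    haplotypes: dict[str, np.ndarray]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        n_hap = 2 * len(self.sample_ids)
        for chrom in self.chrom_names:
            H = self.haplotypes[chrom]
            pos = self.positions[chrom]
            if H.shape != (n_hap, len(pos)):
                raise ValueError(
                    f"{chrom}: haplotype matrix shape {H.shape} inconsistent with "
                    f"{n_hap} haplotypes x {len(pos)} sites"
                )
            if len(pos) and (np.any(pos < 1) or np.any(np.diff(pos) <= 0)):
                raise ValueError(f"{chrom}: positions must be >= 1 and strictly increasing")
        missing = [s for s in self.sample_ids if s not in self.population_of_sample]
        if missing:
            raise ValueError(f"samples without population assignment: {missing}")

    # -- indexing helpers -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.positions[chrom])
        return sum(len(self.positions[c]) for c in self.chrom_names)

    def sample_indices(self, population: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.population_of_sample[s] == population]
        if not idx:
            raise KeyError(f"no samples in population {population!r}")
        return np.asarray(idx)

    def haplotype_rows(self, population: str) -> np.ndarray:
        """Row indices of ``haplotypes`` belonging to one population."""
        sidx = self.sample_indices(population)
        return np.ravel(np.column_stack([2 * sidx, 2 * sidx + 1]))

    def population_matrix(self, population: str, chrom: str) -> np.ndarray:
        return self.haplotypes[chrom][self.haplotype_rows(population)]

    def effective_length(self, chrom: str) -> int:
        """Declared contig length, falling back to the last SNP position."""
        if chrom in self.chrom_lengths:
            return self.chrom_lengths[chrom]
        pos = self.positions[chrom]
        return int(pos[-1]) if len(pos) else 1


# -- VCF I/O --------------------------------------------------------------


def read_phased_vcf(path, panel: PopulationPanel, *, fill_major: bool = False) -> HaplotypeDataset:
    """Read phased biallelic SNPs for the panel's samples from a VCF.

    Multi-allelic and non-SNP records are dropped (with a logged count).
    Unphased or missing genotypes abort with an error naming the first
    offending record, unless ``fill_major`` is set, in which case missing
    alleles are filled with the population-major allele (and logged).
    """
    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    absent = [s for s in panel.samples if s not in header_samples]
    if absent:
        raise ValueError(f"panel samples absent from VCF header: {absent}")
    # keep VCF header order among panel samples
    samples = [s for s in header_samples if s in set(panel.samples)]
    col_of = {s: header_samples.index(s) for s in samples}
    cols = np.asarray([col_of[s] for s in samples])

    chrom_names: list[str] = []
    positions: dict[str, list[int]] = {}
    refs: dict[str, list[str]] = {}
    alts: dict[str, list[str]] = {}
    haps: dict[str, list[np.ndarray]] = {}
    n_excluded = 0
    n_filled = 0

    pop_rows = {}  # population -> haplotype row indices among panel samples

    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_excluded += 1
            continue
        chrom, pos = variant.CHROM, variant.POS
        gts = np.asarray(variant.genotype.array())[cols]  # (n, 3): a, b, phased
        alleles = gts[:, :2]
        phased = gts[:, 2]
        if np.any(alleles < 0):
            if not fill_major:
                raise VcfContractError(
                    f"missing genotype at {chrom}:{pos} (input contract is imputed/phased data)"
                )
            if not pop_rows:
                for label, members in panel.populations.items():
                    sidx = np.asarray([samples.index(s) for s in members])
                    pop_rows[label] = np.ravel(np.column_stack([2 * sidx, 2 * sidx + 1]))
            flat = alleles.reshape(-1).astype(np.int16)
            for label, rows in pop_rows.items():
                sub = flat[rows]
                known = sub[sub >= 0]
                major = 1 if known.size and known.mean() > 0.5 else 0
                n_filled += int(np.sum(sub < 0))
                sub[sub < 0] = major
                flat[rows] = sub
            alleles = flat.reshape(alleles.shape)
        elif np.any(~phased.astype(bool)):
            bad = samples[int(np.flatnonzero(~phased.astype(bool))[0])]
            raise VcfContractError(f"unphased genotype for sample {bad} at {chrom}:{pos}")
        if chrom not in positions:
            chrom_names.append(chrom)
            positions[chrom], refs[chrom], alts[chrom], haps[chrom] = [], [], [], []
        if positions[chrom] and pos <= positions[chrom][-1]:
            raise VcfContractError(f"positions not strictly increasing at {chrom}:{pos}")
        positions[chrom].append(pos)
        refs[chrom].append(variant.REF)
        alts[chrom].append(variant.ALT[0])
        haps[chrom].append(alleles.reshape(-1).astype(np.uint8))

    if n_excluded:
        logger.info("excluded %d multi-allelic/non-SNP records", n_excluded)
    if n_filled:
        logger.warning("filled %d missing alleles with the population-major allele", n_filled)

    chrom_lengths = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            body = line.split("<", 1)[1].rstrip(">")
            kv = dict(item.split("=", 1) for item in body.split(",") if "=" in item)
            if "ID" in kv and "length" in kv:
                chrom_lengths[kv["ID"]] = int(kv["length"])

    n_hap = 2 * len(samples)
    pop_of = {s: panel.population_of(s) for s in samples}
    return HaplotypeDataset(
        sample_ids=samples,
        population_of_sample=pop_of,
        chrom_names=chrom_names,
        positions={c: np.asarray(positions[c], dtype=np.int64) for c in chrom_names},
        ref_alleles={c: np.asarray(refs[c]) for c in chrom_names},
        alt_alleles={c: np.asarray(alts[c]) for c in chrom_names},
        haplotypes={
            c: (
                np.vstack(haps[c]).T.copy()
                if haps[c]
                else np.empty((n_hap, 0), dtype=np.uint8)
            )
            for c in chrom_names
        },
        chrom_lengths={c: chrom_lengths[c] for c in chrom_names if c in chrom_lengths},
    )


def write_phased_vcf(ds: HaplotypeDataset, path) -> None:
    """Write the dataset as a minimal GT-only VCF 4.2 file.

    Round-trip with :func:`read_phased_vcf` reproduces positions, alleles
    and the haplotype matrix exactly.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for chrom in ds.chrom_names:
            fh.write(f"##contig=<ID={chrom},length={ds.effective_length(chrom)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ds.sample_ids) + "\n")
        for chrom in ds.chrom_names:
            H = ds.haplotypes[chrom]
            pos = ds.positions[chrom]
            ref = ds.ref_alleles[chrom]
            alt = ds.alt_alleles[chrom]
            for j in range(len(pos)):
                col = H[:, j]
                gts = "\t".join(f"{col[2*i]}|{col[2*i+1]}" for i in range(ds.n_samples))
                fh.write(f"{chrom}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


# -- counting primitives ---------------------------------------------------


def allele_counts(ds: HaplotypeDataset, population: str, chrom: str, site_index: int):
    """Counts of allele 0 and allele 1 in one population at one site."""
    H = ds.population_matrix(population, chrom)
    if not 0 <= site_index < H.shape[1]:
        raise IndexError(f"site index {site_index} out of range for {chrom}")
    c1 = int(H[:, site_index].sum())
    return H.shape[0] - c1, c1


def genotype_counts(ds: HaplotypeDataset, population: str, chrom: str, site_index: int):
    """(n_homref, n_het, n_homalt) in one population at one site."""
    H = ds.population_matrix(population, chrom)
    if not 0 <= site_index < H.shape[1]:
        raise IndexError(f"site index {site_index} out of range for {chrom}")
    col = H[:, site_index]
    dosage = col[0::2].astype(np.int16) + col[1::2]
    return (
        int(np.sum(dosage == 0)),
        int(np.sum(dosage == 1)),
        int(np.sum(dosage == 2)),
    )


def genotype_count_matrix(ds: HaplotypeDataset, population: str, chrom: str) -> np.ndarray:
    """Vectorised per-site genotype triples, shape (n_sites, 3)."""
    H = ds.population_matrix(population, chrom)
    dosage = H[0::2].astype(np.int16) + H[1::2]
    out = np.empty((H.shape[1], 3), dtype=np.int64)
    for g in range(3):
        out[:, g] = np.sum(dosage == g, axis=0)
    return out
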