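"""Two-population Wright-Fisher simulator with a farm founder bottleneck
and hard selective sweeps.

The generator emulates a domestication design: a wild population at
mutation-drift equilibrium, from which a farm line is founded through a
bottleneck and then evolved under genic selection at one or more sweep
loci while the wild population continues neutrally. The equilibrium
ancestral sample is produced by a coalescent simulation (msprime) — the
standard way to initialise a forward model at stationarity without a
long burn-in — after which the split, drift, recombination, new
mutation, and selection phases are explicit forward Wright-Fisher
generations implemented here.

Selection is genic on the beneficial allele: genotype fitnesses
1, 1+s/2, 1+s. Each sweep allele is injected as a new mutation on a
single founder haplotype at the requested position, so sweeps are hard;
replicates in which the allele is lost are restarted (conditioning on
establishment), up to ``max_restarts``.

Mutations follow an infinite-sites approximation on integer bp
positions (collisions redrawn); recombination is Poisson crossovers per
meiosis; mating is random with selfing allowed. The emitted dataset is
phased, complete, and restricted to sites segregating in the combined
sampled panel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .dataio import HaplotypeDataset

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_two_pop", "emit_fixture_bundle"]

#: Default per-bp per-generation rates. The simulation is a scaled-down
#: stand-in for a large marine fish population: with Ne reduced to
#: desk scale, per-generation rates are scaled up so the population-scaled
#: parameters stay realistic (theta = 4*Ne*mu = 2e-4 per bp gives ~0.9
#: SNP/kb in a 20-diploid panel, ~40 SNPs per 50 kb bin; rho = theta
#: keeps the mu/r ratio ~1 of vertebrate genomes, so LD blocks and sweep
#: footprints are sub-megabase rather than chromosome-wide).
DEFAULT_MU = 2.5e-7
DEFAULT_RECOMB = 2.5e-7


@dataclass
class SimulationConfig:
    """Study-design parameters of the two-population sweep simulation."""

    seed: int
    n_wild: int = 10
    n_farm: int = 10
    genome: list[tuple[str, int]] = field(default_factory=lambda: [("chr1", 5_000_000)])
    mutation_rate: float = DEFAULT_MU
    recombination_rate: float = DEFAULT_RECOMB
    ancestral_ne: int = 200
    farm_founders: int = 50
    #: census size of the farm line after founding; None means it grows
    #: straight to the ancestral size (the founder event is the
    #: bottleneck, as in a hatchery stocked once and then kept at
    #: capacity). Set equal to farm_founders for a sustained bottleneck.
    farm_size: int | None = None
    generations_farm: int = 50
    #: default sweep sits at the centre of its 50 kb bin
    sweep_loci: list[tuple[str, int, float]] = field(
        default_factory=lambda: [("chr1", 2_475_000, 0.5)]
    )
    max_restarts: int = 20

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        for rate in (self.mutation_rate, self.recombination_rate):
            if rate < 0:
                raise ValueError("rates must be nonnegative")
        lengths = dict(self.genome)
        for chrom, pos, s in self.sweep_loci:
            if chrom not in lengths or not 1 <= pos <= lengths[chrom]:
                raise ValueError(f"sweep locus {chrom}:{pos} outside the genome")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated replicate (recomputable from the data)."""

    sweep_loci: pd.DataFrame  # chrom, pos, s, farm_freq, wild_freq, bin_start
    pi_windows: pd.DataFrame | None = None  # realized per-window pi, filled by caller


class _ForwardPop:
    """One forward-time population: haplotype matrix + sorted positions."""

    def __init__(self, haps: np.ndarray, positions: np.ndarray, rng: np.random.Generator):
        self.haps = np.ascontiguousarray(haps, dtype=np.uint8)
        self.positions = positions.astype(np.int64)
        self.rng = rng

    @property
    def n_diploid(self) -> int:
        return self.haps.shape[0] // 2

    def allele_freq(self, pos: int) -> float:
        j = np.searchsorted(self.positions, pos)
        if j >= len(self.positions) or self.positions[j] != pos:
            return 0.0
        return float(self.haps[:, j].mean())

    def add_site(self, pos: int, carrier_hap: int) -> None:
        j = int(np.searchsorted(self.positions, pos))
        col = np.zeros((self.haps.shape[0], 1), dtype=np.uint8)
        col[carrier_hap] = 1
        self.haps = np.hstack([self.haps[:, :j], col, self.haps[:, j:]])
        self.positions = np.insert(self.positions, j, pos)

    def _fitness(self, sel_sites: list[tuple[int, float]]) -> np.ndarray:
        w = np.ones(self.n_diploid)
        for j, s in sel_sites:
            dosage = self.haps[0::2, j].astype(np.float64) + self.haps[1::2, j]
            w *= 1.0 + dosage * (s / 2.0)
        return w

    def next_generation(self, length: int, mu: float, recomb: float,
                        sel_sites: list[tuple[int, float]],
                        n_children: int | None = None) -> None:
        rng = self.rng
        n_par = self.n_diploid
        n = n_par if n_children is None else n_children
        w = self._fitness(sel_sites) if sel_sites else None
        prob = None if w is None else w / w.sum()
        parents = rng.choice(n_par, size=(n, 2), p=prob)  # selfing allowed
        children = np.empty((2 * n, self.haps.shape[1]), dtype=self.haps.dtype)
        exp_xo = recomb * length
        for i in range(n):
            for g in range(2):
                p = parents[i, g]
                hap_a = self.haps[2 * p]
                hap_b = self.haps[2 * p + 1]
                k = rng.poisson(exp_xo)
                start = rng.integers(2)
                if k == 0:
                    gamete = hap_a if start == 0 else hap_b
                    children[2 * i + g] = gamete
                else:
                    breaks = np.sort(rng.integers(1, length + 1, size=k))
                    seg = (np.searchsorted(breaks, self.positions, side="left") + start) % 2
                    children[2 * i + g] = np.where(seg == 0, hap_a, hap_b)
        self.haps = children
        # new mutations: infinite sites over integer bp
        n_mut = rng.poisson(2 * n * mu * length)
        if n_mut:
            existing = set(self.positions.tolist())
            new_pos = []
            while len(new_pos) < n_mut:
                cand = int(rng.integers(1, length + 1))
                if cand not in existing:
                    existing.add(cand)
                    new_pos.append(cand)
            carriers = rng.integers(0, 2 * n, size=n_mut)
            new_cols = np.zeros((2 * n, n_mut), dtype=np.uint8)
            new_cols[carriers, np.arange(n_mut)] = 1
            all_pos = np.concatenate([self.positions, np.asarray(new_pos, dtype=np.int64)])
            order = np.argsort(all_pos, kind="stable")
            self.positions = all_pos[order]
            self.haps = np.hstack([self.haps, new_cols])[:, order]
        # prune lost sites (all-zero columns); fixed sites are kept, they
        # can still be polymorphic against the other population
        if self.haps.shape[1]:
            keep = self.haps.sum(axis=0) > 0
            if not keep.all():
                self.haps = np.ascontiguousarray(self.haps[:, keep])
                self.positions = self.positions[keep]


def _init_ancestral(chrom_len: int, cfg: SimulationConfig, seed: int):
    """Equilibrium ancestral haplotypes for the whole population (2*Ne)."""
    ts = msprime.sim_ancestry(
        samples=cfg.ancestral_ne,
        population_size=cfg.ancestral_ne,
        sequence_length=chrom_len,
        recombination_rate=cfg.recombination_rate,
        random_seed=seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=cfg.mutation_rate,
        random_seed=seed + 1,
        model=msprime.BinaryMutationModel(),
    )
    positions = []
    rows = []
    for var in ts.variants():
        if len(var.alleles) != 2:
            continue
        positions.append(int(var.site.position) + 1)  # 1-based bp
        rows.append(var.genotypes.astype(np.uint8))
    if not positions:
        return np.empty((2 * cfg.ancestral_ne, 0), np.uint8), np.empty(0, np.int64)
    pos = np.asarray(positions, dtype=np.int64)
    haps = np.vstack(rows).T
    # discrete positions: drop duplicates from flooring
    keep = np.concatenate([[True], np.diff(pos) > 0])
    return np.ascontiguousarray(haps[:, keep]), pos[keep]


def simulate_two_pop(config: SimulationConfig) -> tuple[HaplotypeDataset, SimulationTruth]:
    """Simulate the wild/farm pair and return the phased sampled panel.

    Raises RuntimeError when a sweep allele is lost in every restart
    (advise a larger selection coefficient or more restarts).
    """
    ss = np.random.SeedSequence(config.seed)
    chrom_seeds = ss.spawn(len(config.genome))
    sample_ids = [f"w{i+1}" for i in range(config.n_wild)] + [
        f"f{i+1}" for i in range(config.n_farm)
    ]
    pop_of = {s: ("wild" if s.startswith("w") else "farm") for s in sample_ids}

    chrom_names, positions, refs, alts, hapd, lengths = [], {}, {}, {}, {}, {}
    truth_rows = []
    for (chrom, length), cseed in zip(config.genome, chrom_seeds):
        ms_seed = int(cseed.generate_state(1)[0] % (2**31 - 2)) + 1
        anc_haps, anc_pos = _init_ancestral(length, config, ms_seed)
        sweeps_here = [(p, s) for c, p, s in config.sweep_loci if c == chrom]
        rng_wild = np.random.Generator(np.random.PCG64(cseed.spawn(1)[0]))

        wild = _ForwardPop(anc_haps, anc_pos, rng_wild)
        # forward-evolve the wild population neutrally
        for _ in range(config.generations_farm):
            wild.next_generation(length, config.mutation_rate, config.recombination_rate, [])

        # farm: founder bottleneck + selection, restart on sweep loss
        farm = None
        for attempt in range(config.max_restarts + 1):
            sub = cseed.spawn(1)[0]
            rng_farm = np.random.Generator(np.random.PCG64(sub))
            founders = rng_farm.choice(
                config.ancestral_ne, size=config.farm_founders, replace=False
            )
            rows = np.ravel(np.column_stack([2 * founders, 2 * founders + 1]))
            farm_try = _ForwardPop(anc_haps[rows].copy(), anc_pos.copy(), rng_farm)
            sel_positions = []
            for pos_sweep, s in sweeps_here:
                p_adj = int(pos_sweep)
                while np.searchsorted(farm_try.positions, p_adj) < len(farm_try.positions) and \
                        farm_try.positions[np.searchsorted(farm_try.positions, p_adj)] == p_adj:
                    p_adj += 1  # infinite sites: nudge off an existing site
                carrier = int(rng_farm.integers(0, 2 * config.farm_founders))
                farm_try.add_site(p_adj, carrier)
                sel_positions.append((p_adj, s))
            farm_size = config.farm_size or config.ancestral_ne
            ok = True
            for gen in range(config.generations_farm):
                sel_sites = [
                    (int(np.searchsorted(farm_try.positions, p)), s) for p, s in sel_positions
                ]
                farm_try.next_generation(
                    length,
                    config.mutation_rate,
                    config.recombination_rate,
                    sel_sites,
                    n_children=farm_size if gen == 0 else None,
                )
                if any(farm_try.allele_freq(p) == 0.0 for p, _ in sel_positions):
                    ok = False
                    break
            if ok:
                farm = farm_try
                break
        if farm is None:
            raise RuntimeError(
                f"sweep allele lost in all {config.max_restarts + 1} attempts on {chrom}; "
                "increase the selection coefficient or max_restarts"
            )

        # sample panels; with no forward evolution both populations are
        # copies of the ancestral pool, so keep the two panels disjoint
        # (a random split of one pool into two samples)
        fidx = farm.rng.choice(farm.n_diploid, size=config.n_farm, replace=False)
        if config.generations_farm == 0:
            pool = np.setdiff1d(np.arange(wild.n_diploid), founders[fidx])
            widx = wild.rng.choice(pool, size=config.n_wild, replace=False)
        else:
            widx = wild.rng.choice(wild.n_diploid, size=config.n_wild, replace=False)
        wrows = np.ravel(np.column_stack([2 * widx, 2 * widx + 1]))
        frows = np.ravel(np.column_stack([2 * fidx, 2 * fidx + 1]))
        wh, wp = wild.haps[wrows], wild.positions
        fh, fp = farm.haps[frows], farm.positions

        # union of site lists, zero-filled where a population lacks the site
        union = np.union1d(wp, fp)
        H = np.zeros((2 * (config.n_wild + config.n_farm), len(union)), dtype=np.uint8)
        H[: 2 * config.n_wild][:, np.searchsorted(union, wp)] = wh
        H[2 * config.n_wild :][:, np.searchsorted(union, fp)] = fh
        # keep sites segregating in the combined sample
        tot = H.sum(axis=0)
        seg = (tot > 0) & (tot < H.shape[0])
        # always keep sweep sites so truth stays addressable even if fixed
        sweep_pos_arr = np.asarray([p for p, _ in sel_positions], dtype=np.int64)
        if len(sweep_pos_arr):
            seg |= np.isin(union, sweep_pos_arr)
        H = H[:, seg]
        union = union[seg]

        chrom_names.append(chrom)
        positions[chrom] = union
        refs[chrom] = np.full(len(union), "A")
        alts[chrom] = np.full(len(union), "C")
        hapd[chrom] = H
        lengths[chrom] = length

        for (p_adj, s), (pos_orig, _) in zip(sel_positions, sweeps_here):
            j = int(np.searchsorted(union, p_adj))
            at = j < len(union) and union[j] == p_adj
            farm_freq = float(H[2 * config.n_wild :, j].mean()) if at else 0.0
            wild_freq = float(H[: 2 * config.n_wild, j].mean()) if at else 0.0
            truth_rows.append(
                {
                    "chrom": chrom,
                    "pos": p_adj,
                    "requested_pos": pos_orig,
                    "s": s,
                    "farm_freq": farm_freq,
                    "wild_freq": wild_freq,
                    "bin_start": int(1 + ((p_adj - 1) // 50_000) * 50_000),
                }
            )

    ds = HaplotypeDataset(
        sample_ids=sample_ids,
        population_of_sample=pop_of,
        chrom_names=chrom_names,
        positions=positions,
        ref_alleles=refs,
        alt_alleles=alts,
        haplotypes=hapd,
        chrom_lengths=lengths,
    )
    truth = SimulationTruth(
        sweep_loci=pd.DataFrame(
            truth_rows,
            columns=["chrom", "pos", "requested_pos", "s", "farm_freq", "wild_freq", "bin_start"],
        )
    )
    return ds, truth


def emit_fixture_bundle(config: SimulationConfig, outdir, n_genes: int = 40,
                        gene_length: int = 3_000) -> dict[str, str]:
    """Simulate and write a complete input bundle for the pipeline.

    Writes ``sim.vcf`` (phased panel), ``panel.tsv`` (wild/farm labels),
    ``genes.bed`` (uniformly placed genes, one forced to overlap each
    sweep locus), ``truth.tsv`` and ``truth_pi.tsv``. Returns the paths.
    """
    from .dataio import PopulationPanel, write_phased_vcf
    from .diversity import windowed_pi

    os.makedirs(outdir, exist_ok=True)
    ds, truth = simulate_two_pop(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9_173]))

    paths = {
        "vcf": os.path.join(outdir, "sim.vcf"),
        "panel": os.path.join(outdir, "panel.tsv"),
        "genes": os.path.join(outdir, "genes.bed"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "truth_pi": os.path.join(outdir, "truth_pi.tsv"),
    }
    write_phased_vcf(ds, paths["vcf"])
    with open(paths["panel"], "w") as fh:
        for s in ds.sample_ids:
            fh.write(f"{s}\t{ds.population_of_sample[s]}\n")

    with open(paths["genes"], "w") as fh:
        gid = 0
        for chrom, length in config.genome:
            sweep_pos = [p for c, p, _ in config.sweep_loci if c == chrom]
            n_uniform = max(n_genes - len(sweep_pos), 0)
            starts0 = np.sort(rng.integers(0, max(length - gene_length, 1), size=n_uniform))
            for p in sweep_pos:  # one gene forced over each sweep locus
                s0 = max(p - gene_length // 2, 0)
                starts0 = np.append(starts0, s0)
            for s0 in np.sort(starts0):
                gid += 1
                fh.write(f"{chrom}\t{int(s0)}\t{int(s0) + gene_length}\tgene{gid:04d}\t1.0\t+\n")

    panel = PopulationPanel(
        populations={
            "wild": [s for s in ds.sample_ids if ds.population_of_sample[s] == "wild"],
            "farm": [s for s in ds.sample_ids if ds.population_of_sample[s] == "farm"],
        },
        reference="wild",
    )
    truth.pi_windows = windowed_pi(ds, panel)
    truth.sweep_loci.to_csv(paths["truth"], sep="\t", index=False)
    truth.pi_windows.to_csv(paths["truth_pi"], sep="\t", index=False)
    return paths
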