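# Methods

## The scan

The pipeline detects recent positive selection in a test ("farm")
population relative to a reference ("wild") population from phased,
complete, biallelic SNP genotypes. It combines two statistics with
complementary failure modes and keeps only regions extreme in both.

**EHH and XP-EHH.** For a core SNP, EHH(x) is the probability that two
haplotypes drawn at random from a sample are identical at every SNP in
the tract from the core out to physical distance x. The
cross-population statistic uses whole-sample EHH (no partition of the
sample into allele classes): in each population EHH is integrated over
distance by the trapezoid rule in both directions, giving iES, and the
per-site score is ln(iES_test / iES_ref). Both integrals share one
support — extension stops where the EHH of the *pooled*
two-population sample falls below a cutoff (default 0.05), where an
inter-SNP gap exceeds `max_gap` (default 200 kb), or at the chromosome
end — so the ratio cannot be driven by unequal truncation. Two tract
conventions exist in the literature and both are implemented: the scan
default includes the core SNP in the identity tract (the curve starts
at the core's haplotype homozygosity; a fixed difference then splits
the wild sample at the core while a swept farm sample stays intact,
which is a large part of the statistic's power), while the decay-curve
API `ehh_at_core` defaults to the core-exclusive convention with
EHH(0) = 1. Sites where either population's iES is at the floor (1
bp·EHH) are unscoreable and dropped with a log entry, avoiding
infinite log-ratios.

**Windowed diversity and the ratio.** Per-site diversity uses the
unbiased pairwise estimator π_site = c₀c₁ / C(n,2); window π sums the
site values over non-overlapping 50 kb windows anchored at position 1
and divides by the full nominal window length (the per-bp convention
of windowed-diversity tools; the trailing partial window keeps the
full-length denominator, a conservative choice). The relative
diversity of a window is π_ref / π_test; windows with π_test = 0 have
no finite ratio, are flagged undefined and are excluded from ranking
rather than assigned an infinite value (rank-based p-values need
finite ranks; exclusions are logged).

**Bins, empirical p, candidates.** Each chromosome is tiled with
half-open 50 kb bins (ceiling division; short scaffolds are binned
like any chromosome — no length filter). A bin's XP-EHH representative
is the maximum raw score over its SNPs; representatives are
z-normalised across bins. The empirical p of a bin is the
≥-counting rank fraction p_i = #{v_j ≥ v_i}/N, so ties share the
larger, conservative p and p ∈ [1/N, 1]. Significance is the rank
threshold p ≤ α (α = 0.05): with distinct values exactly ⌊αN⌋ bins are
significant per statistic, which is the intended operating point of an
empirical-rank scan; because the p-values sit on a lattice of step
1/N, a strict inequality would silently drop the ⌊αN⌋-th bin. A bin
must be rankable in both statistics, and significant in both, to be a
candidate; the candidate fraction is therefore bounded by α. No
multiple-testing correction is applied — the procedure is an outlier
scan, not a formal test.

**Gene assignment.** Genes are 1-based inclusive intervals (BED input
converted exactly from 0-based half-open; GFF3 `gene` records used
directly; duplicate ids rejected). Candidate bins report all
overlapping genes, or the nearest gene by edge distance when none
overlaps (both on an exact tie). An optional annotation-coverage
filter (default ≥ 0.70, from BED column 5 or a GFF3
`annotation_coverage` attribute) applies to the export list intended
for enrichment tools; at threshold 0 it reproduces the unfiltered
mapping.

**Genotype differentiation.** At each SNP polymorphic in the combined
sample, genotype triples are oriented by the reference population's
major allele (ties keep REF orientation) so "homref" means homozygous
wild-major, then collapsed per model: dominant (carriers vs
non-carriers), recessive (homalt vs rest), allelic (allele counts —
rows on the 2× allele scale), codominant and trend (the raw 2×3
triple). Fisher's exact test (two-sided, sum of fixed-margin tables
with point probability ≤ observed) covers the 2×2 models; Pearson
chi-square without continuity correction covers the codominant model,
dropping empty genotype columns with df reduced accordingly; the
Cochran–Armitage trend statistic with dose weights (0,1,2) — invariant
under affine reweighting, p = 1 at zero trend variance — covers the
trend model. The per-locus minimum p across models is deliberately
uncorrected ("significant under at least one model"), which is
anti-conservative by construction and documented as such. A locus is
*differentiating* when min p < α and it lies within a gene body ± 5 kb
(boundary inclusive: 5,000 bp away counts, 5,001 does not). Sites
monomorphic in both populations are skipped — every model's p would
be 1 — which changes no result. Fisher/chi-square p-values are
memoised by table, which makes the scan fast at small sample sizes
where few distinct tables occur.

## The simulator

The generator emulates the study design the scan targets: one wild
population at mutation–drift equilibrium and a farm line founded from
it through a bottleneck and then selected.

- **Initialisation** is a coalescent simulation (msprime) of the whole
  ancestral population (2·Ne haplotypes) with binary mutations on a
  discrete genome — the standard way to start a forward model at
  stationarity without a long burn-in.
- **Forward phase** (this package's own Wright–Fisher code): the wild
  population continues neutrally at size Ne for `generations_farm`
  generations. The farm line is founded by `farm_founders` diploids
  drawn without replacement (the bottleneck is the founding event) and
  then kept at `farm_size` (default: the ancestral Ne, matching a
  hatchery stocked once and held at capacity; set
  `farm_size = farm_founders` for a sustained bottleneck). Each
  generation: fitness-weighted random mating with selfing allowed,
  Poisson crossovers per meiosis, and new mutations on an
  infinite-sites approximation over integer bp (collisions redrawn;
  lost sites pruned, fixed sites kept — they may still differ from the
  other population).
- **Sweeps** are hard: each selected allele is injected as a single
  new mutation on one founder haplotype at the requested position
  (nudged off any existing site) with genic fitness 1, 1+s/2, 1+s.
  Replicates that lose the allele are restarted with fresh founders
  (conditioning on establishment by restart); exhausting
  `max_restarts` raises an error advising a larger s.
- **Output**: `n_wild` + `n_farm` diploids sampled from the final
  generations, restricted to sites segregating in the combined panel
  (sweep sites always kept so the truth stays addressable), as a
  phased complete dataset plus a truth table (realised allele
  frequencies, sweep bin ids, per-window π).

### Default parameters

| parameter | default | rationale |
|---|---|---|
| ancestral Ne | 200 diploids | desk-scale stand-in for a large marine population |
| μ (per bp/gen) | 2.5e-7 | θ = 4Neμ = 2e-4/bp → ≈ 0.9 SNP/kb in a 20-diploid panel (≈ 40 SNPs per 50 kb bin) |
| r (per bp/gen) | 2.5e-7 | μ/r ≈ 1 as in vertebrate genomes; ρ per 50 kb bin ≈ 10, so bins are quasi-independent and sweep footprints are sub-megabase |
| genome | one 5 Mb chromosome | 100 bins — enough for rank-based p at α = 0.05 |
| farm founders / size | 50 / 200 | founding-event bottleneck, then capacity |
| generations since founding | 50 | decades of breeding at a few years per generation |
| s at sweep loci | 0.5 | strong artificial selection; fixes from one copy in ≈ 40 generations conditional on establishment |
| samples | 10 + 10 diploids | the resequencing panel size per population |

The scaled-down design keeps the population-scaled compound parameters
(θ, ρ) in a realistic regime rather than the per-generation rates
themselves. Consequences worth knowing: genetic drift over 50
generations at Ne = 200 is far stronger than in any real wild
population, so neutral bins show bottleneck-like diversity loss and
haplotype sharing that real data of this design would not; and new
mutations accumulated during the 50 generations re-diversify the swept
haplotype noticeably (the post-sweep diversity floor is ≈ T/2Ne of the
equilibrium level). Passing tests therefore demonstrate that the
statistics rank a true sweep above this *harsher-than-real* drift
background at toy scale; they do not calibrate absolute power or
false-discovery rates for any real genome. The generator also omits
migration, population growth, polygenic/truncation selection, variable
recombination and mutation rate along the genome, and genotyping
error (inputs are phased and complete by contract).

## Numerical and design choices

- Coordinates are 1-based (VCF convention) throughout; bins are
  half-open `[start, start + 50000)`; BED output converts back to
  0-based.
- Haplotype rows follow VCF sample order, two rows per sample
  (left-of-bar, right-of-bar).
- Multi-allelic and non-SNP records are dropped, not split; missing or
  unphased genotypes are hard errors (the upstream contract is
  imputed, phased data), with an explicit opt-in `fill_major` escape
  hatch that fills with the population-major allele and logs counts.
- EHH extension records the first point below the cutoff and then
  stops, so the integral keeps the tail trapezoid.
- z-normalisation uses the population SD; a zero-SD score set is an
  error rather than silent zeros.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning (msprime seeds derived the same
  way, kept below 2³¹), so identical seeds give bit-identical datasets
  and byte-identical pipeline reports.
- Test problem sizes: oracle equivalence checks run on hundreds of
  small random instances (≤ 8 haplotypes × 12 sites for EHH, table
  totals ≤ 40 for Fisher); calibration and recovery checks use 5 Mb
  replicates at the default conditions (20 replicates for sweep
  recovery, one neutral split of ≥ 2,000 loci for type-I error); the
  acceptance script uses 10 sweep replicates plus one neutral split.

## Known limitations

- XP-EHH bins overlapping a sweep's flanks compete with the core bin
  in the genome-wide ranking; with only 100 bins the core bin's
  empirical p can be diluted by its own footprint.
- The exact conditional tests (Fisher) are conservative at 10+10
  diploids — attained size ≈ 0.01–0.04 at nominal 0.05 — as is
  Cochran–Armitage at low counts; type-I error is controlled from
  above, not matched exactly.
- The per-bin maximum is a noisy representative (an extreme-value
  statistic); it is kept because it is the scan's defined operating
  point.
- `population_overlap` treats bin keys as opaque; callers are
  responsible for comparing scans made on the same bin grid (the CLI
  checks this).
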