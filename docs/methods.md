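# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `sweepscan`. It is the place to look when a default
seems arbitrary or a boundary case behaves surprisingly.

## Scope and coordinates

The pipeline consumes a joint multi-sample VCF for two populations (or
simulates one), applies site-level filtration, computes descriptive
statistics, scans for differentiation in sliding windows, calls and merges
candidate regions, tests their overlap with QTL annotations by
permutation, and validates genotypes against an array call set. Upstream
read processing (trimming, alignment, duplicate removal, variant calling)
and downstream functional annotation are out of scope: the VCF is the
interface.

All in-memory coordinates are 1-based inclusive, matching the
`chr:10,001–350,000` convention of region reporting in this literature.
BED on disk is standard 0-based half-open; `genomic_io` is the single
conversion point (disk start+1 on read, start−1 on write). Multi-allelic
VCF records are skipped, not decomposed — the scan treats markers as
biallelic, and decomposition would manufacture data. Half-calls, haploid
genotypes and phase are all normalised: anything that is not a diploid
0/0, 0/1 or 1/1 call becomes missing, and phased separators are read as
unphased.

## The Weir–Cockerham estimator

Per site, the two-level (population/individual) variance components for
diploids are computed from per-population non-missing counts `n_i`, sample
alternate-allele frequencies `p_i`, and observed heterozygote proportions
`h_i` (formulas in the README and in `fst_scan`'s module docstring).
Choices that matter:

* **No clamping.** `a` (and hence per-site and per-window Fst) may be
  negative and is reported as-is. The ratio-of-sums aggregation already
  stabilises windows; truncating at zero would bias the genome-wide mean
  upward.
* **Weighted vs mean window Fst.** The window statistic is
  `Σa / Σ(a+b+c)` over its sites; the mean of per-site ratios is also
  reported but is noisier and not used for thresholds.
* **Skip rule.** Sites with fewer than 2 non-missing diploids in either
  population are skipped (with `n̄ − 1` and `n_c` degenerating below
  that); counts are logged.
* **Monomorphic sites.** Sites monomorphic in the pooled sample give
  `a = b = c = 0` identically and are excluded from window marker counts —
  they carry no differentiation information.
* **Null behaviour.** For two samples with *identical observed*
  frequencies and exact-HWE heterozygosity the plug-in per-site value is
  `−1/(2(n−1))` (e.g. `−1/26` at n = 14), which the tests verify exactly.
  Over *random* splits of one population the estimator is unbiased for
  zero — the plug-in value is not the sampling expectation, and the
  property tests distinguish the two.

## Windows, thresholds, regions

Windows are 20 kb with a 10 kb step (defaults; both configurable),
anchored at position 1 on every chromosome regardless of where the first
variant falls, so region boundaries land on the familiar 10 kb + 1 grid.
An interior site belongs to exactly two windows; terminal windows are
truncated at the chromosome end. Windows qualify with ≥ 10 SNPs or
≥ 5 INDELs (the two classes are scanned as separate datasets).

The top-percentile cutoff is the smallest weighted Fst among the top
`ceil((1−level)·N)` qualifying windows, and *all* windows at or above the
cutoff are selected — ties are included so the result cannot depend on
sort order. (A `1e−9` slack inside the `ceil` guards against binary
floating-point artifacts such as `(1−0.99)·100` evaluating just above 1.)
Selected windows that overlap or are book-ended (next start = previous
end + 1) merge into maximal candidate regions.

The SNP–INDEL scan comparison takes windows that qualify in both datasets
and are in the top set of at least one, and reports Pearson r with its
two-sided p from the t transform. With few selected windows the statistic
is fragile; at least three comparable windows are required.

## Filtration

Six rules, thresholds configurable, applied with first-failing-rule
attribution in a fixed order for reproducible reports: (1) QUAL ≥ 40;
(2) aggregate site depth ≥ 5; (3) depth ≤ mean + 3 SD computed dataset-wide
over all called sites (sample SD, N−1); (4) ≥ 1 alternate-supporting read
on each strand; (5) ≥ 3 alternate-supporting reads; (6) SNP clusters
(> 10 SNPs in any 50 bp span — evaluated over every 50-base window, and
all SNPs in an offending span are removed) and INDEL clusters (two INDELs
whose start positions differ by ≤ gap+1, i.e. at most one intervening base
at the default gap of 1; both are removed).

Interpretive choices: "supported by" reads the alternate-allele entries of
the DP4 tuple (reference reads cannot support the variant); the depth
ceiling is dataset-wide rather than per-sample (an aggregate-DP reading;
an explicit ceiling override is available); the INDEL gap is measured
between start positions. Cluster rules act within chromosomes only. A
site failing several rules is counted once, under the first failing rule.
Sites missing a field a rule needs (QUAL, DP, DP4) are removed by that
rule, with a logged count of unknown-field removals.

## The synthetic cohort generator

The generator emulates a joint call on two selected lines:

* **Cohort**: 14 diploid individuals per line (defaults named
  broiler/layer), unrelated, no linkage — each site is independent given
  the local `F`. Genotypes are Binomial(2, p_pop) per individual
  (Hardy–Weinberg within line).
* **Differentiation**: Balding–Nichols. Ancestral frequency from a
  bounded law (default Uniform(0.05, 0.95)); both population frequencies
  are independent Beta draws with mean `p` and variance `F·p(1−p)`. `F`
  is the background value (default 0.28, the genome-wide mean weighted
  Fst typical of strongly diverged meat/egg lines) except inside injected
  sweep intervals, where it takes the sweep value. The model is stated in
  the VCF header metadata.
* **Densities**: defaults 16.84 SNPs/kb and 1.72 INDELs/kb — the
  genome-wide densities of a deep two-line chicken resequencing cohort.
  The default genome (3 Mb over two chromosomes) is deliberately small so
  a full simulation runs in seconds; tests and the acceptance script set
  genome sizes explicitly per analysis.
* **Nuisance fields**: aggregate depth ~ truncated normal (default mean
  313.6 ≈ 28 samples × 11.2×, SD 60) truncated to [8, mean + 2.5 SD];
  QUAL ~ normal(150, 60) truncated at 40; DP4 split binomially between
  strands with both-strand and ≥ 3-alt-read guarantees. The truncations
  are deliberate: every *non-engineered* site is guaranteed to pass the
  default filters, so the engineered-failure labels in the truth table
  are exactly the removal set and filtration can be tested for exactness
  rather than approximately. For the same reason clean INDELs keep ≥ 5 bp
  start spacing and engineered clusters are placed in cleared zones.
* **Engineered failures**: a `fail_fraction` (default 0.01) of sites per
  rule violates exactly one named rule — low QUAL, depth in {3,4}, depth
  at mean + 8–12 SD, single-strand support, two alt reads, an 11-SNP/11 bp
  cluster, or an INDEL pair with exactly one intervening base. Engineered
  sites are forced to carry at least one alternate allele so they are
  emitted and their labels testable.
* **Emission rule**: sites with zero observed alternate alleles are not
  emitted (a joint caller reports only sites with variant evidence), and
  the truth table covers exactly the emitted sites.
* **Substitutions**: transition fraction 0.7 by default (TS/TV ≈ 2.33,
  matching filtered chicken call sets); INDELs are biallelic length
  polymorphisms of 1–6 bp.
* **Tracks**: gene intervals placed uniformly (10/Mb, 5–50 kb); QTL
  intervals (30 by default, 0.1–1 Mb) placed uniformly except for a
  configurable fraction forced to overlap sweeps.

What the generator does *not* emulate — and therefore what passing tests
do not show about real data: linkage disequilibrium and haplotype
structure, within-line relatedness, mapping artifacts with spatially
correlated depth/quality, allele-frequency spectra shaped by demography,
and real INDEL tandem-repeat clustering (the reason real INDEL call sets
lose ~15 % to filtration while the simulator's default engineered fraction
removes ~5 %).

## QTL-overlap permutation test

The observed statistic is the total genomic size (Mb) of the candidate
regions covered by the union of QTL intervals — each region base counted
once even under multiple overlapping QTLs. Each of `n_perm` (default
1000) permutations re-places every region uniformly at random with length
preserved: a chromosome is drawn with probability proportional to its
length among chromosomes that can hold the region, the start uniformly
among valid positions; placed regions may overlap each other. QTLs stay
fixed (they are the reference annotation); a `per_chromosome` switch
restricts re-placement to each region's own chromosome. The p-value is
add-one empirical, `(1 + #{null ≥ observed}) / (1 + n_perm)`, which is
never zero and is exactly reproducible given a seed. Internally coverage
is computed by prefix sums over the merged QTL union with binary search,
so a 1000-permutation test over tens of regions takes milliseconds and
calibration experiments (hundreds of replicates) run in seconds. Under an
independent null the test is slightly conservative (rejection rates of
~2–5 % at α = 0.05 in calibration runs) because the overlap statistic is
discrete for small region sets.

## Concordance metrics

POS-CONC is the set intersection of site keys — `(chrom, pos)` in
position mode, `(chrom, pos, ref, alt)` in allele mode (no strand
reconciliation; allele-aware matching can only shrink the matched set).
GEN-CONC is the subset of matched sites with identical genotype codes,
stratified by the array call's zygosity; the error rate is
`100 − 100·GEN-CONC/POS-CONC`. Genotypes missing on either side are
excluded from numerator and denominator, with a logged count. Array
genotypes are ingested from a simple TSV keyed by site, not from a
platform-native format. In simulation mode the pipeline manufactures the
array by corrupting one sample's genotypes at a known rate (default 2 %),
so the recovered error rate has a ground truth.

## Pipeline and reproducibility

One root seed is split per stage through a fixed `SeedSequence`
derivation, so identical config + seed give byte-identical data artifacts;
the run manifest records a SHA-256 per artifact. Plots (AAF spectra,
Manhattan panels with the two cutoffs, observed-vs-null overlap bars) are
best-effort and never fail a run, and are excluded from hashing. Stage
toggles remove exactly the corresponding artifacts.

## Problem sizes used in tests and acceptance runs

Estimator recovery uses 1 Mb cohorts at 2.5 SNPs/kb (≥ 2000 SNPs) and
F = 0.25 across 20 seeds. Sweep detection and the SNP–INDEL comparison
use a 10 Mb genome at the study densities (16.84 SNPs/kb, 1.72 INDELs/kb),
background F = 0.2 and five 20 kb sweeps at F = 0.8 (1 % of the genome;
20 kb matches the typical merged-region size). These sizes keep the full
suite under a minute of simulation time while leaving every window
comfortably above the marker minima. Permutation calibration runs
100–200 independent replicates of 1000 permutations on a 50 Mb, 5-
chromosome genome with 10 QTLs of 500 kb and 10 regions of 50 kb.

## Known limitations

* Two populations only; no support for more than two levels of structure.
* No haplotype statistics (iHS, XP-EHH) and no per-site significance.
* The window grid anchor (position 1) and the INDEL-gap reading are
  documented interpretations; alternatives (0-anchored grids, end-to-start
  gap measurement) would shift boundaries by one step or one base.
* Whether depth filters should bind on aggregate or per-sample depth is
  genuinely ambiguous in practice; only the aggregate reading is
  implemented (with an override), and per-sample genotype-level filtering
  is out of scope.
* The correlation between SNP and INDEL scans is meaningful only when the
  selected window set has true between-window variance; on landscapes
  where every selected window shares one sweep value the statistic
  degenerates to noise, which is why the acceptance runs use multiple
  short sweeps at realistic marker densities.
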