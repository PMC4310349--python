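# Methods

## ROH model

A run of homozygosity is treated as an *admissible window* of consecutive
map markers. Window `[i, j]` (marker indices on one chromosome) is
admissible when all of the following hold:

1. markers `i` and `j` carry homozygous calls;
2. the window contains at least `min_snps` (default 30) genotyped markers
   — missing calls neither break a run nor count toward this minimum;
3. no two consecutive markers inside it are more than `max_gap_kb`
   (default 500 kb) apart;
4. at most `max_missing` (default 5) calls are missing;
5. density: `(pos[j] − pos[i]) / (j − i + 1) ≤ max_density_kb_per_snp`
   (default 100 kb), counting every map marker in the span;
6. heterozygote allowance: up to `max_het_long` (default 2) heterozygotes
   when the span is at least `long_threshold_mb` (default 4 Mb), at most
   `max_het_short` (default 0) otherwise.

A called segment is a *maximal* admissible window — no admissible window
strictly contains it — and overlapping maximal windows are resolved
greedily, longest first, ties to the smaller start position. Segment
length is `end_bp − start_bp` (last minus first marker position), the
convention under which a region reported as 51,605,639–53,035,752 bp has
length 1.43 Mb. Runs never cross chromosome ends or gaps above the cap.

The length-conditional heterozygote rule is circular on its face (the
allowance depends on the final length, which depends on the allowance).
It is resolved by the window formulation itself: a sub-4-Mb window
containing a heterozygote is simply inadmissible, so short candidate runs
break at heterozygous sites into pieces that are re-tested independently,
while long windows may keep up to two. Requiring homozygous endpoints
keeps maximal windows from absorbing flanking missing or heterozygous
calls, matching the convention that a run extends from its first to its
last homozygous SNP.

### Scanning algorithm and oracle

`call_roh_individual` computes, for each homozygous start `i`, the largest
admissible end `j*(i)` below a monotone two-pointer frontier (the het and
missing caps only tighten as windows grow); a window is maximal exactly
when `j*(i)` exceeds every earlier `j*`, so one left-to-right pass with a
running best suffices. Worst-case cost is quadratic in pathological
inputs but near-linear on realistic data. `oracle_call_roh` transcribes
the criteria over every `(start, end)` pair (quadratic by construction,
refused above 2,000 markers) and serves as the independent reference: the
test suite asserts exact output equality on hundreds of randomized
instances spanning all parameter regimes.

A note on parameter monotonicity: raising `min_snps` empirically never
increased the number of called segments in >1,000 randomized instances,
but *tightening the gap limit can*, legitimately — a run spanning a 400 kb
gap splits into two admissible runs when the limit drops to 300 kb. Gap
monotonicity is therefore not asserted.

## Genomic inbreeding

`F_ROH = Σ_j L_ROH_j / L_total`, with `L_total` the sum over chromosomes
of the marker-covered span (last minus first marker). Tiers restrict the
numerator to segments at least 0.5/1/2/4/8/16 Mb long; under the
expected-IBD-length relation `L = 100/(2g)` cM with 1 Mb ≈ 1 cM these
correspond to roughly 100/50/25/13/6/3 generations to the common ancestor
(`generations_from_length` rounds half-up, which is what maps 4 Mb →
12.5 → 13). Genome scope is autosomal by default; the autosomal + X scope
changes both numerator and denominator. Chromosome-wise values divide by
the chromosome's own covered span, so their coverage-weighted mean equals
the genome-wide value at the same tier.

`G_ii` follows the VanRaden construction `G = ZZ′ / (2 Σ_l p_l(1−p_l))`
with `Z = M − 2p`. The default fixes `p_l = 0.5`, under which `G_ii`
collapses to twice the sample's homozygous fraction — a closed form the
tests verify to machine precision — and is preferable when base-population
frequencies cannot be estimated. Missing genotypes are removed from the
sample's own numerator and denominator (per-sample renormalization),
which keeps `G_ii` unbiased under random missingness; an `observed` mode
estimates frequencies from the data and excludes monomorphic markers.

## Common ROH

A marker's incidence is the number of samples with a called run enclosing
it (inclusive endpoints); `F_L` divides by the cohort size. Islands are
maximal stretches of consecutive markers with incidence ≥ `n_min`,
retained when their bp span strictly exceeds `s_min` (default 0.5 Mb).
Cohort-fraction thresholds use `n_min = floor(fraction × n)` (for a
1,278-sample cohort, 10/20/25/50% give 127/255/319/639). Island counts
are not formally monotone in `n_min` — shrinking the qualifying mask can
split one island into two — but islands at `n_min = k` always nest inside
islands at `k − 1`, which the tests assert.

## Synthetic data: what it emulates, and what it does not

`simulate_map` draws per-chromosome marker positions with inter-marker
gaps uniform on `[s/2, 3s/2]` around a mean spacing `s` (default 10 kb, a
dense-array regime comfortably inside the density and gap criteria).

`simulate_population` draws background genotypes iid per marker:
heterozygous with probability `background_het_rate` (default 0.30, chosen
so a random 30-SNP homozygous run has probability ≈ 2×10⁻⁵ and
false-positive ROH above 0.5 Mb are vanishingly rare), homozygotes split
evenly between the two alleles. Autozygous tracts are *planted* directly
per individual — lengths and expected counts from `segment_spec`, counts
Poisson, placement uniform over chromosomes proportional to covered span,
non-overlapping within an individual — rather than generated by pedigree
or coalescent simulation: the downstream statistics depend only on tract
length and position, and direct planting yields exact deterministic
truth. The default spectrum (1.5/2/4/8/16 Mb targets, ~3.25 segments and
~13.5 Mb expected per individual) puts the planted burden at a few
percent of the simulated genome, the magnitude reported for indicine
cattle cohorts.

Two deliberate constructions make recovery well-posed at marker
resolution:

* **Boundary demarcation.** The three markers nearest each planted
  boundary (outside the tract) are set heterozygous, emulating haplotype
  divergence at the recombination breakpoints that terminate a real IBD
  tract. Without this, a caller would extend runs over homozygous
  background markers beyond the true boundary (geometric overhang, mean
  ≈ 2.3 markers at het rate 0.30); the demarcation is three markers wide
  so a long run cannot absorb it through the two-heterozygote allowance.
* **Marker-snapped truth.** Planted boundaries coincide with marker
  positions, so each planted length matches its target to within one
  inter-marker gap and the recorded truth is exactly what the array can
  observe.

Noise is applied after planting: each genotype flips to a uniformly
chosen *different* state with probability `genotyping_error_rate` (so a
homozygote becomes heterozygous only half the time an error strikes —
the binomial the tests check) and is masked with probability
`missing_rate`. Everything is a pure function of `(config, seed)`.

What the generator does **not** model: linkage disequilibrium and allele
frequency structure, realistic recombination and pedigree ancestry,
selection, array ascertainment bias, or clustered (non-random)
genotyping failures. Passing recovery tests therefore demonstrates that
the detector and estimators are correct *given* tract-like signal in
noise of the assumed form; they do not certify behavior under real LD or
systematic artifacts.

## Numerical and reporting conventions

* Percentages are reported to two decimals (counts-of-samples
  percentages to one); internal values are never rounded.
* Skewness is the adjusted Fisher–Pearson sample estimator
  (`scipy.stats.skew(bias=False)`), undefined (NaN) below 3 samples;
  CV = 100 × sd/mean with the n−1 standard deviation; correlations are
  Pearson's r on pairwise-complete values.
* QC comparisons mirror their verbal definitions: markers are removed
  when quality `< 0.70` or call rate `< 0.98` (quality checked first for
  reporting; removal is order-invariant), samples kept when call rate
  `> 0.90` strictly. No MAF filter exists anywhere in the pipeline,
  deliberately: rare-allele markers carry homozygosity signal.
* Genotype coding is the reference-allele count with reference = the
  lexicographically smaller observed allele (text input) or the smaller
  .bim allele (binary input). Every downstream statistic is invariant to
  this labelling. One format limitation follows: a text .ped marker
  homozygous for the non-reference allele only cannot round-trip (the
  reader has no second allele to observe), so text round-trip identity
  holds for reader-canonical datasets, while the binary round-trip is an
  exact identity for any dataset. Writers emit A/B allele letters.
* Problem sizes in the test suite were chosen at desk scale: oracle
  equivalence runs on 200 random instances of ≤ 300 markers; parameter
  recovery uses a noise-free population of 200 samples × ~30k markers
  over five 60 Mb chromosomes, which exercises every criterion while the
  whole suite completes in seconds.

## Known limitations

* The per-run reading of "no more than 5 missing genotypes" is
  implemented; a marker-level missingness cap across individuals would
  be a different (also defensible) reading.
* Exact concordance with any specific vendor tool's internal scanning
  order is not claimed — only with the stated criteria, via the
  exhaustive oracle.
* The X chromosome is carried through all modules but treated as diploid
  autosome-like (appropriate for all-female cohorts only).
* `observed`-mode G uses within-cohort frequencies, which absorbs part of
  the inbreeding signal; the fixed-0.5 mode is the supported default for
  autozygosity work.
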