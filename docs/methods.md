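# Methods

`burdenrank` ranks genes by the difference in deleterious rare-mutation
load between a case cohort and a control cohort, for Mendelian disease
gene discovery in cohorts with high locus heterogeneity (each true
disease gene explains only a small fraction of cases).

## Variant scores

Variants are assumed pre-filtered (common/benign alleles removed) and
annotated with a PHRED-like scaled deleteriousness score `C` (CADD-style:
larger = more deleterious, unbounded). Scores are normalized to the unit
interval:

    s = 1 - 10^(-C/10),   s in [0, 1)

so `C = 10 -> s = 0.9`, `C = 20 -> s = 0.99`, and `s -> 1` as
`C -> inf`. Systems already ranked on 0..1 (DANN-, REVEL-like) load with
a `pre-normalized` dialect that bypasses the transform. Unscored
variants follow a configurable policy — `drop` (default), `zero`, or
`error`; the default reflects pipelines that test only pre-annotated
variants.

Numerical note: the inverse map `C = -10 log10(1 - s)` is exact to
1e-9 only up to `C ≈ 60`; beyond that, the spacing of double-precision
values of `s` near 1 bounds the attainable round-trip accuracy (about
5e-6 at `C = 100`). Gene scoring is unaffected — scores that large are
all effectively `s ≈ 1`.

## Gene scores under inheritance models

For each gene in each individual, post-collapse variant scores reduce to
one number:

* **AR / XR (recessive)** — sum of the two highest scores; 0 if fewer
  than two variants remain. Range [0, 2]. The biallelic requirement is
  deliberate: an individual carrying a single pathogenic allele of a
  recessive gene is an unaffected carrier, and counting such genes
  creates false positives.
* **AD / XD (dominant)** — the single highest score; 0 if none.
  Range [0, 1].

A homozygous variant is two call records with identical locus and score
(contributing `2s` under recessive models). AR/AD consider autosomes
1–22 only, XR/XD the X chromosome; Y, MT and unplaced contigs are
excluded everywhere. Hemizygous male X genotypes by default still
require two variant records under XR; a `hemizygous_double` flag lets a
single X variant count twice.

Ties (equal scores within a cis group) resolve to the smaller
(chrom, pos, ref, alt) tuple, making every pipeline stage deterministic.

## Cis handling

Recessive scoring is only valid for variants on different chromosome
copies. Two pre-scoring filters approximate phasing:

1. **Coverage concordance** — variants of one individual within 100 bp
   are covered by largely the same reads when in cis, so their
   alt:ref coverage ratios agree. A two-sided Fisher's exact test on the
   2x2 coverage table classifies the pair: `p >= 0.4` → cis, `p < 0.4`
   → trans; pairs farther apart or without coverage are untested. Cis
   relations merge transitively (union–find) and each group keeps only
   its top-scoring member. The 0.4 threshold is intentionally liberal
   toward calling cis (conservative toward false biallelic calls); both
   the window and threshold are tunable (`--window`, `--cis-p`).
2. **Cohort co-occurrence** — at realistic cohort sizes and allele
   frequencies (≤ 0.5%), two rare variants co-occurring in ≥ 2
   unrelated individuals are overwhelmingly likely to be one inherited
   cis haplotype; in each carrier of the full set only the top-scoring
   member is kept. Limitation: a disease genuinely caused by a specific
   variant *combination* is erased by this filter — disable it
   (`--no-cooccurrence`) for allele-complex scenarios.

Explicit `phase_group` labels, when present, take precedence and are
collapsed inside gene scoring itself.

## The composite test

Gene-score distributions are zero-inflated (most individuals score 0).
A single rank test wastes the proportion signal; a proportion test
ignores score magnitude. Each gene is therefore tested with a two-part
statistic. With `N1` cases, `N2` controls, `r = N2/N1`, and `n1`/`n2`
individuals with non-zero scores:

* **Binomial component.** Under the null, `n1 ~ Binomial(n1+n2, 1/(1+r))`.
  The standardized statistic

      Z1 = (n1/(n1+n2) - 1/(1+r)) / sqrt( r / ((1+r)^2 (n1+n2)) )

  gives a one-tailed `p1` from the standard normal upper tail. The
  normal approximation is the primary path; an exact-binomial tail is
  available (`exact_binomial` flag) for very small `n1+n2`. Measured
  worst-case |normal − exact| over `n ∈ [30, 300]` is 0.089, shrinking
  rapidly with `n` and in the tails.
* **Wilcoxon component.** A standardized one-tailed (cases greater)
  rank-sum test restricted to the *non-zero* scores, with tied-rank
  variance adjustment and 0.5 continuity correction; `p2 = 1` when
  either side has no non-zero scores. Restricting to non-zero values
  keeps the two components nearly independent (the proportion signal
  lives entirely in `Z1`); using all scores would double-count it.
* **Fisher combination.** `X = -2(ln p1 + ln p2)` referred to a
  chi-square distribution with 4 degrees of freedom; the survival
  function has the closed form `exp(-X/2)(1 + X/2)`, which is evaluated
  in log space (`log S = -X/2 + log1p(X/2)`) so extremely significant
  genes keep a finite `log_p` after `p` itself underflows (a printed
  "p = 0" is an underflow, not a true zero). `p1, p2` are floored at
  1e-300 before taking logs.

Genes are ranked ascending by `log_p`, ties broken by descending
chi-square, descending `n1`, then gene id. The default significance
cutoff is the genome-wide level `alpha = 0.05 / 18,500 ≈ 2.7e-6`
(Bonferroni over autosomal protein-coding genes); no FDR mode is
provided, and both components are strictly one-tailed (cases higher).

## Cohort simulator

The simulator draws whole-exome rare-variant profiles from a frequency
panel: for each individual, every site is one multinomial draw over
{each alt with its frequency in the individual's population; reference
with the remainder}, emitting at most one alt per site. Frequencies are
applied per individual, not per haplotype (matching the worked 0.2% /
0.5% / 99.3% example this design follows); the consequence is that
background homozygotes are never generated — only spiked variants can
be homozygous. Population admixture draws each individual's population
from a weight map; the `adjusted` (panel-wide) frequency column is the
default.

Default MAF pre-filter: alleles with maximum population frequency
≤ 0.5% (recessive models) or ≤ 0.01% (dominant models) are retained.

**Spike-in.** `round(proportion × N1)` cases are selected uniformly
without replacement. Recessive models insert two draws with replacement
from the pathogenic list (equal draws = homozygote); dominant models
insert one. Controls are never spiked. Spike-in lists are validated to
maximum panel frequency ≤ 0.5%. A `fixed-pair` mode inserts two
specified variants concurrently into each selected case, for
modest-effect allele-complex scenarios (run those with the
co-occurrence filter disabled, since the filter removes exactly that
signature).

**Reproducibility.** Replicate `k` uses a generator seeded by the pair
(master seed, k) through NumPy's `SeedSequence`, so cohorts are bitwise
reproducible per replicate and across platforms.

**Synthetic panel.** A stand-in for a real reference download:
per-gene variant counts ~ Poisson(25) (floored at 1); allele
frequencies ~ Beta(0.5, 500) (mean ≈ 0.001) truncated at 0.005,
emulating a rare-variant site frequency spectrum; PHRED scores a
mixture of a benign bulk (Gamma(2, 2), mean 4) and a 20% deleterious
tail (Uniform(15, 40)); ~2% of sites tri-allelic; genes laid out
round-robin on chromosomes 1–22 in disjoint 100 kb windows. These
defaults are fixed, not tuned. What the panel does **not** emulate:
linkage disequilibrium, site-specific mutation-rate structure,
indels or structural variants, per-haplotype sampling, sequencing error or
genotype uncertainty — so a green simulation test establishes the
statistical behaviour of the test under the stated sampling model, not
robustness to real-data artifacts.

## Evaluation metrics

Per replicate: the target gene's rank, its p-value, and the number of
significant autosomal genes at the cutoff. Per scenario: mean/median
rank, power (fraction of replicates with target `p < alpha`, compared in
log space), and mean significant-gene count. A target gene that was
never scored is ranked G+1 (worst possible) rather than dropped. Rank
uses first-index under the deterministic tie-break, not midranks.

## Design choices on open points

* Unscored variants drop by default (the pipelines emulated test
  pre-annotated variants only); documented, configurable.
* The recessive rule follows "at least two variants → positive score";
  the contradictory alternative ("any variant → 0") would zero every
  gene and is rejected.
* Wilcoxon continuity and tie corrections are applied; the enumeration
  oracle bounds the residual approximation error (≤ 0.1 on ≤ 12
  observations, far smaller at realistic counts).
* Coverage Fisher test is two-sided: ratio concordance is symmetric.
* Only a single cis p-threshold (0.4, tunable) is provided — no
  dual-threshold mode.

## Known limitations

* With very sparse non-zero counts (n1 + n2 ≤ ~5) the normal
  approximations are coarse; the combined test remains conservative to
  mildly anticonservative at extreme tails. The null-calibration checks
  (empirical type-I within the binomial 99% CI at alpha = 0.05 and
  0.005) bound the practical effect at cohort scales.
* No covariate/kinship adjustment: population stratification between
  cohorts inflates the binomial component (the admixture machinery
  exists precisely to study this).
* VCF ingestion is a convenience layer (needs a gene BED); annotation
  and consequence prediction are out of scope.
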