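# Methods

`methdiv` analyses two-group reduced-representation bisulfite sequencing
(RRBS) data at single-cytosine resolution: it filters CpG sites for
coverage and for overlap with population SNPs, tests each site for
differential methylation between the two groups, and asks whether the
resulting differentially methylated cytosines (DMCs) are unusually
arranged — close to SNPs or to an external reference cytosine list,
clustered into runs of adjacent DMCs ("stretches"), or concentrated in
repeat classes — using an empirical resampling null of random control
cytosines (r-Cs).

## Coordinates and formats

Point features (cytosines, SNPs, reference lists) use 1-based positions,
the convention of the 6-column bisulfite coverage format
(chrom, start, end, methylation %, methylated count, unmethylated count).
Interval annotations are stored half-open exactly as they appear on a BED
line; RepeatMasker rows (1-based inclusive) are shifted by one at the
start on input. A 1-based position `p` overlaps an internal interval
`[start, end)` iff `start <= p < end`; the boundary site at `p = end` is
outside. Chromosome names are compared by exact string equality, and a
warning lists chromosomes not shared between inputs.

SNP tables are read from VCF (per-group alternate-allele frequencies in
INFO keys `AF1`/`AF2`, falling back to a shared `AF`) or a 4-column TSV.
A position is kept iff its frequency is strictly above the cutoff
(default 0.10) in at least one group; the alternate-allele reading of
"allele frequency" is used rather than minor-allele frequency.

## Site filtering

Two filters define the tested site set: coverage of at least `min_cov`
reads (default 10) in **every** sample, and removal of cytosines whose
position coincides with a SNP. By default only the cytosine position is
masked; `dyad_mode` additionally masks sites whose dyad guanine (pos+1 on
the forward strand, pos−1 on the reverse, both for unknown strand)
carries a SNP, because a G→A polymorphism also corrupts bisulfite calls
on the opposite strand. The two cytosines of a CpG dyad are kept as
separate sites throughout: merging them would make the 1-bp
next-neighbour distance class unobservable.

## Per-site test

The test is a binomial logistic regression of methylation state on the
group indicator, evaluated on the per-group pooled counts, with the
group coefficient assessed by a 1-df likelihood-ratio test. With no
overdispersion term this LRT is identically the G-test of independence
on the pooled 2×2 table, and that is how it is computed (vectorised):

G = 2 Σ O · ln(O/E),  p = P(χ²₁ ≥ G).

Pooling means per-sample variability beyond binomial sampling is not
modelled; this matches a plain logistic regression on pooled counts and
keeps the statistic exactly testable against a closed-form oracle. A
replicate-aware quasi-binomial variant (per-sample GLM, Pearson-X²
scale) is available via `method="quasibinomial"` for data where
between-replicate overdispersion is a concern; it is markedly slower and
not the default. Sites where one group has zero pooled coverage are
skipped with a logged count (impossible after the all-sample coverage
filter; the guard protects direct API use).

Multiple testing uses Benjamini–Hochberg over exactly the tested sites
(`q`); a site is a DMC iff `q ≤ 0.05`. The signed difference of
count-weighted group methylation fractions (`delta`) records direction.
High-confidence DMCs satisfy |delta| strictly greater than 0.20 and a
nearest-SNP distance strictly greater than 100 bp.

## Resampling null and the subset test

All enrichment questions are answered against `k = 10` control subsets,
each the size of the DMC set, drawn uniformly without replacement from
the tested sites minus the DMCs. Subset `i` uses generator seed
`master_seed + i`, so enlarging `k` never changes earlier subsets;
subsets are independent of each other and may overlap.

A statistic computed on the DMC set is compared with the k subset values
by a two-sided t-type test with `k − 1` degrees of freedom. The
denominator is `s·sqrt(1 + 1/k)` rather than the classic one-sample
`s/sqrt(k)`: the observed DMC statistic is itself a single draw with the
same sampling variance as each subset statistic, so the classic scaling
treats a random quantity as a constant and rejects a true null about
half the time at k = 10. With the prediction-interval scaling the test
holds its nominal level when the DMC set is exchangeable with the
subsets (verified by simulation in the test suite); the naive scaling
remains available via `include_observed_variance=False`. When all subset
values are equal the test degenerates: p = 1 if the observed value
matches them, else p = 0 with a warning.

Proximity enrichment bins nearest-feature distances cumulatively at
2, 10, 100 and 2000 bp ("up to t" is inclusive; sites on chromosomes
with no features are never counted). Stretch enrichment compares the
fraction of sites belonging to a stretch — a maximal run of ≥ 2 sites
with consecutive gaps ≤ 2000 bp, detected within the DMC set (or within
each subset), strands pooled, span reported inclusively as
end − start + 1. Repeat enrichment counts sites overlapping each repeat
class (a site under two classes increments both; nested intervals of one
class count it once) and applies BH across classes, labelling direction
by the sign of observed minus subset mean. Note that BH controls the
false discovery rate, not the family-wise error: with five classes
tested at q < 0.05, about 8% of null analyses are expected to flag some
unenriched class, exactly as the null-calibration tests allow.

## Embryo-stage projection

For a second, shallow multi-stage dataset, replicates are pooled
site-wise within stage, DMC sites with pooled coverage ≥ 5 in every
stage are retained, and per-stage methylation fractions are clustered
hierarchically. The distance is 1 − Pearson correlation over pairwise
complete sites with average linkage (Euclidean and complete linkage are
available); columns constant across sites have undefined correlation and
are dropped with a warning. The tree is serialised in Newick form.

## QC

Global statistics report per-sample and overall mean methylation and the
fraction of sites whose pooled methylation fraction is at least 0.5
("methylated"; the threshold is a documented default, configurable).
PCA operates on per-site-centred methylation fractions without scaling;
the sign of each component is fixed by making the largest-magnitude
sample coordinate positive.

## Synthetic data generator

The generator emulates the statistical regime of a two-breed sperm RRBS
comparison and is the substrate for every end-to-end test. Defaults:

- 9 + 9 samples in groups H and M; 20,000 CpGs on 2 chromosomes of
  10 Mb (a desk-scale stand-in for a genome-wide RRBS site set).
- Coverage per site/sample ~ negative binomial with mean 30 and size 15
  (variance ≈ 90), so the 10X-in-all filter removes a realistic minority
  of sites.
- Baseline methylation ~ mixture of Beta(1,10) (unmethylated mode) and
  Beta(10,1) (methylated mode) with high-mode weight 0.30, clipped to
  [0.02, 0.98]; this reproduces the strongly bimodal site-level
  methylation and a ~30% methylated-site fraction typical of CpG-dense
  RRBS territory.
- 500 planted DMCs with a constant shift delta = 0.40 applied to one
  randomly chosen group per site, direction chosen to avoid clipping.
  Constant shifts (not odds-ratio shifts) keep the truth accounting
  simple.
- 2,000 SNPs; 30% of planted DMCs get a SNP placed within 100 bp
  (coupling); 2% of background SNPs fall exactly on non-planted CpGs to
  exercise masking; 5% carry sub-threshold allele frequencies in both
  groups to exercise the AF filter.
- 12 planted stretches of 8 DMCs with gaps of 10–500 bp; five repeat
  classes with per-class interval counts, lengths and planted-DMC
  density multipliers.

Counts are binomial given coverage and the group mean — there is no
per-sample random effect and no per-sample library-size effect, matching
the pooled test's assumptions. Passing tests therefore demonstrate
correctness of the machinery under binomial sampling, not robustness to
between-replicate overdispersion, bisulfite conversion error, mapping
bias or read-level artefacts, none of which are simulated. Planted roles
are disjoint (a site is a stretch member, a coupled DMC, or a plain
DMC), and the emitted bundle (coverage tables with covered positions
only, VCF, repeat BED, sample sheet, truth table) is byte-reproducible
from the seed.

Embryo-stage fixtures reuse the same generator with four stage labels of
two replicates each and a low coverage mean to exercise the 5X-in-all
path.

## Evaluation conventions

Planted-DMC recovery (sensitivity) is measured among planted sites that
survive the coverage filter: the filter discards sites on coverage
alone, before any testing, so recovery conditional on being tested is
the property of the test itself. The false-discovery proportion is
computed over all called DMCs.

Problem sizes used by the test suite and the acceptance script: 20,000
CpGs × 18 samples per simulation, 10–50 seeds per statistical check, and
one 100,000-CpG × 18-sample end-to-end run; these sizes give stable
statistics while keeping a full run in the minutes range on one core.

## Numerical choices and edge cases

- G-statistic terms with zero observed count contribute 0; negative
  rounding residue is clamped at 0.
- Nearest-distance lookup is a sorted-merge (`searchsorted`); interval
  stabbing uses sorted start/end arrays (#starts ≤ p minus #ends ≤ p).
  Both are verified against quadratic brute force in the tests.
- Empty feature sets give all-zero proximity fractions and a degenerate
  p = 1; an empty repeat annotation gives an empty report; an empty
  query is an error (fractions undefined).
- All randomness flows from explicit seeds; reductions keep C-order
  memory layout so that re-loading intermediate matrices from disk
  reproduces floating-point sums bit-for-bit. Manifests contain no
  timestamps; two runs with the same inputs and seed are byte-identical.

## Known limitations

- The pooled test is anti-conservative when replicates are overdispersed
  relative to binomial; use the quasi-binomial variant in that case.
- Region-level (DMR) calling, covariate adjustment, beta-binomial
  shrinkage, and covariate-matched resampling (e.g. matching subsets by
  coverage or CpG density) are out of scope.
- The stretch statistic measures positional adjacency only, not
  co-methylation coherence within stretches.
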