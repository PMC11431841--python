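# Methods

This note documents the statistical machinery of `capconcord`: what each
stage computes, the conventions chosen where several were defensible, what
the simulator does and does not emulate, and what a passing test therefore
does and does not establish.

## Genotype representation

Genotypes are B-allele counts: 0 = homozygous reference (AA), 1 =
heterozygous (AB), 2 = homozygous alternate (BB). Missing is a distinct
sentinel (−1 internally, `NA` in TSV, `./.` in VCF) and is never conflated
with 0. Coordinates are 1-based throughout (VCF convention); region spans
are closed intervals; BED output converts to 0-based half-open and says so
in its header.

The array's B allele is mapped to the VCF alternate allele. When the two
platforms list the same pair of alleles in opposite ref/alt orientation at
a site, array calls are recoded 0↔2; allele pairs that are neither equal
nor swapped are dropped and counted. **Strand flips are not resolved**:
the simulator emits plus-strand alleles on both platforms, so an A/G vs
T/C ambiguity never arises in the tested world. Real-data use requires
prior strand harmonization; this is a documented limitation.

## Agreement statistics

All statistics use pairwise-complete deletion — a (sample, site) cell
contributes only when both platforms made a call — since no authoritative
missing-data rule exists for this comparison.

- **Concordance** is the fraction of matching calls; mismatches are
  decomposed by |Δ| into one-allele and two-allele differences.
- **R²** is the squared Pearson correlation of the two genotype vectors
  (per sample over sites; per SNP over samples). This is the only reading
  of the usual printed formula that is bounded by [0, 1]; it is undefined
  (NA, excluded from summary means, with the exclusion count reported)
  when fewer than two complete pairs remain or either vector is constant
  (e.g. a monomorphic site).
- **Weighted kappa** uses squared disagreement weights
  d(i,j) = (i−j)²/(K−1)² with K = 3:
  κ = 1 − (observed weighted disagreement)/(expected under marginal
  independence). When the expected disagreement is zero (both raters
  constant and equal) κ = 1 by convention, logged. Kappa is reported per
  sample and pooled over all calls.
- **Flag lists**: sites with concordance < 0.90 and sites with R² < 0.8,
  separately and as a union; undefined-R² sites join neither list and are
  counted separately.

## Trio Mendelian QC

A trio is *informative* at a site when offspring, sire and dam are all
non-missing; the MI rate is inconsistent/informative over informative
trios only (the natural denominator; an all-trios denominator would
conflate missingness with inconsistency). Consistency means the child
genotype is expressible as one transmitted allele per parent; of the 27
genotype combinations, 12 are inconsistent. X/Y sites are excluded from
trio testing (X inheritance follows different rules; duo checks are out of
scope). Sites with MI > 5% are removed; sites with no informative trio are
kept and logged. QC order: duplicate resolution → MI filter → sample
call-rate filter (< 90% dropped).

Duplicate sites (same chrom, pos) keep the copy with the highest call
rate; ties break by a seeded uniform draw, making runs reproducible.

## Capture-depth QC

`depth_snp` is the depth at the targeted base and `depth_ave` the mean
over its ~250 bp capture region. Conventions, stated because flags near
the boundaries depend on them:

- **IQR outliers**: quartiles by linear interpolation (numpy default,
  type 7); flags low/high outside Q1 − 1.5·IQR, Q3 + 1.5·IQR. Note that
  for any continuous depth distribution the fences flag the natural tails
  (~0.7% under a near-normal), not only planted artifacts.
- **Central capture**: central iff depth_snp ≥ depth_ave (equality counts
  as central); depth_ave = 0 is undefined and logged.
- **Site annotation**: pass iff depth_snp ≥ 100 AND QUAL strictly > 20.
  The flag only annotates; it removes nothing.
- **Low-MQ regions**: maximal runs of ≥ `min_run` (default 3) consecutive
  sites with MQ < 50, reported from the first to the last low site. The
  run-length rule formalizes what is otherwise done by eye; `min_run` is
  configurable.
- The **problematic-SNP table** is the union (one row per site, no double
  counting) of: concordance ≤ 0.50, depth outlier (either side), and
  non-central capture, each row carrying its reasons, MI, MAF and depths.

## Genomic relationships, parentage, sex

**GRM**: VanRaden method 1, G = ZZᵀ / 2Σpᵢ(1−pᵢ) with Z = M − 2p.
Frequencies are estimated from the analysed cohort itself; missing calls
are mean-imputed (2pᵢ, i.e. Z entry 0); monomorphic sites are dropped and
counted. No external reference-panel imputation is performed — GRMs here
deliberately describe the observed matrices. GRM correlation is the
Pearson r over the upper triangle including the diagonal; because the
diagonal can inflate r, the off-diagonal-only value is reported alongside.

**Parentage** uses opposing homozygotes: parent and child cannot be 0/2 at
the same autosomal site barring error. The rate is opposing/comparable
over pairwise-complete autosomal sites; candidates below τ = 0.01 are
accepted. Under HWE an unrelated pair opposes at 2p²(1−p)² per site
(≈ 0.08 averaged over the simulated frequency range), a true parent only
via genotyping error (≈ arr_error/3), so the margin at τ = 0.01 is wide.

**Sex**: a sample is male iff at least half of the Y markers yield a call
AND its non-PAR X heterozygosity is below 5%; female iff neither holds;
anything else — including conflicting evidence — is reported ambiguous,
never silently male. The pseudoautosomal region is excluded because it
recombines and is diploid in both sexes.

## Down-sampling and the likelihood caller

Allele depths are thinned binomially: an entry with total depth d > target
keeps each read with probability target/d (ref and alt separately);
entries at or below target are untouched. One-step thinning of an entry is
exactly Binomial(d, target/d). **Caveat**: staged thinning (260→100→30) is
unbiased for the mean but *narrower* than one-step 260→30, because the
second stage's keep probability adapts to the realized intermediate depth;
the two marginals are not identical. Thin once to the final target.

Genotypes are re-called from thinned counts with a minimal biallelic
caller: read likelihoods with alt-read probability e (hom ref), 1/2 (het),
1 − e (hom alt); flat prior over {0,1,2}; call = maximum likelihood;
QUAL = phred-scaled posterior odds of the call, capped at 99; depth below
`min_depth` (default 4) is a no-call; likelihood ties resolve to the
heterozygote. The flat prior keeps the caller platform-neutral. Because
down-sampling errors emerge from read sampling through this caller rather
than an injected rate, the depth–accuracy relationship is mechanistic: the
het miscall probability at fixed depth has a closed form (binomial tail
mass over the non-het decision region) that the tests check by simulation.
The original study thinned raw reads and re-ran production callers; this
desk-scale analogue reproduces the mechanism, not the software stack.

## The simulator

`SimConfig` defaults state the emulated design: 56 samples of which 8
males, ~12.6K independent sites (29 autosomes by length, 2,500 non-PAR X,
66 PAR X, 5 Y), alt-allele frequency ~ Uniform(0.05, 0.5), mean capture
depth 260X with gamma site-to-site variation (shape 25, so the bulk lies
between ~100X and ~500X and the planted ×0.1/×4 outliers actually fall
outside the IQR fences), array error 0.005 and no-call 0.02 (call rate
~0.98), per-read error 0.01. Planted artifact fractions (3.33% low / 0.13%
high depth outliers, 0.22% off-centre) and three mid-chromosome low-MQ
blocks mirror the magnitudes such panels exhibit. The site count is scaled
down from the ~70K of a production panel for desk-scale runtime; every
statistic in scope is per-site or averages over sites, so scale affects
only sampling noise.

Structure: founders are HWE; trio offspring receive one uniformly chosen
allele per parent; sires are drawn from the male pool with replacement
(one sire, many dams — the livestock norm), dams are distinct, offspring
are female, which keeps the configured male count exact. Males are
hemizygous (coded 0/2) on non-PAR X and Y; females are missing on Y and
have zero Y read depth.

Array errors are adjacent-state (0↔1, 2↔1; from 1 to either side
equiprobably): two-allele array errors are rare in practice, and this
exercises the one-/two-allele decomposition asymmetrically. Error events
are thresholded on uniform draws from a seed-derived stream, so
configurations sharing a seed are coupled: lowering the error rate can
only remove error events, which makes error-rate monotonicity properties
testable without Monte-Carlo slack.

Sequencing depth: each site has a capture intensity (gamma); the depth at
the targeted base is 1.05× the region average for centrally captured
sites — coverage peaks at the probe centre — and u·depth_ave,
u ~ Uniform(0.2, 0.9), at planted off-centre sites. The reported
`depth_snp`/`depth_ave` are these *model* intensities (deterministic per
site), while realized per-sample depths are Poisson draws around them and
live in the AD matrix. This choice makes the depth-QC flags deterministic
functions of the stated world — a clean configuration yields a provably
empty problematic table — at the cost of ignoring the estimator noise a
bedcov-style realized mean would carry. The 1.05 central ratio keeps the
mean SNP depth within 5% of the configured mean.

The zero-error configuration (`SimConfig.clean()`) sets both platforms'
error and missingness to zero, removes planted artifacts, and makes the
capture intensity exactly constant (infinite gamma shape); both platforms
then reproduce the truth exactly at saturating depth and every flag list
is provably empty. Constant intensity is required: any continuous depth
distribution feeds the IQR fences its natural tails.

**Not emulated**: linkage disequilibrium (all sites independent — nothing
in scope needs LD; imputation, which would, is out of scope), read-level
artifacts (alignment, index hopping, BAQ), batch effects between male and
female sequencing runs, strand ambiguity, and indel markers. A green test
therefore establishes that the statistics and filters behave correctly on
their stated inputs, not that a production panel will hit any particular
concordance value.

## Determinism

One root seed drives everything; per-module child seeds are derived via
`SeedSequence` and recorded in the run manifest together with effective
thresholds, input checksums and per-stage filter counts. The same config
and seed produce byte-identical report bundles.
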