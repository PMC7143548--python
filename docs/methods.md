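# Methods

## Genotype model and coding

Genotypes are diploid biallelic calls on autosomes, stored as the dosage
of the per-marker minor allele: 0/2 homozygotes, 1 heterozygote, −1
missing. The minor allele is determined from observed counts at load
time, ties broken by lexicographic allele order; a monomorphic marker
codes its single observed allele. The choice cannot affect any result
downstream — detection, incidence and inbreeding consume only the
hom/het/missing distinction — but it makes file round-trips exact and
deterministic. Markers whose chromosome label is not a positive integer
(X, Y, MT, 0, unplaced) are dropped at load with a logged count; marker
order is (chromosome, position) with strictly increasing positions
(duplicates are rejected rather than silently merged). Sample order is
never changed.

Interval lengths are `end − start` bp everywhere (segments, hotspot
regions, chromosome extents). The convention is pinned by tests against
published sheep ROH-island coordinates, which include a single-SNP
region of printed length 0.

## Quality control

Filters and defaults follow standard 50K-array practice:

| filter | default | removed when |
|---|---|---|
| sample call rate | 0.9 | rate ≤ 0.9 |
| marker call rate | 0.95 | rate < 0.95 |
| minor allele frequency | 0.01 | MAF < 0.01 |
| exact HWE p | 1e-6 | p ≤ 1e-6 |

The sample filter runs first (as PLINK orders `--mind` before `--geno`);
marker filters are evaluated on the survivors and each removed marker is
tallied under the first criterion it fails, in the order above. The HWE
test is the exact two-sided conditional test: with n diploids and k
copies of the rarer allele, the probability of h heterozygotes given the
allele counts is proportional to `n!/(hom_maj! h! hom_min!)·2^h`; the
p-value sums the probabilities of all h no more likely than the observed
one. Weights are computed in exact integer arithmetic (a two-step
integer recurrence), so the p-value is correctly rounded at any cohort
size and the boundary p ≤ 1e-6 is unambiguous. No mid-p correction is
applied.

## ROH detection

Per sample and chromosome, a window of `window_snp` = 50 consecutive
markers slides one marker at a time; a window qualifies with ≤1
heterozygous and ≤5 missing calls. Each marker's hit rate is the
fraction of covering windows that qualify; markers with hit rate ≥ 0.05
are run-eligible (the ≥ matches PLINK's "at least" semantics and is
pinned by tests). Maximal stretches of consecutive eligible markers are
split at inter-marker gaps > 1 Mb *before* the segment filters — a gap
above the cap cannot be bridged by definition — and surviving stretches
must carry ≥40 SNPs, span ≥1 Mb, and average ≤100 kb per SNP.
Chromosomes with fewer markers than the window are scanned with a single
all-marker window. Window smoothing means isolated heterozygous or
missing calls can lie inside a reported run; the per-window allowances,
not a per-segment cap, bound them.

The window size and hit threshold are not dictated by the segment
criteria themselves; the PLINK v1.9 defaults are adopted and every value
is a parameter. A second, deliberately naive implementation
(`brute_force_roh`) evaluates the identical contract by direct
enumeration of every window and hit rate; the two are held equal on
hundreds of random fixtures in the test suite. The fast path is
vectorized cumulative-sum bookkeeping; ~10M genotypes scan in seconds.

## Inbreeding coefficients

F<sub>ROH</sub> = L<sub>ROH</sub>/L<sub>AUT</sub> per animal, with
L<sub>AUT</sub> the sum over autosomes of the first-to-last QC-passing
marker span. The span operationalizes "genome covered by the markers"
and makes the denominator self-contained; an extent built from nominal
assembly lengths can be substituted (`AutosomeExtent.from_lengths`) when
a fixed denominator is preferred. Length-category coefficients
(left-closed bins 1–5, 5–10, 10–20, >20 Mb) share the L<sub>AUT</sub>
denominator, so they sum exactly to the total; chromosomal
F<sub>ROHOAR</sub> uses the chromosome's own span. Summary tables follow
survey conventions: per-chromosome coverage is the mean summed ROH
length among animals carrying ROH on that chromosome divided by the
chromosome length; per-category mean and coefficient of variation
(100·sd/mean, sd with one delta degree of freedom) are computed over
animals owning at least one segment in the category, so the effective n
varies by row.

## ROH islands

A marker's incidence is the percentage of animals whose ROH cover it
(closed interval; a sample counts once per marker however its segments
overlap). The hotspot threshold is the nearest-rank top-1% incidence
value; all markers at or above it are selected (ties included — the rule
is deterministic and order-free), and runs of selected markers that are
consecutive in the QC-passing marker sequence merge into regions.
Zero-incidence markers are never selected: when a track is all zeros the
percentile threshold degenerates to 0 and the tie rule would otherwise
select the entire genome, so the degenerate case yields an empty table
instead. Gene counts use closed-interval overlap (an abutting gene
counts); the mean recombination rate is
(cM(stop) − cM(start))/(Mb length) with piecewise-linear interpolation
between genetic-map anchors and constant extrapolation beyond them,
undefined (rendered "/") for zero-length single-marker regions.

## Generation depth (TMRCA)

An autozygous tract of genetic length ℓ cM has expected time to the
common ancestor g = 100/(2ℓ) generations. Segments are classified by
genetic length into left-open/right-closed classes with default
boundaries 10, 5, 2.5, 1.25 cM (labels "<5", "5–10", "10–20", "20–40"
generations, then "unresolved"): the convention of the sheep ROH
literature, configurable because medium-density arrays cannot resolve
tracts much under ~1.25 cM and studies differ in the oldest class they
report.

## Synthetic cohorts

The generator emulates a medium-density (50K) livestock array cohort: 26
autosomes of 100 Mb (≈2.6 Gb, close to the sheep autosomal genome) with
2000 uniform-random, deduplicated marker positions each (~50 kb
spacing), per-marker allele frequencies uniform on [0.05, 0.5], and
background genotypes in Hardy–Weinberg proportions. Autozygosity is
planted directly: per sample, tracts with genetic lengths
Exp(mean 100/(2g)) cM are placed uniformly (rejected on overlap, bounded
retries) until the planted fraction reaches `target_f`; within a tract
the sample is homozygous for a single haplotype drawn from the marker
frequencies. Genotyping error flips homozygous tract calls to
heterozygous at rate ε; missingness masks calls genome-wide at rate μ. A
`hotspot` spec plants one fixed tract into a random carrier fraction of
samples, creating a shared island. The exact tract list and autozygous
fraction per sample are returned as truth. All draws flow from one seed;
equal seeds give byte-identical output files.

Deliberately not simulated: background linkage disequilibrium (markers
are independent given their frequencies) and mutation on planted tracts.
Passing recovery tests therefore demonstrate the pipeline's arithmetic
and the detector's contract, not robustness to LD-induced chance
homozygosity runs — on real data short chance ROH are more common, which
is exactly what the ≥1 Mb/≥40-SNP floor exists to exclude. Recovery is
bounded below truth by design: tracts below the detection floor are
invisible, so mean F_ROH slightly undershoots the planted fraction.

## Known interaction: HWE filtering erodes strong islands

A tract shared by a fraction q of the cohort gives every marker inside
it a heterozygote deficit equivalent to an inbreeding coefficient F ≈ q.
At q = 0.3 and n = 200 the exact HWE test flags a substantial minority
of island markers at p ≤ 1e-6, and the survivors can fall below the
50-SNP window span, making the island undetectable after QC. Real
SNP-array islands are far weaker (incidence under ~10% in Merino-type
cohorts; n·F² ≈ 5, invisible to the filter), so the interaction only
matters for engineered stress-test islands — but it is a real caveat for
any population whose islands approach such carrier fractions, and a
reason some ROH studies relax the HWE filter. Accordingly, the
island-recovery checks in this package run the
detection → incidence → calling chain on the generated genotypes, while
inbreeding recovery runs the full pipeline including QC.

## Numerical and degenerate-input choices

- Exact integer arithmetic for HWE (no floating-point tie ambiguity);
  the conversion to float is the only rounding step.
- Hit-rate comparison ≥, HWE boundary "kept iff p > threshold", sample
  call-rate boundary "kept iff rate > threshold", marker call-rate
  boundary "kept iff rate ≥ threshold": all pinned by tests.
- Empty segment lists, all-missing samples, single-marker chromosomes,
  zero-length regions and all-zero incidence tracks all have defined,
  tested behaviour; QC that removes every sample or marker raises an
  explicit empty-cohort error rather than returning an empty object.
- Problem sizes in the test suite and acceptance script (200 animals ×
  52k markers for recovery; ≤5 × 500-marker fixtures for oracle
  equivalence; ≤30 diploids for the exhaustive HWE sweep) are chosen so
  the full battery reruns in minutes on one core while keeping every
  statistic at the cohort scale the defaults were designed for.
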