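# Methods

This note documents the models, defaults and design choices behind
`livermeth`: what each stage assumes, what the synthetic-data generator
does and does not emulate, and where the design was genuinely open.

## Data model and conventions

The unit of analysis is a single cytosine anchored at the plus-strand C of
a CpG dinucleotide, addressed by its 1-based coordinate. Opposite-strand
records are never merged or split — the simulator emits one record per CpG
and the readers treat each (chrom, pos) as one unit; whether merging
strands is appropriate for a given real dataset is left to the user.
Coverage files use the Bismark coverage dialect (1-based closed
coordinates); BED tracks are 0-based half-open; all conversions are tested
in both directions. When a coverage file's percent column disagrees with
its counts by more than 0.1 points, the counts win (they are the raw
observable) and a warning is logged. Chromosome names are compared as
exact strings.

The methylation matrix keeps counts and an explicit missingness mask
separately: masking never destroys counts, so QC decisions are reversible
and idempotent.

## QC cascade

Order is part of the contract: (1) mask cells with coverage < 10×
(strictly fewer; 10 is retained), (2) score and remove samples, (3) drop
CpGs with strictly more than 20% missing samples, (4) drop CpGs below 10%
methylation in every sample with data (a CpG with no data at all is
dropped with its own log reason). Sample scores are computed on the
post-mask, pre-filter matrix because sample removal is a screen for
unusual missingness patterns, not a downstream analysis. The
sharedness-weighted score (Σ_c w_c·I(covered)) deliberately rewards
covering *shared* CpGs: a shallow sample covering the common panel scores
higher than a deep sample covering private sites. The classic absolute
cutoff (50 000) only makes sense for genome-scale panels, so the default
here is relative — half the maximum attainable score — with the absolute
cutoff available as a config field. Ordination-based outlier removal is
not automated (no quantitative criterion generalizes); the score table is
written for manual inspection.

The CpH screen flags non-CpG cytosines whose methylation exceeds 5% in
every sample of at least one age group. In a well-converted library these
are vanishingly rare and mostly artifacts (e.g. sample-specific CpGs
misclassified against the reference), so they are reported, not used.

## Differential methylation

Per CpG, an equal-variance two-sided Student's *t* on per-sample percent
methylation (Welch behind a flag). A site is testable only when both
groups retain ≥ 2 unmasked values; untestable sites carry NaN p/q and are
excluded from significance. Zero variance in both groups gives p = 1 at
equal means. FDR control is Benjamini–Hochberg by default — deterministic
and assumption-light; Storey's q-value (λ grid 0.05–0.95 step 0.05, cubic
polynomial smoother for π₀, falling back to π₀ = 1 below 100 tests) is
available as `fdr_method="storey"`. Significance requires both q ≤ 0.1 and
|Δ| strictly greater than 5 percentage points; thresholds and the
comparator are configurable. Deltas are percentage points throughout
(5 → 10% methylation is a 5-point change). Magnitude bins split significant
calls at 30 points. No beta-binomial or regression model is fitted: the
test operates on fractions, matching the analysis recipe this package
implements.

Cross-cohort concordance is the fraction of secondary-cohort-significant
sites (restricted to the shared site universe) that are also significant
in the primary cohort.

## Time course

Per-site trajectories are per-age means over unmasked samples. An age with
no data at a site is skipped and the flanking delta bridges the gap (the
deltas always telescope to last-minus-first). Interval change counts use
an inclusive ≥ 30-point bound ("30 or more"), unlike the strict > 5 of the
two-group caller; both comparators are exposed.

Pattern classification defines the *total methylation change* of a
trajectory as its path length — the sum of absolute consecutive deltas,
which equals the net change for monotone trajectories. A changing
trajectory (|net| > 5 points, ≥ 3 observed ages) is *discrete* when the
largest step in the net direction carries at least half of the path (ties
at exactly half are discrete), *continuous* when monotone (zero steps
allowed, since means are noisy) with every step below half, and *other*
otherwise. Using path length rather than |net| in the denominator is the
one place the rule needs interpretation: for oscillating trajectories it
prevents a large but repeatedly reversed step from being called a discrete
switch, and it changes nothing for monotone trajectories. Classification
is exhaustive and mutually exclusive over changing sites, and reversing a
trajectory flips its direction while preserving its class.

## Genomic context and enrichment

Local CpG density counts CpGs whose C lies within ±200 bp of the focal C
(401 bp window, focal included); GC content is computed over the same
window, clipped at contig ends. Promoters are the 1 kb upstream of the
TSS, strand-aware. The exclusive hierarchy subtracts promoters from exons,
then the remaining exons from introns — literally two subtractions, so
intron/promoter overlap can survive; residual overlaps are counted and
logged rather than silently removed. Interval merge/subtract/nearest is
delegated to pyranges; distances are reported as the number of bases
between the site and the nearest interval (0 when overlapping, undefined
when the chromosome has no interval).

Density-matched enrichment draws, per resample, one universe site with
*exactly* the same integer CpG density for every focal site — no binning,
no nearest-match fallback; unmatched densities are an error. Sampling is
without replacement within a resample and the focal sites remain eligible
(both switches exposed). Empirical p-values are raw tail fractions over
1000 resamples (p_enrich = #{count ≥ observed}/n, p_deplete likewise, ties
in both tails, so p_enrich + p_deplete ≥ 1); a +1 add-one variant is
available for zero avoidance. Both tails are always reported since a
one-sided convention cannot be assumed. Groups mirror the biological
stratification: direction × pattern × magnitude bin.

## Analytic models

Hemimethylation dilution: right after replication the nascent strand is
unmethylated, so a cell caught mid-cycle contributes half its molecules
unmethylated; with fraction *f* of cells dividing and locus methylation
*m*, the expected observed decrease is *m·f/2* (5 points at *f* = 0.10,
*m* = 100%). The model assumes fully asynchronous division and at most one
unreplicated-remethylation lag per cell — no cell-cycle-phase or
region-specific remethylation kinetics. Quantification granularity is
100/coverage percent (2.5% at 40×).

The methylation-level histogram uses 1-point bins centred on the percent
grid so coverage-quantised values do not straddle bin edges. The
"uppermost mode" is the count-weighted centre of the dominant
high-methylation peak (bins holding ≥ 50% of the maximum count among bins
above 50% methylation): at 40× coverage adjacent grid values are nearly
equiprobable (e.g. Binomial(40, 0.95) puts ~0.28 on both 95% and 97.5%),
so a raw argmax is unstable while the weighted centre recovers the
dilution gap to within ~1 point.

## Synthetic data generator

The generator emulates the *structure* of an RRBS study of developing
liver, not any particular genome. Defaults are the study conditions:
6–7 ordered age groups (E18.5 … 9 wk), 3–10 replicates per group, ~40×
mean coverage, 79% of CpGs changing with an 89% gain bias, magnitudes
5–88 points with onset mass concentrated after P5, hematopoietic cell
fractions following liver histology (48, 62, 38, 4, 1, 0% from E18.5 to
P20; 9 wk at 0), a dividing-cell fraction declining linearly from 0.10 to
0 (the decline is motivated by the biology but the values are package
defaults — no measured schedule exists), and 0.5% bisulfite
non-conversion.

Pipeline stages, front to back: random genome at GC 0.42 (optionally with
extra planted CCGG motifs); MspI digest cutting after the first C of CCGG
(the enzyme's actual C^CGG behaviour); inclusive 150–600 bp size
selection; a CpG panel of sites within 50 bp of a fragment end
(approximating single-end 50 bp reads from both ends); per-site truth
trajectories (pattern mix defaults to 50% discrete / 30% continuous / 20%
other — the mix itself is a free parameter, chosen as a plausible blend,
not an estimate); baseline methylation bimodal (25% of sites below 8%,
the rest uniform 15–95%) so the never-methylated filter has something to
catch; a linear two-cell-type mixture with an independent constant
hematopoietic methylome; division dilution *m*(1 − *f*/2); read counts
with observed success probability p = m + (1 − m)·ε (non-conversion is the
only error mode — no over-conversion or sequencing error — keeping the
closed-form moment m + (1 − m)·ε testable); coverage negative-binomial
with mean 40 and dispersion 10 (Poisson at dispersion → ∞; the real
coverage distribution's shape is unknown, only means are). Zero-coverage
cells are missing and omitted from the written coverage files. Everything
is a pure function of (config, seed).

What the generator does not emulate: read-level artifacts (alignment
error, PCR duplicates, adapters), spatial correlation of methylation along
the genome, region-specific remethylation kinetics, batch effects between
cohorts. Passing tests therefore demonstrate the pipeline's statistical
behaviour under clean count-level noise, not robustness to upstream
processing artifacts.

Because the hematopoietic methylome is simulated independently of the
hepatocyte lineage, cohorts with the histology-based composition schedule
show composition-driven apparent changes on top of the lineage signal —
deliberately so, since disentangling the two is part of the scientific
question. Analyses that need a clean measurement-error benchmark (e.g.
parameter-recovery checks) use the neutral schedule (no hematopoietic
cells, no division), which isolates counting noise.

## Problem sizes and numerical choices

The shipped analyses and tests run on desk-scale panels (hundreds to a few
thousand CpGs from genomes of 0.1–0.4 Mb, 1000 resamples, 5–10 replicates)
— sizes chosen so the whole study reruns in minutes while keeping every
statistical assertion well-powered (binomial/Monte-Carlo checks are made
at 3σ). Stochastic tests fix their seeds. Degenerate inputs follow
explicit contracts: empty matrices, groups with < 2 values, sites with no
data, empty tracks and chromosome-less distances each have a defined
behaviour (error, NaN flag, or distinct log reason) rather than a silent
repair.

## Known limitations

- The t-test on fractions ignores coverage heterogeneity between samples;
  a beta-binomial model would weight deep samples more.
- Exact density matching can fail on tiny universes (rare densities);
  the error lists the offending densities rather than falling back.
- The "continuous" class is sensitive to non-monotonicity from noise when
  per-age means are imprecise; with per-age SD ≲ 1–2 points accuracy for
  discrete/continuous truth classes exceeds 90%, but noisier data will
  shift continuous sites into "other".
- The dividing-cell schedule and the trajectory pattern mix are package
  defaults, not estimates; both are single config fields.
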