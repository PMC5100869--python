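# livermeth

Analysis pipeline for reduced-representation bisulfite sequencing (RRBS)
studies of postnatal liver development, together with a synthetic RRBS data
generator so every stage runs offline with known ground truth.

The mouse liver rewires its DNA methylome after birth: starting from
per-CpG bisulfite counts, this package quantifies which CpGs change between
ages, when the changes happen, what trajectory shapes they follow, and
which genomic features (promoters, exons, introns, enhancer-like elements)
the changing CpGs concentrate in — while controlling for local CpG density,
the classic confounder of methylation enrichment tests. It is aimed at
epigenomics researchers who work with Bismark-style coverage files and want
a tested, scriptable implementation of this analysis recipe.

## Methods at a glance

- **QC cascade** — cells with coverage < 10× are missing; CpGs with > 20%
  missing samples are dropped; CpGs < 10% methylated in *every* sample are
  dropped; samples are scored by a sharedness-weighted completeness score
  (score_s = Σ_c w_c·I(coverage_cs ≥ 10) with w_c the fraction of samples
  covering CpG c) and removed below a cutoff (absolute, e.g. 50 000 for
  genome-scale panels, or relative to the maximum attainable score).
- **Differential methylation** — per-CpG equal-variance Student's *t* on
  per-sample percent methylation; Benjamini–Hochberg FDR (Storey's
  smoother-based q-value optional); a CpG is called significant when
  |Δ| > 5 percentage points **and** q ≤ 0.1; significant calls are binned
  into 5–30 and ≥ 30-point changes.
- **Time course** — consecutive-age deltas; per-interval counts of CpGs
  changing ≥ 30 points; sustained-change cross-tabulation; trajectory
  classification into *discrete* (one interval carries ≥ 50% of the total
  change), *continuous* (monotone, every step < 50%) and *other*.
- **Genomic context** — ±200 bp CpG density and GC content; strand-aware
  1 kb promoters; exclusive promoter/exon/intron hierarchy; feature
  enrichment of each CpG group against 1000 random subsamples whose local
  CpG density exactly matches the focal set, with empirical tail p-values.
- **Analytic models** — hemimethylation dilution (a fraction *f* of
  dividing cells lowers observed methylation *m* by *m·f/2*, e.g. 5 points
  at *f* = 0.10, *m* = 100%) and coverage granularity (100/coverage, e.g.
  2.5% steps at 40×).
- **Simulator** — random genome, in-silico MspI digest (C^CGG) with
  150–600 bp size selection, CpGs reachable by 50 bp reads from fragment
  ends, ground-truth trajectories (defaults: 79% of CpGs changing, 89%
  gains, magnitudes up to 88 points, onset concentrated after P5), a
  hepatocyte/hematopoietic cell mixture following liver histology, an
  age-declining dividing-cell fraction, > 99% bisulfite conversion, and
  negative-binomial ~40× coverage.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts (a two-age discovery cohort, E18.5 n=5 vs 9 wk n=10, and a six-age
time course, 5 replicates per age):

```sh
python analysis/01_simulate.py      # writes results/synthetic/
python analysis/02_qc.py
python analysis/03_differential.py
python analysis/04_timecourse.py
python analysis/05_enrichment.py
python analysis/06_models.py
```

With the default seed this prints, among other things:

```
discovery: 1630 of 1843 testable CpGs significant (88.4%); 591 changed 5-30
points, 1039 changed >=30; 81.5% gained methylation with age
truth on the retained panel: 78.9% changed, 89.1% of changes are gains
```

The gap between the 88.4% called and the 78.9% of truly changing CpGs is
real biology faithfully simulated, not a defect: the discovery cohort mixes
an age-declining hematopoietic compartment into the tissue, so
composition-driven apparent changes add to the hepatocyte-lineage signal
(run the simulator with a neutral composition schedule and the two numbers
agree to within sampling error). The time-course script then shows most
≥ 30-point changes falling after P5:

```
  E18.5-P1         7 / 2
  P1-P5           15 / 3
  P5-P10         280 / 37
  P10-P15        114 / 14
  P15-P20        242 / 36
```

and the enrichment script recovers the planted enhancer signal — the
enhancer-like track is 1.8–2.2-fold enriched (p ≤ 0.004) specifically in
CpGs that *lose* methylation by ≥ 30 points, after exact CpG-density
matching. The models script reports the uppermost methylation mode rising
from ~59% (E18.5) to 100% (P15–P20) as the dividing-cell fraction declines.

The same stages are available as a CLI (`livermeth simulate|qc|diff|
timecourse|enrich|models|run-all`) for use on real Bismark coverage files.

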