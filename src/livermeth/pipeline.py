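"""End-to-end orchestration: load -> QC -> differential -> time-course -> enrichment.

Every stage is a pure function of (inputs, config, seed); the run report is
a plain-text funnel (sites in, sites retained, sites significant, ...) that
is byte-identical across reruns with the same config and seed.  Cohorts are
analyzed separately; a run operates on one cohort's samples.
"""

from __future__ import annotations

import glob as globmod
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffmeth, genomic, models, qc, temporal
from .meth_io import (
    MethylationMatrix,
    build_matrix,
    read_bed,
    read_bismark_coverage,
    read_sample_sheet,
    write_table,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    coverage_glob: str = ""
    sample_sheet: str = ""
    outdir: str = "results/run"
    cohort: str | None = None
    group_a: str = "E18.5"
    group_b: str = "9wk"
    track_paths: dict = field(default_factory=dict)  # name -> BED path
    genome_fasta: str | None = None
    qc: qc.QCConfig = field(default_factory=qc.QCConfig)
    test: diffmeth.TestConfig = field(default_factory=diffmeth.TestConfig)
    interval_threshold: float = 30.0
    min_total_change: float = 5.0
    n_resamples: int = 1000
    flank: int = 200
    seed: int = 0


def load_matrix(config: RunConfig) -> MethylationMatrix:
    paths = sorted(globmod.glob(config.coverage_glob))
    if not paths:
        raise FileNotFoundError(f"no coverage files match {config.coverage_glob!r}")
    sheet = read_sample_sheet(config.sample_sheet)
    if config.cohort is not None:
        sheet = sheet[sheet["cohort"] == config.cohort]
        if len(sheet) == 0:
            raise ValueError(f"no samples in cohort {config.cohort!r}")
    records = {}
    by_stem = {Path(p).stem: p for p in paths}
    for sample_id in sheet.index:
        if sample_id not in by_stem:
            raise FileNotFoundError(f"no coverage file for sample {sample_id!r}")
        records[sample_id] = read_bismark_coverage(by_stem[sample_id])
    return build_matrix(records, sheet)


def _load_sequences(fasta_path: str) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(fasta_path)
    return {name: str(fa[name][:]) for name in fa.keys()}


def run_pipeline(config: RunConfig) -> dict:
    """Run every applicable stage and write tables plus a text report.

    Returns a bundle with the QC result, call tables and report lines.
    Stages that lack inputs (e.g. enrichment without tracks) are skipped and
    noted in the report; genuine failures abort naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: list[str] = [f"# livermeth run (seed={config.seed})"]
    bundle: dict = {}

    try:
        matrix = load_matrix(config)
    except Exception as exc:
        raise PipelineError("load", exc) from exc
    report.append(f"load: {matrix.n_sites} sites x {matrix.n_samples} samples")

    try:
        qc_result = qc.run_qc(matrix, config.qc)
    except Exception as exc:
        raise PipelineError("qc", exc) from exc
    bundle["qc"] = qc_result
    write_table(qc_result.sample_scores, outdir / "sample_scores.tsv")
    write_table(qc_result.removal_log, outdir / "site_removals.tsv")
    f = qc_result.funnel
    report.append(
        "qc: {samples_removed} samples removed; sites {sites_in} -> "
        "{sites_after_missingness} (missingness) -> {sites_after_never_methylated} "
        "(never-methylated)".format(**f)
    )
    filtered = qc_result.matrix

    try:
        calls = diffmeth.call_differential(filtered, config.group_a, config.group_b, config.test)
    except Exception as exc:
        raise PipelineError("diff", exc) from exc
    bundle["calls"] = calls
    write_table(calls, outdir / "diff_calls.tsv")
    s = diffmeth.summarize_calls(calls)
    report.append(
        "diff {a} vs {b}: {n_significant}/{n_testable} significant "
        "(5-30: {n_bin_5_30}, >=30: {n_bin_ge30}; increase fraction: {fi})".format(
            a=config.group_a,
            b=config.group_b,
            fi="NA" if np.isnan(s["fraction_increase"]) else f"{s['fraction_increase']:.3f}",
            **{k: s[k] for k in ("n_significant", "n_testable", "n_bin_5_30", "n_bin_ge30")},
        )
    )

    ages_present = [a for a in filtered.samples["age_group"].cat.categories
                    if (filtered.samples["age_group"] == a).any()]
    patterns = None
    if len(ages_present) >= 3:
        try:
            whitelist = list(calls.index[calls["significant"]])
            means, counts = temporal.age_trajectories(filtered, ages_present,
                                                      site_whitelist=whitelist or None)
            intervals = temporal.count_interval_changes(means, config.interval_threshold)
            crosstab = temporal.sustained_crosstab(means, config.interval_threshold)
            patterns = temporal.classify_all(means, config.min_total_change)
        except Exception as exc:
            raise PipelineError("timecourse", exc) from exc
        bundle["interval_counts"] = intervals
        bundle["crosstab"] = crosstab
        bundle["patterns"] = patterns
        write_table(intervals, outdir / "interval_counts.tsv")
        write_table(crosstab, outdir / "sustained_crosstab.tsv")
        write_table(patterns, outdir / "pattern_calls.tsv")
        changed = patterns[patterns["status"] == "changed"]
        report.append(
            f"timecourse: {len(changed)} changing trajectories "
            f"(discrete {int((changed['pattern'] == 'discrete').sum())}, "
            f"continuous {int((changed['pattern'] == 'continuous').sum())}, "
            f"other {int((changed['pattern'] == 'other').sum())})"
        )
    else:
        report.append("timecourse: skipped (fewer than 3 age groups)")

    if config.track_paths:
        try:
            tracks = [read_bed(path, name=name) for name, path in sorted(config.track_paths.items())]
            sequences = _load_sequences(config.genome_fasta) if config.genome_fasta else None
            ann = genomic.annotate(filtered.sites, tracks, sequences=sequences, flank=config.flank)
            bundle["annotations"] = ann
            write_table(ann, outdir / "annotations.tsv")
            source = patterns if patterns is not None else None
            if source is not None:
                enrich = genomic.enrichment_by_group(
                    source, ann, [t.name for t in tracks],
                    n_resamples=config.n_resamples, seed=config.seed,
                )
            else:
                focal = calls.index[calls["significant"]]
                if len(focal):
                    enrich = genomic.density_matched_enrichment(
                        focal, ann, [t.name for t in tracks],
                        n_resamples=config.n_resamples, seed=config.seed,
                        group="significant",
                    )
                else:
                    enrich = pd.DataFrame()
            bundle["enrichment"] = enrich
            write_table(enrich, outdir / "enrichment.tsv", index=False)
            report.append(f"enrich: {len(enrich)} group x track results")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("enrich", exc) from exc
    else:
        report.append("enrich: skipped (no tracks configured)")

    try:
        hist, mode = models.methylation_distribution(filtered)
        write_table(hist, outdir / "methylation_histogram.tsv", index=False)
        report.append(f"models: uppermost methylation mode at {mode:.1f}%")
    except Exception as exc:
        raise PipelineError("models", exc) from exc

    report_text = "\n".join(report) + "\n"
    (outdir / "report.txt").write_text(report_text)
    bundle["report"] = report_text
    return bundle
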