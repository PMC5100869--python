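#!/usr/bin/env python
"""Run the QC cascade on both synthetic cohorts and report the site funnel.

Masks cells under 10x coverage, scores sample completeness (relative cutoff,
half the maximum attainable score), removes CpGs with >20% missing samples
and CpGs under 10% methylation in every sample.  Writes sample scores and
removal logs under results/qc/.
"""

import argparse
from pathlib import Path

from livermeth import qc
from livermeth.meth_io import write_table
from livermeth.pipeline import RunConfig, load_matrix

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "synthetic")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "qc")
    args = parser.parse_args()

    for cohort in ("discovery", "timecourse"):
        cdir = args.data / cohort
        matrix = load_matrix(
            RunConfig(coverage_glob=str(cdir / "*.cov"), sample_sheet=str(cdir / "samples.tsv"))
        )
        result = qc.run_qc(matrix)
        write_table(result.sample_scores, args.out / f"{cohort}_sample_scores.tsv")
        write_table(result.removal_log, args.out / f"{cohort}_site_removals.tsv")
        f = result.funnel
        print(
            f"{cohort}: {f['sites_in']} sites in -> "
            f"{f['sites_after_missingness']} after missingness filter -> "
            f"{f['sites_after_never_methylated']} retained; "
            f"{f['samples_removed']} of {f['samples_in']} samples removed"
        )


if __name__ == "__main__":
    main()
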