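#!/usr/bin/env python
"""Time-course analysis: when do the methylation changes happen?

Restricts the six-age cohort to CpGs called significant in the discovery
comparison, counts CpGs changing >=30 points per consecutive age interval,
cross-tabulates sustained changes, classifies trajectory patterns
(discrete / continuous / other x gain / loss), and measures cross-cohort
concordance of significance calls.  Writes tables under results/timecourse/.
"""

import argparse
from pathlib import Path

import pandas as pd

from livermeth import diffmeth, qc, temporal
from livermeth.meth_io import write_table
from livermeth.pipeline import RunConfig, load_matrix

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "synthetic")
    parser.add_argument("--calls", type=Path,
                        default=ROOT / "results" / "differential" / "discovery_calls.tsv")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "timecourse")
    args = parser.parse_args()

    cdir = args.data / "timecourse"
    matrix = load_matrix(
        RunConfig(coverage_glob=str(cdir / "*.cov"), sample_sheet=str(cdir / "samples.tsv"))
    )
    filtered = qc.run_qc(matrix).matrix

    discovery_calls = pd.read_csv(args.calls, sep="\t", index_col=0)
    whitelist = list(discovery_calls.index[discovery_calls["significant"]])
    means, counts = temporal.age_trajectories(filtered, site_whitelist=whitelist)
    print(
        f"{len(means)} discovery-significant CpGs followed across "
        f"{means.shape[1]} ages (of {filtered.n_sites} retained in the cohort)"
    )

    intervals = temporal.count_interval_changes(means, threshold=30.0)
    write_table(intervals, args.out / "interval_counts.tsv")
    busiest = (intervals["gain"] + intervals["loss"]).idxmax()
    print("CpGs changing >=30 points per interval (gain/loss):")
    for label, row in intervals.iterrows():
        print(f"  {label:<12} {row['gain']:>5} / {row['loss']}")
    print(f"most changes fall in {busiest}")

    crosstab = temporal.sustained_crosstab(means, threshold=30.0)
    write_table(crosstab, args.out / "sustained_crosstab.tsv")

    patterns = temporal.classify_all(means)
    write_table(patterns, args.out / "pattern_calls.tsv")
    changed = patterns[patterns["status"] == "changed"]
    print(
        f"pattern mix among {len(changed)} changing trajectories: "
        + ", ".join(
            f"{k} {int(v)}" for k, v in changed["pattern"].value_counts().items()
        )
    )

    # cross-cohort concordance: significance at the shared extreme ages
    tc_calls = diffmeth.call_differential(filtered, "E18.5", "P20")
    frac, n_shared = diffmeth.concordance(discovery_calls, tc_calls)
    print(
        f"concordance: {100 * frac:.1f}% of time-course-significant CpGs "
        f"(on {n_shared} shared sites) are also discovery-significant"
    )


if __name__ == "__main__":
    main()
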