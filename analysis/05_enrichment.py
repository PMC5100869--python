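#!/usr/bin/env python
"""Genomic-context enrichment of the changing CpGs, density-matched.

Builds synthetic feature tracks on the simulated genome (stranded gene
models -> exclusive promoter/exon/intron hierarchy, plus an "enhancer"
track deliberately placed around a biased subset of methylation-losing
CpGs), annotates every retained CpG with overlap, distance, local CpG
density and GC content, then tests each trajectory group (direction x
pattern x magnitude) for feature enrichment against 1000 CpG-density-matched
resamples.  Also prints the unadjusted promoter fold as a contrast.
Writes tables under results/enrichment/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from livermeth import genomic, qc
from livermeth.meth_io import FeatureTrack, write_table
from livermeth.pipeline import RunConfig, load_matrix, _load_sequences

ROOT = Path(__file__).resolve().parents[1]


def synthetic_gene_models(genome_length: int, rng: np.random.Generator) -> pd.DataFrame:
    starts = np.sort(rng.choice(genome_length - 6000, size=40, replace=False))
    rows = []
    for s in starts:
        length = int(rng.integers(2000, 6000))
        rows.append({
            "chrom": "chrS",
            "start": int(s),
            "end": int(min(s + length, genome_length)),
            "strand": "+" if rng.random() < 0.5 else "-",
        })
    return pd.DataFrame(rows)


def enhancer_track(truth: pd.DataFrame, sites: pd.DataFrame, rng: np.random.Generator) -> FeatureTrack:
    # enhancers preferentially placed over methylation-losing CpGs, the
    # regulatory signature the enrichment analysis is meant to pick up
    losing = sites.loc[sites.index.intersection(
        truth.index[(truth["status"] == "changed") & (truth["direction"] == "decrease")]
    )]
    chosen = losing.sample(frac=0.6, random_state=int(rng.integers(2**31)))
    background = sites.sample(n=min(len(sites), 60), random_state=int(rng.integers(2**31)))
    rows = [
        {"chrom": r["chrom"], "start": max(0, int(r["pos"]) - 150), "end": int(r["pos"]) + 150}
        for _, r in pd.concat([chosen, background]).iterrows()
    ]
    return FeatureTrack("enhancer", pd.DataFrame(rows))


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "synthetic")
    parser.add_argument("--patterns", type=Path,
                        default=ROOT / "results" / "timecourse" / "pattern_calls.tsv")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "enrichment")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-resamples", type=int, default=1000)
    args = parser.parse_args()

    rng = np.random.default_rng(args.seed)
    cdir = args.data / "timecourse"
    matrix = load_matrix(
        RunConfig(coverage_glob=str(cdir / "*.cov"), sample_sheet=str(cdir / "samples.tsv"))
    )
    filtered = qc.run_qc(matrix).matrix
    truth = pd.read_csv(cdir / "truth.tsv", sep="\t", index_col=0)
    sequences = _load_sequences(str(cdir / "genome.fa"))

    genes = synthetic_gene_models(len(sequences["chrS"]), rng)
    promoters = genomic.promoters_from_genes(genes)
    exons = FeatureTrack("exon", genes.assign(end=genes["start"] + 500)[["chrom", "start", "end"]])
    introns = FeatureTrack("intron", genes.assign(start=genes["start"] + 500)[["chrom", "start", "end"]])
    promoters, exons, introns = genomic.make_exclusive_genic(promoters, exons, introns)
    enhancers = enhancer_track(truth, filtered.sites, rng)
    tracks = [promoters, exons, introns, enhancers]

    ann = genomic.annotate(filtered.sites, tracks, sequences=sequences)
    write_table(ann, args.out / "annotations.tsv")

    patterns = pd.read_csv(args.patterns, sep="\t", index_col=0)
    patterns = patterns.loc[patterns.index.intersection(ann.index)]
    enrich = genomic.enrichment_by_group(
        patterns, ann, [t.name for t in tracks],
        n_resamples=args.n_resamples, seed=args.seed,
    )
    write_table(enrich, args.out / "enrichment.tsv", index=False)

    sig = enrich[(enrich["p_enrich"] <= 0.05) | (enrich["p_deplete"] <= 0.05)]
    print(f"{len(enrich)} group x track tests; {len(sig)} significant at p <= 0.05:")
    for _, r in sig.iterrows():
        tail = "enriched" if r["p_enrich"] <= r["p_deplete"] else "depleted"
        print(
            f"  {r['group']:<22} {r['track']:<9} fold {r['fold']:.2f} "
            f"({tail}, p_enrich={r['p_enrich']:.3f}, p_deplete={r['p_deplete']:.3f})"
        )

    # unadjusted contrast: large changes in promoters vs the whole panel
    changed = patterns["status"] == "changed"
    big = changed & (patterns["total_change"].abs() > 30)
    prom_sites = ann["in_promoter"]
    prop_prom = 100 * big[prom_sites.reindex(patterns.index, fill_value=False)].mean()
    prop_all = 100 * big.mean()
    if prop_prom > 0 and prop_all > 0:
        fold, direction = genomic.naive_fold(prop_prom, prop_all)
        print(
            f"naive contrast: {prop_prom:.1f}% of promoter CpGs vs {prop_all:.1f}% of all "
            f"CpGs changed >=30 points -> {fold:.2f}-fold {direction} (unadjusted)"
        )


if __name__ == "__main__":
    main()
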