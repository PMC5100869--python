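"""Genomic-context tests: window stats, track algebra, annotation oracle, enrichment."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from livermeth import genomic
from livermeth.meth_io import FeatureTrack


def track(name, intervals):
    return FeatureTrack(
        name, pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    )


def window_scan_oracle(sequence, pos, flank):
    """Brute-force window stats by direct string scan."""
    lo = max(0, pos - 1 - flank)
    hi = min(len(sequence) - 1, pos - 1 + flank)
    window = sequence[lo : hi + 1]
    gc = sum(b in "GC" for b in window) / len(window)
    density = sum(
        1
        for i in range(lo, hi + 1)
        if sequence[i : i + 2] == "CG"
    )
    return density, gc


class TestWindowStats:
    def test_lone_cpg_in_a_desert(self):
        seq = "A" * 300 + "CG" + "A" * 300
        density, gc = genomic.window_stats(301, sequence=seq, flank=200)
        assert density == 1
        assert gc == pytest.approx(2 / 401)

    def test_alternating_cg_matches_scan_oracle(self):
        seq = "CG" * 400
        pos = 401  # a C (odd positions are Cs)
        density, gc = genomic.window_stats(pos, sequence=seq, flank=200)
        assert (density, gc) == window_scan_oracle(seq, pos, 200)
        assert gc == pytest.approx(1.0)

    def test_zero_flank(self):
        seq = "A" * 10 + "CG" + "A" * 10
        density, _ = genomic.window_stats(11, sequence=seq, flank=0)
        assert density == 1

    def test_contig_end_clipping(self):
        seq = "CG" + "A" * 100
        density, gc = genomic.window_stats(1, sequence=seq, flank=200)
        assert density == 1
        assert gc == pytest.approx(2 / 102)

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            genomic.window_stats(500, sequence="ACGT" * 10)

    def test_position_list_density(self):
        positions = [100, 250, 300, 600]
        density, gc = genomic.window_stats(250, cpg_positions=positions, flank=200)
        assert density == 3  # 100, 250, 300 within +/-200
        assert np.isnan(gc)


class TestPromoters:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])

    def test_plus_strand(self):
        t = genomic.promoters_from_genes(self._genes([("chr1", 5000, 7000, "+")]))
        assert t.df[["start", "end"]].values.tolist() == [[4000, 5000]]

    def test_minus_strand(self):
        t = genomic.promoters_from_genes(self._genes([("chr1", 5000, 7000, "-")]))
        assert t.df[["start", "end"]].values.tolist() == [[7000, 8000]]

    def test_clipped_at_contig_start(self):
        t = genomic.promoters_from_genes(self._genes([("chr1", 400, 900, "+")]))
        assert t.df[["start", "end"]].values.tolist() == [[0, 400]]

    def test_missing_strand_errors(self):
        with pytest.raises(ValueError):
            genomic.promoters_from_genes(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]}))


class TestExclusiveGenic:
    def test_exon_inside_promoter_removed(self):
        prom = track("promoter", [("chr1", 100, 400)])
        ex = track("exon", [("chr1", 150, 300)])
        intr = track("intron", [("chr1", 500, 600)])
        _, ex2, in2 = genomic.make_exclusive_genic(prom, ex, intr)
        assert len(ex2) == 0
        assert in2.df[["start", "end"]].values.tolist() == [[500, 600]]

    def test_partial_overlap_subtraction(self):
        prom = track("promoter", [("chr1", 150, 250)])
        ex = track("exon", [("chr1", 100, 200)])
        intr = track("intron", [("chr1", 120, 160)])
        _, ex2, in2 = genomic.make_exclusive_genic(prom, ex, intr)
        assert ex2.df[["start", "end"]].values.tolist() == [[100, 150]]
        assert in2.df[["start", "end"]].values.tolist() == [[150, 160]]

    def test_disjoint_inputs_unchanged(self):
        prom = track("promoter", [("chr1", 0, 100)])
        ex = track("exon", [("chr1", 200, 300)])
        intr = track("intron", [("chr1", 400, 500)])
        p2, ex2, in2 = genomic.make_exclusive_genic(prom, ex, intr)
        assert ex2.df[["start", "end"]].values.tolist() == [[200, 300]]
        assert in2.df[["start", "end"]].values.tolist() == [[400, 500]]

    def test_outputs_disjoint_from_subtracted_tracks(self):
        rng = np.random.default_rng(5)
        def rand_track(name):
            starts = np.sort(rng.integers(0, 5000, size=20))
            return track(name, [("chr1", int(s), int(s + rng.integers(10, 200))) for s in starts])
        prom, ex, intr = rand_track("promoter"), rand_track("exon"), rand_track("intron")
        _, ex2, in2 = genomic.make_exclusive_genic(prom, ex, intr)
        covered = lambda t: set(itertools.chain.from_iterable(
            range(s, e) for s, e in t.df[["start", "end"]].itertuples(index=False)))
        assert covered(ex2) & covered(prom) == set()
        assert covered(in2) & covered(ex2) == set()


class TestAnnotate:
    def _sites(self, positions):
        return pd.DataFrame(
            {"chrom": "chr1", "pos": positions},
            index=[f"chr1:{p}" for p in positions],
        )

    def test_overlap_convention_1_based(self):
        # BED [99,100) covers exactly the 1-based position 100
        ann = genomic.annotate(self._sites([100]), [track("t", [("chr1", 99, 100)])])
        assert bool(ann["in_t"].iloc[0])
        assert ann["dist_t"].iloc[0] == 0.0

    def test_gap_distance(self):
        ann = genomic.annotate(self._sites([100]), [track("t", [("chr1", 109, 120)])])
        assert not bool(ann["in_t"].iloc[0])
        assert ann["dist_t"].iloc[0] == 9.0

    def test_empty_track_flags_undefined_distance(self):
        empty = FeatureTrack("t", pd.DataFrame(columns=["chrom", "start", "end"]))
        ann = genomic.annotate(self._sites([100, 200]), [empty])
        assert not ann["in_t"].any()
        assert ann["dist_t"].isna().all()

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(8)
        starts = np.sort(rng.choice(10_000, size=30, replace=False))
        intervals = [("chr1", int(s), int(s + rng.integers(5, 120))) for s in starts]
        trk = track("t", intervals)
        positions = sorted(rng.choice(np.arange(1, 10_500), size=80, replace=False).tolist())
        ann = genomic.annotate(self._sites(positions), [trk])
        # merge overlapping intervals for the oracle, then O(n*m) scan
        merged = []
        for s, e in sorted((s, e) for _, s, e in intervals):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for sid, pos in zip(ann.index, positions):
            overlaps = any(s < pos <= e for s, e in merged)
            gaps = [max(s - pos, (pos - 1) - e, 0) for s, e in merged]
            assert bool(ann.loc[sid, "in_t"]) == overlaps
            assert ann.loc[sid, "dist_t"] == pytest.approx(min(gaps))


class TestNaiveFold:
    def test_worked_depletion_example(self):
        fold, direction = genomic.naive_fold(5.3, 8.5)
        assert round(fold, 2) == 1.60
        assert direction == "depletion"

    def test_equal_proportions(self):
        assert genomic.naive_fold(8.5, 8.5) == (1.0, "none")

    def test_enrichment_ratio(self):
        fold, direction = genomic.naive_fold(17.0, 8.5)
        assert (fold, direction) == (pytest.approx(2.0), "enrichment")

    def test_zero_proportion_rejected(self):
        with pytest.raises(ValueError):
            genomic.naive_fold(0.0, 8.5)


def uniform_universe(n=6, in_track=3, density=5):
    return pd.DataFrame(
        {"local_cpg_density": [density] * n, "in_trk": [True] * in_track + [False] * (n - in_track)},
        index=[f"s{i}" for i in range(n)],
    )


class TestDensityMatchedEnrichment:
    def test_exhaustive_enumeration_oracle(self):
        # 6-site universe, 3 in-track, focal = 2 in-track sites: drawing 2 of
        # 6 without replacement gives mean in-track count 1.0 and
        # P(count >= 2) = C(3,2)/C(6,2) = 0.2
        ann = uniform_universe()
        res = genomic.density_matched_enrichment(
            ["s0", "s1"], ann, ["trk"], n_resamples=1000, seed=4
        ).iloc[0]
        counts_var = 2 * 0.5 * 0.5 * (4 / 5)  # hypergeometric variance
        assert res["observed"] == 2
        assert abs(res["resample_mean"] - 1.0) < 3 * np.sqrt(counts_var / 1000)
        assert abs(res["p_enrich"] - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 1000)

    def test_track_covering_everything_is_flat(self):
        ann = uniform_universe(n=6, in_track=6)
        res = genomic.density_matched_enrichment(["s0", "s1"], ann, ["trk"], 200, seed=1).iloc[0]
        assert res["fold"] == pytest.approx(1.0)
        assert res["p_enrich"] == 1.0 and res["p_deplete"] == 1.0

    def test_focal_equals_universe(self):
        ann = uniform_universe()
        res = genomic.density_matched_enrichment(list(ann.index), ann, ["trk"], 200, seed=1).iloc[0]
        assert res["fold"] == pytest.approx(1.0)
        assert res["p_enrich"] == 1.0 and res["p_deplete"] == 1.0

    def test_exact_density_matching_enforced(self):
        # two density strata; in-track status perfectly tracks density, so
        # matched resamples must reproduce the focal count exactly
        ann = pd.DataFrame(
            {
                "local_cpg_density": [3, 3, 3, 9, 9, 9],
                "in_trk": [True, True, True, False, False, False],
            },
            index=[f"s{i}" for i in range(6)],
        )
        res = genomic.density_matched_enrichment(["s0", "s1"], ann, ["trk"], 300, seed=2).iloc[0]
        assert res["resample_mean"] == pytest.approx(2.0)
        assert res["p_enrich"] == 1.0 and res["p_deplete"] == 1.0

    def test_unmatched_density_errors(self):
        ann = uniform_universe()
        lonely = pd.DataFrame(
            {"local_cpg_density": [99], "in_trk": [True]}, index=["w"]
        )
        with pytest.raises(ValueError, match="density 99"):
            genomic.density_matched_enrichment(
                ["w"], pd.concat([ann, lonely]), ["trk"], 100, seed=1,
                exclude_focal=True,
            )

    def test_focal_site_outside_universe_errors(self):
        with pytest.raises(ValueError, match="not in universe"):
            genomic.density_matched_enrichment(["nope"], uniform_universe(), ["trk"], 10)

    def test_universe_order_invariance_within_noise(self):
        ann = uniform_universe(n=40, in_track=12)
        shuffled = ann.sample(frac=1.0, random_state=0)
        r1 = genomic.density_matched_enrichment(["s0", "s1", "s2"], ann, ["trk"], 4000, seed=9).iloc[0]
        r2 = genomic.density_matched_enrichment(["s0", "s1", "s2"], shuffled, ["trk"], 4000, seed=9).iloc[0]
        assert r1["observed"] == r2["observed"]
        assert abs(r1["p_enrich"] - r2["p_enrich"]) < 3 * np.sqrt(0.3 * 0.7 / 4000) * 2

    def test_convergence_1000_vs_10000(self):
        ann = uniform_universe(n=12, in_track=5)
        focal = ["s0", "s1", "s5"]
        r1 = genomic.density_matched_enrichment(focal, ann, ["trk"], 1000, seed=3).iloc[0]
        r2 = genomic.density_matched_enrichment(focal, ann, ["trk"], 10_000, seed=4).iloc[0]
        se = np.sqrt(max(r2["p_enrich"] * (1 - r2["p_enrich"]), 0.01) / 1000)
        assert abs(r1["p_enrich"] - r2["p_enrich"]) < 3 * se
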