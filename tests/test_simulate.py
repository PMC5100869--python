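"""Generator tests: digest oracle, moment checks, trajectory truth, round trips."""

from __future__ import annotations

import hashlib
import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from livermeth import simulate as sim
from livermeth.meth_io import build_matrix, read_bismark_coverage, read_sample_sheet


def digest_oracle(sequence: str) -> list[tuple[int, int]]:
    """Independent C^CGG cut-site oracle by regex scan."""
    cuts = sorted({0, len(sequence)} | {m.start() + 1 for m in re.finditer("(?=CCGG)", sequence)})
    return list(zip(cuts[:-1], cuts[1:]))


class TestGenerateGenome:
    def test_length_and_determinism(self):
        g1 = sim.generate_genome(10_000, 0.42, 1.0, seed=7)
        g2 = sim.generate_genome(10_000, 0.42, 1.0, seed=7)
        assert g1.length == 10_000
        assert g1.sequence == g2.sequence
        assert sim.generate_genome(10_000, 0.42, 1.0, seed=8).sequence != g1.sequence

    def test_gc_moment_over_seeds(self):
        fracs = []
        for seed in range(1, 21):
            g = sim.generate_genome(10_000, 0.42, 1.0, seed=seed)
            fracs.append(sum(1 for b in g.sequence if b in "GC") / g.length)
        se = np.sqrt(0.42 * 0.58 / 10_000) / np.sqrt(20)
        assert abs(np.mean(fracs) - 0.42) < 3 * se

    def test_ccgg_rate_supports_size_selection(self):
        g = sim.generate_genome(100_000, 0.42, 1.0, seed=3)
        selected = sim.size_select(sim.mspi_digest(g))
        assert len(selected) >= g.length / 10_000  # >=1 fragment per 10 kb

    @pytest.mark.parametrize(
        "kwargs",
        [dict(length=0), dict(length=500), dict(gc_fraction=0.0), dict(gc_fraction=1.0)],
    )
    def test_invalid_inputs(self, kwargs):
        args = dict(length=10_000, gc_fraction=0.42)
        args.update(kwargs)
        with pytest.raises(ValueError):
            sim.generate_genome(args["length"], args["gc_fraction"])


class TestDigest:
    def test_hand_example(self):
        g = sim.SyntheticGenome("t", "AAACCGGAAA")
        frags = sim.mspi_digest(g)
        assert [(f.start, f.end) for f in frags] == [(0, 4), (4, 10)]
        assert g.sequence[:4] == "AAAC" and g.sequence[4:] == "CGGAAA"

    def test_no_site_single_fragment(self):
        g = sim.SyntheticGenome("t", "AAATTTAAA")
        assert [(f.start, f.end) for f in sim.mspi_digest(g)] == [(0, 9)]

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=400))
    def test_conservation_and_oracle(self, seq):
        g = sim.SyntheticGenome("t", seq)
        frags = sim.mspi_digest(g)
        assert "".join(seq[f.start : f.end] for f in frags) == seq
        assert [(f.start, f.end) for f in frags] == digest_oracle(seq)
        # tiling: no gaps or overlaps
        assert frags[0].start == 0 and frags[-1].end == len(seq)
        for a, b in zip(frags[:-1], frags[1:]):
            assert a.end == b.start


class TestSizeSelect:
    def test_inclusive_bounds(self):
        frags = [sim.Fragment(0, n) for n in (149, 150, 600, 601)]
        kept = sim.size_select(frags)
        assert [f.length for f in kept] == [150, 600]

    def test_empty_and_identity(self):
        assert sim.size_select([]) == []
        frags = [sim.Fragment(0, 10), sim.Fragment(10, 5000)]
        assert sim.size_select(frags, min_len=0, max_len=10**9) == frags

    def test_inverted_bounds_error(self):
        with pytest.raises(ValueError):
            sim.size_select([], min_len=10, max_len=5)


class TestAssayedCpGs:
    def test_short_fragment_fully_assayed(self):
        # 100 bp fragment: every base is within 50 bp of an end
        seq = "AT" * 20 + "CG" + "AT" * 29
        g = sim.SyntheticGenome("t", seq)
        sites = sim.enumerate_assayed_cpgs(g, [sim.Fragment(0, 100)], read_length=50)
        assert [s.pos for s in sites] == [41]

    def test_center_of_long_fragment_not_assayed(self):
        # CpG exactly at offset 150 of a 300 bp fragment: 150 from start,
        # 149 from end - both >= 50
        seq = "AT" * 75 + "CG" + "AT" * 74
        g = sim.SyntheticGenome("t", seq)
        sites = sim.enumerate_assayed_cpgs(g, [sim.Fragment(0, 300)], read_length=50)
        assert sites == []
        # but a read-sized flank reaches it
        sites = sim.enumerate_assayed_cpgs(g, [sim.Fragment(0, 300)], read_length=151)
        assert [s.pos for s in sites] == [151]

    def test_no_cpg_empty(self):
        g = sim.SyntheticGenome("t", "AT" * 100)
        assert sim.enumerate_assayed_cpgs(g, [sim.Fragment(0, 200)]) == []

    def test_sorted_unique_across_fragments(self):
        g = sim.generate_genome(20_000, 0.5, 1.0, seed=2)
        frags = sim.size_select(sim.mspi_digest(g), min_len=50, max_len=600)
        sites = sim.enumerate_assayed_cpgs(g, frags)
        pos = [s.pos for s in sites]
        assert pos == sorted(pos) and len(pos) == len(set(pos))
        for s in sites:
            assert g.sequence[s.pos - 1 : s.pos + 1] == "CG"


def _sites(n):
    return [sim.CpGSite("chr1", 10 * (i + 1)) for i in range(n)]


class TestTrajectories:
    def test_no_change_is_flat(self):
        cfg = sim.TrajectoryConfig(change_fraction=0.0, seed=1)
        hep, hema, truth = sim.assign_trajectories(_sites(50), cfg)
        assert (truth["status"] == "unchanged").all()
        assert np.allclose(hep.to_numpy().std(axis=1), 0.0)

    def test_gain_bias_one_all_increase(self):
        cfg = sim.TrajectoryConfig(change_fraction=1.0, gain_bias=1.0, seed=1)
        _, _, truth = sim.assign_trajectories(_sites(100), cfg)
        assert (truth["direction"] == "increase").all()

    def test_realized_fractions_match_config(self):
        cfg = sim.TrajectoryConfig(change_fraction=0.79, gain_bias=0.89, seed=5)
        _, _, truth = sim.assign_trajectories(_sites(5000), cfg)
        changed = truth["status"] == "changed"
        se_c = np.sqrt(0.79 * 0.21 / 5000)
        assert abs(changed.mean() - 0.79) < 3 * se_c
        gains = (truth.loc[changed, "direction"] == "increase").mean()
        se_g = np.sqrt(0.89 * 0.11 / changed.sum())
        assert abs(gains - 0.89) < 3 * se_g

    def test_values_in_unit_interval_and_deterministic(self):
        cfg = sim.TrajectoryConfig(seed=3)
        hep1, hema1, _ = sim.assign_trajectories(_sites(200), cfg)
        hep2, _, _ = sim.assign_trajectories(_sites(200), cfg)
        assert ((hep1.to_numpy() >= 0) & (hep1.to_numpy() <= 1)).all()
        assert ((hema1.to_numpy() >= 0) & (hema1.to_numpy() <= 1)).all()
        pd.testing.assert_frame_equal(hep1, hep2)


class TestMixtureAndDilution:
    def test_mixture_endpoints_and_blend(self):
        assert sim.mixture_methylation(0.8, 0.4, 0.0) == pytest.approx(0.8)
        assert sim.mixture_methylation(0.8, 0.4, 1.0) == pytest.approx(0.4)
        assert sim.mixture_methylation(0.8, 0.4, 0.5) == pytest.approx(0.6)

    def test_mixture_range_check(self):
        with pytest.raises(ValueError):
            sim.mixture_methylation(1.2, 0.4, 0.5)

    def test_dilution_worked_example(self):
        assert sim.division_dilution(1.0, 0.10) == pytest.approx(0.95)
        assert sim.division_dilution(0.6, 0.0) == pytest.approx(0.6)
        assert sim.division_dilution(0.0, 0.7) == pytest.approx(0.0)


class TestSimulateCounts:
    def test_extremes_without_nonconversion(self):
        noise = sim.NoiseModel(nonconversion_rate=0.0)
        meth, total = sim.simulate_counts(np.ones(500), noise, seed=1)
        assert (meth == total).all()
        meth, total = sim.simulate_counts(np.zeros(500), noise, seed=1)
        assert (meth == 0).all()

    def test_mean_fraction_closed_form(self):
        # E[fraction] = m + (1 - m) * eps = 0.5025 at m=0.5, eps=0.005
        noise = sim.NoiseModel(nonconversion_rate=0.005, coverage_mean=40.0)
        meth, total = sim.simulate_counts(np.full(10_000, 0.5), noise, seed=9)
        ok = total > 0
        frac = meth[ok] / total[ok]
        sem = frac.std(ddof=1) / np.sqrt(ok.sum())
        assert abs(frac.mean() - 0.5025) < 3 * sem

    def test_counts_deterministic(self):
        noise = sim.NoiseModel()
        a = sim.simulate_counts(np.full(100, 0.3), noise, seed=4)
        b = sim.simulate_counts(np.full(100, 0.3), noise, seed=4)
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()


class TestCpHPanel:
    def test_no_nonconversion_no_calls(self):
        g = sim.generate_genome(20_000, 0.42, seed=1)
        panel = sim.simulate_cph_panel(g, 500, sim.NoiseModel(nonconversion_rate=0.0), seed=2)
        assert (panel["meth"] == 0).all()

    def test_pooled_rate_matches_nonconversion(self):
        g = sim.generate_genome(40_000, 0.42, seed=1)
        noise = sim.NoiseModel(nonconversion_rate=0.005, coverage_mean=40.0)
        panel = sim.simulate_cph_panel(g, 3000, noise, seed=2)
        n_obs = panel["total"].sum()
        assert n_obs >= 100_000
        rate = panel["meth"].sum() / n_obs
        se = np.sqrt(0.005 * 0.995 / n_obs)
        assert abs(rate - 0.005) < 3 * se
        conv = sim.estimate_conversion_rate(panel)
        assert (conv > 0.99).all()

    def test_empty_and_insufficient(self):
        g = sim.generate_genome(20_000, 0.42, seed=1)
        assert len(sim.simulate_cph_panel(g, 0, sim.NoiseModel(), seed=1)) == 0
        with pytest.raises(ValueError):
            sim.simulate_cph_panel(g, 10**7, sim.NoiseModel(), seed=1)


class TestWriteDataset:
    def test_round_trip_and_determinism(self, tmp_path):
        ages = ("E18.5", "9wk")
        cfg = sim.DatasetConfig(
            genome_length=30_000, age_groups=ages, n_replicates=3, seed=6,
            trajectory=sim.TrajectoryConfig(age_groups=ages, seed=6),
        )
        man1 = sim.write_dataset(cfg, tmp_path / "a")
        man2 = sim.write_dataset(cfg, tmp_path / "b")
        assert man1["n_samples"] == 6
        for p1, p2 in zip(man1["coverage"], man2["coverage"]):
            assert p1.read_bytes() == p2.read_bytes()

        genome, sites, samples, meth, total, truth, hep, hema = sim.simulate_dataset(cfg)
        sheet = read_sample_sheet(man1["sample_sheet"])
        records = {sid: read_bismark_coverage(tmp_path / "a" / f"{sid}.cov") for sid in sheet.index}
        # rows with zero coverage are omitted from the files
        for j, sid in enumerate(sheet.index):
            assert len(records[sid]) == int((total[:, j] > 0).sum())
        matrix = build_matrix(records, sheet)
        # every written cell round-trips to the simulated counts
        row_of = {s.site_id: i for i, s in enumerate(sites)}
        for sid, recs in records.items():
            j = list(sheet.index).index(sid)
            for site, m, t in recs:
                i = row_of[site.site_id]
                assert (m, t) == (meth[i, j], total[i, j])
        assert matrix.n_samples == 6
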