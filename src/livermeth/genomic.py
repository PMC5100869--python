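"""Genomic context annotation and CpG-density-matched enrichment.

Annotates assayed CpGs with feature-track overlap and distance, local CpG
density and GC content (±200 bp windows), builds strand-aware promoters and
the exclusive promoter/exon/intron hierarchy, and tests feature enrichment
of focal CpG sets against random subsamples of the assayed universe whose
local CpG density exactly matches the focal set — removing sequence
composition as a confounder.

Interval arithmetic (merge, subtraction, overlap, nearest) is delegated to
pyranges; distances follow the base-gap convention (adjacent intervals are
at distance 0 gap = 1 base apart reported as the number of bases between
them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meth_io import FeatureTrack

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Window statistics
# ---------------------------------------------------------------------------

def window_stats(
    pos: int,
    sequence: str | None = None,
    cpg_positions: np.ndarray | list[int] | None = None,
    flank: int = 200,
) -> tuple[int, float]:
    """Local CpG density and GC content around a CpG.

    ``pos`` is the 1-based plus-strand C.  The window spans ``flank`` bases
    up- and downstream of the C (401 bp at the default), clipped at contig
    ends.  Density counts CpG dinucleotides whose C lies in the window
    (the focal CpG included); GC content is (G+C)/window length and requires
    the sequence.  With only a CpG position list, GC is returned as NaN.
    """
    if sequence is None and cpg_positions is None:
        raise ValueError("need a genome sequence or a CpG position list")
    if sequence is not None:
        n = len(sequence)
        if not 1 <= pos <= n:
            raise ValueError(f"position {pos} beyond contig end {n}")
        lo = max(0, pos - 1 - flank)  # 0-based inclusive
        hi = min(n - 1, pos - 1 + flank)
        window = sequence[lo : hi + 1]
        gc = sum(1 for b in window if b in "GC") / len(window)
        density = 0
        for i in range(lo, hi + 1):
            if sequence[i] == "C" and i + 1 < n and sequence[i + 1] == "G":
                density += 1
        return density, gc
    cpg = np.asarray(cpg_positions)
    lo, hi = pos - flank, pos + flank
    density = int(np.count_nonzero((cpg >= lo) & (cpg <= hi)))
    return density, float("nan")


def window_stats_table(
    sites: pd.DataFrame,
    sequences: dict[str, str] | None = None,
    flank: int = 200,
) -> pd.DataFrame:
    """Vectorised per-site window stats for a sites table (chrom, pos).

    With ``sequences`` (chrom -> sequence) both density and GC are computed;
    without, density comes from the panel's own CpG positions per chromosome
    and GC is NaN.
    """
    density = np.zeros(len(sites), dtype=int)
    gc = np.full(len(sites), np.nan)
    for chrom, sub in sites.groupby("chrom", sort=False):
        idx = [sites.index.get_loc(i) for i in sub.index]
        if sequences is not None and chrom in sequences:
            seq = sequences[chrom]
            for i, p in zip(idx, sub["pos"]):
                density[i], gc[i] = window_stats(int(p), sequence=seq, flank=flank)
        else:
            pos = np.sort(sub["pos"].to_numpy())
            lo = np.searchsorted(pos, sub["pos"].to_numpy() - flank, side="left")
            hi = np.searchsorted(pos, sub["pos"].to_numpy() + flank, side="right")
            for k, i in enumerate(idx):
                density[i] = hi[k] - lo[k]
    return pd.DataFrame(
        {"local_cpg_density": density, "gc_content": gc}, index=sites.index
    )


# ---------------------------------------------------------------------------
# Track construction
# ---------------------------------------------------------------------------

def promoters_from_genes(
    genes: pd.DataFrame,
    upstream: int = 1000,
    chrom_sizes: dict[str, int] | None = None,
    name: str = "promoter",
) -> FeatureTrack:
    """1 kb-upstream promoters from stranded gene records (BED semantics).

    Plus-strand gene [s, e) gets promoter [s-upstream, s); minus-strand
    [e, e+upstream).  Clipped at contig bounds when sizes are supplied.
    """
    if "strand" not in genes.columns:
        raise ValueError("gene records need a strand column")
    rows = []
    for _, g in genes.iterrows():
        if g["strand"] == "+":
            start, end = g["start"] - upstream, g["start"]
        elif g["strand"] == "-":
            start, end = g["end"], g["end"] + upstream
        else:
            raise ValueError(f"bad strand {g['strand']!r}")
        start = max(0, start)
        if chrom_sizes and g["chrom"] in chrom_sizes:
            end = min(end, chrom_sizes[g["chrom"]])
        if start < end:
            rows.append({"chrom": g["chrom"], "start": start, "end": end})
    return FeatureTrack(name=name, df=pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def _merged_pr(track: FeatureTrack):
    g = track.to_pyranges()
    if len(track) == 0:
        return g
    return g.merge()


def _pr_to_track(pr_obj, name: str) -> FeatureTrack:
    df = pr_obj.df if len(pr_obj) else pd.DataFrame(columns=["Chromosome", "Start", "End"])
    out = pd.DataFrame(
        {"chrom": df.get("Chromosome", pd.Series(dtype=str)).astype(str),
         "start": df.get("Start", pd.Series(dtype=int)).astype(int),
         "end": df.get("End", pd.Series(dtype=int)).astype(int)}
    )
    return FeatureTrack(name=name, df=out)


def make_exclusive_genic(
    promoters: FeatureTrack, exons: FeatureTrack, introns: FeatureTrack
) -> tuple[FeatureTrack, FeatureTrack, FeatureTrack]:
    """Exclusive genic hierarchy: exons minus promoters, then introns minus
    the remaining exons.  Promoters are returned unchanged.  Residual
    intron/promoter overlap (possible under this two-step subtraction) is
    counted and logged, not removed.
    """
    prom_pr = _merged_pr(promoters)
    exons_excl = _merged_pr(exons).subtract(prom_pr) if len(exons) else exons.to_pyranges()
    introns_excl = (
        _merged_pr(introns).subtract(exons_excl) if len(introns) else introns.to_pyranges()
    )
    intron_track = _pr_to_track(introns_excl, "intron")
    exon_track = _pr_to_track(exons_excl, "exon")
    if len(intron_track) and len(promoters):
        residual = intron_track.to_pyranges().overlap(prom_pr)
        n_res = len(residual)
        if n_res:
            logger.info("exclusive hierarchy leaves %d intron intervals overlapping promoters", n_res)
    return (
        FeatureTrack(name="promoter", df=promoters.df.copy()),
        exon_track,
        intron_track,
    )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def annotate(
    sites: pd.DataFrame,
    tracks: list[FeatureTrack],
    sequences: dict[str, str] | None = None,
    flank: int = 200,
) -> pd.DataFrame:
    """Overlap flags, distances and window stats for each site.

    ``sites`` needs chrom and pos (1-based C).  Per track ``<name>`` the
    result carries ``in_<name>`` (bool) and ``dist_<name>`` (bp to the
    nearest interval on the same chromosome, 0 when overlapping, NaN when
    the chromosome has no interval).  Overlapping intervals within a track
    are merged first.
    """
    import pyranges as pr

    out = window_stats_table(sites, sequences=sequences, flank=flank)
    if len(sites) == 0:
        for t in tracks:
            out[f"in_{t.name}"] = pd.Series(dtype=bool)
            out[f"dist_{t.name}"] = pd.Series(dtype=float)
        return out
    site_pr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": sites["chrom"].astype(str),
                "Start": sites["pos"].astype(int) - 1,
                "End": sites["pos"].astype(int),
                "site_id": sites.index,
            }
        )
    )
    for track in tracks:
        in_col, dist_col = f"in_{track.name}", f"dist_{track.name}"
        if len(track) == 0:
            out[in_col] = False
            out[dist_col] = np.nan
            continue
        merged = _merged_pr(track)
        counts = site_pr.count_overlaps(merged).df.set_index("site_id")["NumberOverlaps"]
        out[in_col] = (counts.reindex(sites.index).fillna(0) > 0).to_numpy()
        near = site_pr.nearest(merged, overlap=True, apply_strand_suffix=False).df
        if len(near):
            near = near.set_index("site_id")
            dist = near["Distance"].astype(float)
            dist = np.maximum(dist - 1.0, 0.0)  # pyranges reports gap + 1
            out[dist_col] = dist.reindex(sites.index).to_numpy()
        else:
            out[dist_col] = np.nan
        out.loc[out[in_col], dist_col] = 0.0
    return out


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def naive_fold(prop_focal: float, prop_universe: float) -> tuple[float, str]:
    """Unadjusted fold enrichment/depletion between two proportions.

    Returns the ratio >= 1 and its direction ("enrichment" when the focal
    proportion exceeds the universe, "depletion" when below, "none" at
    equality).
    """
    if prop_focal <= 0 or prop_universe <= 0:
        raise ValueError("proportions must be > 0")
    if prop_focal > prop_universe:
        return prop_focal / prop_universe, "enrichment"
    if prop_focal < prop_universe:
        return prop_universe / prop_focal, "depletion"
    return 1.0, "none"


@dataclass
class EnrichmentResult:
    track: str
    observed: int
    resample_mean: float
    fold: float
    p_enrich: float
    p_deplete: float
    n_resamples: int
    group: str = ""


def density_matched_enrichment(
    focal_ids,
    annotations: pd.DataFrame,
    track_names: list[str],
    n_resamples: int = 1000,
    seed: int | np.random.Generator = 0,
    replace: bool = False,
    exclude_focal: bool = False,
    group: str = "",
) -> pd.DataFrame:
    """Feature enrichment of a focal CpG set against density-matched resamples.

    Each resample draws, for every focal site, a random universe site with
    identical ``local_cpg_density`` (exact integer match), without
    replacement within one resample by default; the focal sites themselves
    stay eligible unless ``exclude_focal``.  Per track the observed overlap
    count is compared with the resample distribution: fold =
    observed / mean(resample counts), p_enrich = fraction of resamples with
    count >= observed, p_deplete = fraction with count <= observed (ties
    count in both tails).

    ``annotations`` must index the universe (every focal id included) and
    carry ``local_cpg_density`` plus ``in_<track>`` flags.
    """
    focal_ids = pd.Index(focal_ids)
    missing = focal_ids.difference(annotations.index)
    if len(missing):
        raise ValueError(f"focal sites not in universe: {list(missing[:5])}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    densities = annotations["local_cpg_density"]
    focal_counts = densities.loc[focal_ids].value_counts()
    pool: dict[int, np.ndarray] = {}
    universe_pos = {sid: i for i, sid in enumerate(annotations.index)}
    for d, k in focal_counts.items():
        candidates = annotations.index[densities == d]
        if exclude_focal:
            candidates = candidates.difference(focal_ids)
        if (not replace and len(candidates) < k) or len(candidates) == 0:
            raise ValueError(
                f"density {d}: need {k} matched sites, universe offers {len(candidates)}"
            )
        pool[int(d)] = np.array([universe_pos[s] for s in candidates])

    membership = np.column_stack(
        [annotations[f"in_{t}"].to_numpy(dtype=bool) for t in track_names]
    )
    observed = membership[[universe_pos[s] for s in focal_ids]].sum(axis=0)

    counts = np.zeros((n_resamples, len(track_names)), dtype=int)
    for d, k in focal_counts.items():
        idx = pool[int(d)]
        if replace:
            picks = rng.integers(0, len(idx), size=(n_resamples, k))
        else:
            # k smallest of uniform randoms = uniform draw without replacement
            u = rng.random((n_resamples, len(idx)))
            picks = np.argsort(u, axis=1, kind="stable")[:, :k]
        chosen = idx[picks]  # (n_resamples, k)
        counts += membership[chosen].sum(axis=1)

    rows = []
    for t_i, t in enumerate(track_names):
        obs = int(observed[t_i])
        mean = float(counts[:, t_i].mean())
        fold = obs / mean if mean > 0 else float("nan")
        rows.append(
            {
                "group": group,
                "track": t,
                "observed": obs,
                "resample_mean": mean,
                "fold": fold,
                "p_enrich": float((counts[:, t_i] >= obs).mean()),
                "p_deplete": float((counts[:, t_i] <= obs).mean()),
                "n_resamples": n_resamples,
            }
        )
    return pd.DataFrame(rows)


def enrichment_by_group(
    pattern_calls: pd.DataFrame,
    annotations: pd.DataFrame,
    track_names: list[str],
    n_resamples: int = 1000,
    seed: int = 0,
    min_group_size: int = 5,
) -> pd.DataFrame:
    """Density-matched enrichment per (direction x pattern x magnitude bin) group.

    Groups mirror the biological stratification of changing CpGs: gain vs
    loss, discrete/continuous/other trajectory shape, moderate (5-30 point)
    vs large (>=30 point) net change.  Groups smaller than
    ``min_group_size`` are skipped.
    """
    rng = np.random.default_rng(seed)
    shared = pattern_calls.index.intersection(annotations.index)
    calls = pattern_calls.loc[shared]
    changed = calls[calls["status"] == "changed"]
    results = []
    for direction in ("increase", "decrease"):
        for pattern in ("discrete", "continuous", "other"):
            for bin_label, lo, hi in (("5-30", 5.0, 30.0), (">=30", 30.0, np.inf)):
                sel = changed[
                    (changed["direction"] == direction)
                    & (changed["pattern"] == pattern)
                    & (changed["total_change"].abs() > lo)
                    & (changed["total_change"].abs() <= hi if np.isfinite(hi) else True)
                ]
                if len(sel) < min_group_size:
                    continue
                label = f"{direction}/{pattern}/{bin_label}"
                res = density_matched_enrichment(
                    sel.index,
                    annotations,
                    track_names,
                    n_resamples=n_resamples,
                    seed=rng,
                    group=label,
                )
                results.append(res)
    if not results:
        return pd.DataFrame(
            columns=["group", "track", "observed", "resample_mean", "fold", "p_enrich", "p_deplete", "n_resamples"]
        )
    return pd.concat(results, ignore_index=True)
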