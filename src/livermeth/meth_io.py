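"""Readers, writers and the methylation matrix container.

The pipeline starts from per-sample, per-CpG bisulfite counts in the
Bismark coverage dialect (TAB-separated: chrom, start, end, percent
methylation, methylated count, unmethylated count; 1-based closed
coordinates, no header).  Feature tracks arrive as BED (0-based,
half-open).  Internally every site is a single plus-strand-anchored
cytosine addressed by its 1-based position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered postnatal age groups used throughout (embryonic day 18.5 to 9 weeks).
AGE_ORDER = ("E18.5", "P1", "P5", "P10", "P15", "P20", "9wk")

#: Tolerance (percentage points) for the coverage-file percent column check.
PERCENT_TOLERANCE = 0.1


@dataclass(frozen=True)
class CpGSite:
    """A cytosine assayed by bisulfite sequencing.

    ``pos`` is the 1-based coordinate of the plus-strand C; ``context`` is
    "CpG" (C followed by G) or "CpH" (C followed by A/C/T, the
    bisulfite-conversion control context).
    """

    chrom: str
    pos: int
    context: str = "CpG"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.context not in ("CpG", "CpH"):
            raise ValueError(f"context must be CpG or CpH, got {self.context!r}")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass(frozen=True)
class SampleMeta:
    """Sample-sheet record: id, ordered age group, tissue and cohort."""

    sample_id: str
    age_group: str
    tissue: str = "liver"
    cohort: str = "discovery"

    def __post_init__(self) -> None:
        if self.age_group not in AGE_ORDER:
            raise ValueError(
                f"unknown age group {self.age_group!r}; expected one of {AGE_ORDER}"
            )


@dataclass
class FeatureTrack:
    """A named set of genomic intervals with BED semantics (0-based, half-open)."""

    name: str
    df: pd.DataFrame  # columns: chrom, start, end[, strand]

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"track {self.name!r} missing columns {required - set(self.df.columns)}")
        if len(self.df) and (self.df["start"] >= self.df["end"]).any():
            raise ValueError(f"track {self.name!r} contains empty or inverted intervals")
        self.df = self.df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def to_pyranges(self):
        import pyranges as pr

        if len(self.df) == 0:
            return pr.PyRanges()
        cols = {"Chromosome": self.df["chrom"], "Start": self.df["start"], "End": self.df["end"]}
        if "strand" in self.df.columns:
            cols["Strand"] = self.df["strand"]
        return pr.PyRanges(pd.DataFrame(cols))


def _ordered_age_categorical(values: Iterable[str]) -> pd.Categorical:
    return pd.Categorical(list(values), categories=list(AGE_ORDER), ordered=True)


@dataclass
class MethylationMatrix:
    """Sites x samples grid of bisulfite counts with an explicit missingness mask.

    ``meth``/``total`` hold methylated and total read counts; ``masked`` marks
    cells treated as missing (zero coverage at build time, later low-coverage
    masking).  Fractions are defined only on unmasked cells with positive
    coverage.
    """

    sites: pd.DataFrame  # index site_id; columns chrom, pos, context
    samples: pd.DataFrame  # index sample_id; columns age_group, tissue, cohort
    meth: np.ndarray
    total: np.ndarray
    masked: np.ndarray

    def __post_init__(self) -> None:
        n_sites, n_samples = len(self.sites), len(self.samples)
        for name in ("meth", "total", "masked"):
            arr = getattr(self, name)
            if arr.shape != (n_sites, n_samples):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {(n_sites, n_samples)}"
                )
        if np.any(self.meth < 0) or np.any(self.meth > self.total):
            raise ValueError("methylated counts must satisfy 0 <= meth <= total")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def fraction(self) -> np.ndarray:
        """Methylated fraction in [0, 1]; NaN where masked or uncovered."""
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = self.meth / self.total
        frac = np.where(self.masked | (self.total == 0), np.nan, frac)
        return frac

    @property
    def percent(self) -> np.ndarray:
        """Methylation percentage in [0, 100]; NaN where missing."""
        return 100.0 * self.fraction

    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def site_ids(self) -> list[str]:
        return list(self.sites.index)

    def select_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        idx = [self.samples.index.get_loc(s) for s in sample_ids]
        return MethylationMatrix(
            sites=self.sites.copy(),
            samples=self.samples.iloc[idx].copy(),
            meth=self.meth[:, idx].copy(),
            total=self.total[:, idx].copy(),
            masked=self.masked[:, idx].copy(),
        )

    def select_sites(self, keep: np.ndarray | Sequence[str]) -> "MethylationMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            rows = np.flatnonzero(keep)
        else:
            rows = np.array([self.sites.index.get_loc(s) for s in keep])
        return MethylationMatrix(
            sites=self.sites.iloc[rows].copy(),
            samples=self.samples.copy(),
            meth=self.meth[rows].copy(),
            total=self.total[rows].copy(),
            masked=self.masked[rows].copy(),
        )

    def with_mask(self, masked: np.ndarray) -> "MethylationMatrix":
        return MethylationMatrix(
            sites=self.sites.copy(),
            samples=self.samples.copy(),
            meth=self.meth.copy(),
            total=self.total.copy(),
            masked=masked.copy(),
        )

    def samples_in_group(self, age_group: str) -> list[str]:
        return list(self.samples.index[self.samples["age_group"] == age_group])


class CoverageFormatError(ValueError):
    """Raised for structurally invalid coverage/BED lines (carries line number)."""


def read_bismark_coverage(path: str | Path, context: str = "CpG") -> list[tuple[CpGSite, int, int]]:
    """Parse one Bismark coverage file into (site, methylated, total) records.

    The percent column is cross-checked against the counts; a mismatch beyond
    0.1 percentage points is logged as a warning and the counts win.
    Structural problems (wrong column count, non-integer counts) raise
    :class:`CoverageFormatError` naming the offending line.
    """
    path = Path(path)
    records: list[tuple[CpGSite, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise CoverageFormatError(
                    f"{path.name} line {lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            chrom, start_s, _end_s, pct_s, meth_s, unmeth_s = fields
            try:
                start = int(start_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
                pct = float(pct_s)
            except ValueError as exc:
                raise CoverageFormatError(f"{path.name} line {lineno}: {exc}") from None
            if meth < 0 or unmeth < 0:
                raise CoverageFormatError(f"{path.name} line {lineno}: negative count")
            total = meth + unmeth
            if total > 0 and abs(pct - 100.0 * meth / total) > PERCENT_TOLERANCE:
                logger.warning(
                    "%s line %d: percent column %.3f disagrees with counts (%.3f); trusting counts",
                    path.name, lineno, pct, 100.0 * meth / total,
                )
            records.append((CpGSite(chrom, start, context=context), meth, total))
    return records


def read_bed(path: str | Path, name: str | None = None) -> FeatureTrack:
    """Read a BED3/BED6 file into a :class:`FeatureTrack` (sorted, half-open)."""
    path = Path(path)
    rows = []
    has_strand = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CoverageFormatError(
                    f"{path.name} line {lineno}: BED needs >= 3 fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise CoverageFormatError(f"{path.name} line {lineno}: {exc}") from None
            if start >= end:
                raise CoverageFormatError(
                    f"{path.name} line {lineno}: start {start} >= end {end}"
                )
            row = {"chrom": fields[0], "start": start, "end": end}
            if len(fields) >= 6:
                row["strand"] = fields[5]
                has_strand = True
            rows.append(row)
    cols = ["chrom", "start", "end"] + (["strand"] if has_strand else [])
    df = pd.DataFrame(rows, columns=cols)
    if not has_strand and "strand" in df.columns:
        df = df.drop(columns="strand")
    return FeatureTrack(name=name or path.stem, df=df)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a TSV sample sheet (sample_id, age_group, tissue, cohort)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "age_group", "tissue", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    bad = set(df["age_group"]) - set(AGE_ORDER)
    if bad:
        raise ValueError(f"unknown age groups in sample sheet: {sorted(bad)}")
    df = df.set_index("sample_id")
    df["age_group"] = _ordered_age_categorical(df["age_group"])
    return df


def build_matrix(
    records: Mapping[str, list[tuple[CpGSite, int, int]]],
    samples: pd.DataFrame | Sequence[SampleMeta],
) -> MethylationMatrix:
    """Assemble per-sample coverage records into a :class:`MethylationMatrix`.

    The site universe is the union over samples; absent (site, sample) pairs
    get total=0 and are masked.  Sites covered in no sample are dropped with
    a logged count.  A duplicate (chrom, pos) within one sample is an error.
    """
    if not isinstance(samples, pd.DataFrame):
        if len(samples) == 0:
            raise ValueError("cannot build a matrix with zero samples")
        samples = pd.DataFrame(
            [
                {"sample_id": s.sample_id, "age_group": s.age_group, "tissue": s.tissue, "cohort": s.cohort}
                for s in samples
            ]
        ).set_index("sample_id")
        samples["age_group"] = _ordered_age_categorical(samples["age_group"])
    if len(samples) == 0:
        raise ValueError("cannot build a matrix with zero samples")
    missing_samples = set(samples.index) - set(records)
    if missing_samples:
        raise ValueError(f"no records supplied for samples: {sorted(missing_samples)}")

    site_index: dict[str, CpGSite] = {}
    for sample_id in samples.index:
        seen: set[str] = set()
        for site, _m, _t in records[sample_id]:
            if site.site_id in seen:
                raise ValueError(
                    f"duplicate site {site.site_id} in sample {sample_id!r}"
                )
            seen.add(site.site_id)
            site_index.setdefault(site.site_id, site)

    sites_sorted = sorted(site_index.values(), key=lambda s: (s.chrom, s.pos))
    row_of = {s.site_id: i for i, s in enumerate(sites_sorted)}
    n_sites, n_samples = len(sites_sorted), len(samples)
    meth = np.zeros((n_sites, n_samples), dtype=np.int64)
    total = np.zeros((n_sites, n_samples), dtype=np.int64)
    for j, sample_id in enumerate(samples.index):
        for site, m, t in records[sample_id]:
            i = row_of[site.site_id]
            meth[i, j] = m
            total[i, j] = t
    masked = total == 0

    covered_somewhere = (total > 0).any(axis=1)
    n_dropped = int((~covered_somewhere).sum())
    if n_dropped:
        logger.info("dropping %d sites with zero coverage in every sample", n_dropped)
    keep = np.flatnonzero(covered_somewhere)

    sites_df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites_sorted],
            "pos": [s.pos for s in sites_sorted],
            "context": [s.context for s in sites_sorted],
        },
        index=[s.site_id for s in sites_sorted],
    ).iloc[keep]
    return MethylationMatrix(
        sites=sites_df,
        samples=samples.copy(),
        meth=meth[keep],
        total=total[keep],
        masked=masked[keep],
    )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a result table as TSV with header (lossless, re-readable)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
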