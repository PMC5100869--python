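"""Synthetic RRBS data generator.

Emulates the structure of a reduced-representation bisulfite experiment on
postnatal mouse liver: a random genome, an in-silico MspI digest (C^CGG)
with 150-600 bp size selection, the CpG panel reachable by 50 bp reads from
fragment ends, per-cell-type methylation trajectories across ordered age
groups, a two-cell-type mixture (hepatocyte lineage vs hematopoietic cells)
whose proportions follow the histology of developing liver, a cell-division
hemimethylation dilution, bisulfite non-conversion noise, and
negative-binomial read coverage.  Output is written in the Bismark coverage
dialect so the whole downstream pipeline is exercisable offline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .meth_io import AGE_ORDER, CpGSite, SampleMeta

_BASES = np.array(list("ACGT"))

#: Hematopoietic cell percentage of liver by age (histology; 9 wk extended at 0).
TABLE1_HEMATOPOIETIC = {
    "E18.5": 0.48,
    "P1": 0.62,
    "P5": 0.38,
    "P10": 0.04,
    "P15": 0.01,
    "P20": 0.00,
    "9wk": 0.00,
}


@dataclass(frozen=True)
class SyntheticGenome:
    """A single-contig random genome standing in for a reference assembly."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("genome must be non-empty")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("genome sequence must contain only A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Fragment:
    """A digest fragment as a 0-based half-open interval [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid fragment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TrajectoryConfig:
    """Ground-truth trajectory sampling parameters.

    Defaults follow the observed structure of the postnatal liver methylome:
    ~79% of retained CpGs change with age, 89% of changes are gains, total
    magnitudes reach ~88 percentage points, and most change is concentrated
    after P5.
    """

    age_groups: tuple[str, ...] = AGE_ORDER
    change_fraction: float = 0.79
    gain_bias: float = 0.89
    magnitude_range: tuple[float, float] = (5.0, 88.0)  # percentage points
    pattern_mix: dict = field(
        default_factory=lambda: {"discrete": 0.5, "continuous": 0.3, "other": 0.2}
    )
    # Probability that the dominant change interval is each consecutive age
    # pair; default puts most mass after P5 (intervals indexed from the first
    # age pair).  None -> built from age_groups at validation.
    onset_distribution: tuple[float, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.change_fraction <= 1.0:
            raise ValueError("change_fraction must be in [0,1]")
        if not 0.0 <= self.gain_bias <= 1.0:
            raise ValueError("gain_bias must be in [0,1]")
        lo, hi = self.magnitude_range
        if not (0.0 <= lo <= hi <= 100.0):
            raise ValueError("magnitude_range must satisfy 0 <= lo <= hi <= 100")
        if len(self.age_groups) < 2:
            raise ValueError("need at least two age groups")
        if abs(sum(self.pattern_mix.values()) - 1.0) > 1e-9:
            raise ValueError("pattern_mix must sum to 1")
        if any(p < 0 for p in self.pattern_mix.values()):
            raise ValueError("pattern_mix probabilities must be >= 0")
        onset = self.resolved_onset()
        if len(onset) != len(self.age_groups) - 1:
            raise ValueError("onset_distribution length must be n_ages - 1")
        if abs(sum(onset) - 1.0) > 1e-9 or any(p < 0 for p in onset):
            raise ValueError("onset_distribution must be a probability vector")

    def resolved_onset(self) -> tuple[float, ...]:
        if self.onset_distribution is not None:
            return tuple(self.onset_distribution)
        # Mass concentrated on intervals after P5: weight 1 for pairs whose
        # left age is at or after P5, 0.1 before (uniform if P5 absent).
        if "P5" in self.age_groups:
            p5 = self.age_groups.index("P5")
            weights = [1.0 if i >= p5 else 0.1 for i in range(len(self.age_groups) - 1)]
        else:
            weights = [1.0] * (len(self.age_groups) - 1)
        w = np.asarray(weights, dtype=float)
        return tuple(w / w.sum())


@dataclass
class CellCompositionSchedule:
    """Per-age hematopoietic and dividing-cell fractions of the tissue."""

    hematopoietic: dict
    dividing: dict

    @classmethod
    def default(cls, age_groups: Sequence[str] = AGE_ORDER) -> "CellCompositionSchedule":
        """Histology-based hematopoietic fractions; dividing fraction declines
        linearly from 0.10 at the first age to 0 at the last."""
        ages = list(age_groups)
        n = len(ages)
        dividing = {
            a: 0.10 * (1 - i / (n - 1)) if n > 1 else 0.10 for i, a in enumerate(ages)
        }
        hema = {a: TABLE1_HEMATOPOIETIC.get(a, 0.0) for a in ages}
        return cls(hematopoietic=hema, dividing=dividing)

    @classmethod
    def neutral(cls, age_groups: Sequence[str] = AGE_ORDER) -> "CellCompositionSchedule":
        """Pure hepatocyte-lineage tissue with no dividing cells."""
        return cls(
            hematopoietic={a: 0.0 for a in age_groups},
            dividing={a: 0.0 for a in age_groups},
        )

    def validate(self, age_groups: Sequence[str]) -> None:
        for a in age_groups:
            for d in (self.hematopoietic, self.dividing):
                if a not in d:
                    raise ValueError(f"schedule missing age group {a!r}")
                if not 0.0 <= d[a] <= 1.0:
                    raise ValueError(f"fraction for {a!r} out of [0,1]")


@dataclass
class NoiseModel:
    """Bisulfite non-conversion and read-coverage model.

    ``nonconversion_rate`` is the probability an unmethylated cytosine reads
    as methylated; coverage is negative-binomial with the given mean and
    dispersion (Poisson when ``coverage_dispersion`` is None/inf).
    """

    nonconversion_rate: float = 0.005
    coverage_mean: float = 40.0
    coverage_dispersion: float | None = 10.0

    def validate(self) -> None:
        if not 0.0 <= self.nonconversion_rate <= 0.05:
            raise ValueError("nonconversion_rate must be in [0, 0.05]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if self.coverage_dispersion is not None and self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be > 0 or None")

    def draw_coverage(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.coverage_dispersion is None or np.isinf(self.coverage_dispersion):
            return rng.poisson(self.coverage_mean, size=size)
        k = self.coverage_dispersion
        p = k / (k + self.coverage_mean)
        return rng.negative_binomial(k, p, size=size)


def generate_genome(
    length: int,
    gc_fraction: float = 0.42,
    ccgg_boost: float = 1.0,
    seed: int = 0,
    name: str = "chrS",
) -> SyntheticGenome:
    """Random genome with a target GC fraction and optional extra CCGG motifs.

    ``ccgg_boost`` multiplies the background CCGG occurrence rate by planting
    additional motifs at random positions (1.0 = no planting).
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0,1)")
    if ccgg_boost < 1.0:
        raise ValueError("ccgg_boost must be >= 1")
    rng = np.random.default_rng(seed)
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    seq = rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    if ccgg_boost > 1.0:
        base_rate = (gc_fraction / 2.0) ** 4
        n_extra = rng.poisson((ccgg_boost - 1.0) * base_rate * length)
        if n_extra > 0:
            starts = rng.integers(0, length - 3, size=n_extra)
            for s in starts:
                seq[s : s + 4] = list("CCGG")
    return SyntheticGenome(name=name, sequence="".join(seq))


def mspi_digest(genome: SyntheticGenome) -> list[Fragment]:
    """In-silico MspI digest: cut after the first C of every CCGG (C^CGG).

    Fragments tile the genome without gaps or overlaps.
    """
    seq = genome.sequence
    cuts = [0]
    start = 0
    while True:
        i = seq.find("CCGG", start)
        if i < 0:
            break
        cuts.append(i + 1)  # cut between the two Cs
        start = i + 1
    cuts.append(len(seq))
    # A CCGG at position 0 would yield a cut at 1 after the leading 0.
    uniq = sorted(set(cuts))
    return [Fragment(a, b) for a, b in zip(uniq[:-1], uniq[1:])]


def size_select(
    fragments: Sequence[Fragment], min_len: int = 150, max_len: int = 600
) -> list[Fragment]:
    """Gel size selection with inclusive bounds [min_len, max_len]."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [f for f in fragments if min_len <= f.length <= max_len]


def enumerate_assayed_cpgs(
    genome: SyntheticGenome,
    selected_fragments: Sequence[Fragment],
    read_length: int = 50,
) -> list[CpGSite]:
    """CpGs reachable by single-end reads from either end of each fragment.

    A CpG (anchored at its plus-strand C, reported 1-based) is assayed when
    the C lies within ``read_length`` bases of a fragment end.  Sorted,
    deduplicated.
    """
    seq = genome.sequence
    positions: set[int] = set()
    for frag in selected_fragments:
        for i in range(frag.start, frag.end):
            if seq[i] == "C" and i + 1 < len(seq) and seq[i + 1] == "G":
                dist_start = i - frag.start
                dist_end = frag.end - 1 - i
                if min(dist_start, dist_end) < read_length:
                    positions.add(i + 1)  # 1-based C
    return [CpGSite(genome.name, p) for p in sorted(positions)]


# ---------------------------------------------------------------------------
# Ground-truth trajectories
# ---------------------------------------------------------------------------

def _pattern_steps(pattern: str, n_intervals: int, onset: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-normalized signed step profile (sums to 1) realizing a pattern."""
    steps = np.zeros(n_intervals)
    if pattern == "discrete" or n_intervals == 1:
        steps[onset] = 1.0
    elif pattern == "continuous":
        # Monotone with every step below half the total travel; mild random
        # weights keep trajectories from being perfectly linear.
        w = rng.uniform(0.5, 1.5, size=n_intervals)
        w = w / w.sum()
        if n_intervals >= 3:
            w = np.clip(w, None, 0.45)
            w = w / w.sum()
        steps = w
    elif pattern == "other":
        if n_intervals < 3:
            steps[onset] = 1.0  # cannot realize a zigzag; degrade to discrete
        else:
            # Zigzag: non-monotone, net +1, no step reaching half the path.
            base = [0.45, -0.25, 0.45, -0.25, 0.45, 0.15]
            prof = np.zeros(n_intervals)
            for i in range(n_intervals):
                prof[i] = base[i % len(base)]
            prof = prof / prof.sum()
            # Guard: keep max |step| under half the path length.
            path = np.abs(prof).sum()
            if np.abs(prof).max() >= 0.5 * path:
                prof = np.array([0.4, -0.2, 0.4, -0.2, 0.6][:n_intervals])
                prof = prof / prof.sum()
            steps = prof
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return steps


def assign_trajectories(
    sites: Sequence[CpGSite],
    config: TrajectoryConfig,
    schedule: CellCompositionSchedule | None = None,
    hematopoietic_mode: str = "independent",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sample ground-truth methylation trajectories for each site.

    Returns ``(hep, hema, truth)``: hepatocyte-lineage and hematopoietic
    per-age true methylation fractions (sites x ages, values in [0,1]) and a
    truth table (changed, direction, pattern, total_change in percentage
    points, dominant_interval, baseline).

    ``hematopoietic_mode`` is "independent" (each site gets an independent
    constant hematopoietic methylation level) or "mirror" (equal to the
    hepatocyte baseline, making the mixture composition-neutral).
    """
    config.validate()
    if schedule is None:
        schedule = CellCompositionSchedule.default(config.age_groups)
    schedule.validate(config.age_groups)
    if hematopoietic_mode not in ("independent", "mirror"):
        raise ValueError("hematopoietic_mode must be 'independent' or 'mirror'")

    rng = np.random.default_rng(config.seed)
    ages = list(config.age_groups)
    n_sites, n_ages = len(sites), len(ages)
    n_intervals = n_ages - 1
    onset_p = np.asarray(config.resolved_onset())

    changed = rng.random(n_sites) < config.change_fraction
    increase = rng.random(n_sites) < config.gain_bias
    lo, hi = config.magnitude_range
    magnitude = rng.uniform(lo, hi, size=n_sites) / 100.0  # fraction scale
    patterns = rng.choice(
        list(config.pattern_mix.keys()), size=n_sites, p=list(config.pattern_mix.values())
    )
    onsets = rng.choice(n_intervals, size=n_sites, p=onset_p)

    # Baseline methylation: bimodal, like a real methylome (a low-methylation
    # mode that the never-methylated filter will catch, and a broad
    # intermediate/high mode).
    low_mode = rng.random(n_sites) < 0.25
    baseline = np.where(
        low_mode, rng.uniform(0.0, 0.08, size=n_sites), rng.uniform(0.15, 0.95, size=n_sites)
    )

    hep = np.tile(baseline[:, None], (1, n_ages))
    truth_rows = []
    for s in range(n_sites):
        if not changed[s]:
            truth_rows.append(
                ("unchanged", "none", "none", 0.0, "none", baseline[s])
            )
            continue
        sign = 1.0 if increase[s] else -1.0
        mag = magnitude[s]
        # Keep the trajectory inside [0,1]: shift the baseline if needed.
        b = baseline[s]
        steps = _pattern_steps(patterns[s], n_intervals, int(onsets[s]), rng) * sign * mag
        traj = b + np.concatenate([[0.0], np.cumsum(steps)])
        overshoot_hi = traj.max() - 1.0
        overshoot_lo = -traj.min()
        if overshoot_hi > 0:
            traj = traj - overshoot_hi
        elif overshoot_lo > 0:
            traj = traj + overshoot_lo
        traj = np.clip(traj, 0.0, 1.0)
        hep[s] = traj
        direction = "increase" if sign > 0 else "decrease"
        interval = f"{ages[onsets[s]]}-{ages[onsets[s] + 1]}" if patterns[s] == "discrete" else "none"
        truth_rows.append(
            ("changed", direction, patterns[s], sign * mag * 100.0, interval, traj[0])
        )

    if hematopoietic_mode == "independent":
        hema_level = np.where(
            rng.random(n_sites) < 0.25,
            rng.uniform(0.0, 0.08, size=n_sites),
            rng.uniform(0.15, 0.95, size=n_sites),
        )
    else:
        hema_level = hep[:, 0]
    hema = np.tile(hema_level[:, None], (1, n_ages))

    idx = [s.site_id for s in sites]
    hep_df = pd.DataFrame(hep, index=idx, columns=ages)
    hema_df = pd.DataFrame(hema, index=idx, columns=ages)
    truth = pd.DataFrame(
        truth_rows,
        index=idx,
        columns=["status", "direction", "pattern", "total_change", "dominant_interval", "baseline"],
    )
    return hep_df, hema_df, truth


def mixture_methylation(
    m_parenchyma: float | np.ndarray,
    m_hematopoietic: float | np.ndarray,
    hsc_fraction: float,
) -> float | np.ndarray:
    """Bulk methylation of a two-cell-type mixture (linear blend)."""
    for name, v in (
        ("m_parenchyma", m_parenchyma),
        ("m_hematopoietic", m_hematopoietic),
        ("hsc_fraction", hsc_fraction),
    ):
        arr = np.asarray(v, dtype=float)
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"{name} out of [0,1]")
    return hsc_fraction * np.asarray(m_hematopoietic, dtype=float) + (
        1.0 - hsc_fraction
    ) * np.asarray(m_parenchyma, dtype=float)


def division_dilution(m: float | np.ndarray, dividing_fraction: float) -> float | np.ndarray:
    """Hemimethylation dilution by active cell division.

    Immediately after replication the nascent strand is unmethylated, so a
    dividing cell contributes half its molecules unmethylated: observed
    methylation is m * (1 - dividing_fraction / 2).
    """
    arr = np.asarray(m, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("m out of [0,1]")
    if not 0.0 <= dividing_fraction <= 1.0:
        raise ValueError("dividing_fraction out of [0,1]")
    out = arr * (1.0 - dividing_fraction / 2.0)
    return float(out) if np.isscalar(m) else out


def simulate_counts(
    m_true: np.ndarray,
    noise: NoiseModel,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (methylated, total) read counts for true methylation fractions.

    Observed read-level methylation probability is
    ``p = m + (1 - m) * nonconversion_rate``; total coverage follows the
    noise model's count distribution (zero coverage means missing).
    """
    noise.validate()
    m = np.asarray(m_true, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("m_true out of [0,1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = noise.draw_coverage(rng, m.shape)
    p = m + (1.0 - m) * noise.nonconversion_rate
    meth = rng.binomial(total, p)
    return meth, total


def simulate_cph_panel(
    genome: SyntheticGenome,
    n_sites: int,
    noise: NoiseModel,
    n_samples: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a non-CpG cytosine (CpH) conversion-control panel.

    True CpH methylation is zero everywhere; apparently methylated calls
    arise only from bisulfite non-conversion.  Returns a long DataFrame with
    columns site_id, chrom, pos, sample, meth, total.
    """
    noise.validate()
    seq = genome.sequence
    cph_pos = [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] == "C" and seq[i + 1] != "G"
    ]
    if len(cph_pos) < n_sites:
        raise ValueError(
            f"genome has only {len(cph_pos)} CpH cytosines, need {n_sites}"
        )
    if n_sites == 0:
        return pd.DataFrame(columns=["site_id", "chrom", "pos", "sample", "meth", "total"])
    rng = np.random.default_rng(seed)
    pos = np.array(cph_pos[:n_sites])
    rows = []
    for j in range(n_samples):
        meth, total = simulate_counts(np.zeros(n_sites), noise, rng)
        for p, m, t in zip(pos, meth, total):
            rows.append((f"{genome.name}:{p}", genome.name, int(p), f"sample_{j + 1}", int(m), int(t)))
    return pd.DataFrame(rows, columns=["site_id", "chrom", "pos", "sample", "meth", "total"])


def estimate_conversion_rate(panel: pd.DataFrame) -> pd.Series:
    """Per-sample conversion rate: 1 - methylated/total over the CpH panel."""
    grouped = panel.groupby("sample")[["meth", "total"]].sum()
    return 1.0 - grouped["meth"] / grouped["total"]


# ---------------------------------------------------------------------------
# Dataset writer
# ---------------------------------------------------------------------------

@dataclass
class DatasetConfig:
    """Everything needed to synthesize one cohort of coverage files."""

    genome_length: int = 200_000
    gc_fraction: float = 0.42
    ccgg_boost: float = 1.0
    age_groups: tuple[str, ...] = AGE_ORDER
    # replicates per age group: one int for all ages, or a per-age mapping
    n_replicates: int | dict = 5
    cohort: str = "discovery"
    tissue: str = "liver"
    trajectory: TrajectoryConfig | None = None
    schedule: CellCompositionSchedule | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    hematopoietic_mode: str = "independent"
    seed: int = 0


def simulate_dataset(config: DatasetConfig):
    """Run the full generative model in memory.

    Returns ``(genome, sites, sample_meta, meth, total, truth, hep, hema)``
    where ``meth``/``total`` are (n_sites, n_samples) arrays.
    """
    traj_cfg = config.trajectory or TrajectoryConfig(
        age_groups=config.age_groups, seed=config.seed
    )
    if tuple(traj_cfg.age_groups) != tuple(config.age_groups):
        raise ValueError("trajectory age_groups must match dataset age_groups")
    schedule = config.schedule or CellCompositionSchedule.default(config.age_groups)
    config.noise.validate()

    genome = generate_genome(
        config.genome_length, config.gc_fraction, config.ccgg_boost, seed=config.seed
    )
    fragments = size_select(mspi_digest(genome))
    sites = enumerate_assayed_cpgs(genome, fragments)
    hep, hema, truth = assign_trajectories(
        sites, traj_cfg, schedule, hematopoietic_mode=config.hematopoietic_mode
    )

    ages = list(config.age_groups)
    reps = (
        config.n_replicates
        if isinstance(config.n_replicates, dict)
        else {a: config.n_replicates for a in ages}
    )
    samples = [
        SampleMeta(
            sample_id=f"{config.cohort}_{age}_r{r + 1}",
            age_group=age,
            tissue=config.tissue,
            cohort=config.cohort,
        )
        for age in ages
        for r in range(reps[age])
    ]
    n_sites, n_samples = len(sites), len(samples)
    meth = np.zeros((n_sites, n_samples), dtype=np.int64)
    total = np.zeros((n_sites, n_samples), dtype=np.int64)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    for j, sm in enumerate(samples):
        age = sm.age_group
        bulk = mixture_methylation(
            hep[age].to_numpy(), hema[age].to_numpy(), schedule.hematopoietic[age]
        )
        bulk = division_dilution(bulk, schedule.dividing[age])
        meth[:, j], total[:, j] = simulate_counts(bulk, config.noise, rng)
    return genome, sites, samples, meth, total, truth, hep, hema


def write_dataset(config: DatasetConfig, outdir: str | Path) -> dict:
    """Write one coverage file per sample plus sample sheet and truth tables.

    Rows with zero coverage are omitted from coverage files (they are missing
    observations).  Output is byte-deterministic given the config seed.
    Returns a manifest of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, sites, samples, meth, total, truth, hep, hema = simulate_dataset(config)

    coverage_paths = []
    for j, sm in enumerate(samples):
        path = outdir / f"{sm.sample_id}.cov"
        with open(path, "w") as fh:
            for i, site in enumerate(sites):
                t = total[i, j]
                if t == 0:
                    continue
                m = meth[i, j]
                pct = 100.0 * m / t
                fh.write(f"{site.chrom}\t{site.pos}\t{site.pos}\t{pct:.1f}\t{m}\t{t - m}\n")
        coverage_paths.append(path)

    sheet_path = outdir / "samples.tsv"
    with open(sheet_path, "w") as fh:
        fh.write("sample_id\tage_group\ttissue\tcohort\n")
        for sm in samples:
            fh.write(f"{sm.sample_id}\t{sm.age_group}\t{sm.tissue}\t{sm.cohort}\n")

    truth_path = outdir / "truth.tsv"
    truth_out = truth.copy()
    truth_out.index.name = "site_id"
    truth_out.to_csv(truth_path, sep="\t", float_format="%.6g")

    traj_path = outdir / "truth_trajectories.tsv"
    hep_out = hep.copy()
    hep_out.index.name = "site_id"
    hep_out.to_csv(traj_path, sep="\t", float_format="%.6g")

    fasta_path = outdir / "genome.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, genome.length, 80):
            fh.write(genome.sequence[i : i + 80] + "\n")

    return {
        "coverage": coverage_paths,
        "sample_sheet": sheet_path,
        "truth": truth_path,
        "trajectories": traj_path,
        "genome": fasta_path,
        "n_sites": len(sites),
        "n_samples": len(samples),
    }
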