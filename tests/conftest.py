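"""Shared fixtures: hand-built matrices and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from livermeth import simulate as sim
from livermeth.meth_io import AGE_ORDER, MethylationMatrix, SampleMeta, build_matrix


def make_matrix(
    percent: np.ndarray,
    total: np.ndarray | int = 100,
    ages: list[str] | None = None,
    cohort: str = "discovery",
) -> MethylationMatrix:
    """Build a matrix from a (sites x samples) percent grid and coverage.

    NaN percent marks a zero-coverage (missing) cell.  Counts are rounded,
    so pick coverage values that represent the percents exactly when
    exactness matters.
    """
    percent = np.asarray(percent, dtype=float)
    n_sites, n_samples = percent.shape
    if np.isscalar(total) or np.ndim(total) == 0:
        total = np.full(percent.shape, int(total))
    total = np.asarray(total)
    total = np.where(np.isnan(percent), 0, total).astype(np.int64)
    meth = np.where(total > 0, np.round(np.nan_to_num(percent) / 100.0 * total), 0).astype(np.int64)
    if ages is None:
        ages = ["E18.5"] * (n_samples // 2) + ["9wk"] * (n_samples - n_samples // 2)
    samples = pd.DataFrame(
        {
            "age_group": pd.Categorical(ages, categories=list(AGE_ORDER), ordered=True),
            "tissue": "liver",
            "cohort": cohort,
        },
        index=[f"s{j}" for j in range(n_samples)],
    )
    samples.index.name = "sample_id"
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_sites + 1) * 10,
            "context": "CpG",
        },
        index=[f"chr1:{p}" for p in np.arange(1, n_sites + 1) * 10],
    )
    return MethylationMatrix(
        sites=sites, samples=samples, meth=meth, total=total, masked=total == 0
    )


@pytest.fixture(scope="session")
def two_age_cohort():
    """A small composition-neutral two-age cohort with known truth."""
    ages = ("E18.5", "9wk")
    cfg = sim.DatasetConfig(
        genome_length=120_000,
        age_groups=ages,
        n_replicates=5,
        schedule=sim.CellCompositionSchedule.neutral(ages),
        trajectory=sim.TrajectoryConfig(
            age_groups=ages, magnitude_range=(15.0, 60.0), seed=11
        ),
        seed=11,
    )
    genome, sites, samples, meth, total, truth, hep, hema = sim.simulate_dataset(cfg)
    records = {
        sm.sample_id: [
            (s, int(meth[i, j]), int(total[i, j]))
            for i, s in enumerate(sites)
            if total[i, j] > 0
        ]
        for j, sm in enumerate(samples)
    }
    matrix = build_matrix(records, samples)
    return {
        "config": cfg,
        "genome": genome,
        "matrix": matrix,
        "truth": truth,
        "meth": meth,
        "total": total,
        "sites": sites,
    }
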