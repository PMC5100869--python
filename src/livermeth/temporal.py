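"""Time-course analysis across ordered age groups.

Builds per-site trajectories of group-mean methylation, computes
consecutive-interval deltas, counts sites with large changes per interval,
cross-tabulates sustained changes across intervals, and classifies each
changing trajectory as discrete, continuous, or other.

Classification rule: the total methylation change of a trajectory is its
path length (the sum of absolute consecutive deltas; equal to the net
change for monotone trajectories).  A trajectory is *discrete* when a
single consecutive interval in the direction of the net change carries at
least half of that total; *continuous* when it is monotone (zero steps
allowed) with every step below half the total; *other* otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meth_io import AGE_ORDER, MethylationMatrix

logger = logging.getLogger(__name__)


def age_trajectories(
    matrix: MethylationMatrix,
    ages: list[str] | None = None,
    site_whitelist: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site, per-age mean percent methylation and observation counts.

    Ages with no unmasked observation at a site are NaN in the means table.
    ``site_whitelist`` restricts to a designated discovery-significant set.
    """
    if ages is None:
        present = set(matrix.samples["age_group"].astype(str))
        ages = [a for a in AGE_ORDER if a in present]
    if len(ages) < 2:
        raise ValueError("need at least two age groups with samples")
    pct = matrix.percent
    means = np.full((matrix.n_sites, len(ages)), np.nan)
    counts = np.zeros((matrix.n_sites, len(ages)), dtype=int)
    for j, age in enumerate(ages):
        cols = [matrix.samples.index.get_loc(s) for s in matrix.samples_in_group(age)]
        if not cols:
            raise ValueError(f"age group {age!r} has no samples")
        sub = pct[:, cols]
        n = (~np.isnan(sub)).sum(axis=1)
        counts[:, j] = n
        with np.errstate(invalid="ignore"):
            means[:, j] = np.where(n > 0, np.nanmean(sub, axis=1), np.nan)
    means_df = pd.DataFrame(means, index=matrix.sites.index, columns=ages)
    counts_df = pd.DataFrame(counts, index=matrix.sites.index, columns=ages)
    if site_whitelist is not None:
        keep = means_df.index.intersection(pd.Index(site_whitelist))
        means_df, counts_df = means_df.loc[keep], counts_df.loc[keep]
    return means_df, counts_df


def consecutive_changes(values) -> np.ndarray:
    """Signed deltas between consecutive ages with data.

    NaN entries (ages with no observations) are skipped so deltas bridge the
    gap; the deltas telescope to last-minus-first observed mean.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise ValueError("need at least two ages with data")
    return np.diff(v)


def interval_labels(ages: list[str]) -> list[str]:
    return [f"{a}-{b}" for a, b in zip(ages[:-1], ages[1:])]


def count_interval_changes(
    means: pd.DataFrame, threshold: float = 30.0
) -> pd.DataFrame:
    """Per consecutive interval: number of sites gaining / losing >= threshold points.

    The bound is inclusive ("30% or more").  A site can contribute to several
    intervals.  Intervals with a NaN endpoint at a site do not count that site.
    """
    ages = list(means.columns)
    deltas = means.to_numpy()[:, 1:] - means.to_numpy()[:, :-1]
    with np.errstate(invalid="ignore"):
        gain = np.nansum(deltas >= threshold, axis=0)
        loss = np.nansum(deltas <= -threshold, axis=0)
    return pd.DataFrame(
        {"gain": gain.astype(int), "loss": loss.astype(int)},
        index=pd.Index(interval_labels(ages), name="interval"),
    )


def sustained_crosstab(means: pd.DataFrame, threshold: float = 30.0) -> pd.DataFrame:
    """M[i, j] = number of sites changing >= threshold (either direction) in
    both interval i and interval j; the diagonal gives per-interval totals."""
    ages = list(means.columns)
    labels = interval_labels(ages)
    deltas = means.to_numpy()[:, 1:] - means.to_numpy()[:, :-1]
    with np.errstate(invalid="ignore"):
        member = np.abs(deltas) >= threshold
    member = np.where(np.isnan(deltas), False, member)
    m = member.T.astype(int) @ member.astype(int)
    return pd.DataFrame(m, index=pd.Index(labels, name="interval"), columns=labels)


@dataclass(frozen=True)
class PatternCall:
    status: str  # changed / unchanged / unclassifiable
    direction: str  # increase / decrease / none
    pattern: str  # discrete / continuous / other / none
    dominant_interval: str  # age-pair label or "none"
    total_change: float  # net change, percentage points (signed)


def classify_pattern(
    values,
    ages: list[str] | None = None,
    min_total_change: float = 5.0,
) -> PatternCall:
    """Classify one trajectory by the half-of-total-change rule.

    ``values`` are per-age mean percentages (NaN = age without data, skipped).
    Trajectories with fewer than three observed ages are unclassifiable; a
    net change within ``min_total_change`` points is unchanged.  Ties at
    exactly half the total classify as discrete.
    """
    v = np.asarray(values, dtype=float)
    if ages is None:
        ages = [str(i) for i in range(len(v))]
    keep = ~np.isnan(v)
    v_obs = v[keep]
    ages_obs = [a for a, k in zip(ages, keep) if k]
    if len(v_obs) < 3:
        return PatternCall("unclassifiable", "none", "none", "none", float("nan"))
    deltas = np.diff(v_obs)
    net = float(v_obs[-1] - v_obs[0])
    if abs(net) <= min_total_change:
        return PatternCall("unchanged", "none", "none", "none", net)
    sign = 1.0 if net > 0 else -1.0
    path = float(np.abs(deltas).sum())
    same_signed = deltas * sign
    max_same = float(same_signed.max())
    if max_same >= 0.5 * path:
        k = int(np.argmax(same_signed))
        dominant = f"{ages_obs[k]}-{ages_obs[k + 1]}"
        pattern = "discrete"
    elif np.all(same_signed >= 0):
        dominant, pattern = "none", "continuous"
    else:
        dominant, pattern = "none", "other"
    direction = "increase" if sign > 0 else "decrease"
    return PatternCall("changed", direction, pattern, dominant, net)


def classify_all(
    means: pd.DataFrame, min_total_change: float = 5.0
) -> pd.DataFrame:
    """Classify every trajectory; returns a per-site table of pattern calls."""
    ages = list(means.columns)
    rows = [
        classify_pattern(means.loc[site].to_numpy(), ages, min_total_change)
        for site in means.index
    ]
    return pd.DataFrame(
        {
            "status": [r.status for r in rows],
            "direction": [r.direction for r in rows],
            "pattern": [r.pattern for r in rows],
            "dominant_interval": [r.dominant_interval for r in rows],
            "total_change": [r.total_change for r in rows],
        },
        index=means.index,
    )
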