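"""Two-group differential methylation.

Per CpG: an equal-variance two-sided Student's t-test on per-sample percent
methylation, false discovery rate control (Benjamini-Hochberg by default,
Storey's smoother-based q-value optionally), a biological delta threshold in
percentage points on top of the statistical one, magnitude binning
(5-30 vs >=30 points) and direction summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .meth_io import MethylationMatrix


@dataclass
class TestConfig:
    min_delta: float = 5.0  # percentage points; significance needs |delta| > min_delta
    major_delta: float = 30.0  # boundary between the 5-30 and >=30 magnitude bins
    max_fdr: float = 0.1
    fdr_method: str = "bh"  # "bh" or "storey"
    equal_var: bool = True  # classic Student's t; False gives Welch
    # comparator for the delta threshold: "gt" (strictly greater, default) or "ge"
    delta_comparator: str = "gt"

    def validate(self) -> None:
        if not 0 < self.min_delta <= self.major_delta <= 100:
            raise ValueError("need 0 < min_delta <= major_delta <= 100")
        if not 0.0 < self.max_fdr < 1.0:
            raise ValueError("max_fdr must be in (0,1)")
        if self.fdr_method not in ("bh", "storey"):
            raise ValueError("fdr_method must be 'bh' or 'storey'")
        if self.delta_comparator not in ("gt", "ge"):
            raise ValueError("delta_comparator must be 'gt' or 'ge'")


def cpg_ttest(values_a, values_b, equal_var: bool = True) -> float:
    """Two-sided Student's t-test p-value for one CpG.

    Returns NaN (untestable) when either group has fewer than two values.
    Zero variance in both groups gives p=1 for equal means, p=0 otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    with warnings.catch_warnings():
        # near-identical groups trigger scipy's catastrophic-cancellation
        # warning; the degenerate exact-tie case is handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def _storey_qvalues(p: np.ndarray) -> np.ndarray:
    """Storey q-values with the cubic-smoother pi0 estimate (lambda grid 0.05..0.95)."""
    m = len(p)
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_hat = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    if m < 100:
        pi0 = 1.0
    else:
        coef = np.polyfit(lambdas, pi0_hat, 3)
        pi0 = float(np.polyval(coef, lambdas.max()))
        pi0 = min(max(pi0, 1e-8), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def fdr_adjust(p_values, method: str = "bh") -> np.ndarray:
    """Adjust p-values for multiple testing; NaNs propagate and are excluded from ranking."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if not ok.any():
        return q
    if method == "bh":
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    elif method == "storey":
        q[ok] = _storey_qvalues(p[ok])
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    return q


def call_differential(
    matrix: MethylationMatrix,
    group_a: str,
    group_b: str,
    config: TestConfig | None = None,
) -> pd.DataFrame:
    """Per-CpG differential calls between two age groups (delta = b - a).

    Significant calls require both the FDR bound (q <= max_fdr) and the
    biological delta bound (|delta| beyond min_delta).  Sites with fewer than
    two usable values in either group are marked untestable and excluded
    from significance (their p and q are NaN).
    """
    config = config or TestConfig()
    config.validate()
    cols_a = matrix.samples_in_group(group_a)
    cols_b = matrix.samples_in_group(group_b)
    if not cols_a:
        raise ValueError(f"group {group_a!r} absent from sample sheet")
    if not cols_b:
        raise ValueError(f"group {group_b!r} absent from sample sheet")
    idx_a = [matrix.samples.index.get_loc(s) for s in cols_a]
    idx_b = [matrix.samples.index.get_loc(s) for s in cols_b]

    pct = matrix.percent
    pa, pb = pct[:, idx_a], pct[:, idx_b]
    n_a = (~np.isnan(pa)).sum(axis=1)
    n_b = (~np.isnan(pb)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_a = np.nanmean(np.where(np.isnan(pa), np.nan, pa), axis=1)
        mean_b = np.nanmean(np.where(np.isnan(pb), np.nan, pb), axis=1)
    delta = mean_b - mean_a

    p = np.array([cpg_ttest(pa[i], pb[i], equal_var=config.equal_var) for i in range(matrix.n_sites)])
    testable = (n_a >= 2) & (n_b >= 2)
    p = np.where(testable, p, np.nan)
    q = fdr_adjust(p, method=config.fdr_method)

    if config.delta_comparator == "gt":
        passes_delta = np.abs(delta) > config.min_delta
        major = np.abs(delta) > config.major_delta
    else:
        passes_delta = np.abs(delta) >= config.min_delta
        major = np.abs(delta) >= config.major_delta
    significant = testable & passes_delta & (q <= config.max_fdr)
    magnitude_bin = np.where(
        significant, np.where(major, ">=30", "5-30"), "none"
    )
    direction = np.where(delta > 0, "increase", np.where(delta < 0, "decrease", "none"))

    return pd.DataFrame(
        {
            "chrom": matrix.sites["chrom"],
            "pos": matrix.sites["pos"],
            "mean_a": mean_a,
            "mean_b": mean_b,
            "n_a": n_a,
            "n_b": n_b,
            "delta": delta,
            "p_value": p,
            "q_value": q,
            "testable": testable,
            "significant": significant,
            "magnitude_bin": magnitude_bin,
            "direction": direction,
        },
        index=matrix.sites.index,
    )


def direction_summary(calls: pd.DataFrame) -> float:
    """Fraction of significant calls gaining methylation; NaN when none are significant."""
    sig = calls[calls["significant"]]
    if len(sig) == 0:
        return float("nan")
    return float((sig["direction"] == "increase").mean())


def summarize_calls(calls: pd.DataFrame) -> dict:
    """Funnel-style count summary of a call table."""
    sig = calls[calls["significant"]]
    return {
        "n_sites": int(len(calls)),
        "n_testable": int(calls["testable"].sum()),
        "n_significant": int(len(sig)),
        "n_bin_5_30": int((sig["magnitude_bin"] == "5-30").sum()),
        "n_bin_ge30": int((sig["magnitude_bin"] == ">=30").sum()),
        "fraction_significant": float(calls["significant"].mean()) if len(calls) else float("nan"),
        "fraction_increase": direction_summary(calls),
    }


def concordance(calls_primary: pd.DataFrame, calls_secondary: pd.DataFrame) -> tuple[float, int]:
    """Replication of secondary-significant sites in the primary call set.

    Restricted to the shared site universe: the fraction of sites significant
    in the secondary set that are also significant in the primary set.
    Returns (fraction, n_shared_sites); fraction is NaN when the secondary
    set has no significant shared site.
    """
    shared = calls_primary.index.intersection(calls_secondary.index)
    if len(shared) == 0:
        raise ValueError("call sets share no sites")
    sec_sig = calls_secondary.loc[shared, "significant"]
    sec_sig_sites = shared[sec_sig]
    if len(sec_sig_sites) == 0:
        return float("nan"), len(shared)
    also = calls_primary.loc[sec_sig_sites, "significant"]
    return float(also.mean()), len(shared)
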