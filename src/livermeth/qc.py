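"""Quality-control cascade for the methylation matrix.

Order of operations is part of the contract: (1) mask cells below the
coverage floor, (2) score and drop samples with unusual missingness using a
sharedness-weighted completeness score, (3) drop CpGs with too much missing
data, (4) drop CpGs that are essentially unmethylated in every sample.  A
separate screen flags apparently methylated CpH (non-CpG) sites, which in a
well-converted library should be vanishingly rare.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meth_io import MethylationMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    min_coverage: int = 10
    max_missing_fraction: float = 0.20
    never_methylated_threshold: float = 10.0  # percent
    # Absolute score cutoff (genome-scale panels use 50,000); if None, the
    # relative cutoff (fraction of the maximum attainable score) applies,
    # which scales to small synthetic panels.
    sample_score_cutoff: float | None = None
    relative_score_cutoff: float = 0.5
    cph_threshold: float = 5.0  # percent

    def validate(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0,1]")
        if not 0.0 <= self.never_methylated_threshold <= 100.0:
            raise ValueError("never_methylated_threshold must be in [0,100]")
        if not 0.0 <= self.relative_score_cutoff <= 1.0:
            raise ValueError("relative_score_cutoff must be in [0,1]")


def mask_low_coverage(matrix: MethylationMatrix, min_coverage: int = 10) -> MethylationMatrix:
    """Mask every cell with coverage strictly below ``min_coverage``.

    Counts are preserved; only the missingness mask changes.  Idempotent and
    monotone in ``min_coverage``.
    """
    masked = matrix.masked | (matrix.total < min_coverage)
    return matrix.with_mask(masked)


def score_samples(
    matrix: MethylationMatrix,
    cutoff: float | None = None,
    relative_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Sharedness-weighted sample completeness scores.

    Each CpG c gets weight w_c = fraction of samples with data at c; a
    sample's score is the sum of w_c over the CpGs it has data for.  Samples
    scoring below the cutoff (absolute if given, else
    ``relative_cutoff * sum(w_c)``, the maximum attainable score) are
    flagged for removal.  This keeps samples that cover few but widely
    shared CpGs, and flags samples covering many CpGs nobody else has.
    """
    if matrix.n_sites == 0 or matrix.n_samples == 0:
        raise ValueError("cannot score an empty matrix")
    has_data = ~matrix.masked
    w = has_data.mean(axis=1)  # per-CpG sharedness
    scores = has_data.T.astype(float) @ w
    max_score = float(w.sum())
    resolved = cutoff if cutoff is not None else relative_cutoff * max_score
    return pd.DataFrame(
        {
            "score": scores,
            "max_score": max_score,
            "cutoff": resolved,
            "retained": scores >= resolved,
        },
        index=matrix.samples.index,
    )


def filter_high_missingness(
    matrix: MethylationMatrix, max_missing_fraction: float = 0.20
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Remove CpGs where strictly more than the allowed fraction of samples is missing."""
    missing_frac = matrix.masked.mean(axis=1)
    remove = missing_frac > max_missing_fraction
    log = pd.DataFrame(
        {
            "reason": "high_missingness",
            "missing_fraction": missing_frac[remove],
        },
        index=matrix.sites.index[remove],
    )
    return matrix.select_sites(~remove), log


def filter_never_methylated(
    matrix: MethylationMatrix, threshold: float = 10.0
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Remove CpGs unmethylated (below ``threshold`` percent) in every sample.

    Evaluated on unmasked cells only.  A CpG with no unmasked cell at all is
    also removed, logged with its own reason.
    """
    pct = matrix.percent
    with np.errstate(invalid="ignore"):
        below = pct < threshold
    n_obs = (~np.isnan(pct)).sum(axis=1)
    all_below = np.where(n_obs > 0, np.nansum(below, axis=1) == n_obs, False)
    no_data = n_obs == 0
    remove = all_below | no_data
    reasons = np.where(no_data, "no_unmasked_data", "never_methylated")
    log = pd.DataFrame(
        {"reason": reasons[remove]},
        index=matrix.sites.index[remove],
    )
    return matrix.select_sites(~remove), log


def screen_cph(
    matrix: MethylationMatrix, threshold: float = 5.0
) -> pd.DataFrame:
    """Flag CpH sites methylated above ``threshold`` percent in all samples of some age group.

    Such sites are candidate artifacts (sample-specific CpGs misclassified
    as CpH, or conversion failures) rather than genuine non-CpG methylation.
    Returns a per-site table with the flag and the triggering group.
    """
    pct = matrix.percent
    groups = matrix.samples["age_group"]
    flagged = np.zeros(matrix.n_sites, dtype=bool)
    which_group = np.full(matrix.n_sites, "", dtype=object)
    for g in pd.unique(groups.dropna()):
        cols = np.flatnonzero((groups == g).to_numpy())
        if len(cols) == 0:
            continue
        sub = pct[:, cols]
        n_obs = (~np.isnan(sub)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            above = np.nansum(sub > threshold, axis=1)
        hit = (n_obs > 0) & (above == n_obs)
        newly = hit & ~flagged
        which_group[newly] = str(g)
        flagged |= hit
    return pd.DataFrame(
        {"flagged": flagged, "group": which_group}, index=matrix.sites.index
    )


@dataclass
class QCResult:
    matrix: MethylationMatrix
    sample_scores: pd.DataFrame
    removed_samples: list[str]
    removal_log: pd.DataFrame
    funnel: dict = field(default_factory=dict)


def run_qc(matrix: MethylationMatrix, config: QCConfig | None = None) -> QCResult:
    """Run the full cascade: mask -> sample removal -> missingness -> never-methylated."""
    config = config or QCConfig()
    config.validate()
    funnel = {"sites_in": matrix.n_sites, "samples_in": matrix.n_samples}

    masked = mask_low_coverage(matrix, config.min_coverage)
    scores = score_samples(
        masked, cutoff=config.sample_score_cutoff, relative_cutoff=config.relative_score_cutoff
    )
    removed_samples = list(scores.index[~scores["retained"]])
    kept = masked.select_samples(list(scores.index[scores["retained"]]))
    if kept.n_samples == 0:
        raise ValueError("sample completeness cutoff removed every sample")
    funnel["samples_removed"] = len(removed_samples)

    kept, miss_log = filter_high_missingness(kept, config.max_missing_fraction)
    funnel["sites_after_missingness"] = kept.n_sites
    kept, never_log = filter_never_methylated(kept, config.never_methylated_threshold)
    funnel["sites_after_never_methylated"] = kept.n_sites

    removal_log = pd.concat([miss_log, never_log])
    removal_log.index.name = "site_id"
    for sample in removed_samples:
        logger.info("sample %s removed: completeness score below cutoff", sample)
    logger.info(
        "QC funnel: %d sites in, %d after missingness, %d retained; %d/%d samples kept",
        funnel["sites_in"],
        funnel["sites_after_missingness"],
        funnel["sites_after_never_methylated"],
        kept.n_samples,
        matrix.n_samples,
    )
    return QCResult(
        matrix=kept,
        sample_scores=scores,
        removed_samples=removed_samples,
        removal_log=removal_log,
        funnel=funnel,
    )
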