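"""Small analytic models and distribution summaries.

Covers the hemimethylation dilution model (how active cell division lowers
observed bulk methylation), the quantification granularity implied by read
coverage, and per-age methylation-level histograms whose upper mode tracks
the dividing-cell fraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .meth_io import MethylationMatrix


def expected_dilution(dividing_fraction: float, methylation_percent: float) -> float:
    """Expected drop in observed methylation (percentage points) from division.

    Right after replication the nascent strand is unmethylated, so each
    dividing cell contributes half its DNA unmethylated: the expected
    decrease is methylation * dividing_fraction / 2.  With 10% of cells
    dividing at a fully methylated locus that is 5 percentage points.
    """
    if not 0.0 <= dividing_fraction <= 1.0:
        raise ValueError("dividing_fraction must be in [0,1]")
    if not 0.0 <= methylation_percent <= 100.0:
        raise ValueError("methylation_percent must be in [0,100]")
    return methylation_percent * dividing_fraction / 2.0


def quantification_interval(coverage: int) -> float:
    """Smallest resolvable methylation step (percent) at a given read coverage.

    A CpG covered by n reads can only take methylation values on a 100/n
    percent grid (40 reads -> 2.5% steps).
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    return 100.0 / coverage


def methylation_distribution(
    matrix: MethylationMatrix,
    group: str | None = None,
    bin_width: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Histogram of per-cell (site x sample) percent methylation and its upper mode.

    Returns a normalised histogram (default 1-point bins over [0, 100]) and
    the location of the uppermost mode: the count-weighted centre of the
    dominant high-methylation peak (bins holding >= 50% of the maximum count
    among bins above 50% methylation).  A raw argmax is unstable because
    coverage quantisation concentrates mass on a coarse grid.
    """
    if group is not None:
        ids = matrix.samples_in_group(group)
        if not ids:
            raise ValueError(f"group {group!r} has no samples")
        matrix = matrix.select_samples(ids)
    values = matrix.percent.ravel()
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise ValueError("no unmasked observations to histogram")
    # Bins centred on the percent grid (…, 99, 100) so coverage-quantised
    # values land in their own bins rather than on edges.
    edges = np.arange(-bin_width / 2.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    density = counts / counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    hist = pd.DataFrame({"bin_center": centers, "density": density})

    upper = centers > 50.0
    if upper.any() and counts[upper].max() > 0:
        sub_counts = counts[upper].astype(float)
        sub_centers = centers[upper]
    else:
        sub_counts = counts.astype(float)
        sub_centers = centers
    peak = sub_counts >= 0.5 * sub_counts.max()
    mode = float(np.average(sub_centers[peak], weights=sub_counts[peak]))
    return hist, mode
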