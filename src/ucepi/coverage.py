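"""Data-driven coverage cutoff for the Stacked mode.

Aggregate coverage n_i (the number of characters observed at core-relative
position i, summed over loci) collapses toward the far flanks, where only a
handful of unusually long loci still have columns — typically alignment
artefacts. The Stacked fit therefore excludes positions with n_i below a
cutoff delta chosen from the data.

The coverage distribution is characteristically a high-coverage bulk plus a
long low-coverage tail. To place delta between them, a cubic smoothing
spline is fitted to the log-transformed empirical CDF of coverage and delta
is set at the first coverage (scanning upward) where the spline's second
derivative changes sign — the inflection separating tail from bulk. The
log transform stretches the tail-vs-bulk contrast of the ECDF so that the
inflection lands in the sparse region between the two components.

Smoothing is calibrated to the sampling noise of the ECDF itself: each
point is weighted by the inverse of its relative binomial noise scale
sqrt((1 - F)/F), and the smoothing factor is set to the number of points,
the classical choice that makes the spline track the ECDF to within about
one noise unit per point. Both ingredients are scale-free, so the cutoff
is invariant to duplicating every position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline

logger = logging.getLogger(__name__)

MIN_DISTINCT = 10
GRID_SIZE = 512


@dataclass
class CoverageProfile:
    """Aggregate coverage by position with the delta inclusion mask."""

    positions: np.ndarray
    n: np.ndarray
    delta: int

    @property
    def included(self) -> np.ndarray:
        return self.n >= self.delta


def estimate_delta(n_values) -> int:
    """Coverage cutoff from the inflection of the smoothed log-ECDF.

    Steps: (1) empirical CDF of the positive aggregate coverages;
    (2) log-transform; (3) noise-weighted cubic smoothing spline;
    (4) second derivative on a dense grid; (5) delta = smallest coverage at
    which the second derivative changes sign, scanning upward.

    Falls back to ``delta = 0`` (no filtering) with a warning when there are
    fewer than 10 distinct coverage values or no sign change exists.
    """
    n_values = np.asarray(n_values, dtype=float)
    n_values = n_values[n_values > 0]
    values, counts = np.unique(n_values, return_counts=True)
    if len(values) < MIN_DISTINCT:
        logger.warning(
            "coverage cutoff: only %d distinct values (< %d); using delta=0",
            len(values),
            MIN_DISTINCT,
        )
        return 0
    F = np.cumsum(counts) / counts.sum()  # ECDF, invariant to duplication
    y = np.log(F)
    # relative binomial noise of the ECDF, up to the common 1/sqrt(N) factor
    sigma = np.sqrt(np.maximum((1.0 - F) / F, 1e-6))
    spline = UnivariateSpline(values, y, w=1.0 / sigma, k=3, s=float(len(values)))
    grid = np.linspace(values[0], values[-1], GRID_SIZE)
    d2 = spline.derivative(2)(grid)
    sign = np.sign(d2)
    nz = sign != 0
    flips = np.nonzero(np.diff(sign[nz]) != 0)[0]
    if len(flips) == 0:
        logger.warning("coverage cutoff: no inflection found; using delta=0")
        return 0
    delta = int(np.ceil(grid[nz][flips[0] + 1]))
    logger.info("coverage cutoff: delta = %d", delta)
    return delta
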