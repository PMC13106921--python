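"""Per-site diversity statistics.

For a column with ``n`` non-missing characters of which ``s`` carry the
minor allele, the per-site nucleotide diversity is

    pi = s * (n - s) / C(n, 2)

the fraction of unordered sequence pairs that differ at the site. Sites are
classified as missing (n < 2), monomorphic, biallelic or multiallelic;
multiallelic sites are excluded from every downstream sum (population-scale
data is overwhelmingly biallelic, and a third allele at a site usually
signals alignment or sequencing artefacts). Monomorphic sites are genuine
pi = 0 observations and are kept — dropping them would inflate diversity.

Each included site gets the weight

    w = 1 - 2 / (n + 1) = (n - 1) / (n + 1)

the inverse of the leading term of Tajima's variance of pi,
Var(pi) ~ theta * (n + 1) / (3 (n - 1)), so better-covered sites count more
(Aitken/BLUE weighting). w = 0 at n = 1 and w -> 1 as n -> infinity.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignments import LocusAlignment
from .errors import NoDataError, UndefinedSiteError

#: Site classes.
MISSING = "missing"
MONOMORPHIC = "monomorphic"
BIALLELIC = "biallelic"
MULTIALLELIC = "multiallelic"

_CLASS_BY_ALLELES = {0: MISSING, 1: MONOMORPHIC, 2: BIALLELIC}

STATS_COLUMNS = ["locus_id", "position", "n", "s", "pi", "site_class", "weight"]


def per_site_pi(s: int, n: int) -> float:
    """Diversity ``s (n - s) / C(n, 2)`` for minor count ``s`` at coverage ``n``.

    Undefined for ``n < 2`` (no pair of sequences to compare).
    """
    if n < 2:
        raise UndefinedSiteError(f"per-site pi undefined at coverage n={n}")
    if not 0 <= s <= n // 2:
        raise ValueError(f"minor count s={s} outside [0, {n // 2}] for n={n}")
    return s * (n - s) / (n * (n - 1) / 2)


def site_weight(n):
    """Variance-based weight ``1 - 2/(n+1)``, clamped to 0 for ``n <= 1``."""
    n = np.asarray(n, dtype=float)
    w = np.where(n > 1, (n - 1) / (n + 1), 0.0)
    return w if w.ndim else float(w)


def classify_site(column) -> tuple[str, int, Counter]:
    """Classify one alignment column.

    Parameters
    ----------
    column:
        Characters at one position — a string, bytes, or sequence of
        single characters.

    Returns
    -------
    (site_class, n, allele_counts):
        ``n`` is the non-missing coverage and ``allele_counts`` maps each
        observed A/C/G/T allele to its count. Columns with ``n < 2`` are
        ``missing``; with 3+ distinct alleles ``multiallelic``.
    """
    if isinstance(column, str):
        chars = column.upper()
    elif isinstance(column, bytes):
        chars = column.decode("ascii").upper()
    else:
        chars = "".join(
            c.decode("ascii") if isinstance(c, bytes) else str(c) for c in column
        ).upper()
    counts = Counter(c for c in chars if c in "ACGT")
    n = sum(counts.values())
    if n < 2:
        return MISSING, n, counts
    return _CLASS_BY_ALLELES.get(len(counts), MULTIALLELIC), n, counts


def _locus_site_arrays(locus: LocusAlignment):
    """Vectorized per-site stats for the *included* sites of one locus.

    Returns ``(positions, n, s, pi)`` int/float arrays covering the
    monomorphic and biallelic sites with coverage >= 2, plus a boolean
    ``biallelic`` mask over those sites.
    """
    codes = locus.codes()  # (n_ind, L), -1 = missing
    counts = np.stack([(codes == a).sum(axis=0) for a in range(4)])  # (4, L)
    n = counts.sum(axis=0)
    n_alleles = (counts > 0).sum(axis=0)
    included = (n >= 2) & (n_alleles >= 1) & (n_alleles <= 2)
    n_inc = n[included]
    s = n_inc - counts[:, included].max(axis=0)
    pi = s * (n_inc - s) / (n_inc * (n_inc - 1) / 2)
    return (
        locus.positions[included],
        n_inc.astype(np.int64),
        s.astype(np.int64),
        pi,
        (n_alleles[included] == 2),
    )


def locus_site_stats(locus: LocusAlignment) -> pd.DataFrame:
    """Per-site statistics for one locus as a tidy DataFrame.

    One row per included site (monomorphic or biallelic with coverage >= 2);
    positions are signed offsets from the core. Columns:
    ``locus_id, position, n, s, pi, site_class, weight``.
    """
    pos, n, s, pi, biallelic = _locus_site_arrays(locus)
    return pd.DataFrame(
        {
            "locus_id": locus.locus_id,
            "position": pos,
            "n": n,
            "s": s,
            "pi": pi,
            "site_class": np.where(biallelic, BIALLELIC, MONOMORPHIC),
            "weight": site_weight(n),
        }
    )


def dataset_site_stats(loci: Iterable[LocusAlignment]) -> pd.DataFrame:
    """Concatenated :func:`locus_site_stats` over all loci."""
    frames = [locus_site_stats(loc) for loc in loci]
    if not frames:
        raise NoDataError("no loci supplied")
    return pd.concat(frames, ignore_index=True)


def uncorrected_mean_pi(stats: pd.DataFrame | Sequence[LocusAlignment]) -> float:
    """Unweighted mean of per-site pi over all included sites of all loci.

    This is the naive estimator that ignores core conservation; it
    systematically underestimates diversity near a conserved core.
    """
    if not isinstance(stats, pd.DataFrame):
        stats = dataset_site_stats(stats)
    if len(stats) == 0:
        raise NoDataError("no included sites")
    return float(stats["pi"].mean())


def write_site_stats_tsv(stats: pd.DataFrame, path) -> None:
    """Dump per-site stats to TSV (for smilogram-style plotting)."""
    stats.to_csv(path, sep="\t", index=False)
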