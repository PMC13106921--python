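"""Synthetic UCE-like alignment generator.

No coalescent simulator reproduces UCE architecture (a conserved core with
diversity recovering into the flanks), so validation uses this generator:
independent sites whose expected per-site diversity follows the Gompertz
curve e_i = theta * exp(-beta * exp(-gamma |i|)), with whole-individual
missingness, per-sequence terminal gaps (length heterogeneity) and
biallelic sites by construction (optionally injecting multiallelic sites to
exercise the filter).

Site construction is exact, not approximate: in ``singleton`` mode a site
with realized coverage n_i is polymorphic with probability
q_i = e_i * n_i / 2 and one covered individual carries the alternate base,
so E[pi_i | n_i] = q_i * (n_i - 1)/C(n_i, 2) = e_i. In ``neutral`` mode the
minor count a is drawn from the folded neutral frequency spectrum
P(a) proportional to 1/a + 1/(n_i - a), with the polymorphism probability
solved so that E[pi_i | n_i] = e_i again holds exactly.

What this does not emulate: linkage between sites, probe-capture bias,
sequencing error and alignment artefacts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignments import LocusAlignment, write_locus_alignment
from .errors import ParameterError

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Defaults are the standard validation conditions: 2000 loci of 10
#: individuals with 750 bp flanks, theta = 0.005, beta = 10, gamma = 0.009.
@dataclass
class SimConfig:
    k: int = 2000  # number of loci
    n: int = 10  # individuals per locus
    flank: int = 750  # bp on each side of the core; locus length 2*flank + 1
    theta: float = 0.005  # asymptotic diversity
    beta: float = 10.0  # core depression depth
    gamma: float = 0.009  # recovery rate per bp
    missing_rate: float = 0.0  # P(an individual is absent from a locus)
    edge_trim_max: int = 0  # max random terminal gap length per sequence end
    sfs_mode: str = "singleton"  # "singleton" | "neutral"
    multiallelic_rate: float = 0.0  # extra sites forced to 3 alleles
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.n < 2 or self.flank < 1:
            raise ParameterError("need k >= 1, n >= 2, flank >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ParameterError("missing_rate must be in [0, 1)")
        if self.sfs_mode not in ("singleton", "neutral"):
            raise ParameterError(f"unknown sfs_mode {self.sfs_mode!r}")
        if min(self.theta, self.beta, self.gamma) <= 0:
            raise ParameterError("theta, beta, gamma must be positive")

    @property
    def length(self) -> int:
        return 2 * self.flank + 1

    def expected_pi(self) -> np.ndarray:
        """e_i over positions -flank..flank (the generative mean)."""
        i = np.arange(-self.flank, self.flank + 1)
        return self.theta * np.exp(-self.beta * np.exp(-self.gamma * np.abs(i)))


def _folded_sfs(m: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Minor counts, their folded-neutral pmf, and E[pi | polymorphic]."""
    a = np.arange(1, m // 2 + 1)
    w = 1.0 / a + 1.0 / (m - a)
    p = w / w.sum()
    e_pi = float(np.sum(p * a * (m - a) / (m * (m - 1) / 2)))
    return a, p, e_pi


def simulate_locus(config: SimConfig, locus_index: int) -> LocusAlignment:
    """Generate one locus alignment; deterministic in (seed, locus_index)."""
    rng = np.random.default_rng([config.seed, locus_index])
    n, L = config.n, config.length
    e = config.expected_pi()

    present = rng.random(n) >= config.missing_rate
    left = rng.integers(0, config.edge_trim_max + 1, size=n)
    right = rng.integers(0, config.edge_trim_max + 1, size=n)
    cols = np.arange(L)
    covered = present[:, None] & (cols >= left[:, None]) & (cols < L - right[:, None])
    n_i = covered.sum(axis=0)

    # polymorphism probability q_i making E[pi_i | n_i] = e_i exact
    q = np.zeros(L)
    ok = n_i >= 2
    if config.sfs_mode == "singleton":
        q[ok] = e[ok] * n_i[ok] / 2.0
    else:
        for m in np.unique(n_i[ok]):
            sel = n_i == m
            _, _, e_pi = _folded_sfs(int(m))
            q[sel] = e[sel] / e_pi
    if np.any(q > 1.0):
        pos = int(np.argmax(q > 1.0)) - config.flank
        raise ParameterError(
            f"theta too large for coverage at position {pos}: "
            f"polymorphism probability {q.max():.3f} > 1"
        )

    poly = (rng.random(L) < q) & ok

    # minor count per site
    a_count = np.where(poly, 1, 0)
    if config.sfs_mode == "neutral":
        u = rng.random(L)
        for m in np.unique(n_i[poly]):
            sel = poly & (n_i == m)
            counts, pmf, _ = _folded_sfs(int(m))
            a_count[sel] = counts[np.searchsorted(np.cumsum(pmf), u[sel])]

    # uniform choice of minor-allele carriers among covered individuals
    r = rng.random((n, L))
    r[~covered] = np.inf
    ranks = np.argsort(np.argsort(r, axis=0), axis=0)
    carriers = ranks < a_count[None, :]

    ref = rng.integers(0, 4, size=L)
    alt = (ref + rng.integers(1, 4, size=L)) % 4
    codes = np.broadcast_to(ref, (n, L)).copy()
    codes[carriers] = np.broadcast_to(alt, (n, L))[carriers]

    matrix = _BASES[codes]
    matrix[~covered] = b"-"

    if config.multiallelic_rate > 0:
        tri = (rng.random(L) < config.multiallelic_rate) & (n_i >= 3)
        for j in np.nonzero(tri)[0]:
            rows = np.nonzero(covered[:, j])[0]
            pick = rng.choice(rows, size=2, replace=False)
            others = [b for b in range(4) if b not in (ref[j],)]
            matrix[pick[0], j] = _BASES[others[0]]
            matrix[pick[1], j] = _BASES[others[1]]

    individuals = [f"ind{t:03d}" for t in range(n)]
    return LocusAlignment(f"uce-{locus_index:06d}", individuals, matrix, config.flank)


def simulate_dataset(config: SimConfig) -> list[LocusAlignment]:
    """All ``config.k`` loci (each locus seeded independently)."""
    return [simulate_locus(config, j) for j in range(config.k)]


def write_truth_table(config: SimConfig, path: str | os.PathLike) -> None:
    """Per-position expected diversity plus the true parameters, as TSV."""
    e = config.expected_pi()
    with open(path, "w") as out:
        out.write(
            f"# theta={config.theta}\tbeta={config.beta}\tgamma={config.gamma}\n"
            f"# k={config.k}\tn={config.n}\tflank={config.flank}\n"
        )
        out.write("position\texpected_pi\n")
        for i, val in zip(range(-config.flank, config.flank + 1), e):
            out.write(f"{i}\t{val:.10g}\n")


def write_dataset(config: SimConfig, outdir: str | os.PathLike) -> list[Path]:
    """Write per-locus FASTA files plus ``truth.tsv``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for locus in simulate_dataset(config):
        p = outdir / f"{locus.locus_id}.fasta"
        write_locus_alignment(locus, p)
        paths.append(p)
    write_truth_table(config, outdir / "truth.tsv")
    return paths
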