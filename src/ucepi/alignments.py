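"""Per-locus UCE alignment I/O and locus-level filtering.

A UCE dataset is a directory of aligned FASTA files, one per locus, the
shape produced by a Phyluce + MAFFT workflow: rows are individuals, columns
are sites centered on the conserved core. The core column is mapped to
position 0 and every other column gets a signed base-pair offset from it.
"""

from __future__ import annotations

import glob as _glob
import gzip
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import EmptyInputError, MalformedAlignmentError, ParameterError

logger = logging.getLogger(__name__)

FASTA_EXTENSIONS = (".fa", ".fasta", ".fna")

#: Characters treated as missing for diversity purposes: gaps, unknowns and
#: all IUPAC ambiguity codes (an ambiguous base cannot be assigned to an
#: allele without genotype information).
MISSING_CHARS = set(b"-?.NRYSWKMBDHVX*")

_ACGT = b"ACGT"

# 256-entry lookup: ACGT -> 0..3, everything else -> -1 (missing).
_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _idx, _base in enumerate(_ACGT):
    _CODE_TABLE[_base] = _idx


def assign_center(length: int) -> int:
    """Column index mapped to position 0 for an alignment of ``length`` columns.

    Returns ``floor((length - 1) / 2)``: the exact middle for odd lengths and
    the left of the two middle columns for even lengths. The diversity models
    depend only on ``|position|``, so the one-column asymmetry for even
    lengths is immaterial.
    """
    if length <= 0:
        raise ParameterError(f"alignment length must be >= 1, got {length}")
    return (length - 1) // 2


@dataclass
class LocusAlignment:
    """One UCE locus: individuals x aligned sites, centered on the core.

    Parameters
    ----------
    locus_id:
        Identifier, normally the file name stem.
    individuals:
        Sample identifiers, one per matrix row (FASTA header token up to the
        first whitespace).
    matrix:
        ``(n_individuals, length)`` array of single-byte characters
        (dtype ``S1``), uppercase.
    center:
        Column index mapped to position 0 (defaults to the alignment
        midpoint, see :func:`assign_center`).
    """

    locus_id: str
    individuals: list[str]
    matrix: np.ndarray
    center: int = field(default=-1)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise MalformedAlignmentError(
                f"{self.locus_id}: matrix must be 2-D, got shape {self.matrix.shape}"
            )
        n, length = self.matrix.shape
        if n < 1 or length < 1:
            raise EmptyInputError(f"{self.locus_id}: empty alignment")
        if len(self.individuals) != n:
            raise MalformedAlignmentError(
                f"{self.locus_id}: {len(self.individuals)} ids for {n} rows"
            )
        if len(set(self.individuals)) != n:
            raise MalformedAlignmentError(
                f"{self.locus_id}: duplicate individual identifiers"
            )
        if self.center < 0:
            self.center = assign_center(length)
        if not 0 <= self.center < length:
            raise ParameterError(
                f"{self.locus_id}: center {self.center} outside [0, {length - 1}]"
            )

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def positions(self) -> np.ndarray:
        """Signed position of every column: ``column - center``."""
        return np.arange(self.length) - self.center

    def codes(self) -> np.ndarray:
        """Integer-coded matrix: A,C,G,T -> 0..3; anything else -> -1."""
        return _CODE_TABLE[self.matrix.view(np.uint8)]

    def n_present_individuals(self) -> int:
        """Number of rows with at least one non-missing character."""
        return int((self.codes() >= 0).any(axis=1).sum())

    def trim_flank(self, flank: int) -> "LocusAlignment":
        """Restrict to columns with ``|position| <= flank`` (new object)."""
        if flank < 1:
            raise ParameterError(f"flank must be >= 1, got {flank}")
        keep = np.abs(self.positions) <= flank
        sub = self.matrix[:, keep]
        new_center = int(np.nonzero(self.positions[keep] == 0)[0][0])
        return LocusAlignment(self.locus_id, list(self.individuals), sub, new_center)

    def select_individuals(self, ids: Iterable[str]) -> "LocusAlignment | None":
        """Restrict to the given individuals; None if no rows remain."""
        wanted = set(ids)
        rows = [k for k, ind in enumerate(self.individuals) if ind in wanted]
        if not rows:
            return None
        return LocusAlignment(
            self.locus_id,
            [self.individuals[k] for k in rows],
            self.matrix[rows, :],
            self.center,
        )


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_locus_alignment(path: str | os.PathLike) -> LocusAlignment:
    """Read one aligned FASTA file into a :class:`LocusAlignment`.

    The locus id is the file name stem (with ``.gz`` and the FASTA extension
    removed); characters are uppercased; the center column is the alignment
    midpoint.
    """
    path = Path(path)
    stem = path.name
    if stem.endswith(".gz"):
        stem = stem[: -len(".gz")]
    stem = Path(stem).stem

    ids: list[str] = []
    rows: list[bytes] = []
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            ids.append(record.id)
            rows.append(str(record.seq).upper().encode("ascii"))
    if not rows:
        raise EmptyInputError(f"{path}: no FASTA records")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise MalformedAlignmentError(
            f"{path}: unequal sequence lengths {sorted(lengths)}"
        )
    matrix = np.frombuffer(b"".join(rows), dtype="S1").reshape(len(rows), -1)
    return LocusAlignment(stem, ids, matrix.copy())


def write_locus_alignment(locus: LocusAlignment, path: str | os.PathLike) -> None:
    """Write a locus back to aligned FASTA (plain text)."""
    with open(path, "w") as out:
        for ind, row in zip(locus.individuals, locus.matrix):
            out.write(f">{ind}\n{row.tobytes().decode('ascii')}\n")


def _iter_fasta_paths(source: str | os.PathLike) -> list[Path]:
    source = str(source)
    if os.path.isdir(source):
        paths = []
        for ext in FASTA_EXTENSIONS:
            paths.extend(Path(source).glob(f"*{ext}"))
            paths.extend(Path(source).glob(f"*{ext}.gz"))
        return sorted(paths)
    return sorted(Path(p) for p in _glob.glob(source))


def read_loci(source: str | os.PathLike, *, on_error: str = "raise") -> list[LocusAlignment]:
    """Read every per-locus FASTA under a directory or matching a glob.

    With ``on_error="skip"`` malformed files are logged and skipped
    (the CLI's behaviour); with ``"raise"`` the first error propagates.
    """
    paths = _iter_fasta_paths(source)
    if not paths:
        raise EmptyInputError(f"no FASTA files found under {source!r}")
    loci: list[LocusAlignment] = []
    skipped = 0
    for p in paths:
        try:
            loci.append(read_locus_alignment(p))
        except (MalformedAlignmentError, EmptyInputError):
            if on_error == "raise":
                raise
            skipped += 1
            logger.warning("skipping unreadable locus file %s", p)
    logger.info("read %d loci (%d files skipped)", len(loci), skipped)
    return loci


def filter_loci(
    loci: Sequence[LocusAlignment], min_individuals: int = 3
) -> list[LocusAlignment]:
    """Keep loci represented by at least ``min_individuals`` individuals.

    An individual counts as represented when its row carries at least one
    non-missing character, so fully gapped rows do not count. Order is
    preserved; an empty result is allowed (with a warning).
    """
    if min_individuals < 1:
        raise ParameterError("min_individuals must be >= 1")
    kept = [loc for loc in loci if loc.n_present_individuals() >= min_individuals]
    logger.info(
        "locus filter (>= %d individuals): kept %d / %d",
        min_individuals,
        len(kept),
        len(loci),
    )
    if not kept:
        logger.warning("no loci remain after the min-individuals filter")
    return kept
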