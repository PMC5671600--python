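"""Trinucleotide-frequency feature space.

A sequence is summarized by the counts of its 64 overlapping 3-mers
(lexicographic order AAA..TTT, sliding window of width 3, step 1). Windows
containing N are skipped and do not count toward ``n_valid``. With
``strand_symmetric=True`` (the default) the counts of the sequence and of its
reverse complement are summed before normalizing, which makes the feature
vector invariant to read orientation — reads land on either strand, so train
and test must live in the same strand-symmetrized space.

Training material is produced by tiling reference contigs into non-overlapping
clipped segments of ``segment_length`` (default 2,000 bp); the terminal
remainder shorter than a full segment is discarded.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import SeqRecord, revcomp

logger = logging.getLogger("sagbin")

BASES = "ACGT"
TRIMERS: tuple[str, ...] = tuple(
    "".join(t) for t in itertools.product(BASES, repeat=3)
)
TRIMER_INDEX: dict[str, int] = {t: i for i, t in enumerate(TRIMERS)}

# index permutation sending trimer i to its reverse complement
_RC_PERM = np.array([TRIMER_INDEX[revcomp(t)] for t in TRIMERS], dtype=np.intp)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i


class NoSignalError(ValueError):
    """Raised when a no-signal vector (n_valid == 0) is used as frequencies."""


@dataclass(frozen=True)
class TrimerVector:
    """Counts of the 64 overlapping trimers of one sequence.

    ``n_valid`` is the number of N-free windows counted (doubled when strand-
    symmetric). A vector with ``n_valid == 0`` carries no compositional signal;
    asking for its frequencies raises :class:`NoSignalError` rather than
    silently yielding a zero vector.
    """

    counts: np.ndarray  # shape (64,), int64
    n_valid: int
    strand_symmetric: bool = True

    def __post_init__(self) -> None:
        if self.counts.shape != (64,):
            raise ValueError("counts must have shape (64,)")
        if int(self.counts.sum()) != self.n_valid:
            raise ValueError("sum(counts) must equal n_valid")

    @property
    def has_signal(self) -> bool:
        return self.n_valid > 0

    @property
    def freqs(self) -> np.ndarray:
        if self.n_valid == 0:
            raise NoSignalError("no valid trimer windows (sequence too short or all-N)")
        return self.counts / self.n_valid


def _raw_counts(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < 3:
        return np.zeros(64, dtype=np.int64)
    valid = codes < 4
    ok = valid[:-2] & valid[1:-1] & valid[2:]
    idx = (
        codes[:-2].astype(np.int64) * 16
        + codes[1:-1].astype(np.int64) * 4
        + codes[2:].astype(np.int64)
    )[ok]
    return np.bincount(idx, minlength=64).astype(np.int64)


def trimer_counts(seq: str | SeqRecord, strand_symmetric: bool = True) -> TrimerVector:
    """Count overlapping trimers of ``seq`` (optionally strand-symmetrized)."""
    if isinstance(seq, SeqRecord):
        seq = seq.seq
    counts = _raw_counts(seq)
    if strand_symmetric:
        counts = counts + counts[_RC_PERM]
    return TrimerVector(
        counts=counts, n_valid=int(counts.sum()), strand_symmetric=strand_symmetric
    )


def feature_matrix(
    seqs: Sequence[str | SeqRecord], strand_symmetric: bool = True
) -> tuple[np.ndarray, list[int]]:
    """Stack frequency vectors into an (n, 64) matrix.

    Returns the matrix and the indices of no-signal inputs (their rows are
    left as NaN so callers cannot mistake them for real vectors).
    """
    X = np.full((len(seqs), 64), np.nan)
    no_signal = []
    for i, s in enumerate(seqs):
        v = trimer_counts(s, strand_symmetric=strand_symmetric)
        if v.has_signal:
            X[i] = v.freqs
        else:
            no_signal.append(i)
    return X, no_signal


@dataclass(frozen=True)
class TrainingSegment:
    parent_id: str
    start: int          # 0-based offset within the parent contig
    length: int
    label: str
    vector: TrimerVector


def clip_segments(
    contigs: Iterable[SeqRecord],
    labels: Mapping[str, str] | str,
    segment_length: int = 2000,
    strand_symmetric: bool = True,
) -> list[TrainingSegment]:
    """Tile each contig into non-overlapping labeled training segments.

    ``labels`` maps contig id to population label (or is a single label for
    all contigs). Tiling starts at position 0; the terminal remainder shorter
    than ``segment_length`` is discarded. Contigs shorter than one segment
    yield nothing (logged).
    """
    if segment_length < 100:
        raise ValueError("segment_length must be >= 100")
    segments = []
    for contig in contigs:
        label = labels if isinstance(labels, str) else labels[contig.id]
        n_full = len(contig.seq) // segment_length
        if n_full == 0:
            logger.info(
                "contig %s (%d bp) shorter than segment_length %d: no segments",
                contig.id, len(contig.seq), segment_length,
            )
            continue
        for k in range(n_full):
            start = k * segment_length
            piece = contig.seq[start : start + segment_length]
            segments.append(
                TrainingSegment(
                    parent_id=contig.id,
                    start=start,
                    length=segment_length,
                    label=label,
                    vector=trimer_counts(piece, strand_symmetric=strand_symmetric),
                )
            )
    return segments
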