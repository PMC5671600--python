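"""Readers/writers for the formats the pipeline touches, plus configuration.

Everything downstream works on :class:`SeqRecord` (nucleotide or protein) and
:class:`AlignmentHit` (the 12-column tabular convention of standard local-
alignment tools, so an external aligner's output can be substituted verbatim).

Coordinate convention: internal coordinates are 0-based half-open everywhere;
conversion to 1-based inclusive happens only at the tabular-hit boundary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger("sagbin")

NT_ALPHABET = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case nucleotide string (N self-maps)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """An identified sequence with optional per-base quality scores.

    ``moltype`` is ``"nt"`` (alphabet {A,C,G,T,N}) or ``"aa"``.
    """

    id: str
    seq: str
    description: str = ""
    quality: tuple[int, ...] | None = None
    moltype: str = "nt"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a non-empty token, got {self.id!r}")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.seq)}"
            )
        if self.moltype not in ("nt", "aa"):
            raise ValueError(f"unknown moltype {self.moltype!r}")

    def __len__(self) -> int:
        return len(self.seq)


def _sanitize_nt(seq: str, rec_id: str) -> str:
    """Upper-case; map ambiguity codes outside {A,C,G,T} to N with a logged count."""
    seq = seq.upper()
    if set(seq) <= NT_ALPHABET:
        return seq
    n_bad = sum(1 for c in seq if c not in NT_ALPHABET)
    logger.info("record %s: %d non-ACGT characters mapped to N", rec_id, n_bad)
    return "".join(c if c in NT_ALPHABET else "N" for c in seq)


def _validate_fasta_structure(path: Path) -> None:
    """Structural pre-check so parse errors can name a line number."""
    n_since_header = 0
    saw_header = False
    lineno = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if saw_header and n_since_header == 0:
                    raise ParseError(f"{path}:{lineno}: record with empty sequence")
                if not line[1:].strip():
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                saw_header = True
                n_since_header = 0
            else:
                if not saw_header:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                n_since_header += len(line.strip())
    if saw_header and n_since_header == 0:
        raise ParseError(f"{path}:{lineno}: record with empty sequence")


def read_fasta(path: str | Path, moltype: str = "nt") -> list[SeqRecord]:
    """Read a FASTA file into records, in file order.

    Multi-line sequences are concatenated; nucleotide input is case-folded to
    upper and ambiguity codes outside {A,C,G,T} are mapped to N (logged).
    Malformed files raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    _validate_fasta_structure(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if moltype == "nt":
            seq = _sanitize_nt(seq, rec.id)
        else:
            seq = seq.upper()
        desc = rec.description[len(rec.id):].strip()
        records.append(SeqRecord(id=rec.id, seq=seq, description=desc, moltype=moltype))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, line_width: int = 70) -> None:
    """Write records as FASTA; deterministic byte output for fixed input."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), line_width):
                fh.write(rec.seq[i : i + line_width] + "\n")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read FASTQ; qualities are kept but ignored by downstream stages."""
    records = []
    try:
        for rec in SeqIO.parse(str(Path(path)), "fastq"):
            seq = _sanitize_nt(str(rec.seq), rec.id)
            records.append(
                SeqRecord(
                    id=rec.id,
                    seq=seq,
                    quality=tuple(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return records


def read_seqs(path: str | Path) -> list[SeqRecord]:
    """Dispatch on extension: .fq/.fastq → FASTQ, anything else → FASTA."""
    suffix = Path(path).suffix.lower()
    if suffix in (".fq", ".fastq"):
        return read_fastq(path)
    return read_fasta(path)


# ---------------------------------------------------------------------------
# 12-column tabular hit format
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentHit:
    """One local-alignment record in the 12-column tabular convention.

    Coordinates are 1-based inclusive; minus-strand subject hits have
    ``sstart > send``. ``gap_opens`` is always 0 in ungapped mode.
    """

    qid: str
    sid: str
    percent_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 < self.percent_identity <= 100.0):
            raise ValueError(f"percent identity {self.percent_identity} out of (0,100]")
        if self.evalue < 0:
            raise ValueError("negative E-value")

    @property
    def minus_strand(self) -> bool:
        return self.sstart > self.send


_HIT_COLS = 12


def read_hits_tsv(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column tab-separated hit table (outfmt-6 style)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != _HIT_COLS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_HIT_COLS} tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                hits.append(
                    AlignmentHit(
                        qid=parts[0],
                        sid=parts[1],
                        percent_identity=float(parts[2]),
                        aln_len=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        qstart=int(parts[6]),
                        qend=int(parts[7]),
                        sstart=int(parts[8]),
                        send=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hits_tsv(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits losslessly (floats via shortest round-trip repr)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    (
                        h.qid,
                        h.sid,
                        repr(h.percent_identity),
                        str(h.aln_len),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.qstart),
                        str(h.qend),
                        str(h.sstart),
                        str(h.send),
                        repr(h.evalue),
                        repr(h.bitscore),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Fully-resolved parameters for every stage of the binning pipeline.

    Paths are interpreted relative to the config file's directory when loaded
    from TOML. The resolved config (plus seed) is embedded in every JSON run
    report so stochastic runs are reproducible.
    """

    # inputs
    anchor_fastas: dict[str, str] = field(default_factory=dict)  # label -> SAG FASTA
    reads_path: str = ""
    anchor_genes_path: str = ""   # nucleotide genes for homology recruitment
    marker_path: str = ""         # rRNA-like marker sequences (separate report)
    truth_path: str = ""          # read_id TAB label, enables evaluation block

    # featurization
    segment_length: int = 2000
    strand_symmetric: bool = True

    # classifier
    hidden_units: int = 0         # 0 -> (64 + C) // 2
    learning_rate: float = 0.3
    momentum: float = 0.2
    epochs: int = 500
    confidence_threshold: float = 0.9
    calibrate: bool = False       # pick threshold on a decoy-containing holdout
    holdout_fraction: float = 0.25

    # homology recruitment
    evalue_max: float = 1e-15
    marker_evalue_max: float = 1e-15
    match: int = 1
    mismatch: int = -1
    seed_k: int = 11
    xdrop: int = 20
    ka_K: float = 0.1

    # genome comparison defaults (used by the `compare` command)
    fragment_length: int = 1000
    ani_min_identity: float = 70.0
    ani_min_coverage: float = 70.0
    aai_min_identity: float = 30.0
    aai_min_coverage: float = 70.0

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must be in (0, 1]")
        if self.segment_length < 100:
            raise ValueError("segment_length must be >= 100")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if not self.match > 0 > self.mismatch:
            raise ValueError("need match > 0 > mismatch")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        base = path.parent
        for name in ("reads_path", "anchor_genes_path", "marker_path", "truth_path"):
            val = getattr(cfg, name)
            if val:
                setattr(cfg, name, str((base / val).resolve()))
        cfg.anchor_fastas = {
            k: str((base / v).resolve()) for k, v in cfg.anchor_fastas.items()
        }
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_run_report(report: dict, path: str | Path) -> None:
    """Write a JSON run report with stable key order."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
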