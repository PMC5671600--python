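"""Genome-to-genome comparison: fragment ANI, reciprocal-best-hit AAI,
and shared-gene fraction.

ANI follows the fragment-based scheme of the classic two-way calculator: the
query genome is chopped into consecutive 1,000-bp fragments, each fragment is
aligned to the other genome, and fragments whose best hit reaches >= 70%
identity over >= 70% of the fragment length contribute their identity to the
one-way mean; the reported ANI averages the two directions. Too few passing
fragments (default < 50 across both directions) makes the estimate
unreliable — genuinely unrelated genomes come back with a "below reliable
range" status instead of a number.

AAI pairs the two proteomes by reciprocal best hit (mutual top bit-score
passing identity/coverage filters, BLOSUM62 ungapped scoring) and averages
the identity over RBH pairs; the shared-gene fraction counts nucleotide genes
with an RBH partner under an E-value cutoff (1e-5 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .io_formats import SeqRecord
from .homology_recruiter import (
    ProteinScoringParams,
    ScoringParams,
    SeqDatabase,
)

logger = logging.getLogger("sagbin")

BELOW_RELIABLE = "below reliable range"


@dataclass(frozen=True)
class ANIResult:
    ani_percent: float | None
    status: str                    # "ok" or "below reliable range"
    n_fragments_total: int
    n_fragments_passing: int
    aligned_fraction: float
    one_way: tuple[float | None, float | None]  # A->B mean, B->A mean


@dataclass(frozen=True)
class AAIResult:
    aai_percent: float | None
    status: str
    n_rbh_pairs: int
    mean_identity: float | None
    median_identity: float | None


def _fragments(genome: SeqRecord, fragment_len: int) -> list[SeqRecord]:
    n_full = len(genome.seq) // fragment_len
    return [
        SeqRecord(
            id=f"{genome.id}.f{i + 1}",
            seq=genome.seq[i * fragment_len : (i + 1) * fragment_len],
        )
        for i in range(n_full)
    ]


def _one_way_ani(
    query: SeqRecord,
    db: SeqDatabase,
    fragment_len: int,
    min_identity: float,
    min_coverage: float,
) -> tuple[list[float], int]:
    """(identities of passing fragments, total fragments) for query -> db."""
    identities = []
    frags = _fragments(query, fragment_len)
    min_len = min_coverage / 100.0 * fragment_len
    for frag in frags:
        best = None
        for hit in db.search(frag, min_raw_score=int(min_len) // 4):
            if hit.percent_identity >= min_identity and hit.aln_len >= min_len:
                best = hit  # hits are bitscore-sorted: first passing is best
                break
        if best is not None:
            identities.append(best.percent_identity)
    return identities, len(frags)


def ani(
    genome_a: SeqRecord,
    genome_b: SeqRecord,
    fragment_len: int = 1000,
    min_identity: float = 70.0,
    min_coverage: float = 70.0,
    min_fragments: int = 50,
    params: ScoringParams | None = None,
) -> ANIResult:
    """Two-way fragment-based average nucleotide identity."""
    if params is None:
        params = ScoringParams()
    for g in (genome_a, genome_b):
        if len(g.seq) < fragment_len:
            raise ValueError(
                f"genome {g.id!r} ({len(g.seq)} bp) shorter than one fragment "
                f"({fragment_len} bp)"
            )
    db_b = SeqDatabase([genome_b], params)
    db_a = SeqDatabase([genome_a], params)
    ids_ab, n_ab = _one_way_ani(genome_a, db_b, fragment_len, min_identity, min_coverage)
    ids_ba, n_ba = _one_way_ani(genome_b, db_a, fragment_len, min_identity, min_coverage)
    n_total = n_ab + n_ba
    n_pass = len(ids_ab) + len(ids_ba)
    one_way = (
        float(np.mean(ids_ab)) if ids_ab else None,
        float(np.mean(ids_ba)) if ids_ba else None,
    )
    if n_pass < min_fragments:
        return ANIResult(
            ani_percent=None,
            status=BELOW_RELIABLE,
            n_fragments_total=n_total,
            n_fragments_passing=n_pass,
            aligned_fraction=n_pass / n_total if n_total else 0.0,
            one_way=one_way,
        )
    return ANIResult(
        ani_percent=float(np.mean([v for v in one_way if v is not None])),
        status="ok",
        n_fragments_total=n_total,
        n_fragments_passing=n_pass,
        aligned_fraction=n_pass / n_total,
        one_way=one_way,
    )


def translate_cds(nt_seq: str, table: int = 11) -> str:
    """Translate a CDS (bacterial/archaeal code by default); the terminal stop
    is dropped, an internal stop or a length not divisible by 3 is an error
    naming the codon."""
    if len(nt_seq) % 3 != 0:
        raise ValueError(
            f"CDS length {len(nt_seq)} is not divisible by 3"
        )
    aa = str(Seq(nt_seq).translate(table=table))
    internal = aa[:-1].find("*")
    if internal != -1:
        raise ValueError(f"internal stop codon at codon {internal + 1}")
    return aa[:-1] if aa.endswith("*") else aa


def _best_hits(
    queries: Sequence[SeqRecord],
    db: SeqDatabase,
    min_identity: float,
    min_coverage: float,
) -> dict[str, tuple[str, float, float]]:
    """query id -> (best subject id, identity, bitscore), after filters."""
    best = {}
    for q in queries:
        if len(q.seq) < db.params.seed_k:
            continue
        min_len = min_coverage / 100.0 * len(q.seq)
        for hit in db.search(q):
            if hit.percent_identity >= min_identity and hit.aln_len >= min_len:
                best[q.id] = (hit.sid, hit.percent_identity, hit.bitscore)
                break
    return best


def _rbh_pairs(
    fwd: dict[str, tuple[str, float, float]],
    rev: dict[str, tuple[str, float, float]],
) -> list[tuple[str, str, float]]:
    """Mutual best pairs with the mean of the two directions' identities."""
    pairs = []
    for a, (b, id_ab, _) in fwd.items():
        back = rev.get(b)
        if back is not None and back[0] == a:
            pairs.append((a, b, 0.5 * (id_ab + back[1])))
    return pairs


def aai(
    proteome_a: Sequence[SeqRecord],
    proteome_b: Sequence[SeqRecord],
    min_identity: float = 30.0,
    min_coverage: float = 70.0,
    params: ProteinScoringParams | None = None,
) -> AAIResult:
    """Reciprocal-best-hit average amino-acid identity (symmetric)."""
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must contain at least one protein")
    if params is None:
        params = ProteinScoringParams()
    db_b = SeqDatabase(list(proteome_b), params)
    db_a = SeqDatabase(list(proteome_a), params)
    fwd = _best_hits(proteome_a, db_b, min_identity, min_coverage)
    rev = _best_hits(proteome_b, db_a, min_identity, min_coverage)
    pairs = _rbh_pairs(fwd, rev)
    if not pairs:
        return AAIResult(
            aai_percent=None, status="no reciprocal best hits",
            n_rbh_pairs=0, mean_identity=None, median_identity=None,
        )
    identities = [p[2] for p in pairs]
    return AAIResult(
        aai_percent=float(np.mean(identities)),
        status="ok",
        n_rbh_pairs=len(pairs),
        mean_identity=float(np.mean(identities)),
        median_identity=float(median(identities)),
    )


@dataclass(frozen=True)
class SharedGeneResult:
    fraction: float
    n_shared: int
    n_total: int
    pairs: list[tuple[str, str]]


def shared_gene_fraction(
    genes_a: Sequence[SeqRecord],
    genes_b: Sequence[SeqRecord],
    evalue_max: float = 1e-5,
    params: ScoringParams | None = None,
) -> SharedGeneResult:
    """Fraction of A's genes with a reciprocal best hit in B under the cutoff."""
    if not genes_a or not genes_b:
        raise ValueError("both gene sets must be non-empty")
    if params is None:
        params = ScoringParams()
    db_b = SeqDatabase(list(genes_b), params)
    db_a = SeqDatabase(list(genes_a), params)

    def best(queries, db):
        out = {}
        for q in queries:
            if len(q.seq) < params.seed_k:
                continue
            for hit in db.search(q):
                if hit.evalue <= evalue_max:
                    out[q.id] = (hit.sid, hit.percent_identity, hit.bitscore)
                    break
        return out

    fwd = best(genes_a, db_b)
    rev = best(genes_b, db_a)
    pairs = [(a, b) for a, b, _ in _rbh_pairs(fwd, rev)]
    return SharedGeneResult(
        fraction=len(pairs) / len(genes_a),
        n_shared=len(pairs),
        n_total=len(genes_a),
        pairs=sorted(pairs),
    )
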