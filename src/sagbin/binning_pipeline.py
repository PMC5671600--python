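"""End-to-end binning: featurize -> train -> (calibrate) -> classify ->
recruit -> merge, plus per-bin assembly statistics.

The terminal artifact is the labeled read set per bin; de novo assembly of
those reads is deliberately out of scope (an external assembler's contigs can
be fed back through :func:`assembly_stats`).

Merging policy: a read claimed by both the classifier and homology
recruitment with the same label gets provenance "both"; on a label conflict
homology wins — recruitment is anchored in explicit gene identity while
composition is correlative — and the conflict rate is reported as a quality
metric. "Removal of redundant sequences" is read minimally: exact (or
reverse-complement-exact) duplicate read sequences under different ids
collapse to the lexicographically smallest id, logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    AlignmentHit,
    PipelineConfig,
    SeqRecord,
    read_seqs,
    revcomp,
    write_run_report,
)
from .trimer_features import clip_segments, feature_matrix
from .mlp_classifier import (
    Hyperparameters,
    Prediction,
    assign_reads,
    calibrate_threshold,
    segments_to_xy,
    train_mlp,
)
from .homology_recruiter import (
    RecruitmentResult,
    ScoringParams,
    recover_marker_reads,
    recruit_reads,
)
from .evaluation import evaluate_bins

logger = logging.getLogger("sagbin")

PROVENANCE_MLP = "mlp"
PROVENANCE_HOMOLOGY = "homology"
PROVENANCE_BOTH = "both"


@dataclass(frozen=True)
class ReadBin:
    label: str
    provenance: str                 # mlp | homology | both
    confidence: float | None = None  # MLP confidence, when applicable
    evalue: float | None = None      # best recruitment E-value, when applicable


@dataclass
class BinAssignment:
    assignments: dict[str, ReadBin]
    n_conflicts: int = 0
    collapsed: dict[str, str] = field(default_factory=dict)  # dropped -> kept

    def labels(self) -> dict[str, str]:
        return {rid: rb.label for rid, rb in self.assignments.items()}

    def counts_by_provenance(self) -> dict[str, int]:
        out = {PROVENANCE_MLP: 0, PROVENANCE_HOMOLOGY: 0, PROVENANCE_BOTH: 0}
        for rb in self.assignments.values():
            out[rb.provenance] += 1
        return out

    def counts_by_bin(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rb in self.assignments.values():
            out[rb.label] = out.get(rb.label, 0) + 1
        return dict(sorted(out.items()))


def merge_and_dedupe(
    mlp_assigned: Mapping[str, tuple[str, float | None]],
    recruited: Mapping[str, tuple[str, float | None]],
    reads: Sequence[SeqRecord] | None = None,
) -> BinAssignment:
    """Union the two assignment sources and collapse duplicate sequences.

    ``mlp_assigned`` maps read_id to (label, confidence); ``recruited`` maps
    read_id to (label, best E-value). Label conflicts resolve in favor of
    homology and are counted. When ``reads`` is given, reads whose sequences
    are identical (or reverse-complement identical) keep only the
    lexicographically smallest assigned id.
    """
    merged: dict[str, ReadBin] = {}
    conflicts = 0
    for rid, (label, conf) in mlp_assigned.items():
        merged[rid] = ReadBin(label=label, provenance=PROVENANCE_MLP, confidence=conf)
    for rid, (label, ev) in recruited.items():
        prior = merged.get(rid)
        if prior is None:
            merged[rid] = ReadBin(label=label, provenance=PROVENANCE_HOMOLOGY, evalue=ev)
        elif prior.label == label:
            merged[rid] = ReadBin(
                label=label,
                provenance=PROVENANCE_BOTH,
                confidence=prior.confidence,
                evalue=ev,
            )
        else:
            conflicts += 1
            logger.info(
                "label conflict for %s: mlp=%s homology=%s -> homology wins",
                rid, prior.label, label,
            )
            merged[rid] = ReadBin(label=label, provenance=PROVENANCE_HOMOLOGY, evalue=ev)

    collapsed: dict[str, str] = {}
    if reads is not None:
        groups: dict[str, list[str]] = {}
        seq_by_id = {r.id: r.seq for r in reads}
        for rid in merged:
            seq = seq_by_id.get(rid)
            if seq is None:
                continue
            canon = min(seq, revcomp(seq))
            groups.setdefault(canon, []).append(rid)
        for ids in groups.values():
            if len(ids) < 2:
                continue
            ids.sort()
            keep = ids[0]
            for drop in ids[1:]:
                collapsed[drop] = keep
                logger.info("duplicate sequence: %s collapsed into %s", drop, keep)
                del merged[drop]
    return BinAssignment(assignments=merged, n_conflicts=conflicts, collapsed=collapsed)


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_len: int
    largest: int
    n50: int
    l50: int
    gc_percent: float

    def to_dict(self) -> dict:
        return {
            "n_contigs": self.n_contigs,
            "total_len": self.total_len,
            "largest": self.largest,
            "n50": self.n50,
            "l50": self.l50,
            "gc_percent": self.gc_percent,
        }


def assembly_stats(contigs: Sequence[SeqRecord]) -> AssemblyStats:
    """Standard assembly summary.

    N50 is the smallest length l such that contigs of length >= l sum to at
    least half the assembly; L50 is how many contigs that takes. G+C percent
    is computed over unambiguous bases only.
    """
    if not contigs:
        raise ValueError("assembly_stats requires at least one contig")
    lengths = np.sort(np.array([len(c.seq) for c in contigs]))[::-1]
    total = int(lengths.sum())
    cum = np.cumsum(lengths)
    # smallest index where the descending cumulative sum reaches half the total
    i = int(np.searchsorted(cum, total / 2))
    gc = at = 0
    for c in contigs:
        gc += c.seq.count("G") + c.seq.count("C")
        at += c.seq.count("A") + c.seq.count("T")
    denom = gc + at
    return AssemblyStats(
        n_contigs=len(contigs),
        total_len=total,
        largest=int(lengths[0]),
        n50=int(lengths[i]),
        l50=i + 1,
        gc_percent=100.0 * gc / denom if denom else 0.0,
    )


def _read_truth(path: str) -> dict[str, str]:
    truth = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            rid, label = line.split("\t")
            truth[rid] = label
    return truth


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> tuple[BinAssignment, dict]:
    """Run the full binning pipeline described by ``config``.

    Returns the merged assignment and a JSON-serializable run report holding
    the resolved config, the seed, per-stage counts, the calibration table
    (when calibration ran) and the evaluation block (when ground truth was
    supplied). Reruns with the same config are byte-identical — the report
    carries no timestamps.
    """
    report: dict = {"config": config.to_dict(), "seed": config.seed}

    def _stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    stage = _stage("featurize")
    try:
        if not config.anchor_fastas:
            raise ValueError("config.anchor_fastas is empty")
        segments = []
        for label in sorted(config.anchor_fastas):
            contigs = read_seqs(config.anchor_fastas[label])
            segments.extend(
                clip_segments(
                    contigs,
                    labels=label,
                    segment_length=config.segment_length,
                    strand_symmetric=config.strand_symmetric,
                )
            )
        report["n_training_segments"] = len(segments)

        stage = _stage("train")
        X, y = segments_to_xy(segments)
        hyper = Hyperparameters(
            learning_rate=config.learning_rate,
            momentum=config.momentum,
            epochs=config.epochs,
            hidden_units=config.hidden_units,
            seed=config.seed,
        )
        model = train_mlp(
            X, y, hyper,
            feature_convention={"k": 3, "strand_symmetric": config.strand_symmetric},
        )
        report["classes"] = model.class_labels
        report["final_training_loss"] = model.training_log[-1]

        stage = _stage("classify")
        reads = read_seqs(config.reads_path)
        threshold = config.confidence_threshold

        if config.calibrate:
            stage = _stage("calibrate")
            if not config.truth_path:
                raise ValueError("calibration requires a labeled holdout (truth_path)")
            truth = _read_truth(config.truth_path)
            rng = np.random.default_rng(config.seed)
            n_hold = max(1, int(round(config.holdout_fraction * len(reads))))
            hold_idx = rng.choice(len(reads), size=n_hold, replace=False)
            hold_reads = [reads[i] for i in sorted(hold_idx)]
            Xh, no_sig = feature_matrix(
                hold_reads, strand_symmetric=config.strand_symmetric
            )
            keep = [i for i in range(len(hold_reads)) if i not in set(no_sig)]
            cal = calibrate_threshold(
                model,
                Xh[keep],
                [truth[hold_reads[i].id] for i in keep],
            )
            threshold = cal.chosen_threshold
            report["calibration"] = {
                "chosen_threshold": cal.chosen_threshold,
                "table": cal.to_table(),
            }
        report["confidence_threshold"] = threshold

        stage = _stage("classify")
        assigned, unassigned = assign_reads(model, reads, threshold=threshold)
        report["n_mlp_assigned"] = len(assigned)
        report["n_unassigned"] = len(unassigned)

        stage = _stage("recruit")
        params = ScoringParams(
            match=config.match,
            mismatch=config.mismatch,
            seed_k=config.seed_k,
            xdrop=config.xdrop,
            K=config.ka_K,
        )
        recruited_map: dict[str, tuple[str, float | None]] = {}
        if config.anchor_genes_path:
            genes = read_seqs(config.anchor_genes_path)
            gene_labels = {g.id: g.description or g.id.split(".")[0] for g in genes}
            rec = recruit_reads(
                genes, reads, anchor_labels=gene_labels, params=params,
                evalue_max=config.evalue_max,
            )
            recruited_map = {
                rid: (label, hit.evalue) for rid, (label, hit) in rec.recruited.items()
            }
            report["n_recruited"] = len(recruited_map)
            report["recruitment_db_len"] = rec.db_len
        if config.marker_path:
            stage = _stage("marker-recovery")
            markers = read_seqs(config.marker_path)
            marker_labels = {m.id: m.description or m.id.split(".")[0] for m in markers}
            mrec = recover_marker_reads(
                markers, reads, marker_labels=marker_labels, params=params,
                evalue_max=config.marker_evalue_max,
            )
            report["n_marker_recovered"] = len(mrec.recruited)
            report["marker_read_ids"] = sorted(mrec.recruited)
            for rid, (label, hit) in mrec.recruited.items():
                prev = recruited_map.get(rid)
                if prev is None or hit.evalue < (prev[1] or np.inf):
                    recruited_map[rid] = (label, hit.evalue)

        stage = _stage("merge")
        mlp_map = {rid: (p.top_label, p.confidence) for rid, p in assigned.items()}
        bins = merge_and_dedupe(mlp_map, recruited_map, reads=reads)
        report["provenance_counts"] = bins.counts_by_provenance()
        report["bin_counts"] = bins.counts_by_bin()
        report["n_label_conflicts"] = bins.n_conflicts
        report["n_collapsed_duplicates"] = len(bins.collapsed)

        if config.truth_path:
            stage = _stage("evaluate")
            truth = _read_truth(config.truth_path)
            ev = evaluate_bins(bins.labels(), truth, model_classes=model.class_labels)
            report["evaluation"] = ev.to_dict()
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "assignments.tsv", "w") as fh:
            for rid in sorted(bins.assignments):
                rb = bins.assignments[rid]
                fh.write(
                    f"{rid}\t{rb.label}\t{rb.provenance}\t"
                    f"{'' if rb.confidence is None else repr(rb.confidence)}\t"
                    f"{'' if rb.evalue is None else repr(rb.evalue)}\n"
                )
        write_run_report(report, outdir / "report.json")
    return bins, report
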