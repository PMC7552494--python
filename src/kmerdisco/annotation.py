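"""Alignment-derived feature (ADF) classification of assembled sequences.

Once the graph sequences are aligned to a genome (any aligner emitting
SAM), each one is turned into annotated events against a GTF gene model:

* ``insertion`` / ``deletion`` / ``clipping`` from I, D and S CIGAR
  operations; ``mutation`` from mismatches inside M runs (requires MD or
  NM evidence — bare M cannot distinguish match from mismatch);
* ``splice`` when a sequence is split across distinct exons of one
  transcript, via an N-gapped CIGAR or a supplementary split alignment;
* ``DE`` when the k-mer graphs cover at least a fraction d (default 0.5)
  of an annotated transcript, ``gene`` when they cover less but more
  than nothing; ``intron`` when an annotated intron is covered >= d;
* ``intergenic`` for genomic hits outside any transcript, ``unmapped``
  and ``multimapped`` for sequences without a usable unique hit.

One representative k-mer is preserved per event: the candidate with the
highest accuracy, ties broken by the smaller integer code.  All internal
coordinates are 0-based half-open; GTF (1-based inclusive) and SAM
(1-based) are converted at the boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
import gffutils

from .kmer_store import encode_kmer
from .graph import GraphSequence

DEFAULT_EXCLUDED_TYPES = frozenset({"retained_intron"})


@dataclass
class TranscriptModel:
    """One transcript: sorted exons plus derived introns (0-based half-open)."""

    gene_id: str
    gene_name: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    transcript_type: str = ""

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


def load_gtf(
    path: str | Path, excluded_types: Iterable[str] = DEFAULT_EXCLUDED_TYPES
) -> list[TranscriptModel]:
    """Parse a GTF into transcript models, dropping excluded biotypes."""
    path = Path(path)
    excluded = set(excluded_types)
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if len(line.split("\t")) < 9:
            raise ValueError(f"{path}: malformed GTF line {i}")
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        tid = exon.attributes.get("transcript_id", [""])[0]
        ttype = (
            exon.attributes.get("transcript_type", [""])[0]
            or exon.attributes.get("transcript_biotype", [""])[0]
        )
        if ttype in excluded:
            continue
        rec = by_tx.setdefault(
            tid,
            {
                "gene_id": exon.attributes.get("gene_id", [""])[0],
                "gene_name": exon.attributes.get("gene_name", [""])[0]
                or exon.attributes.get("gene_id", [""])[0],
                "chrom": exon.seqid,
                "strand": exon.strand,
                "type": ttype,
                "exons": [],
            },
        )
        # GTF is 1-based inclusive
        rec["exons"].append((exon.start - 1, exon.end))
    return [
        TranscriptModel(
            gene_id=r["gene_id"],
            gene_name=r["gene_name"],
            transcript_id=tid,
            chrom=r["chrom"],
            strand=r["strand"],
            exons=r["exons"],
            transcript_type=r["type"],
        )
        for tid, r in sorted(by_tx.items())
    ]


# ---------------------------------------------------------------------------
# interval arithmetic (merged, never double-counted)


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def covered_fraction(target: Sequence[tuple[int, int]], cover: Sequence[tuple[int, int]]) -> float:
    """Fraction of the target intervals covered by the cover intervals."""
    target = merge_intervals(target)
    cover = merge_intervals(cover)
    total = sum(e - s for s, e in target)
    if total == 0:
        return 0.0
    covered = 0
    for ts, te in target:
        for cs, ce in cover:
            covered += max(0, min(te, ce) - max(ts, cs))
    return covered / total


# ---------------------------------------------------------------------------
# events


@dataclass
class AdfEvent:
    """One annotated feature with its representative k-mer."""

    event_class: str
    chrom: str | None
    start: int | None  # 0-based half-open internally
    end: int | None
    gene_id: str = ""
    gene_name: str = ""
    transcript_id: str = ""
    note: str = ""
    sequences: list[str] = field(default_factory=list)
    candidates: list[tuple[str, float]] = field(default_factory=list)
    kmer: str = ""
    accuracy: float = float("nan")

    @property
    def key(self) -> tuple:
        return (self.event_class, self.chrom, self.start, self.end, self.transcript_id)


def _candidates_of(seq: GraphSequence | None, seqmap: dict) -> list[tuple[str, float]]:
    if seq is None:
        return []
    accs = seqmap.get(seq.name)
    if accs is not None:
        return accs
    return [(m, seq.best_accuracy if m == seq.best_kmer else 0.0) for m in seq.members]


def classify_events(
    sam_path: str | Path,
    models: Sequence[TranscriptModel],
    sequences: Sequence[GraphSequence] | None = None,
    d: float = 0.5,
    member_accuracies: dict[str, list[tuple[str, float]]] | None = None,
) -> list[AdfEvent]:
    """Classify aligned graph sequences into ADF events.

    ``member_accuracies`` maps a sequence name to its (k-mer, accuracy)
    candidates; when absent it is derived from ``sequences``.  Transcript
    and intron coverage is accumulated over all sequences before the
    coverage-based events are emitted, so the result is independent of
    alignment order.
    """
    seq_by_name: dict[str, GraphSequence] = {s.name: s for s in (sequences or [])}
    if member_accuracies is None:
        member_accuracies = {}
        for s in sequences or []:
            member_accuracies[s.name] = _candidates_of(s, {})
    chrom_models: dict[str, list[TranscriptModel]] = {}
    for m in models:
        chrom_models.setdefault(m.chrom, []).append(m)
    known_chroms = set(chrom_models)

    events: dict[tuple, AdfEvent] = {}

    def emit(ev: AdfEvent) -> None:
        prev = events.get(ev.key)
        if prev is None:
            events[ev.key] = ev
        else:
            prev.sequences = sorted(set(prev.sequences) | set(ev.sequences))
            prev.candidates.extend(ev.candidates)

    # per-transcript / per-intron coverage accumulators
    tx_cover: dict[str, list[tuple[int, int]]] = {}
    tx_support: dict[str, list[str]] = {}

    by_query: dict[str, list] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            by_query.setdefault(rec.query_name, []).append(rec)

    for qname in sorted(by_query):
        recs = by_query[qname]
        cands = member_accuracies.get(qname, [])
        if all(r.is_unmapped for r in recs):
            emit(AdfEvent("unmapped", None, None, None, sequences=[qname], candidates=list(cands)))
            continue
        mapped = [r for r in recs if not r.is_unmapped]
        n_sites = sum(1 for r in mapped if not r.is_supplementary)
        if any(r.is_secondary for r in mapped) or n_sites > 1 or all(
            r.mapping_quality == 0 for r in mapped
        ):
            chrom = mapped[0].reference_name
            emit(
                AdfEvent(
                    "multimapped",
                    chrom,
                    mapped[0].reference_start,
                    mapped[0].reference_end,
                    sequences=[qname],
                    candidates=list(cands),
                )
            )
            continue

        overlapped_any = False
        antisense_only = False
        split_exons: dict[str, set[int]] = {}
        for rec in mapped:
            chrom = rec.reference_name
            if chrom not in known_chroms:
                warnings.warn(f"reference {chrom} absent from annotation; treated as intergenic")
            here = chrom_models.get(chrom, [])
            blocks = rec.get_blocks()
            aln_strand = "-" if rec.is_reverse else "+"
            touching = [
                m for m in here if m.start < rec.reference_end and m.end > rec.reference_start
            ]
            sense_models = [m for m in touching if m.strand == aln_strand]
            if touching and not sense_models:
                antisense_only = True
            if sense_models:
                overlapped_any = True
            for m in sense_models:
                # raw blocks accumulate per transcript; exon/intron coverage
                # fractions clip them against the respective intervals later
                tx_cover.setdefault(m.transcript_id, []).extend(blocks)
                tx_support.setdefault(m.transcript_id, []).append(qname)
                hit_exons = {
                    i
                    for i, (es, ee) in enumerate(m.exons)
                    for bs, be in blocks
                    if bs < ee and be > es
                }
                if hit_exons:
                    split_exons.setdefault(m.transcript_id, set()).update(hit_exons)

            # CIGAR-derived events
            ref_pos = rec.reference_start
            for op, length in rec.cigartuples or []:
                if op in (0, 7, 8):  # M, =, X consume both
                    ref_pos += length
                elif op == 1:  # I
                    emit(
                        AdfEvent(
                            "insertion",
                            chrom,
                            ref_pos,
                            ref_pos,
                            sequences=[qname],
                            candidates=list(cands),
                            note=f"len={length}",
                        )
                    )
                elif op == 2:  # D
                    emit(
                        AdfEvent(
                            "deletion",
                            chrom,
                            ref_pos,
                            ref_pos + length,
                            sequences=[qname],
                            candidates=list(cands),
                        )
                    )
                    ref_pos += length
                elif op == 4:  # S
                    emit(
                        AdfEvent(
                            "clipping",
                            chrom,
                            ref_pos,
                            ref_pos,
                            sequences=[qname],
                            candidates=list(cands),
                            note=f"len={length}",
                        )
                    )
                elif op == 3:  # N
                    ref_pos += length

            # mismatches need MD/NM evidence
            if rec.has_tag("MD") or rec.has_tag("NM"):
                try:
                    pairs = rec.get_aligned_pairs(with_seq=True)
                except ValueError:
                    pairs = []
                for qpos, rpos, ref_base in pairs:
                    if qpos is None or rpos is None or ref_base is None:
                        continue
                    if ref_base.islower():  # pysam marks mismatches lowercase
                        emit(
                            AdfEvent(
                                "mutation",
                                chrom,
                                rpos,
                                rpos + 1,
                                sequences=[qname],
                                candidates=list(cands),
                                note=f"ref={ref_base.upper()}",
                            )
                        )

        # splice: N-gapped or split alignment across distinct exons of one tx
        for tid, exon_ids in split_exons.items():
            if len(exon_ids) < 2:
                continue
            m = next(t for t in models if t.transcript_id == tid)
            gapped = any((op == 3) for r in mapped for op, _ in (r.cigartuples or []))
            if gapped or len(mapped) > 1:
                lo, hi = sorted(exon_ids)[0], sorted(exon_ids)[-1]
                emit(
                    AdfEvent(
                        "splice",
                        m.chrom,
                        m.exons[lo][1],
                        m.exons[hi][0],
                        gene_id=m.gene_id,
                        gene_name=m.gene_name,
                        transcript_id=tid,
                        sequences=[qname],
                        candidates=list(cands),
                    )
                )

        if not overlapped_any:
            r0 = mapped[0]
            emit(
                AdfEvent(
                    "intergenic",
                    r0.reference_name,
                    r0.reference_start,
                    r0.reference_end,
                    sequences=[qname],
                    candidates=list(cands),
                    note="antisense" if antisense_only else "",
                )
            )

    # coverage-based events over the accumulated graph footprint
    for m in models:
        cover = tx_cover.get(m.transcript_id, [])
        if not cover:
            continue
        support = sorted(set(tx_support.get(m.transcript_id, [])))
        cands = [c for q in support for c in member_accuracies.get(q, [])]
        frac = covered_fraction(m.exons, cover)
        cls = "DE" if frac >= d else "gene"
        if frac > 0:
            emit(
                AdfEvent(
                    cls,
                    m.chrom,
                    m.start,
                    m.end,
                    gene_id=m.gene_id,
                    gene_name=m.gene_name,
                    transcript_id=m.transcript_id,
                    note=f"coverage={frac:.3f}",
                    sequences=support,
                    candidates=cands,
                )
            )
        for intron in m.introns:
            ifrac = covered_fraction([intron], cover)
            if ifrac >= d:
                emit(
                    AdfEvent(
                        "intron",
                        m.chrom,
                        intron[0],
                        intron[1],
                        gene_id=m.gene_id,
                        gene_name=m.gene_name,
                        transcript_id=m.transcript_id,
                        note=f"coverage={ifrac:.3f}",
                        sequences=support,
                        candidates=cands,
                    )
                )

    out = list(events.values())
    select_representatives(out)
    return out


def select_representatives(events: Sequence[AdfEvent]) -> Sequence[AdfEvent]:
    """Keep one k-mer per event: highest accuracy, ties to smaller code."""
    for ev in events:
        if not ev.candidates:
            continue
        best = max(ev.candidates, key=lambda ka: (ka[1], -encode_kmer(ka[0])))
        ev.kmer, ev.accuracy = best
    return events


def aggregate_output(
    events: Sequence[AdfEvent], json_path: str | Path | None = None, tsv_path: str | Path | None = None
) -> pd.DataFrame:
    """Flat report: JSON (full) and TSV sorted by accuracy descending."""
    rows = [
        {
            "event": ev.event_class,
            "chrom": ev.chrom or "",
            # report 1-based inclusive coordinates
            "start": (ev.start + 1) if ev.start is not None else "",
            "end": ev.end if ev.end is not None else "",
            "gene": ev.gene_name,
            "transcript": ev.transcript_id,
            "kmer": ev.kmer,
            "accuracy": ev.accuracy,
            "sequences": ",".join(ev.sequences),
            "note": ev.note,
        }
        for ev in events
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "event",
            "chrom",
            "start",
            "end",
            "gene",
            "transcript",
            "kmer",
            "accuracy",
            "sequences",
            "note",
        ],
    )
    df = df.sort_values("accuracy", ascending=False, kind="mergesort").reset_index(drop=True)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(
                [
                    {
                        "event": ev.event_class,
                        "chrom": ev.chrom,
                        "start": ev.start,
                        "end": ev.end,
                        "gene_id": ev.gene_id,
                        "gene_name": ev.gene_name,
                        "transcript_id": ev.transcript_id,
                        "kmer": ev.kmer,
                        "accuracy": None if ev.accuracy != ev.accuracy else ev.accuracy,
                        "sequences": ev.sequences,
                        "candidates": [[k, a] for k, a in ev.candidates],
                        "note": ev.note,
                    }
                    for ev in events
                ],
                indent=1,
            )
        )
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    return df
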