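"""Ground-truthed synthetic cohorts for exercising the whole pipeline.

The generator emits a toy genome (one chromosome of spacer-separated
genes), a matching GTF, per-sample FASTQ read sets for two (or more)
sample groups, and a truth table naming every planted signal with the
k-mers diagnostic of it.  Three signal classes are planted:

* ``DE``     — a single-exon gene expressed with a group-specific fold
               change; every transcript k-mer is diagnostic.
* ``SNV``    — a single-exon gene whose transcript carries an alternative
               allele at a group-specific frequency; the k windows of the
               alt transcript overlapping the variant are diagnostic.
* ``splice`` — a three-exon gene expressed as a mixture of the full
               isoform and an exon-skipping isoform with group-specific
               fractions; the k-1 junction-spanning k-mers of the
               skipping isoform are diagnostic.

``null`` genes expressed identically in all groups provide background.
Reads are drawn uniformly along transcripts with uniform substitution
errors and no quality model; read starts, allele and isoform choices are
the only within-group randomness.  Everything derives from one seed, so
output is byte-identical across runs.

The module also bundles a small exact/affine aligner (edlib-based) that
maps assembled sequences back onto the toy genome through the known
isoform structures, writing SAM with CIGAR/NM/MD — a synthetic stand-in
for running a spliced genome aligner on real data.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
import pysam

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    seed: int
    n_groups: int = 2
    samples_per_group: int = 20
    n_de: int = 10
    n_snv: int = 5
    n_splice: int = 3
    n_null: int = 4
    gene_length: int = 300
    splice_exon_lengths: tuple[int, int, int] = (150, 90, 150)
    intron_length: int = 80
    spacer_length: int = 150
    read_length: int = 100
    depth: float = 30.0
    de_fold: float = 6.0
    snv_alt_freq: tuple[float, ...] = (1.0, 0.0)
    skip_isoform_fraction: tuple[float, ...] = (0.9, 0.1)
    error_rate: float = 0.001
    k: int = 31

    def __post_init__(self) -> None:
        for p in (self.error_rate, *self.snv_alt_freq, *self.skip_isoform_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if len(self.snv_alt_freq) < self.n_groups or len(self.skip_isoform_fraction) < self.n_groups:
            raise ValueError("per-group frequencies must cover every group")

    @property
    def group_names(self) -> list[str]:
        return [chr(ord("A") + g) for g in range(self.n_groups)]


@dataclass
class Isoform:
    """One expressed transcript: an ordered subset of a gene's exons."""

    isoform_id: str
    exon_indices: list[int]
    annotated: bool = True


@dataclass
class SynthGene:
    gene_id: str
    signal_class: str  # DE | SNV | splice | null
    chrom: str
    exons: list[tuple[int, int]]  # genomic 0-based half-open
    isoforms: list[Isoform]
    snv_offset: int | None = None  # transcript coordinate of the variant
    snv_ref: str | None = None
    snv_alt: str | None = None
    de_group: int | None = None  # group index with the elevated expression

    def isoform_tx(self, reference: "Reference", iso: Isoform, allele: str = "ref") -> str:
        seq = "".join(
            reference.genome[self.chrom][s:e] for i in (iso.exon_indices) for s, e in [self.exons[i]]
        )
        if allele == "alt" and self.snv_offset is not None:
            seq = seq[: self.snv_offset] + self.snv_alt + seq[self.snv_offset + 1 :]
        return seq

    def tx_to_genome(self, iso: Isoform, tx_pos: int) -> int:
        """Map a transcript coordinate to a genomic coordinate."""
        off = tx_pos
        for i in iso.exon_indices:
            s, e = self.exons[i]
            if off < e - s:
                return s + off
            off -= e - s
        raise ValueError("transcript position out of range")


@dataclass
class Reference:
    genome: dict[str, str]
    genes: list[SynthGene]

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        return path

    def write_gtf(self, path: str | Path) -> Path:
        """GTF of the annotated isoforms (1-based inclusive coordinates)."""
        path = Path(path)
        lines = []
        for g in self.genes:
            attr_g = f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";'
            gs, ge = g.exons[0][0], g.exons[-1][1]
            lines.append(
                f"{g.chrom}\tsynth\tgene\t{gs + 1}\t{ge}\t.\t+\t.\t{attr_g}"
            )
            for iso in g.isoforms:
                if not iso.annotated:
                    continue
                tid = f"{g.gene_id}.{iso.isoform_id}"
                attr_t = (
                    f'gene_id "{g.gene_id}"; transcript_id "{tid}"; '
                    f'gene_name "{g.gene_id}"; transcript_type "protein_coding";'
                )
                first, last = g.exons[iso.exon_indices[0]], g.exons[iso.exon_indices[-1]]
                lines.append(
                    f"{g.chrom}\tsynth\ttranscript\t{first[0] + 1}\t{last[1]}\t.\t+\t.\t{attr_t}"
                )
                for i in iso.exon_indices:
                    s, e = g.exons[i]
                    lines.append(f"{g.chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t+\t.\t{attr_t}")
        path.write_text("\n".join(lines) + "\n")
        return path


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[b] for b in rng.integers(0, 4, size=n))


def make_reference(cfg: SimConfig) -> Reference:
    """Build the toy genome and gene models, deterministically from the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    chrom = "chrS"
    parts: list[str] = []
    pos = 0
    genes: list[SynthGene] = []

    def spacer() -> None:
        nonlocal pos
        s = _random_seq(rng, cfg.spacer_length)
        parts.append(s)
        pos += len(s)

    def add_single_exon(gene_id: str, cls: str) -> SynthGene:
        nonlocal pos
        spacer()
        seq = _random_seq(rng, cfg.gene_length)
        exons = [(pos, pos + len(seq))]
        parts.append(seq)
        pos += len(seq)
        g = SynthGene(
            gene_id=gene_id,
            signal_class=cls,
            chrom=chrom,
            exons=exons,
            isoforms=[Isoform("t1", [0])],
        )
        genes.append(g)
        return g

    # fold changes alternate between groups so library totals stay balanced
    for i in range(cfg.n_de):
        g = add_single_exon(f"DE{i + 1}", "DE")
        g.de_group = i % cfg.n_groups
    for i in range(cfg.n_snv):
        g = add_single_exon(f"SNV{i + 1}", "SNV")
        offset = cfg.gene_length // 2
        ref_base = _base_at(parts, g.exons[0][0] + offset)
        alt = _BASES[(_BASES.index(ref_base) + 1 + int(rng.integers(0, 3))) % 4]
        g.snv_offset = offset
        g.snv_ref = ref_base
        g.snv_alt = alt
    for i in range(cfg.n_splice):
        spacer()
        exons = []
        for j, ln in enumerate(cfg.splice_exon_lengths):
            if j:
                intron = _random_seq(rng, cfg.intron_length)
                parts.append(intron)
                pos += len(intron)
            ex = _random_seq(rng, ln)
            exons.append((pos, pos + ln))
            parts.append(ex)
            pos += ln
        genes.append(
            SynthGene(
                gene_id=f"SPL{i + 1}",
                signal_class="splice",
                chrom=chrom,
                exons=exons,
                isoforms=[
                    Isoform("full", [0, 1, 2], annotated=True),
                    Isoform("skip", [0, 2], annotated=False),
                ],
            )
        )
    for i in range(cfg.n_null):
        add_single_exon(f"NULL{i + 1}", "null")
    spacer()
    return Reference(genome={chrom: "".join(parts)}, genes=genes)


def _base_at(parts: list[str], pos: int) -> str:
    off = pos
    for p in parts:
        if off < len(p):
            return p[off]
        off -= len(p)
    raise IndexError(pos)


# ---------------------------------------------------------------------------
# truth


def _kmers(seq: str, k: int) -> list[str]:
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def build_truth(cfg: SimConfig, reference: Reference) -> pd.DataFrame:
    """One row per planted signal.

    ``diagnostic_kmers`` are the defining k-mers of the signal (DE: every
    transcript k-mer; SNV: alt-allele windows over the variant; splice:
    the junction-spanning k-mers of the skipping isoform).
    ``attributable_kmers`` additionally include k-mers whose abundance
    differs between groups as a side effect of the same signal (the
    displaced ref-allele windows; the full isoform's junctions and the
    skipped exon), used when scoring precision.
    """
    k = cfg.k
    rows = []
    for g in reference.genes:
        if g.signal_class == "DE":
            tx = g.isoform_tx(reference, g.isoforms[0])
            diag = _kmers(tx, k)
            rows.append(
                {
                    "signal_id": g.gene_id,
                    "class": "DE",
                    "gene_id": g.gene_id,
                    "position": g.exons[0][0],
                    "effect": f"fold={cfg.de_fold} up_in={cfg.group_names[g.de_group]}",
                    "diagnostic_kmers": ";".join(diag),
                    "attributable_kmers": ";".join(diag),
                }
            )
        elif g.signal_class == "SNV":
            alt_tx = g.isoform_tx(reference, g.isoforms[0], allele="alt")
            ref_tx = g.isoform_tx(reference, g.isoforms[0])
            lo = max(0, g.snv_offset - k + 1)
            alt_window = _kmers(alt_tx[lo : g.snv_offset + k], k)
            ref_window = _kmers(ref_tx[lo : g.snv_offset + k], k)
            rows.append(
                {
                    "signal_id": g.gene_id,
                    "class": "SNV",
                    "gene_id": g.gene_id,
                    "position": g.exons[0][0] + g.snv_offset,
                    "effect": f"{g.snv_ref}>{g.snv_alt} freq={cfg.snv_alt_freq[: cfg.n_groups]}",
                    "diagnostic_kmers": ";".join(alt_window),
                    "attributable_kmers": ";".join(alt_window + ref_window),
                }
            )
        elif g.signal_class == "splice":
            skip = next(i for i in g.isoforms if i.isoform_id == "skip")
            full = next(i for i in g.isoforms if i.isoform_id == "full")
            tx_skip = g.isoform_tx(reference, skip)
            tx_full = g.isoform_tx(reference, full)
            e0 = g.exons[0][1] - g.exons[0][0]
            e1 = g.exons[1][1] - g.exons[1][0]
            # junction-spanning k-mers of the skipping isoform; boundary
            # windows can coincide with full-isoform sequence by chance and
            # are then not diagnostic
            diag = [km for km in _kmers(tx_skip[e0 - k + 1 : e0 + k - 1], k) if km not in tx_full]
            # full-isoform junctions plus the skipped exon itself
            attributable = (
                diag
                + _kmers(tx_full[e0 - k + 1 : e0 + k - 1], k)
                + _kmers(tx_full[e0 + e1 - k + 1 : e0 + e1 + k - 1], k)
                + _kmers(tx_full[e0 : e0 + e1], k)
            )
            rows.append(
                {
                    "signal_id": g.gene_id,
                    "class": "splice",
                    "gene_id": g.gene_id,
                    "position": g.exons[0][1],
                    "effect": f"skip_fraction={cfg.skip_isoform_fraction[: cfg.n_groups]}",
                    "diagnostic_kmers": ";".join(diag),
                    "attributable_kmers": ";".join(attributable),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reads


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        cur = _BASES.index(chr(arr[i]))
        arr[i] = ord(_BASES[(cur + 1 + int(rng.integers(0, 3))) % 4])
    return arr.tobytes().decode()


def _gene_depth(cfg: SimConfig, gene: SynthGene, group_idx: int) -> float:
    if gene.signal_class == "DE" and group_idx == gene.de_group:
        return cfg.depth * cfg.de_fold
    return cfg.depth


def expected_read_count(cfg: SimConfig, gene: SynthGene, group_idx: int) -> int:
    """round(depth * transcript_length / read_length) for the longest isoform."""
    tx_len = sum(gene.exons[i][1] - gene.exons[i][0] for i in gene.isoforms[0].exon_indices)
    return int(math.floor(_gene_depth(cfg, gene, group_idx) * tx_len / cfg.read_length + 0.5))


def simulate_reads(
    cfg: SimConfig, reference: Reference, out_dir: str | Path, gzip_output: bool = True
) -> tuple[list[Path], list[str], pd.DataFrame]:
    """Write one FASTQ per sample; return (paths, group labels, truth table).

    Read count per gene and sample is round(depth * tx_len / read_len)
    with the group's fold change applied; start positions are uniform,
    allele and isoform drawn per read at the group frequency, and
    substitution errors applied uniformly per base.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = build_truth(cfg, reference)
    paths: list[Path] = []
    labels: list[str] = []
    for gi, group in enumerate(cfg.group_names):
        for si in range(cfg.samples_per_group):
            name = f"{group}{si + 1:02d}"
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2, gi, si]))
            reads: list[str] = []
            for gene in reference.genes:
                n_reads = expected_read_count(cfg, gene, gi)
                full_iso = gene.isoforms[0]
                skip_iso = gene.isoforms[1] if len(gene.isoforms) > 1 else None
                tx_full = gene.isoform_tx(reference, full_iso)
                tx_alt = (
                    gene.isoform_tx(reference, full_iso, allele="alt")
                    if gene.signal_class == "SNV"
                    else None
                )
                tx_skip = gene.isoform_tx(reference, skip_iso) if skip_iso else None
                for _ in range(n_reads):
                    tx = tx_full
                    if tx_alt is not None and rng.random() < cfg.snv_alt_freq[gi]:
                        tx = tx_alt
                    elif tx_skip is not None and rng.random() < cfg.skip_isoform_fraction[gi]:
                        tx = tx_skip
                    if len(tx) <= cfg.read_length:
                        frag = tx
                    else:
                        start = int(rng.integers(0, len(tx) - cfg.read_length + 1))
                        frag = tx[start : start + cfg.read_length]
                    reads.append(_mutate(frag, rng, cfg.error_rate))
            suffix = ".fastq.gz" if gzip_output else ".fastq"
            path = out_dir / f"{name}{suffix}"
            payload = "".join(
                f"@{name}_r{ri}\n{seq}\n+\n{'I' * len(seq)}\n" for ri, seq in enumerate(reads)
            ).encode()
            if gzip_output:
                with open(path, "wb") as raw:
                    # fixed mtime keeps output byte-identical across runs
                    with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
                        gz.write(payload)
            else:
                path.write_bytes(payload)
            paths.append(path)
            labels.append(group)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return paths, labels, truth


# ---------------------------------------------------------------------------
# recovery scoring


def score_recovery(
    retained_kmers: Iterable[str],
    truth: pd.DataFrame,
    events: Sequence | None = None,
) -> dict:
    """Recall per signal class and precision of the retained k-mer set.

    A signal is recovered when at least one of its diagnostic k-mers is
    retained (or, if ``events`` is given, when an event of the matching
    class touches it).  Precision is the fraction of retained k-mers
    attributable to any planted signal; reported as None when nothing
    was retained.
    """
    retained = set(retained_kmers)
    attributable: set[str] = set()
    per_class: dict[str, list[bool]] = {}
    recovered_ids = []
    has_attr = "attributable_kmers" in truth.columns
    for row in truth.itertuples(index=False):
        diag = set(str(row.diagnostic_kmers).split(";"))
        attributable |= set(str(row.attributable_kmers).split(";")) if has_attr else diag
        hit = bool(diag & retained)
        per_class.setdefault(row[1], []).append(hit)  # column "class"
        if hit:
            recovered_ids.append(row.signal_id)
    recall_by_class = {cls: float(np.mean(v)) for cls, v in per_class.items()}
    all_hits = [h for v in per_class.values() for h in v]
    result = {
        "recall": float(np.mean(all_hits)) if all_hits else 0.0,
        "recall_by_class": recall_by_class,
        "precision": (
            len(retained & attributable) / len(retained) if retained else None
        ),
        "recovered": recovered_ids,
    }
    if events is not None:
        class_map = {"DE": "DE", "SNV": "mutation", "splice": "splice"}
        ev_by_class: dict[str, list] = {}
        for ev in events:
            ev_by_class.setdefault(ev.event_class, []).append(ev)
        event_hits = {}
        for row in truth.itertuples(index=False):
            cls = row[1]
            want = class_map.get(cls)
            pos = int(row.position)
            hit = False
            for ev in ev_by_class.get(want, []):
                if cls == "DE" and ev.gene_id == row.gene_id:
                    hit = True
                elif cls == "SNV" and ev.start is not None and ev.start == pos:
                    hit = True
                elif cls == "splice" and ev.gene_id == row.gene_id:
                    hit = True
            event_hits[row.signal_id] = hit
        result["event_recall"] = {
            sid: hit for sid, hit in event_hits.items()
        }
    return result


# ---------------------------------------------------------------------------
# synthetic spliced alignment (toy aligner for the toy genome)


def _cigar_ops(edlib_cigar: str) -> list[tuple[str, int]]:
    ops = []
    num = ""
    for ch in edlib_cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


def _md_and_nm(query: str, genome: str, pos: int, cigar: list[tuple[int, int]]) -> tuple[str, int]:
    """MD tag and NM count for a genomic alignment (ops: pysam numeric)."""
    md = []
    match_run = 0
    nm = 0
    q = 0
    r = pos
    for op, ln in cigar:
        if op == 0:  # M
            for _ in range(ln):
                if query[q] == genome[r]:
                    match_run += 1
                else:
                    md.append(str(match_run))
                    md.append(genome[r])
                    match_run = 0
                    nm += 1
                q += 1
                r += 1
        elif op == 1:  # I
            q += ln
            nm += ln
        elif op == 2:  # D
            md.append(str(match_run))
            match_run = 0
            md.append("^" + genome[r : r + ln])
            nm += ln
            r += ln
        elif op == 3:  # N
            r += ln
        elif op == 4:  # S
            q += ln
    md.append(str(match_run))
    return "".join(md), nm


def align_to_reference(
    named_seqs: Sequence[tuple[str, str]],
    reference: Reference,
    out_sam: str | Path,
    max_divergence: float = 0.2,
) -> Path:
    """Map sequences onto the toy genome and write SAM (synthetic aligner).

    Each sequence is aligned (edlib, infix mode) against every isoform
    transcript — annotated or not — and against raw genome windows; the
    best hit is projected through the isoform's exon structure into a
    genomic CIGAR with N gaps across introns, plus NM/MD tags.  Ties
    across distinct genes yield an extra secondary record (a multimapped
    sequence); hits worse than ``max_divergence`` edits per base are
    reported unmapped.  This aligner knows the simulation's isoform
    structures; it stands in for a spliced genome aligner on real data.
    """
    out_sam = Path(out_sam)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": chrom, "LN": len(seq)} for chrom, seq in sorted(reference.genome.items())
        ],
    }
    chrom_index = {c: i for i, c in enumerate(sorted(reference.genome))}

    # candidate targets: every isoform transcript with its projection map
    targets = []
    for g in reference.genes:
        for iso in g.isoforms:
            targets.append((g, iso, g.isoform_tx(reference, iso)))

    with pysam.AlignmentFile(str(out_sam), "wh", header=header) as sam:
        for name, seq in named_seqs:
            hits = []
            for g, iso, tx in targets:
                res = edlib.align(seq, tx, mode="HW", task="path")
                if res["editDistance"] < 0:
                    continue
                hits.append((res["editDistance"], g.gene_id, g, iso, tx, res))
            # also raw genome (covers intergenic sequences)
            for chrom, gseq in sorted(reference.genome.items()):
                res = edlib.align(seq, gseq, mode="HW", task="path")
                if res["editDistance"] >= 0:
                    hits.append((res["editDistance"], f"genome:{chrom}", None, None, gseq, res))
            hits.sort(key=lambda h: (h[0], h[1]))
            if not hits or hits[0][0] > max_divergence * len(seq):
                rec = pysam.AlignedSegment()
                rec.query_name = name
                rec.query_sequence = seq
                rec.flag = 4
                rec.reference_id = -1
                rec.reference_start = -1
                rec.mapping_quality = 0
                sam.write(rec)
                continue
            best = [h for h in hits if h[0] == hits[0][0]]
            # distinct loci only: a transcript hit and its own genome hit overlap
            loci: list[tuple] = []
            for h in best:
                span = _genomic_span(h, reference)
                if not any(_spans_overlap(span, s) for _, s in loci):
                    loci.append((h, span))
            for hi, (h, _span) in enumerate(loci):
                dist, _, g, iso, tx, res = h
                start_t, _end_t = res["locations"][0]
                start_t = start_t if start_t is not None else 0
                ops_tx = _cigar_ops(res["cigar"])
                if g is not None:
                    pos, cigar = _project_to_genome(g, iso, start_t, ops_tx)
                    chrom = g.chrom
                else:
                    chrom = _span_chrom(h, reference)
                    pos = start_t
                    cigar = [(_EDLIB_TO_PYSAM[o], ln) for o, ln in ops_tx]
                rec = pysam.AlignedSegment()
                rec.query_name = name
                rec.query_sequence = seq
                rec.flag = 0 if hi == 0 else 256
                rec.reference_id = chrom_index[chrom]
                rec.reference_start = pos
                rec.mapping_quality = 60 if len(loci) == 1 else 0
                rec.cigartuples = cigar
                md, nm = _md_and_nm(seq, reference.genome[chrom], pos, cigar)
                rec.set_tag("NM", nm)
                rec.set_tag("MD", md)
                sam.write(rec)
    return out_sam


_EDLIB_TO_PYSAM = {"M": 0, "=": 0, "X": 0, "I": 1, "D": 2}


def _project_to_genome(
    g: SynthGene, iso: Isoform, start_t: int, ops_tx: list[tuple[str, int]]
) -> tuple[int, list[tuple[int, int]]]:
    """Project a transcript-space alignment into genome space with N gaps."""
    # exon segments in transcript coordinates
    segs = []  # (tx_start, tx_end, genome_start)
    t = 0
    for i in iso.exon_indices:
        s, e = g.exons[i]
        segs.append((t, t + (e - s), s))
        t += e - s
    pos0 = None
    cigar: list[tuple[int, int]] = []

    def push(op: int, ln: int) -> None:
        if ln <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))

    tpos = start_t
    for op_ch, ln in ops_tx:
        op = _EDLIB_TO_PYSAM[op_ch]
        if op == 1:  # insertion: no reference advance
            push(1, ln)
            continue
        # ops consuming the transcript reference: split across exons
        remaining = ln
        while remaining > 0:
            seg = next(s for s in segs if s[0] <= tpos < s[1])
            take = min(remaining, seg[1] - tpos)
            gstart = seg[2] + (tpos - seg[0])
            if pos0 is None:
                pos0 = gstart
            elif cigar:
                # intron gap between previous genomic end and this start
                prev_end = pos0 + sum(
                    l for o, l in cigar if o in (0, 2, 3)
                )
                if gstart > prev_end:
                    push(3, gstart - prev_end)
            push(op, take)
            tpos += take
            remaining -= take
    assert pos0 is not None
    return pos0, cigar


def _genomic_span(hit, reference: Reference) -> tuple[str, int, int]:
    dist, tag, g, iso, tx, res = hit
    s, e = res["locations"][0]
    s = s if s is not None else 0
    if g is None:
        chrom = tag.split(":", 1)[1]
        return (chrom, s, e + 1)
    return (g.chrom, g.tx_to_genome(iso, s), g.tx_to_genome(iso, e) + 1)


def _span_chrom(hit, reference: Reference) -> str:
    return hit[1].split(":", 1)[1]


def _spans_overlap(a: tuple[str, int, int], b: tuple[str, int, int]) -> bool:
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]
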