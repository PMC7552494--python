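"""GTF models, coverage arithmetic and event classification from SAM."""

import numpy as np
import pytest

from kmerdisco import annotation as ann


GTF_HEADER = 'gene_id "{g}"; transcript_id "{t}"; gene_name "{g}"; transcript_type "{ty}";'


def write_gtf(path, entries):
    """entries: (chrom, feature, start1, end1, gene, tx, ttype)."""
    lines = [
        f"{c}\tsrc\t{f}\t{s}\t{e}\t.\t+\t.\t" + GTF_HEADER.format(g=g, t=t, ty=ty)
        for c, f, s, e, g, t, ty in entries
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def sam_text(records, refs=(("chr1", 1000),)):
    head = "".join(f"@SQ\tSN:{n}\tLN:{l}\n" for n, l in refs)
    return head + "".join(records)


def sam_rec(name, flag, chrom, pos1, cigar, seq, tags=()):
    tag_str = "".join("\t" + t for t in tags)
    return f"{name}\t{flag}\t{chrom}\t{pos1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*{tag_str}\n"


@pytest.fixture
def two_exon_gtf(tmp_path):
    return write_gtf(
        tmp_path / "m.gtf",
        [
            ("chr1", "exon", 1, 100, "G1", "T1", "protein_coding"),
            ("chr1", "exon", 201, 300, "G1", "T1", "protein_coding"),
        ],
    )


class TestLoadGtf:
    def test_intron_derivation(self, two_exon_gtf):
        (m,) = ann.load_gtf(two_exon_gtf)
        assert m.exons == [(0, 100), (200, 300)]
        assert m.introns == [(100, 200)]
        assert m.length == 200

    def test_retained_intron_excluded(self, tmp_path):
        gtf = write_gtf(
            tmp_path / "m.gtf",
            [
                ("chr1", "exon", 1, 100, "G1", "T1", "protein_coding"),
                ("chr1", "exon", 1, 100, "G1", "T2", "retained_intron"),
            ],
        )
        models = ann.load_gtf(gtf)
        assert [m.transcript_id for m in models] == ["T1"]

    def test_multi_gene_fixture_matches_hand_table(self, tmp_path):
        gtf = write_gtf(
            tmp_path / "m.gtf",
            [
                ("chr1", "exon", 11, 50, "GA", "TA", "protein_coding"),
                ("chr2", "exon", 1, 30, "GB", "TB", "lincRNA"),
                ("chr2", "exon", 61, 90, "GB", "TB", "lincRNA"),
                ("chr2", "exon", 121, 150, "GB", "TB", "lincRNA"),
            ],
        )
        models = {m.transcript_id: m for m in ann.load_gtf(gtf)}
        assert models["TA"].exons == [(10, 50)]
        assert models["TB"].exons == [(0, 30), (60, 90), (120, 150)]
        assert models["TB"].introns == [(30, 60), (90, 120)]
        assert models["TB"].gene_id == "GB" and models["TB"].chrom == "chr2"

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "G";\nbroken line\n')
        with pytest.raises(ValueError, match="line 2"):
            ann.load_gtf(p)


class TestCoverage:
    def test_merged_interval_vs_boolean_mask_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            target = [(int(s), int(s + l)) for s, l in
                      zip(rng.integers(0, 500, 3), rng.integers(1, 80, 3))]
            cover = [(int(s), int(s + l)) for s, l in
                     zip(rng.integers(0, 500, 5), rng.integers(1, 60, 5))]
            frac = ann.covered_fraction(target, cover)
            mask_t = np.zeros(700, bool)
            mask_c = np.zeros(700, bool)
            for s, e in target:
                mask_t[s:e] = True
            for s, e in cover:
                mask_c[s:e] = True
            expect = (mask_t & mask_c).sum() / mask_t.sum()
            assert frac == pytest.approx(expect)
            assert 0.0 <= frac <= 1.0


class TestClassifyEvents:
    def _run(self, tmp_path, sam_body, gtf_entries=None, d=0.5, member_acc=None):
        gtf_entries = gtf_entries or [
            ("chr1", "exon", 1, 100, "G1", "T1", "protein_coding"),
            ("chr1", "exon", 201, 300, "G1", "T1", "protein_coding"),
        ]
        gtf = write_gtf(tmp_path / "m.gtf", gtf_entries)
        sam = tmp_path / "a.sam"
        sam.write_text(sam_body)
        models = ann.load_gtf(gtf)
        return ann.classify_events(sam, models, d=d, member_accuracies=member_acc or {})

    def test_insertion_cigar(self, tmp_path):
        body = sam_text([sam_rec("q1", 0, "chr1", 10, "10M1I20M", "A" * 31)])
        events = self._run(tmp_path, body)
        assert "insertion" in {e.event_class for e in events}

    def test_unmapped_record(self, tmp_path):
        body = sam_text([f"q1\t4\t*\t0\t0\t*\t*\t0\t0\t{'A' * 20}\t*\n"])
        events = self._run(tmp_path, body)
        assert {e.event_class for e in events} == {"unmapped"}

    def test_deletion_and_clipping(self, tmp_path):
        body = sam_text(
            [
                sam_rec("q1", 0, "chr1", 10, "10M2D10M", "A" * 20),
                sam_rec("q2", 0, "chr1", 30, "5S15M", "C" * 20),
            ]
        )
        classes = {e.event_class for e in self._run(tmp_path, body)}
        assert {"deletion", "clipping"} <= classes

    def test_mutation_requires_md_evidence(self, tmp_path):
        # same alignment with and without MD: mutation only with MD
        rec_md = sam_rec("q1", 0, "chr1", 11, "20M", "A" * 20, tags=["NM:i:1", "MD:Z:9T10"])
        rec_plain = sam_rec("q2", 0, "chr1", 41, "20M", "A" * 20)
        events = self._run(tmp_path, sam_text([rec_md, rec_plain]))
        muts = [e for e in events if e.event_class == "mutation"]
        assert len(muts) == 1
        assert muts[0].sequences == ["q1"]
        assert muts[0].start == 19  # 0-based: pos 10 + 9 matched bases

    def test_coverage_de_vs_gene(self, tmp_path):
        # transcript length 200; q1+q2 cover 120 exonic bases (60%)
        body = sam_text(
            [
                sam_rec("q1", 0, "chr1", 1, "80M", "A" * 80),
                sam_rec("q2", 0, "chr1", 201, "40M", "A" * 40),
            ]
        )
        events = self._run(tmp_path, body, d=0.5)
        assert any(e.event_class == "DE" and e.transcript_id == "T1" for e in events)
        # 40% coverage -> gene event instead
        body2 = sam_text([sam_rec("q1", 0, "chr1", 1, "80M", "A" * 80)])
        events2 = self._run(tmp_path, body2, d=0.5)
        classes2 = {e.event_class for e in events2}
        assert "DE" not in classes2 and "gene" in classes2

    def test_n_gap_across_exons_is_splice(self, tmp_path):
        body = sam_text([sam_rec("q1", 0, "chr1", 81, "20M100N20M", "A" * 40)])
        events = self._run(tmp_path, body)
        splices = [e for e in events if e.event_class == "splice"]
        assert len(splices) == 1
        assert (splices[0].start, splices[0].end) == (100, 200)

    def test_intron_coverage_event(self, tmp_path):
        body = sam_text([sam_rec("q1", 0, "chr1", 81, "80M", "A" * 80)])
        events = self._run(tmp_path, body, d=0.5)
        # bases 100-160 of the 100-long intron are covered (60%)
        assert any(e.event_class == "intron" for e in events)

    def test_intergenic_and_unknown_reference(self, tmp_path):
        body = sam_text(
            [
                sam_rec("q1", 0, "chr1", 601, "20M", "A" * 20),
                sam_rec("q2", 0, "chr9", 11, "20M", "C" * 20),
            ],
            refs=(("chr1", 1000), ("chr9", 1000)),
        )
        with pytest.warns(UserWarning, match="chr9"):
            events = self._run(tmp_path, body)
        inter = [e for e in events if e.event_class == "intergenic"]
        assert {e.sequences[0] for e in inter} == {"q1", "q2"}

    def test_multimapped_secondary(self, tmp_path):
        body = sam_text(
            [
                sam_rec("q1", 0, "chr1", 11, "20M", "A" * 20),
                sam_rec("q1", 256, "chr1", 501, "20M", "A" * 20),
            ]
        )
        events = self._run(tmp_path, body)
        assert {e.event_class for e in events} == {"multimapped"}

    def test_order_invariance(self, tmp_path):
        recs = [
            sam_rec("q1", 0, "chr1", 1, "80M", "A" * 80),
            sam_rec("q2", 0, "chr1", 201, "40M", "C" * 40),
            sam_rec("q3", 0, "chr1", 601, "20M", "G" * 20),
        ]
        ev_a = self._run(tmp_path, sam_text(recs))
        ev_b = self._run(tmp_path, sam_text(recs[::-1]))
        key = lambda evs: sorted((e.event_class, e.start, e.end, tuple(e.sequences)) for e in evs)
        assert key(ev_a) == key(ev_b)

    def test_candidates_feed_representatives(self, tmp_path):
        body = sam_text([sam_rec("q1", 0, "chr1", 1, "80M", "A" * 80)])
        events = self._run(
            tmp_path, body, member_acc={"q1": [("ACGT", 80.0), ("CGTA", 92.0)]}
        )
        gene_ev = next(e for e in events if e.event_class == "gene")
        assert gene_ev.kmer == "CGTA" and gene_ev.accuracy == 92.0


class TestRepresentatives:
    def _ev(self, cands):
        return ann.AdfEvent("gene", "chr1", 0, 10, candidates=list(cands))

    def test_argmax(self):
        ev = self._ev([("AAAA", 80.0), ("CCCC", 92.0)])
        ann.select_representatives([ev])
        assert ev.kmer == "CCCC"

    def test_single_candidate(self):
        ev = self._ev([("AAAA", 80.0)])
        ann.select_representatives([ev])
        assert ev.kmer == "AAAA"

    @pytest.mark.parametrize("order", [0, 1])
    def test_tie_breaks_to_smaller_code(self, order):
        cands = [("CCCC", 80.0), ("AAAA", 80.0)]
        if order:
            cands = cands[::-1]
        ev = self._ev(cands)
        ann.select_representatives([ev])
        assert ev.kmer == "AAAA"


class TestAggregate:
    def test_empty_report(self, tmp_path):
        df = ann.aggregate_output([], json_path=tmp_path / "o.json", tsv_path=tmp_path / "o.tsv")
        assert df.empty and (tmp_path / "o.json").read_text() == "[]"

    def test_sorted_by_accuracy_and_one_based_output(self, tmp_path):
        evs = [
            ann.AdfEvent("gene", "chr1", 0, 100, kmer="AAAA", accuracy=70.0),
            ann.AdfEvent("DE", "chr1", 10, 50, kmer="CCCC", accuracy=95.0),
            ann.AdfEvent("splice", "chr1", 5, 20, kmer="GGGG", accuracy=80.0),
        ]
        df = ann.aggregate_output(evs)
        assert df.accuracy.tolist() == [95.0, 80.0, 70.0]
        # internal 0-based half-open [0, 100) reported as 1-based [1, 100]
        assert df.iloc[2].start == 1 and df.iloc[2].end == 100
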