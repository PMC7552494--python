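"""Overlap-graph construction, pruning, rescaling and sequence extraction."""

import numpy as np
import pandas as pd
import pytest
import networkx as nx

from kmerdisco import graph as gr
from kmerdisco.kmer_store import encode_kmer


def retained_df(kmers, accs, pairs=("A_B",)):
    """Build a reduction-output frame for a list of k-mers.

    accs: one accuracy per k-mer (single pair) or one vector per k-mer.
    """
    rows = []
    for km, a in zip(kmers, accs):
        vec = [a] if np.isscalar(a) else list(a)
        rows.append(
            {"kmer": km, "code": encode_kmer(km), "entropy": 2.0}
            | {f"acc_{p}": v for p, v in zip(pairs, vec)}
            | {f"iters_{p}": 10 for p in pairs}
        )
    return pd.DataFrame(rows)


def kmers_of(seq, k):
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


class TestBuildGraph:
    def test_adjacent_kmers_link(self):
        df = retained_df(["ACGT", "CGTA"], [80, 80])
        (G,) = gr.build_graph(df, w=1, min_accuracy=65)
        assert G.has_edge("ACGT", "CGTA")
        assert G.edges["ACGT", "CGTA"]["shift"] == 1

    def test_disjoint_kmers_make_singletons(self):
        df = retained_df(["AAAA", "CCCC"], [80, 80])
        comps = gr.build_graph(df, w=1, min_accuracy=65)
        assert len(comps) == 2

    def test_threshold_excludes_nodes(self):
        df = retained_df(["ACGT", "CGTA"], [80, 60])
        comps = gr.build_graph(df, w=1, min_accuracy=65)
        assert [list(G.nodes) for G in comps] == [["ACGT"]]

    def test_full_kmer_set_of_sequence_is_path(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 60))
        kms = kmers_of(seq, 31)
        assert len(set(kms)) == 30
        (G,) = gr.build_graph(retained_df(kms, [70] * 30), w=1, min_accuracy=65)
        assert G.number_of_nodes() == 30 and G.number_of_edges() == 29
        assert all(G.out_degree(n) <= 1 for n in G.nodes)

    @pytest.mark.parametrize("w", [1, 2])
    def test_brute_force_overlap_oracle(self, w):
        rng = np.random.default_rng(1)
        k = 8
        kms = list({"".join("ACGT"[b] for b in rng.integers(0, 4, k)) for _ in range(300)})
        comps = gr.build_graph(retained_df(kms, [70] * len(kms)), w=w, min_accuracy=65)
        got = {(u, v, d["shift"]) for G in comps for u, v, d in G.edges(data=True)}
        expect = set()
        for u in kms:
            for v in kms:
                if u == v:
                    continue
                for d in range(1, w + 1):
                    if u[d:] == v[: k - d]:
                        expect.add((u, v, d))
                        break
        assert got == expect


def _hand_graph(edges, accs):
    """DiGraph with the attributes pruning and extraction rely on."""
    G = nx.DiGraph()
    for i, (n, a) in enumerate(accs.items()):
        vec = np.atleast_1d(np.asarray(a, dtype=float))
        G.add_node(n, code=i, acc=vec, max_acc=float(vec.max()), entropy=2.0)
    for u, v in edges:
        G.add_edge(u, v, shift=1)
    return G


class TestPruning:
    def test_single_terminal_branch_removed(self):
        G = _hand_graph(
            [("A", "B"), ("B", "C"), ("B", "X")],
            {"A": 80, "B": 85, "C": 82, "X": 70},
        )
        pruned = gr.prune_bifurcations(G)
        assert "X" not in pruned and set(pruned.nodes) == {"A", "B", "C"}

    def test_linear_path_unchanged(self):
        G = _hand_graph([("A", "B"), ("B", "C")], {"A": 80, "B": 70, "C": 90})
        pruned = gr.prune_bifurcations(G)
        assert set(pruned.nodes) == {"A", "B", "C"}
        assert set(pruned.edges) == set(G.edges)

    def test_chained_bifurcations_drop_lowest_accuracy_branch(self):
        # A bifurcates into the b-branch (max 80), itself bifurcating, and
        # the c-branch (max 70): the 70 branch goes
        G = _hand_graph(
            [("A", "B1"), ("A", "C1"), ("C1", "C2"), ("B1", "B2"), ("B1", "B3"), ("B2", "D"), ("B3", "D")],
            {"A": 90, "B1": 78, "B2": 80, "B3": 79, "C1": 70, "C2": 68, "D": 75},
        )
        pruned = gr.prune_bifurcations(G)
        assert "C1" not in pruned and "C2" not in pruned
        assert {"A", "B1", "D"} <= set(pruned.nodes)

    def test_component_maximum_never_pruned(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(4, 12))
            names = [f"n{i}" for i in range(n)]
            accs = {m: float(rng.uniform(60, 100)) for m in names}
            edges = set()
            for _ in range(int(rng.integers(n, 3 * n))):
                u, v = rng.choice(n, 2, replace=False)
                if u < v:  # acyclic
                    edges.add((names[u], names[v]))
            G = _hand_graph(sorted(edges), accs)
            best = max(accs, key=accs.get)
            pruned = gr.prune_bifurcations(G)
            assert best in pruned


class TestRescaling:
    def test_affine_rescale(self):
        G = _hand_graph([], {"a": 65, "b": 80, "c": 95})
        gr.rescale_accuracies([G])
        got = {n: G.nodes[n]["rescaled"][0] for n in G}
        assert got == {"a": 0.0, "b": 50.0, "c": 100.0}

    def test_degenerate_maps_to_100(self):
        G = _hand_graph([], {"a": 77})
        gr.rescale_accuracies([G])
        assert G.nodes["a"]["rescaled"][0] == 100.0

    def test_pairs_rescaled_independently(self):
        G = _hand_graph(
            [], {"a": (60, 70), "b": (90, 70), "c": (75, 100)}
        )
        gr.rescale_accuracies([G])
        got = {n: G.nodes[n]["rescaled"].tolist() for n in G}
        assert got["a"] == [0.0, 0.0]
        assert got["b"] == [100.0, 0.0]
        assert got["c"] == [50.0, 100.0]

    def test_idempotent_on_preset_values(self):
        G = _hand_graph([], {"a": 65, "b": 95})
        gr.rescale_accuracies([G])
        first = {n: G.nodes[n]["rescaled"].copy() for n in G}
        for n in G:
            G.nodes[n]["acc"] = G.nodes[n]["rescaled"]
        gr.rescale_accuracies([G])
        for n in G:
            assert np.allclose(G.nodes[n]["rescaled"], first[n])


def _verify_assembly(seq_obj, k):
    """Independent overlap check: rebuild the sequence character by character."""
    rebuilt = seq_obj.members[0]
    for a, b in zip(seq_obj.members, seq_obj.members[1:]):
        shift = None
        for d in range(1, k):
            if a[d:] == b[: k - d]:
                shift = d
                break
        assert shift is not None, (a, b)
        rebuilt += b[-shift:]
    assert rebuilt == seq_obj.sequence


class TestExtraction:
    def test_linear_path_single_sequence(self):
        seq = "ACGTACGTACGT"
        kms = kmers_of(seq, 8)  # 5 k-mers
        df = retained_df(kms, [70, 71, 72, 73, 74])
        out = gr.assemble(df, min_node_accuracy=65, min_seq_accuracy=65)
        assert len(out) == 1
        assert out[0].sequence == seq
        assert len(out[0].sequence) == 8 + 4
        _verify_assembly(out[0], 8)

    def test_snv_bubble_two_sequences_with_context(self):
        rng = np.random.default_rng(4)
        hap1 = "".join("ACGT"[b] for b in rng.integers(0, 4, 60))
        pos = 30
        alt = "ACGT"[("ACGT".index(hap1[pos]) + 1) % 4]
        hap2 = hap1[:pos] + alt + hap1[pos + 1 :]
        k = 15
        kms = sorted(set(kmers_of(hap1, k)) | set(kmers_of(hap2, k)))
        out = gr.assemble(retained_df(kms, [80] * len(kms)), min_node_accuracy=65,
                          min_seq_accuracy=65)
        assert len(out) == 2
        for s in out:
            _verify_assembly(s, k)
        full = max(out, key=lambda s: len(s.sequence))
        branch = min(out, key=lambda s: len(s.sequence))
        assert full.sequence in (hap1, hap2)
        # the branch starts with 3 context k-mers shared with the main path:
        # its first 3 + (k-1) bases occur verbatim in the full sequence
        assert branch.sequence[: 3 + k - 1] in full.sequence

    def test_planted_snv_haplotypes_differ_at_one_position(self):
        rng = np.random.default_rng(9)
        hap1 = "".join("ACGT"[b] for b in rng.integers(0, 4, 80))
        pos = 40
        alt = "ACGT"[("ACGT".index(hap1[pos]) + 2) % 4]
        hap2 = hap1[:pos] + alt + hap1[pos + 1 :]
        k = 21
        kms = sorted(set(kmers_of(hap1, k)) | set(kmers_of(hap2, k)))
        out = gr.assemble(retained_df(kms, [90] * len(kms)), min_node_accuracy=65,
                          min_seq_accuracy=65)
        assert len(out) == 2
        full = max(out, key=lambda s: len(s.sequence))
        branch = min(out, key=lambda s: len(s.sequence))
        assert full.sequence in (hap1, hap2)
        # align the branch onto the emitted haplotype via its shared context:
        # exactly one mismatch (the variant), 3 + k - 1 bases in
        idx = full.sequence.find(branch.sequence[: k - 1])
        assert idx >= 0
        window = full.sequence[idx : idx + len(branch.sequence)]
        diffs = [i for i, (a, b) in enumerate(zip(branch.sequence, window)) if a != b]
        assert len(diffs) == 1
        assert diffs[0] == 3 + k - 1

    def test_branch_choice_minimizes_accuracy_distance(self):
        G = _hand_graph(
            [("AAAA", "AAAC"), ("AAAA", "AAAG"), ("AAAC", "AACT"), ("AAAG", "AAGT")],
            {
                "AAAA": (90, 10),
                "AAAC": (85, 15),
                "AAAG": (20, 80),
                "AACT": (85, 15),
                "AAGT": (20, 80),
            },
        )
        for n in G:
            G.nodes[n]["rescaled"] = G.nodes[n]["acc"].astype(float)
        seqs = gr.extract_sequences(G, min_seq_accuracy=0)
        first = next(s for s in seqs if s.members[0] == "AAAA")
        assert first.members[:2] == ["AAAA", "AAAC"]  # closest vector continues

    def test_low_accuracy_sequences_dropped(self):
        kms = kmers_of("ACGTACGTACGT", 8)
        df = retained_df(kms, [60] * len(kms))
        out = gr.assemble(df, min_node_accuracy=50, min_seq_accuracy=65)
        assert out == []

    def test_cycle_terminates(self):
        # AAAA -> AAAA would be a self loop (excluded); use a 2-cycle
        G = _hand_graph([("ACAC", "CACA"), ("CACA", "ACAC")], {"ACAC": 80, "CACA": 81})
        G.edges["ACAC", "CACA"]["shift"] = 1
        G.edges["CACA", "ACAC"]["shift"] = 1
        seqs = gr.extract_sequences(G, min_seq_accuracy=0)
        assert seqs  # terminated and emitted something
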