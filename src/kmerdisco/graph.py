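"""Overlap-graph assembly of retained k-mers and sequence extraction.

Retained k-mers become nodes of a directed graph; an edge u -> v is drawn
whenever the last k-d nucleotides of u equal the first k-d of v for some
shift d between 1 and w (w is the maximum shift between consecutive
k-mers; larger w tolerates holes left by k-mers that barely missed the
accuracy threshold).  Bifurcations in these graphs are the footprint of
biological events — a point mutation or an alternative junction opens a
bubble — so after two pruning rules (dead-end single-node branches are
clipped; where bifurcations chain, the lowest-accuracy branch is dropped)
each divergent path is emitted as its own sequence via depth-first
traversal.  Before extraction the accuracies are rescaled 0-100 within
each pairwise comparison so that pairs that are intrinsically harder to
separate still influence branch choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import json
import numpy as np
import pandas as pd
import networkx as nx

from .kmer_store import encode_kmer


@dataclass
class GraphSequence:
    """One assembled path through a k-mer graph."""

    sequence: str
    members: list[str]
    best_kmer: str
    best_accuracy: float
    pair_accuracies: dict[str, float]  # max raw accuracy per pair over members
    graph_id: int
    branch_id: int

    @property
    def name(self) -> str:
        return f"graph{self.graph_id}_branch{self.branch_id}"


def _acc_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("acc_")]


def build_graph(
    retained: pd.DataFrame, w: int = 1, min_accuracy: float = 65.0
) -> list[nx.DiGraph]:
    """Build overlap graphs (one per weakly connected component).

    Nodes are the k-mers whose best pairwise accuracy reaches
    ``min_accuracy`` (the -T threshold); node attributes carry the raw
    accuracy vector, the entropy and the integer code.  Edges carry the
    shift d in [1, w].
    """
    if retained.empty:
        return []
    acc_cols = _acc_columns(retained)
    keep = retained[retained[acc_cols].max(axis=1) >= min_accuracy]
    G = nx.DiGraph()
    for row in keep.itertuples(index=False):
        acc = np.array([getattr(row, c) for c in acc_cols], dtype=np.float64)
        G.add_node(
            row.kmer,
            code=int(row.code),
            acc=acc,
            max_acc=float(acc.max()),
            entropy=float(row.entropy),
        )
    if not G.nodes:
        return []
    k = len(next(iter(G.nodes)))
    by_prefix: dict[int, dict[str, list[str]]] = {}
    for d in range(1, w + 1):
        idx: dict[str, list[str]] = {}
        for v in G.nodes:
            idx.setdefault(v[: k - d], []).append(v)
        by_prefix[d] = idx
    for u in G.nodes:
        for d in range(1, w + 1):
            for v in by_prefix[d].get(u[d:], []):
                if v != u and not G.has_edge(u, v):
                    G.add_edge(u, v, shift=d)
    comps = sorted(nx.weakly_connected_components(G), key=lambda c: min(G.nodes[n]["code"] for n in c))
    return [G.subgraph(c).copy() for c in comps]


def _component_max(G: nx.DiGraph) -> str:
    return max(G.nodes, key=lambda n: (G.nodes[n]["max_acc"], -G.nodes[n]["code"]))


def _exclusive_branch(G: nx.DiGraph, u: str, v: str) -> set[str]:
    """Nodes reachable from successor v but from no sibling branch of u."""
    others: set[str] = set()
    for s in G.successors(u):
        if s != v:
            others |= nx.descendants(G, s) | {s}
    mine = nx.descendants(G, v) | {v}
    return (mine - others) - {u}


def prune_bifurcations(G: nx.DiGraph) -> nx.DiGraph:
    """Apply the two pruning rules to a fixed point.

    Rule 1: at a bifurcation, a branch consisting of exactly one terminal
    node is removed.  Rule 2: where bifurcations chain (a successor
    branch itself bifurcates), the branch with the lowest maximum
    accuracy is removed.  The component's best node is never pruned.
    """
    G = G.copy()
    changed = True
    while changed and G.number_of_nodes() > 1:
        changed = False
        best = _component_max(G)
        for u in sorted(G.nodes, key=lambda n: G.nodes[n]["code"]):
            if u not in G or G.out_degree(u) < 2:
                continue
            # rule 1: dead-end single-node branches
            dead = [
                v
                for v in G.successors(u)
                if G.out_degree(v) == 0 and G.in_degree(v) == 1 and v != best
            ]
            for v in sorted(dead, key=lambda n: (G.nodes[n]["max_acc"], G.nodes[n]["code"])):
                if G.out_degree(u) <= 1:
                    break
                G.remove_node(v)
                changed = True
            if u not in G or G.out_degree(u) < 2:
                continue
            # rule 2: chained bifurcations — a branch of u itself bifurcates
            succs = list(G.successors(u))
            branches = {v: _exclusive_branch(G, v=v, u=u) for v in succs}
            chained = any(
                G.out_degree(n) >= 2 for nodes in branches.values() for n in nodes
            )
            if not chained:
                continue
            scored = sorted(
                (max(G.nodes[n]["max_acc"] for n in nodes), G.nodes[v]["code"], v, nodes)
                for v, nodes in branches.items()
                if nodes and best not in nodes
            )
            if scored:
                G.remove_nodes_from(scored[0][3])
                changed = True
    return G


def rescale_accuracies(graphs: Sequence[nx.DiGraph]) -> None:
    """Rescale accuracies 0-100 per pairwise comparison, in place.

    The affine map uses the min and max over all surviving nodes of all
    graphs; a degenerate pair (max == min) maps to 100 so that a lone
    informative node is never discarded downstream.  Idempotent.
    """
    all_nodes = [(G, n) for G in graphs for n in G.nodes]
    if not all_nodes:
        return
    accs = np.stack([G.nodes[n]["acc"] for G, n in all_nodes])
    lo, hi = accs.min(axis=0), accs.max(axis=0)
    span = hi - lo
    for (G, n), vec in zip(all_nodes, accs):
        scaled = np.where(span > 0, 100.0 * (vec - lo) / np.where(span > 0, span, 1.0), 100.0)
        G.nodes[n]["rescaled"] = scaled


def extract_sequences(
    G: nx.DiGraph, min_seq_accuracy: float = 65.0, graph_id: int = 0, context: int = 3
) -> list[GraphSequence]:
    """Depth-first extraction of one sequence per divergent path.

    At a bifurcation, the branch whose first node's rescaled accuracy
    vector is closest (Euclidean) to the bifurcating node's continues
    the current sequence; every other branch starts a new sequence
    prefixed with up to ``context`` k-mers preceding the bifurcation.
    Visited-edge marking terminates cycles.  Sequences whose best member
    accuracy falls below ``min_seq_accuracy`` (the -t threshold) are
    dropped.
    """
    if G.number_of_nodes() == 0:
        return []
    for n in G.nodes:
        if "rescaled" not in G.nodes[n]:
            rescale_accuracies([G])
            break
    starts = sorted(
        (n for n in G.nodes if G.in_degree(n) == 0), key=lambda n: G.nodes[n]["code"]
    )
    visited_edges: set[tuple[str, str]] = set()
    visited_nodes: set[str] = set()
    raw_seqs: list[list[str]] = []
    pending: list[tuple[list[str], str]] = [([], s) for s in starts]
    while pending or len(visited_nodes) < G.number_of_nodes():
        if not pending:
            rest = sorted(set(G.nodes) - visited_nodes, key=lambda n: G.nodes[n]["code"])
            pending.append(([], rest[0]))
        prefix, node = pending.pop(0)
        members = list(prefix)
        cur = node
        while True:
            members.append(cur)
            visited_nodes.add(cur)
            succ = [v for v in G.successors(cur) if (cur, v) not in visited_edges]
            if not succ:
                break
            if len(succ) == 1:
                nxt = succ[0]
            else:
                ref = G.nodes[cur]["rescaled"]
                nxt = min(
                    succ,
                    key=lambda v: (
                        float(np.linalg.norm(G.nodes[v]["rescaled"] - ref)),
                        G.nodes[v]["code"],
                    ),
                )
                ctx = members[-context:]
                for v in succ:
                    if v != nxt:
                        pending.append((list(ctx), v))
            visited_edges.add((cur, nxt))
            cur = nxt
        raw_seqs.append(members)

    out: list[GraphSequence] = []
    branch_id = 0
    pair_names = None
    for members in raw_seqs:
        best = max(members, key=lambda n: (G.nodes[n]["max_acc"], -G.nodes[n]["code"]))
        if G.nodes[best]["max_acc"] < min_seq_accuracy:
            continue
        seq = members[0]
        ok = True
        for a, b in zip(members, members[1:]):
            if not G.has_edge(a, b):
                ok = False
                break
            d = G.edges[a, b]["shift"]
            seq += b[-d:]
        if not ok:  # defensive: context + branch start must be adjacent
            continue
        accs = np.stack([G.nodes[n]["acc"] for n in members])
        pair_accs = {f"pair{i}": float(v) for i, v in enumerate(accs.max(axis=0))}
        out.append(
            GraphSequence(
                sequence=seq,
                members=members,
                best_kmer=best,
                best_accuracy=float(G.nodes[best]["max_acc"]),
                pair_accuracies=pair_accs,
                graph_id=graph_id,
                branch_id=branch_id,
            )
        )
        branch_id += 1
    return out


def assemble(
    retained: pd.DataFrame,
    w: int = 1,
    min_node_accuracy: float = 65.0,
    min_seq_accuracy: float = 65.0,
) -> list[GraphSequence]:
    """build -> prune -> rescale -> extract over all components."""
    graphs = [prune_bifurcations(G) for G in build_graph(retained, w, min_node_accuracy)]
    rescale_accuracies(graphs)
    seqs: list[GraphSequence] = []
    for gid, G in enumerate(graphs):
        seqs.extend(extract_sequences(G, min_seq_accuracy, graph_id=gid))
    return seqs


def write_sequences(seqs: Sequence[GraphSequence], fasta: str | Path, sidecar: str | Path) -> None:
    """FASTA of assembled sequences plus a JSON sidecar with members."""
    fasta, sidecar = Path(fasta), Path(sidecar)
    with open(fasta, "w") as fh:
        for s in seqs:
            pairs = " ".join(f"{k}={v:.1f}" for k, v in s.pair_accuracies.items())
            fh.write(f">{s.name} best={s.best_accuracy:.1f} {pairs}\n{s.sequence}\n")
    sidecar.write_text(
        json.dumps(
            [
                {
                    "name": s.name,
                    "sequence": s.sequence,
                    "members": s.members,
                    "best_kmer": s.best_kmer,
                    "best_accuracy": s.best_accuracy,
                    "pair_accuracies": s.pair_accuracies,
                }
                for s in seqs
            ],
            indent=1,
        )
    )
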