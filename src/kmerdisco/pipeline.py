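"""End-to-end glue: counting -> matrix -> reduction -> graphs -> events -> model.

Convenience drivers that chain the library modules on a set of read
files (typically the synthetic cohort), plus the 5-fold cross-validation
harness in which feature reduction is re-run on each training fold and
the final model is scored on the held-out samples by balanced accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from . import annotation, classify, graph, kmer_store, matrix, reduction, synthetic


@dataclass
class PipelineResult:
    spec: matrix.MatrixSpec
    retained: pd.DataFrame
    sequences: list[graph.GraphSequence]
    events: list[annotation.AdfEvent]
    feature_table: pd.DataFrame
    labels: list[str]
    selected: list[str]
    oob: classify.OobCurve
    recovery: dict


def count_samples(
    read_files: Sequence[Path],
    labels: Sequence[str],
    k: int,
    out_dir: str | Path,
    canonical: bool = False,
) -> matrix.MatrixSpec:
    """Count every sample and assemble the matrix spec."""
    out_dir = Path(out_dir)
    metas = []
    for path, group in zip(read_files, labels):
        name = Path(path).name.split(".")[0]
        meta, _ = kmer_store.build_sample([path], k, name, group, out_dir, canonical=canonical)
        metas.append(meta)
    return matrix.MatrixSpec(samples=metas)


def member_accuracy_map(
    retained: pd.DataFrame, sequences: Sequence[graph.GraphSequence]
) -> dict[str, list[tuple[str, float]]]:
    acc_cols = [c for c in retained.columns if c.startswith("acc_")]
    best = dict(zip(retained["kmer"], retained[acc_cols].max(axis=1)))
    return {s.name: [(m, float(best.get(m, 0.0))) for m in s.members] for s in sequences}


def feature_table_from_events(
    spec: matrix.MatrixSpec, events: Sequence[annotation.AdfEvent]
) -> pd.DataFrame:
    """Samples x representative-k-mer table of normalized counts."""
    kmers = sorted({ev.kmer for ev in events if ev.kmer})
    codes = [kmer_store.encode_kmer(km) for km in kmers]
    rows = matrix.fetch_rows(spec, codes)
    data = {km: rows[code].normalized for km, code in zip(kmers, codes)}
    return pd.DataFrame(data, index=[m.name for m in spec.samples])


def run_synthetic_pipeline(
    cfg: synthetic.SimConfig,
    workdir: str | Path,
    reduction_cfg: reduction.ReductionConfig | None = None,
    workers: int = 1,
    seed: int | None = None,
    d: float = 0.5,
) -> PipelineResult:
    """Simulate a cohort and run the full discovery pipeline on it."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    reference = synthetic.make_reference(cfg)
    reference.write_fasta(workdir / "genome.fa")
    gtf_path = reference.write_gtf(workdir / "annotation.gtf")
    fastqs, labels, truth = synthetic.simulate_reads(cfg, reference, workdir / "reads")

    spec = count_samples(fastqs, labels, cfg.k, workdir / "stores")
    rcfg = reduction_cfg or reduction.ReductionConfig()
    retained = reduction.reduce_matrix(spec, rcfg, workers=workers, seed=seed)

    sequences = graph.assemble(
        retained, w=1, min_node_accuracy=rcfg.acc_threshold, min_seq_accuracy=rcfg.acc_threshold
    )
    sam_path = synthetic.align_to_reference(
        [(s.name, s.sequence) for s in sequences], reference, workdir / "aligned.sam"
    )
    models = annotation.load_gtf(gtf_path)
    events = annotation.classify_events(
        sam_path,
        models,
        sequences=sequences,
        d=d,
        member_accuracies=member_accuracy_map(retained, sequences),
    )
    recovery = synthetic.score_recovery(set(retained["kmer"]), truth, events=events)

    table = feature_table_from_events(spec, events)
    if table.shape[1] >= 2:
        selected, curve, _model, _imp = classify.evaluate(
            table, labels, n_select=min(20, table.shape[1]), seed=seed
        )
    else:
        selected, curve = [], classify.OobCurve([], [], [])
    return PipelineResult(
        spec=spec,
        retained=retained,
        sequences=sequences,
        events=events,
        feature_table=table,
        labels=list(labels),
        selected=selected,
        oob=curve,
        recovery=recovery,
    )


def cross_validate(
    spec: matrix.MatrixSpec,
    n_folds: int = 5,
    reduction_cfg: reduction.ReductionConfig | None = None,
    seed: int = 0,
    n_features: int = 20,
    n_trees: int = classify.DEFAULT_N_TREES,
) -> pd.DataFrame:
    """K-fold cross-validation of the whole discovery procedure.

    Feature reduction, graph assembly and feature selection are re-run on
    each training fold alone; the fold's model is then scored on the
    held-out samples by balanced accuracy.
    """
    rcfg = reduction_cfg or reduction.ReductionConfig()
    labels = np.asarray(spec.groups)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        train_spec = matrix.MatrixSpec(
            samples=[spec.samples[i] for i in train_idx], rescale_factor=spec.rescale_factor
        )
        retained = reduction.reduce_matrix(train_spec, rcfg, seed=seed)
        if retained.empty:
            rows.append({"fold": fold, "n_features": 0, "balanced_accuracy": np.nan})
            continue
        seqs = graph.assemble(
            retained,
            min_node_accuracy=rcfg.acc_threshold,
            min_seq_accuracy=rcfg.acc_threshold,
        )
        kmers = sorted({s.best_kmer for s in seqs})[: max(n_features, 2)]
        codes = [kmer_store.encode_kmer(km) for km in kmers]
        rows_by_code = matrix.fetch_rows(spec, codes)
        X = np.column_stack([rows_by_code[c].normalized for c in codes])
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed).fit(
            X[train_idx], labels[train_idx]
        )
        bacc = balanced_accuracy_score(labels[test_idx], rf.predict(X[test_idx]))
        rows.append(
            {"fold": fold, "n_features": len(kmers), "balanced_accuracy": float(bacc)}
        )
    return pd.DataFrame(rows)
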