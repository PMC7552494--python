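"""Shared fixtures: in-memory matrix specs and the standard synthetic cohort."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from kmerdisco import kmer_store, matrix, pipeline
from kmerdisco.synthetic import SimConfig


def spec_from_counts(
    tmp_dir: Path,
    counts: np.ndarray,
    groups: list[str],
    k: int = 8,
    codes: np.ndarray | None = None,
) -> matrix.MatrixSpec:
    """Build a MatrixSpec from a dense (k-mers x samples) count matrix."""
    counts = np.asarray(counts)
    n_kmers, n_samples = counts.shape
    if codes is None:
        codes = np.arange(n_kmers, dtype=np.uint64)
    tmp_dir.mkdir(parents=True, exist_ok=True)
    metas = []
    for j in range(n_samples):
        col = counts[:, j]
        mask = col > 0
        store_path = tmp_dir / f"s{j}.kstr"
        kmer_store.write_store(codes[mask], col[mask].astype(np.uint32), k, store_path)
        meta = kmer_store.SampleMeta(
            name=f"s{j}",
            group=groups[j],
            store_path=store_path,
            total_count=int(col.sum()),
            k=k,
        )
        meta.to_json(tmp_dir / f"s{j}.json")
        metas.append(meta)
    return matrix.MatrixSpec(samples=metas)


@pytest.fixture
def make_spec(tmp_path):
    def _make(counts, groups, k=8, codes=None):
        return spec_from_counts(tmp_path / "stores", np.asarray(counts), groups, k, codes)

    return _make


@pytest.fixture(scope="session")
def standard_cfg() -> SimConfig:
    """The standard two-group cohort: 20 vs 20 samples, 10 DE + 5 SNV +
    3 splice planted signals, seed 42."""
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def standard_run(standard_cfg, tmp_path_factory) -> pipeline.PipelineResult:
    """Full pipeline run on the standard cohort (shared, expensive)."""
    workdir = tmp_path_factory.mktemp("standard_cohort")
    return pipeline.run_synthetic_pipeline(standard_cfg, workdir, seed=standard_cfg.seed)


@pytest.fixture(scope="session")
def standard_truth(standard_cfg, standard_run):
    import pandas as pd

    # simulate_reads wrote truth.tsv next to the reads
    reads_dir = Path(standard_run.spec.samples[0].store_path).parent.parent / "reads"
    return pd.read_csv(reads_dir / "truth.tsv", sep="\t")
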