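"""Streamed, normalized k-mer x sample count matrix.

The matrix is never materialized: it exists as an iterator of rows built
by a buffered k-way merge over the samples' sorted stores.  Counts are
normalized as N_ij = C_ij * RF / T_j where T_j is the sample's total
k-mer count and RF a rescaling factor (default 1e9) that keeps the values
in a numerically comfortable range.

The k-mer space [0, 4^k) is tiled into worker partitions with
K_t = (4^k - 1) / T * t, evaluated in double precision and rounded to the
nearest integer; worker t covers [K_t, K_{t+1}) and the last partition is
closed at 4^k.
"""

from __future__ import annotations

import heapq
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .kmer_store import SampleMeta, SampleStore, read_store

DEFAULT_RF = 1e9
#: GiB occupied by 1000 buffered k-mer records (empirical constant).
ALPHA_GIB_PER_1000 = 0.011
DEFAULT_RAM_GIB = 4.0
RAM_ENV_VAR = "KMERDISCO_MAX_MEM_GB"


@dataclass
class Partition:
    """Half-open code interval [start, end) handled by one worker."""

    index: int
    start: int
    end: int
    total: int


@dataclass
class MatrixRow:
    code: int
    raw: np.ndarray  # int64 per sample
    normalized: np.ndarray  # float64 per sample


@dataclass
class MatrixSpec:
    """Ordered samples, their group labels and the rescaling factor."""

    samples: list[SampleMeta]
    rescale_factor: float = DEFAULT_RF

    def __post_init__(self) -> None:
        if len({m.k for m in self.samples}) > 1:
            raise ValueError("all samples must share the same k")
        if len(self.groups_set) < 2:
            raise ValueError("a matrix needs at least 2 distinct groups")
        for m in self.samples:
            if m.total_count <= 0:
                raise ValueError(f"sample {m.name} has total_count 0 (unusable)")

    @property
    def k(self) -> int:
        return self.samples[0].k

    @property
    def groups(self) -> list[str]:
        return [m.group for m in self.samples]

    @property
    def groups_set(self) -> set[str]:
        return {m.group for m in self.samples}

    @property
    def totals(self) -> np.ndarray:
        return np.array([m.total_count for m in self.samples], dtype=np.float64)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "rescale_factor": self.rescale_factor,
                    "k": self.k,
                    "samples": [
                        {
                            "name": m.name,
                            "group": m.group,
                            "store": str(m.store_path),
                            "total_count": m.total_count,
                            "k": m.k,
                        }
                        for m in self.samples
                    ],
                },
                indent=1,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "MatrixSpec":
        d = json.loads(Path(path).read_text())
        samples = [
            SampleMeta(
                name=s["name"],
                group=s["group"],
                store_path=Path(s["store"]),
                total_count=int(s["total_count"]),
                k=int(s["k"]),
            )
            for s in d["samples"]
        ]
        return cls(samples=samples, rescale_factor=float(d.get("rescale_factor", DEFAULT_RF)))

    @classmethod
    def from_sample_jsons(
        cls, paths: Sequence[str | Path], rescale_factor: float = DEFAULT_RF
    ) -> "MatrixSpec":
        return cls(
            samples=[SampleMeta.from_json(p) for p in paths], rescale_factor=rescale_factor
        )


def partition_space(workers: int, k: int) -> list[Partition]:
    """Tile [0, 4^k) into `workers` partitions via K_t = (4^k-1)/T * t.

    K_t is evaluated in double precision and rounded to nearest (this
    reproduces the canonical two-worker 31-mer split whose second start
    index is 4^31/2 rather than the integer floor of (4^31-1)/2).
    """
    if workers < 1:
        raise ValueError("need at least one worker")
    space = 4**k
    if workers > space:
        raise ValueError(f"more workers ({workers}) than k-mers ({space})")
    starts = [int(round(float(space - 1) / workers * t)) for t in range(workers)]
    ends = starts[1:] + [space]
    return [
        Partition(index=t, start=s, end=e, total=workers)
        for t, (s, e) in enumerate(zip(starts, ends))
    ]


def normalize_row(raw: np.ndarray, totals: np.ndarray, rf: float = DEFAULT_RF) -> np.ndarray:
    """N_ij = C_ij * RF / T_j."""
    totals = np.asarray(totals, dtype=np.float64)
    if np.any(totals <= 0):
        raise ValueError("sample with total count 0 is unusable")
    return np.asarray(raw, dtype=np.float64) * (rf / totals)


def buffer_size(ram_gib: float | None = None, n_samples: int = 1, workers: int = 1) -> int:
    """Records buffered per sample: floor(1000 * RAM / (alpha*N*T)), min 1."""
    if ram_gib is None:
        ram_gib = float(os.environ.get(RAM_ENV_VAR, DEFAULT_RAM_GIB))
    buff = int(1000.0 * ram_gib / (ALPHA_GIB_PER_1000 * n_samples * workers))
    return max(1, buff)


class _StoreCursor:
    """Sequential buffered reader over one store restricted to a partition."""

    def __init__(self, store: SampleStore, name: str, start: int, end: int, buffer: int):
        self.name = name
        self.codes = store.codes
        self.counts = store.counts
        self.buffer = max(1, buffer)
        self.pos = int(np.searchsorted(self.codes, np.uint64(start)))
        self.stop = int(np.searchsorted(self.codes, np.uint64(end)))
        self._chunk_codes: np.ndarray | None = None
        self._chunk_counts: np.ndarray | None = None
        self._i = 0
        self._last_code = -1

    def __iter__(self) -> Iterator[tuple[int, int]]:
        while self.pos < self.stop or (
            self._chunk_codes is not None and self._i < len(self._chunk_codes)
        ):
            if self._chunk_codes is None or self._i >= len(self._chunk_codes):
                nxt = min(self.pos + self.buffer, self.stop)
                self._chunk_codes = self.codes[self.pos : nxt]
                self._chunk_counts = self.counts[self.pos : nxt]
                self.pos = nxt
                self._i = 0
                if len(self._chunk_codes) == 0:
                    return
            code = int(self._chunk_codes[self._i])
            count = int(self._chunk_counts[self._i])
            self._i += 1
            if code <= self._last_code:
                raise ValueError(f"store of sample {self.name} is not sorted")
            self._last_code = code
            yield code, count


def stream_rows(
    spec: MatrixSpec,
    part: Partition | None = None,
    buffer: int | None = None,
    stores: Sequence[SampleStore] | None = None,
) -> Iterator[MatrixRow]:
    """Yield each k-mer present in >=1 sample, in strictly increasing order.

    Each store is read sequentially once through a bounded per-sample
    buffer; rows are produced by a k-way heap merge, samples without the
    k-mer contributing a raw count of 0.  Output is independent of the
    buffer size.
    """
    if part is None:
        part = partition_space(1, spec.k)[0]
    if buffer is None:
        buffer = buffer_size(n_samples=len(spec.samples), workers=part.total)
    if stores is None:
        stores = [read_store(m.store_path) for m in spec.samples]
    totals = spec.totals
    rf = spec.rescale_factor
    n = len(spec.samples)
    cursors = [
        _StoreCursor(store, meta.name, part.start, part.end, buffer)
        for store, meta in zip(stores, spec.samples)
    ]
    def _tagged(cur: _StoreCursor, j: int) -> Iterator[tuple[int, int, int]]:
        for code, count in cur:
            yield code, j, count

    merged = heapq.merge(*(_tagged(cur, j) for j, cur in enumerate(cursors)))
    current_code = None
    raw = np.zeros(n, dtype=np.int64)
    for code, j, count in merged:
        if current_code is None:
            current_code = code
        elif code != current_code:
            yield MatrixRow(current_code, raw, normalize_row(raw, totals, rf))
            raw = np.zeros(n, dtype=np.int64)
            current_code = code
        raw[j] = count
    if current_code is not None:
        yield MatrixRow(current_code, raw, normalize_row(raw, totals, rf))


def fetch_rows(spec: MatrixSpec, codes: Sequence[int]) -> dict[int, MatrixRow]:
    """Random-access lookup of specific k-mer rows (for feature tables)."""
    stores = [read_store(m.store_path) for m in spec.samples]
    totals = spec.totals
    out: dict[int, MatrixRow] = {}
    for code in codes:
        raw = np.array([s.lookup(code) for s in stores], dtype=np.int64)
        out[code] = MatrixRow(code, raw, normalize_row(raw, totals, spec.rescale_factor))
    return out
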