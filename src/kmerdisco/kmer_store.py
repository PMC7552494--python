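"""Per-sample k-mer counting and the sorted prefix/suffix binary store.

A k-mer over {A, C, G, T} is encoded as a base-4 integer (A=0, C=1, G=2,
T=3, first nucleotide most significant), so the full k-mer space maps onto
[0, 4^k) and lexicographic order of sequences equals numeric order of
codes.  Each sample's counts are kept in a sorted binary file split into a
prefix index (each distinct p-nucleotide prefix with the offset of its
first record) and a suffix section holding the remaining nucleotides and
the count.  A JSON sidecar stores the sample name, its group label and the
total k-mer count T_j used later for normalization.

k is capped at 31 so codes fit comfortably in an unsigned 64-bit integer.
"""

from __future__ import annotations

import gzip
import json
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

MAX_K = 31
STORE_MAGIC = b"KSTR1"
COUNT_SATURATION = 2**32 - 1

_BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODES[_b] = _i
    _BASE_CODES[_b + 32] = _i  # lowercase accepted and upcased
_BASES = "ACGT"
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)


class StoreFormatError(ValueError):
    """Raised when a binary store file is corrupt or truncated."""


# ---------------------------------------------------------------------------
# encoding


def encode_kmer(seq: str) -> int:
    """Encode a nucleotide string as its base-4 integer code.

    Raises ValueError for characters outside {A, C, G, T} (case
    insensitive); callers counting read windows skip such k-mers instead.
    """
    if len(seq) > MAX_K:
        raise ValueError(f"k-mer longer than {MAX_K}: {len(seq)}")
    code = 0
    for ch in seq.upper():
        b = _BASES.find(ch)
        if b < 0:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer")
        code = code * 4 + b
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    if not 0 <= code < 4**k:
        raise ValueError(f"code {code} out of range for k={k}")
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def revcomp_code(code: int, k: int) -> int:
    """Reverse-complement a k-mer in code space."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def _encode_windows(seq: str, k: int) -> np.ndarray:
    """All valid k-mer codes of one read, in read order (vectorized).

    Windows touching a non-ACGT character are dropped.
    """
    b = _BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(b) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = (b > 3).astype(np.int32)
    badcum = np.concatenate(([0], np.cumsum(bad)))
    valid = (badcum[k:] - badcum[:-k]) == 0
    codes = np.zeros(n, dtype=np.uint64)
    b64 = b.astype(np.uint64)
    for i in range(k):
        codes = codes * np.uint64(4) + b64[i : i + n]
    return codes[valid]


def _encode_windows_from_bases(b: np.ndarray, k: int) -> np.ndarray:
    n = len(b) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    b64 = np.clip(b, 0, 3).astype(np.uint64)
    for i in range(k):
        codes = codes * np.uint64(4) + b64[i : i + n]
    return codes


# ---------------------------------------------------------------------------
# counting


def count_kmers(
    reads: Iterable[str], k: int, canonical: bool = False
) -> tuple[np.ndarray, np.ndarray, int]:
    """Count every valid k-mer window over an iterable of read sequences.

    Returns (codes, counts, total_count) with codes strictly increasing.
    With ``canonical=True`` each window is replaced by the smaller of its
    code and its reverse-complement code before counting.
    """
    if k < 1 or k > MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}]")
    chunks: list[np.ndarray] = []
    for seq in reads:
        b = _BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        n = len(b) - k + 1
        if n <= 0:
            continue
        bad = (b > 3).astype(np.int32)
        badcum = np.concatenate(([0], np.cumsum(bad)))
        valid = (badcum[k:] - badcum[:-k]) == 0
        codes = _encode_windows_from_bases(b, k)
        if canonical:
            # forward window j pairs with window (n-1-j) of the rc strand
            rc = _encode_windows_from_bases(_COMPLEMENT[np.clip(b, 0, 3)][::-1], k)[::-1]
            codes = np.minimum(codes, rc)
        codes = codes[valid]
        if codes.size:
            chunks.append(codes)
    if not chunks:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.uint32), 0
    allcodes = np.concatenate(chunks)
    uniq, counts = np.unique(allcodes, return_counts=True)
    total = int(counts.sum())
    counts = np.minimum(counts, COUNT_SATURATION).astype(np.uint32)
    return uniq, counts, total


def prefix_length(t: int, k: int = MAX_K) -> int:
    """Prefix size for a store holding t distinct k-mers.

    p = round(0.5*log2(t) - 0.5*log2(log2(t))), round-half-up, clamped to
    [1, k-1].  For t < 4 the formula degenerates and p = 1.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if t < 4:
        return 1
    p = 0.5 * math.log2(t) - 0.5 * math.log2(math.log2(t))
    p_int = math.floor(p + 0.5)  # round half up
    return max(1, min(k - 1, p_int))


# ---------------------------------------------------------------------------
# binary store

_HEADER = struct.Struct("<5sBBQ")  # magic, k, p, n_distinct


@dataclass
class SampleStore:
    """One sample's sorted (k-mer, count) records, memory-resident view."""

    k: int
    p: int
    codes: np.ndarray  # uint64, strictly increasing
    counts: np.ndarray  # uint32
    path: Path | None = None

    @property
    def n_distinct(self) -> int:
        return int(self.codes.size)

    @property
    def total_count(self) -> int:
        return int(self.counts.sum(dtype=np.uint64))

    def lookup(self, code: int) -> int:
        """Count for one k-mer code, 0 if absent (binary search)."""
        i = int(np.searchsorted(self.codes, np.uint64(code)))
        if i < self.codes.size and int(self.codes[i]) == code:
            return int(self.counts[i])
        return 0


def write_store(codes: np.ndarray, counts: np.ndarray, k: int, path: str | Path) -> SampleStore:
    """Persist sorted records to the prefix/suffix binary layout.

    Layout (little-endian): header = magic ``KSTR1``, u8 k, u8 p,
    u64 n_distinct; prefix section = (u64 prefix_code, u64 first_record
    index) pairs sorted by prefix; suffix section = (u64 suffix_code,
    u32 count) records.
    """
    codes = np.asarray(codes, dtype=np.uint64)
    counts = np.asarray(counts, dtype=np.uint32)
    if codes.size and np.any(np.diff(codes.astype(np.int64)) <= 0):
        raise ValueError("records must be strictly increasing in code")
    if np.any(counts < 1) and codes.size:
        raise ValueError("zero-count records are never written")
    t = codes.size
    p = prefix_length(max(t, 1), k)
    shift = np.uint64(2 * (k - p))
    prefixes = codes >> shift
    suffix_mask = np.uint64((1 << (2 * (k - p))) - 1)
    suffixes = codes & suffix_mask
    uniq_pref, first_idx = np.unique(prefixes, return_index=True) if t else (
        np.empty(0, dtype=np.uint64),
        np.empty(0, dtype=np.int64),
    )
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(STORE_MAGIC, k, p, t))
        fh.write(struct.pack("<Q", uniq_pref.size))
        pref_block = np.empty((uniq_pref.size, 2), dtype="<u8")
        pref_block[:, 0] = uniq_pref
        pref_block[:, 1] = first_idx
        fh.write(pref_block.tobytes())
        rec = np.zeros(t, dtype=[("suffix", "<u8"), ("count", "<u4")])
        rec["suffix"] = suffixes
        rec["count"] = counts
        fh.write(rec.tobytes())
    return SampleStore(k=k, p=p, codes=codes, counts=counts, path=path)


def read_store(path: str | Path) -> SampleStore:
    """Load a binary store, validating each section."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER.size + 8:
        raise StoreFormatError(f"{path}: truncated header")
    magic, k, p, t = _HEADER.unpack_from(raw, 0)
    if magic != STORE_MAGIC:
        raise StoreFormatError(f"{path}: bad magic in header")
    (n_pref,) = struct.unpack_from("<Q", raw, _HEADER.size)
    off = _HEADER.size + 8
    pref_bytes = n_pref * 16
    rec_bytes = t * 12
    if len(raw) != off + pref_bytes + rec_bytes:
        section = "prefix section" if len(raw) < off + pref_bytes else "suffix section"
        raise StoreFormatError(f"{path}: truncated {section}")
    pref_block = np.frombuffer(raw, dtype="<u8", count=2 * n_pref, offset=off).reshape(-1, 2)
    rec = np.frombuffer(
        raw, dtype=[("suffix", "<u8"), ("count", "<u4")], count=t, offset=off + pref_bytes
    )
    suffix_bits = np.uint64(2 * (k - p))
    codes = np.empty(t, dtype=np.uint64)
    counts = np.ascontiguousarray(rec["count"])
    prefixes = pref_block[:, 0]
    starts = pref_block[:, 1].astype(np.int64)
    ends = np.append(starts[1:], t)
    for pref, s, e in zip(prefixes, starts, ends):
        codes[s:e] = (pref << suffix_bits) | rec["suffix"][s:e]
    if t and np.any(np.diff(codes.astype(np.int64)) <= 0):
        raise StoreFormatError(f"{path}: suffix section not sorted")
    return SampleStore(k=k, p=p, codes=codes, counts=counts, path=path)


# ---------------------------------------------------------------------------
# samples


@dataclass
class SampleMeta:
    """JSON sidecar describing one counted sample."""

    name: str
    group: str
    store_path: Path
    total_count: int
    k: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "name": self.name,
                    "group": self.group,
                    "store": str(self.store_path),
                    "total_count": self.total_count,
                    "k": self.k,
                },
                indent=1,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SampleMeta":
        d = json.loads(Path(path).read_text())
        return cls(
            name=d["name"],
            group=d["group"],
            store_path=Path(d["store"]),
            total_count=int(d["total_count"]),
            k=int(d["k"]),
        )


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: Path) -> str:
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            raise ValueError(f"{path}: neither FASTA nor FASTQ")
    raise ValueError(f"{path}: empty read file")


def iter_reads(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTA or FASTQ file, plain or gzipped."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"read file not found: {path}")
    fmt = _sniff_format(path)
    with _open_maybe_gzip(path) as fh:
        for record in SeqIO.parse(fh, fmt):
            yield str(record.seq)


def build_sample(
    read_files: Sequence[str | Path],
    k: int,
    name: str,
    group: str,
    out_dir: str | Path,
    canonical: bool = False,
) -> tuple[SampleMeta, SampleStore]:
    """Count one sample's reads and emit its store plus JSON metadata.

    Idempotent for identical input.  A sample with no valid k-mer produces
    an empty store with total_count 0 and is flagged unusable downstream.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def reads() -> Iterator[str]:
        for f in read_files:
            yield from iter_reads(f)

    codes, counts, total = count_kmers(reads(), k, canonical=canonical)
    store_path = out_dir / f"{name}.kstr"
    store = write_store(codes, counts, k, store_path)
    meta = SampleMeta(name=name, group=group, store_path=store_path, total_count=total, k=k)
    meta.to_json(out_dir / f"{name}.json")
    return meta, store
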