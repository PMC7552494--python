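"""Feature reduction: entropy-gated naive-Bayes accuracy per k-mer.

Every streamed matrix row is scored by how well its counts alone separate
each pair of sample groups.  The score is the mean test accuracy of a
single-feature Gaussian naive-Bayes classifier under Monte Carlo
cross-validation: each iteration draws, per group and without
replacement, a balanced train/test split sized to the smaller group
(n_test = round(n_min * p_test), n_train = n_min - n_test), fits one
Gaussian per class on the training counts and predicts the test samples
by maximum likelihood with equal priors.  Iterations stop early once the
running standard error of the per-iteration accuracies falls below a
threshold.  A k-mer is retained when its best pairwise accuracy reaches
the accuracy threshold.

Because most k-mers are uninformative, an adaptive Shannon-entropy gate
runs in front of the classifier: k-mers whose count distribution across
samples has entropy below an adaptive threshold H_thr are discarded
without being scored.  H_thr starts at 0 (everything in the first batch
is evaluated), tracks the lowest entropy H_min seen among retained
k-mers, and is re-tuned each time more than E_up k-mers pass, with E_up
growing by a fixed step to damp fluctuations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .kmer_store import decode_kmer
from .matrix import MatrixRow, MatrixSpec, partition_space, stream_rows


@dataclass
class ReductionConfig:
    """Knobs of the reduction step.

    acc_threshold, se_break and the accuracies are expressed in percent.
    """

    acc_threshold: float = 65.0
    max_iterations: int = 100
    se_break: float = 0.5
    test_fraction: float = 0.25
    entropy_adjust_down: float = 0.25  # a1
    entropy_adjust_up: float = 0.05  # a2, a1 >> a2
    e_up_init: int = 30
    e_up_step: int = 30
    min_iterations: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if not 0 < self.entropy_adjust_up < self.entropy_adjust_down < 1:
            raise ValueError("need 0 < a2 < a1 < 1")
        if not 50 < self.acc_threshold <= 101:
            raise ValueError("acc_threshold must exceed chance (50) and be <= 101")


def shannon_entropy(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of a k-mer's count distribution over samples.

    H = -sum f_i log2 f_i with f_i = c_i / sum(c); zero fractions
    contribute nothing.  Bounded by log2(n_samples).
    """
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("entropy undefined for all-zero counts")
    f = counts[counts > 0] / total
    return float(-(f * np.log2(f)).sum())


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def split_sizes(n_min: int, test_fraction: float = 0.25) -> tuple[int, int]:
    """(n_test, n_train) for the smaller group size, round-half-up."""
    n_test = _round_half_up(n_min * test_fraction)
    n_train = n_min - n_test
    return n_test, n_train


def mc_accuracy(
    values: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    pair: tuple[str, str],
    cfg: ReductionConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, int]:
    """Monte Carlo cross-validated single-feature naive-Bayes accuracy.

    Returns (mean accuracy in percent, iterations used).  Deterministic
    given the seed; invariant to swapping the two group labels and to a
    common positive rescaling of the counts.
    """
    cfg = cfg or ReductionConfig()
    labels = np.asarray(labels)
    values = np.asarray(values, dtype=np.float64)
    # group order is canonicalized so the result cannot depend on how the
    # pair is written; the accuracy itself is symmetric in the two groups
    x = [values[labels == g] for g in sorted(pair)]
    if min(len(x[0]), len(x[1])) < 2:
        raise ValueError("both groups need >= 2 samples")
    n_min = min(len(x[0]), len(x[1]))
    n_test, n_train = split_sizes(n_min, cfg.test_fraction)
    if n_test < 1 or n_train < 1:
        raise ValueError(f"degenerate split: n_test={n_test}, n_train={n_train}")
    rng = np.random.default_rng(seed)
    var_floor = 1e-9 * (float(np.concatenate(x).var()) + 1.0)

    # all candidate iterations are drawn and scored in one vectorized pass;
    # the sequential stopping rule is then applied to the per-iteration
    # accuracies, which reproduces iteration-by-iteration early breaking
    c = cfg.max_iterations
    correct = np.zeros(c, dtype=np.int64)
    test_sets = []
    params = []  # (mu, var) per group, arrays of shape (c,)
    for xg in x:
        perm = np.argsort(rng.random((c, len(xg))), axis=1)[:, :n_min]
        vals = xg[perm]
        test_sets.append(vals[:, :n_test])
        train = vals[:, n_test:]
        mu = train.mean(axis=1)
        var = np.maximum(train.var(axis=1), var_floor)
        params.append((mu, var))
    for gi, test in enumerate(test_sets):
        # log-likelihood under each class Gaussian, equal priors
        ll = [
            -0.5 * np.log(2.0 * np.pi * var)[:, None]
            - (test - mu[:, None]) ** 2 / (2.0 * var[:, None])
            for mu, var in params
        ]
        pred = (ll[1] > ll[0]).astype(np.int8)  # argmax over the pair
        correct += (pred == gi).sum(axis=1)
    accs = correct / (2.0 * n_test) * 100.0
    used = _iterations_until_break(accs, cfg.min_iterations, cfg.se_break)
    return float(accs[:used].mean()), used


def _iterations_until_break(accs: np.ndarray, min_iter: int, se_break: float) -> int:
    """First m >= min_iter at which the running standard error drops below
    the break threshold; len(accs) if it never does."""
    c = len(accs)
    if c <= min_iter:
        return c
    m = np.arange(1, c + 1, dtype=np.float64)
    cs = np.cumsum(accs)
    css = np.cumsum(accs * accs)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.maximum(css - cs * cs / m, 0.0) / np.maximum(m - 1.0, 1.0)
        se = np.sqrt(var / m)
    hit = np.nonzero(se[min_iter - 1 :] < se_break)[0]
    return int(hit[0]) + min_iter if hit.size else c


# ---------------------------------------------------------------------------
# adaptive entropy filter


@dataclass
class EntropyFilterState:
    """Adaptive Shannon-entropy threshold, one instance per worker."""

    h_thr: float = 0.0
    h_min: float | None = None
    passed_since_update: int = 0
    e_up: int = 30
    e_up_step: int = 30
    a1: float = 0.25
    a2: float = 0.05
    updates_done: int = 0

    @classmethod
    def from_config(cls, cfg: ReductionConfig) -> "EntropyFilterState":
        return cls(
            e_up=cfg.e_up_init,
            e_up_step=cfg.e_up_step,
            a1=cfg.entropy_adjust_down,
            a2=cfg.entropy_adjust_up,
        )

    def gate(self, h: float) -> bool:
        """True to keep (evaluate) the k-mer; strict `<` discards."""
        return not h < self.h_thr

    def record_pass(self, h: float) -> None:
        """Note a k-mer that passed the accuracy filter; maybe re-tune."""
        self.h_min = h if self.h_min is None else min(self.h_min, h)
        self.passed_since_update += 1
        if self.passed_since_update > self.e_up:
            self.update_threshold()

    def update_threshold(self) -> None:
        """Re-tune H_thr from H_min; first assignment differs from later ones."""
        assert self.h_min is not None
        if self.updates_done == 0:
            self.h_thr = self.h_min - self.h_min * self.a1 * 2.0
        elif self.h_thr > self.h_min - self.h_min * self.a1:
            self.h_thr = self.h_min - self.h_min * self.a1
        else:
            self.h_thr = self.h_min + self.h_min * self.a2
        self.updates_done += 1
        self.passed_since_update = 0
        self.e_up += self.e_up_step


def entropy_gate(h: float, state: EntropyFilterState) -> bool:
    """Functional form of :meth:`EntropyFilterState.gate`."""
    return state.gate(h)


# ---------------------------------------------------------------------------
# full reduction


def group_pairs(groups: Iterable[str]) -> list[tuple[str, str]]:
    uniq = sorted(set(groups))
    return [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1 :]]


def _kmer_seed(master_seed: int, code: int) -> np.random.SeedSequence:
    # depends only on (master seed, code): reproducible and invariant to
    # the number of partitions
    return np.random.SeedSequence([int(master_seed), int(code)])


def reduce_matrix(
    spec: MatrixSpec,
    cfg: ReductionConfig | None = None,
    workers: int = 1,
    seed: int = 0,
    use_entropy_gate: bool = True,
) -> pd.DataFrame:
    """Stream the whole matrix and retain discriminative k-mers.

    Returns a DataFrame sorted by code with columns: kmer, code, entropy,
    one ``acc_<g1>_<g2>`` and one ``iters_<g1>_<g2>`` per unordered group
    pair.  A k-mer is retained when its maximum pairwise accuracy is at
    least ``cfg.acc_threshold``.  Each worker partition runs an
    independent entropy-filter state.
    """
    cfg = cfg or ReductionConfig()
    pairs = group_pairs(spec.groups)
    labels = np.asarray(spec.groups)
    k = spec.k
    rows: list[dict] = []
    for part in partition_space(workers, k):
        state = EntropyFilterState.from_config(cfg)
        for row in stream_rows(spec, part):
            assert row.raw.any(), "streamed row with all-zero counts"
            h = shannon_entropy(row.raw)
            if use_entropy_gate and not state.gate(h):
                continue
            accs: dict[str, float] = {}
            iters: dict[str, int] = {}
            best = 0.0
            for g1, g2 in pairs:
                acc, it = mc_accuracy(
                    row.normalized, labels, (g1, g2), cfg, _kmer_seed(seed, row.code)
                )
                accs[f"acc_{g1}_{g2}"] = acc
                iters[f"iters_{g1}_{g2}"] = it
                best = max(best, acc)
            if best >= cfg.acc_threshold:
                state.record_pass(h)
                rows.append(
                    {"kmer": decode_kmer(row.code, k), "code": row.code, "entropy": h}
                    | accs
                    | iters
                )
    columns = (
        ["kmer", "code", "entropy"]
        + [f"acc_{g1}_{g2}" for g1, g2 in pairs]
        + [f"iters_{g1}_{g2}" for g1, g2 in pairs]
    )
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values("code", kind="mergesort").reset_index(drop=True)


def write_reduction(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_reduction(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
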