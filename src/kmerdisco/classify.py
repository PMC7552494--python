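"""Feature evaluation: decision-tree selection and random-forest OOB curves.

A single decision tree fit on all samples ranks features by
impurity-based importance; the top 20 are retained.  Random forests with
bootstrap out-of-bag (OOB) scoring are then trained on the top n
features for n = 2..20, giving an accuracy curve that estimates
held-out performance without a separate validation split.  A final
forest on the selected features is serialized together with its
importance ranking.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

DEFAULT_N_FEATURES = 20
DEFAULT_N_TREES = 500


@dataclass
class OobCurve:
    n_features: list[int]
    scores: list[float]
    selected: list[str]  # importance order; top-n is a prefix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_features": self.n_features, "oob_score": self.scores})


def _validate_table(table: pd.DataFrame, labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    X = table.to_numpy(dtype=np.float64)
    y = np.asarray(labels)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    if len(set(y)) < 2:
        raise ValueError("need at least 2 classes")
    if len(table.columns) != len(set(table.columns)):
        raise ValueError("feature ids must be unique")
    return X, y


def select_features(
    table: pd.DataFrame, labels: Sequence[str], n: int = DEFAULT_N_FEATURES, seed: int = 0
) -> list[str]:
    """Rank features with one decision tree; return the top n in rank order.

    Ties in importance are broken by column order.  If fewer than n
    features receive nonzero importance, all of those are returned with a
    warning.
    """
    X, y = _validate_table(table, labels)
    tree = DecisionTreeClassifier(random_state=seed).fit(X, y)
    imp = tree.feature_importances_
    order = np.argsort(-imp, kind="stable")
    nonzero = [i for i in order if imp[i] > 0]
    if len(nonzero) < n:
        warnings.warn(
            f"only {len(nonzero)} features have nonzero importance (requested {n})"
        )
        chosen = nonzero
    else:
        chosen = list(order[:n])
    return [table.columns[i] for i in chosen]


def oob_curve(
    table: pd.DataFrame,
    labels: Sequence[str],
    selected: Sequence[str],
    n_range: Sequence[int] | None = None,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> OobCurve:
    """OOB accuracy of forests on the top-n selected features, n = 2..20."""
    _, y = _validate_table(table[list(selected)], labels)
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 samples")
    if n_range is None:
        n_range = range(2, min(DEFAULT_N_FEATURES, len(selected)) + 1)
    scores = []
    for n in n_range:
        if n > len(selected):
            raise ValueError(f"requested top-{n} but only {len(selected)} features selected")
        X = table[list(selected[:n])].to_numpy(dtype=np.float64)
        rf = RandomForestClassifier(
            n_estimators=n_trees, oob_score=True, random_state=seed, bootstrap=True
        ).fit(X, y)
        scores.append(float(rf.oob_score_))
    return OobCurve(n_features=list(n_range), scores=scores, selected=list(selected))


def train_final_model(
    table: pd.DataFrame,
    labels: Sequence[str],
    selected: Sequence[str],
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    model_path: str | Path | None = None,
    importances_path: str | Path | None = None,
) -> tuple[RandomForestClassifier, pd.Series]:
    """Fit the final forest on the selected features and serialize it.

    Returns the fitted model and its per-feature importances sorted
    descending.  Reloading the model file reproduces predictions on the
    training table bit-identically.
    """
    X, y = _validate_table(table[list(selected)], labels)
    rf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, bootstrap=True
    ).fit(X, y)
    # every sample must be out-of-bag at least once for the OOB estimate
    assert not np.isnan(rf.oob_decision_function_).any(), (
        "too few trees for OOB: some sample never out-of-bag"
    )
    importances = pd.Series(rf.feature_importances_, index=list(selected)).sort_values(
        ascending=False, kind="mergesort"
    )
    if model_path is not None:
        joblib.dump({"model": rf, "features": list(selected)}, model_path)
    if importances_path is not None:
        Path(importances_path).write_text(
            json.dumps({k: float(v) for k, v in importances.items()}, indent=1)
        )
    return rf, importances


def load_model(model_path: str | Path) -> tuple[RandomForestClassifier, list[str]]:
    d = joblib.load(model_path)
    return d["model"], d["features"]


def evaluate(
    table: pd.DataFrame,
    labels: Sequence[str],
    n_select: int = DEFAULT_N_FEATURES,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    out_dir: str | Path | None = None,
) -> tuple[list[str], OobCurve, RandomForestClassifier, pd.Series]:
    """select_features -> oob_curve -> train_final_model in one call."""
    selected = select_features(table, labels, n=n_select, seed=seed)
    if len(selected) < 2:
        # pad with zero-importance columns so an OOB curve still exists
        selected = selected + [c for c in table.columns if c not in selected]
        selected = selected[: max(2, min(n_select, len(selected)))]
    if len(selected) < 2:
        raise ValueError("need at least 2 features for the OOB curve")
    curve = oob_curve(table, labels, selected, seed=seed, n_trees=n_trees)
    out_dir = Path(out_dir) if out_dir is not None else None
    model, importances = train_final_model(
        table,
        labels,
        selected,
        seed=seed,
        n_trees=n_trees,
        model_path=None if out_dir is None else out_dir / "model.joblib",
        importances_path=None if out_dir is None else out_dir / "importances.json",
    )
    if out_dir is not None:
        curve.to_frame().to_csv(out_dir / "oob_curve.tsv", sep="\t", index=False)
    return selected, curve, model, importances
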