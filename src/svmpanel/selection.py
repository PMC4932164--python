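"""Greedy SVM-embedded forward feature selection (SVMFS and SVMTFS).

Both algorithms grow a biomarker panel one feature at a time and score
every candidate panel by the leave-one-out cross-validated accuracy of a
fixed-configuration radial SVM. They differ only in which feature is the
candidate at each round:

* **SVMFS** scans all remaining features and takes the one whose addition
  maximizes the panel's LOOCV accuracy;
* **SVMTFS** pre-ranks all features once by their single-feature LOOCV
  accuracy and considers them strictly in that order.

A candidate is included only if it improves the score by strictly more
than ``threshold`` (default 0: a zero-improvement feature is rejected),
which is also the natural stopping rule — the searches in practice stop
at panels of two or three markers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_data import ExpressionDataset
from .svm import SvmSpec, loocv_accuracy, train_svm  # re-exported for convenience

__all__ = [
    "SvmSpec", "train_svm", "loocv_accuracy",
    "SelectionTrace", "rank_single_features", "svmfs", "svmtfs",
]

logger = logging.getLogger(__name__)


@dataclass
class SelectionTrace:
    """Result of a forward-selection run.

    ``scores[k]`` is the LOOCV accuracy of the panel ``selected[:k+1]``;
    consecutive scores increase by strictly more than ``threshold``.
    """

    selected: list[str]
    scores: list[float]
    method: str
    threshold: float
    terminated_reason: str  # no_improvement | pool_exhausted | max_size

    def __post_init__(self) -> None:
        if len(self.selected) != len(self.scores) or not self.selected:
            raise ValueError("trace must have one score per selected feature")
        for a, b in zip(self.scores, self.scores[1:]):
            if not b - a > self.threshold:
                raise ValueError("trace scores violate the strict-improvement rule")

    @property
    def final_score(self) -> float:
        return self.scores[-1]

    def to_frame(self, ds: ExpressionDataset | None = None) -> pd.DataFrame:
        genes = None
        if ds is not None:
            genes = ds.feature_meta["gene_symbol"].reindex(self.selected).to_numpy()
        return pd.DataFrame({
            "round": np.arange(1, len(self.selected) + 1),
            "feature_id": self.selected,
            "gene_symbol": genes if genes is not None else [None] * len(self.selected),
            "loocv_accuracy": self.scores,
        })

    def save(self, path: str | Path, ds: ExpressionDataset | None = None,
             spec: SvmSpec | None = None, seed: int | None = None) -> None:
        """Write the trace as TSV plus a JSON sidecar with run parameters."""
        path = Path(path)
        self.to_frame(ds).to_csv(path, sep="\t", index=False, float_format="%.10g")
        sidecar = {
            "method": self.method,
            "threshold": self.threshold,
            "terminated_reason": self.terminated_reason,
            "spec": None if spec is None else {
                "kernel": spec.kernel, "cost": spec.cost,
                "gamma_rule": spec.gamma_rule, "standardize": spec.standardize,
            },
            "seed": seed,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def _check_two_class(y: np.ndarray) -> None:
    for cls in (0, 1):
        if int((y == cls).sum()) < 2:
            raise ValueError(f"classification needs >= 2 samples per class; class {cls} is short")


def rank_single_features(ds: ExpressionDataset, spec: SvmSpec | None = None) -> pd.DataFrame:
    """Score every feature by its single-feature SVM LOOCV accuracy.

    Returns a DataFrame (feature_id, gene_symbol, loocv_accuracy) sorted by
    descending accuracy; exact ties keep the original column order.
    """
    spec = spec if spec is not None else SvmSpec()
    if ds.n_features < 1:
        raise ValueError("dataset has no features")
    y = ds.binary_labels(spec.positive_label)
    _check_two_class(y)
    X = ds.matrix()
    scores = np.array([loocv_accuracy(X[:, [j]], y, spec) for j in range(ds.n_features)])
    order = np.argsort(-scores, kind="stable")
    return pd.DataFrame({
        "feature_id": np.array(ds.feature_ids)[order],
        "gene_symbol": ds.feature_meta["gene_symbol"].to_numpy()[order],
        "loocv_accuracy": scores[order],
    }).reset_index(drop=True)


def _forward_search(
    ds: ExpressionDataset,
    spec: SvmSpec,
    threshold: float,
    max_size: Optional[int],
    method: str,
    candidate_order: Optional[list[int]] = None,
) -> SelectionTrace:
    """Shared greedy loop. With ``candidate_order`` (SVMTFS) the candidate at
    round k is fixed; otherwise (SVMFS) all remaining features are scanned."""
    y = ds.binary_labels(spec.positive_label)
    _check_two_class(y)
    X = ds.matrix()
    n_features = X.shape[1]
    feature_ids = ds.feature_ids

    def panel_score(cols: list[int]) -> float:
        return loocv_accuracy(X[:, cols], y, spec)

    selected: list[int] = []
    scores: list[float] = []
    reason = "pool_exhausted"

    if candidate_order is None:
        remaining = list(range(n_features))
    else:
        remaining = list(candidate_order)

    while remaining:
        if max_size is not None and len(selected) >= max_size:
            reason = "max_size"
            break
        current = scores[-1] if scores else -np.inf
        if candidate_order is None:
            cand_scores = [panel_score(selected + [j]) for j in remaining]
            best = int(np.argmax(cand_scores))  # ties -> lowest original index
            best_score, best_j = cand_scores[best], remaining[best]
        else:
            best_j = remaining[0]
            best_score = panel_score(selected + [best_j])
        if best_score - current > threshold:
            selected.append(best_j)
            scores.append(best_score)
            remaining.remove(best_j)
        else:
            reason = "no_improvement"
            break
    else:
        reason = "pool_exhausted"

    if not selected:
        # even the best single feature failed the threshold: keep it anyway so
        # the trace is non-empty, and report the stop (spec: len >= 1 on success)
        raise ValueError(
            "no feature admissible at the given threshold "
            f"(best single-feature score did not exceed {threshold})"
        )
    return SelectionTrace(
        selected=[feature_ids[j] for j in selected],
        scores=scores, method=method, threshold=threshold, terminated_reason=reason,
    )


def svmfs(
    ds: ExpressionDataset,
    spec: SvmSpec | None = None,
    threshold: float = 0.0,
    max_size: Optional[int] = None,
) -> SelectionTrace:
    """SVM forward selection: each round adds the remaining feature whose
    inclusion maximizes panel LOOCV accuracy, while the improvement exceeds
    ``threshold``."""
    spec = spec if spec is not None else SvmSpec()
    if ds.n_features < 1:
        raise ValueError("dataset has no features")
    return _forward_search(ds, spec, threshold, max_size, "SVMFS")


def svmtfs(
    ds: ExpressionDataset,
    spec: SvmSpec | None = None,
    threshold: float = 0.0,
    max_size: Optional[int] = None,
    skip_non_improving: bool = False,
) -> SelectionTrace:
    """SVM top-forward selection: features are considered strictly in the
    order of the single-feature LOOCV ranking.

    By default the search terminates at the first non-improving ranked
    feature; with ``skip_non_improving`` it moves on to the next one
    instead (termination then only at pool exhaustion or ``max_size``).
    """
    spec = spec if spec is not None else SvmSpec()
    if ds.n_features < 1:
        raise ValueError("dataset has no features")
    ranking = rank_single_features(ds, spec)
    pos = {fid: j for j, fid in enumerate(ds.feature_ids)}
    order = [pos[fid] for fid in ranking["feature_id"]]
    if not skip_non_improving:
        return _forward_search(ds, spec, threshold, max_size, "SVMTFS", candidate_order=order)

    # skip mode: walk the ranking, keeping any feature that improves
    y = ds.binary_labels(spec.positive_label)
    X = ds.matrix()
    selected: list[int] = []
    scores: list[float] = []
    reason = "pool_exhausted"
    for j in order:
        if max_size is not None and len(selected) >= max_size:
            reason = "max_size"
            break
        current = scores[-1] if scores else -np.inf
        s = loocv_accuracy(X[:, selected + [j]], y, spec)
        if s - current > threshold:
            selected.append(j)
            scores.append(s)
    if not selected:
        raise ValueError("no feature admissible at the given threshold")
    return SelectionTrace(
        selected=[ds.feature_ids[j] for j in selected],
        scores=scores, method="SVMTFS", threshold=threshold, terminated_reason=reason,
    )
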