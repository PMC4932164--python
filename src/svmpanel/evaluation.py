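"""Panel evaluation: repeated stratified-split metrics, ROC/AUC, cross-cohort
validation, per-group LOOCV, banded interval classifiers, and inter-marker
correlation.

The headline evaluation repeats a stratified random split (by default 30
AD + 30 healthy training samples, remainder held out, 5000 repeats) and
averages a confusion-derived metric panel: sensitivity, specificity, PPV,
NPV, FDR (= 1 − PPV), FOR (= 1 − NPV), accuracy, plus AUC of the decision
scores. Ratios with a zero denominator are undefined (NaN) and excluded
from the averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_data import ExpressionDataset
from .svm import SvmSpec, loocv_accuracy, train_svm

logger = logging.getLogger(__name__)

#: columns of the per-repeat / averaged metric tables, Table-2-style order
METRIC_COLUMNS = ["accuracy", "sensitivity", "specificity", "npv", "ppv", "fdr", "for_rate", "auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table; positive class = AD."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    """Confusion-derived metric panel; NaN marks an undefined ratio."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    fdr: float
    for_rate: float
    accuracy: float
    auc: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("sensitivity", "specificity", "ppv", "npv", "fdr", "for_rate", "accuracy", "auc")}


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, PPV, NPV, FDR, FOR and accuracy from counts.

    FDR and FOR are the confusion-matrix complements 1 − PPV and 1 − NPV
    (rates among positive and negative *calls*), not multiple-testing
    quantities. A zero-denominator ratio is NaN.
    """
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    return MetricSet(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=ppv,
        npv=npv,
        fdr=1.0 - ppv if not np.isnan(ppv) else float("nan"),
        for_rate=1.0 - npv if not np.isnan(npv) else float("nan"),
        accuracy=(c.tp + c.tn) / c.total,
    )


def counts_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, pd.DataFrame]:
    """AUC by the Mann–Whitney rank statistic (ties count 1/2) plus the ROC
    point list (threshold, fpr, tpr) at every distinct score.

    Scores are decision values, higher = more AD-like.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    ranks = rankdata(scores)  # average ranks -> ties contribute 1/2
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    s_sorted, y_sorted = scores[order], labels[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate([distinct, [len(s_sorted) - 1]])  # last index of each score block
    tp = np.cumsum(y_sorted == 1)[cut]
    fp = np.cumsum(y_sorted == 0)[cut]
    points = pd.DataFrame({
        "threshold": np.concatenate([[np.inf], s_sorted[cut]]),
        "fpr": np.concatenate([[0.0], fp / n_neg]),
        "tpr": np.concatenate([[0.0], tp / n_pos]),
    })
    return float(auc), points


# ---------------------------------------------------------------------------
# repeated stratified-split cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitScheme:
    """Repeated stratified split: ``n_train_pos``/``n_train_neg`` training
    samples per class, remainder tested, ``n_repeats`` draws from ``seed``.

    One master seed spawns independent per-repeat substreams, so growing
    ``n_repeats`` re-uses (not reshuffles) the earlier repeats.
    """

    n_train_pos: int = 30
    n_train_neg: int = 30
    n_repeats: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.n_train_pos < 1 or self.n_train_neg < 1:
            raise ValueError("training counts must be >= 1")


@dataclass
class RepeatedCvResult:
    """Averaged metrics plus the full per-repeat table."""

    mean_metrics: MetricSet
    per_repeat: pd.DataFrame
    n_undefined: dict[str, int]


def repeated_split_cv(
    ds: ExpressionDataset,
    panel: Iterable[str],
    spec: SvmSpec | None = None,
    scheme: SplitScheme | None = None,
) -> RepeatedCvResult:
    """Train on random stratified draws, test on the remainder, average the
    metric panel over repeats (undefined repeats excluded per metric)."""
    spec = spec if spec is not None else SvmSpec()
    scheme = scheme if scheme is not None else SplitScheme()
    panel = list(panel)
    X = ds.matrix(panel)
    y = ds.binary_labels(spec.positive_label)
    pos_idx = np.nonzero(y == 1)[0]
    neg_idx = np.nonzero(y == 0)[0]
    if len(pos_idx) < scheme.n_train_pos + 1:
        raise ValueError(f"positive class has {len(pos_idx)} samples, "
                         f"needs > {scheme.n_train_pos}")
    if len(neg_idx) < scheme.n_train_neg + 1:
        raise ValueError(f"negative class has {len(neg_idx)} samples, "
                         f"needs > {scheme.n_train_neg}")

    streams = np.random.SeedSequence(scheme.seed).spawn(scheme.n_repeats)
    rows = []
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        tr = np.concatenate([
            rng.choice(pos_idx, size=scheme.n_train_pos, replace=False),
            rng.choice(neg_idx, size=scheme.n_train_neg, replace=False),
        ])
        te_mask = np.ones(len(y), dtype=bool)
        te_mask[tr] = False
        model = train_svm(X[tr], y[tr], spec)
        pred = model.predict(X[te_mask])
        m = metrics_from_counts(counts_from_predictions(y[te_mask], pred))
        try:
            m.auc, _ = roc_auc(model.decision_score(X[te_mask]), y[te_mask])
        except ValueError:
            m.auc = float("nan")
        rows.append({"repeat": rep, **m.as_dict()})
    table = pd.DataFrame(rows)
    means = {k: float(np.nanmean(table[k])) if table[k].notna().any() else float("nan")
             for k in MetricSet.__dataclass_fields__}
    n_undef = {k: int(table[k].isna().sum()) for k in MetricSet.__dataclass_fields__}
    dropped = {k: v for k, v in n_undef.items() if v}
    if dropped:
        logger.info("undefined repeats excluded from averages: %s", dropped)
    return RepeatedCvResult(mean_metrics=MetricSet(**means), per_repeat=table,
                            n_undefined=n_undef)


# ---------------------------------------------------------------------------
# cross-cohort validation
# ---------------------------------------------------------------------------

def match_panel_features(
    train_ds: ExpressionDataset, test_ds: ExpressionDataset, panel: Iterable[str]
) -> list[str]:
    """Map panel feature ids of the training cohort onto the test cohort,
    preferring gene-symbol matches (cross-platform) over probe ids."""
    test_genes = test_ds.feature_meta["gene_symbol"].astype("string").str.upper()
    matched, missing = [], []
    for fid in panel:
        gene = train_ds.feature_meta.loc[fid, "gene_symbol"]
        gene = None if pd.isna(gene) else str(gene).upper()
        hits = list(test_ds.feature_meta.index[test_genes == gene]) if gene else []
        if fid in hits or (not hits and fid in test_ds.feature_meta.index):
            matched.append(fid)
        elif hits:
            if len(hits) > 1:
                logger.info("gene %s has %d probes in test cohort; using %s",
                            gene, len(hits), hits[0])
            matched.append(hits[0])
        else:
            missing.append(fid)
    if missing:
        raise ValueError(f"panel features missing in test cohort: {missing}")
    return matched


def cross_cohort_validate(
    train_ds: ExpressionDataset,
    test_ds: ExpressionDataset,
    panel: Iterable[str],
    spec: SvmSpec | None = None,
) -> tuple[MetricSet, pd.DataFrame]:
    """Train once on the full training cohort, test on every sample of the
    independent cohort; returns the metric panel (with AUC) and ROC points."""
    spec = spec if spec is not None else SvmSpec()
    panel = list(panel)
    test_panel = match_panel_features(train_ds, test_ds, panel)
    X_tr = train_ds.matrix(panel)
    y_tr = train_ds.binary_labels(spec.positive_label)
    X_te = test_ds.matrix(test_panel)
    y_te = test_ds.binary_labels(spec.positive_label)
    model = train_svm(X_tr, y_tr, spec)
    metrics = metrics_from_counts(counts_from_predictions(y_te, model.predict(X_te)))
    metrics.auc, points = roc_auc(model.decision_score(X_te), y_te)
    return metrics, points


def grouped_loocv(
    ds: ExpressionDataset,
    panel: Iterable[str],
    spec: SvmSpec | None = None,
    group_field: str = "group",
) -> pd.DataFrame:
    """LOOCV accuracy of the panel computed independently inside each group
    (e.g. brain region). Groups with < 2 samples in either class are
    reported as skipped rather than failing the whole table."""
    spec = spec if spec is not None else SvmSpec()
    panel = list(panel)
    rows = []
    for group, meta in ds.sample_meta.groupby(group_field, sort=True, dropna=False):
        sub = ds.select_samples(meta.index)
        y = sub.binary_labels(spec.positive_label)
        n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
        row = {"group": group, "n_pos": n_pos, "n_neg": n_neg,
               "loocv_accuracy": float("nan"), "status": "ok"}
        if min(n_pos, n_neg) < 2:
            row["status"] = "skipped"
        else:
            row["loocv_accuracy"] = loocv_accuracy(sub.matrix(panel), y, spec)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# banded (two-threshold) single-marker classifier
# ---------------------------------------------------------------------------

@dataclass
class BandedFit:
    """Best two-threshold interval rule for one marker.

    The rule classifies values inside ``(lower, upper]`` as healthy and
    values outside as AD. ``is_banded`` flags markers where the interval
    beats the best single-threshold rule by more than ``margin``.
    """

    lower: float
    upper: float
    interval_accuracy: float
    best_single_threshold_accuracy: float
    is_banded: bool


def _threshold_grid(values: np.ndarray) -> np.ndarray:
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def fit_banded(values: np.ndarray, labels: np.ndarray, margin: float = 0.05) -> BandedFit:
    """Exhaustive search for the accuracy-maximizing interval rule.

    Thresholds run over midpoints of sorted distinct values plus ±inf;
    accuracy ties are broken toward the widest interval (an empty interval
    — classify everything AD — is allowed, so the family always contains
    both single-threshold orientations and the trivial rules).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(values).size < 2:
        raise ValueError("degenerate feature: constant values")
    if np.unique(values).size < 4:
        raise ValueError("need >= 4 distinct values")
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present")
    grid = _threshold_grid(values)
    healthy = labels == 0
    n = len(values)

    # inside(lo, hi] counts via cumulative sums over the grid
    lo = grid[:, None]              # candidate lower thresholds
    hi = grid[None, :]              # candidate upper thresholds
    # counts of healthy / AD values in (lo, hi] for all pairs, vectorized:
    v_sorted = np.sort(values)
    below = np.searchsorted(v_sorted, grid, side="right")  # values <= t
    h_sorted = np.sort(values[healthy])
    below_h = np.searchsorted(h_sorted, grid, side="right")
    n_h, n_a = int(healthy.sum()), int((~healthy).sum())

    inside_h = below_h[None, :] - below_h[:, None]      # healthy in (lo, hi]
    inside_all = below[None, :] - below[:, None]
    inside_a = inside_all - inside_h
    correct = inside_h + (n_a - inside_a)               # healthy inside + AD outside
    valid = lo <= hi
    acc = np.where(valid, correct / n, -1.0)

    with np.errstate(invalid="ignore"):
        width = hi - lo
    width[np.isnan(width)] = 0.0  # equal infinite thresholds: empty interval
    width = np.where(valid, width, -np.inf)
    # pick max accuracy, then widest, then smallest lower threshold
    best_acc = acc.max()
    tie = np.isclose(acc, best_acc)
    width_masked = np.where(tie, width, -np.inf)
    best_width = width_masked.max()
    tie &= np.isclose(width_masked, best_width) | (np.isinf(width_masked) & (width_masked > 0))
    i, j = np.argwhere(tie)[0]
    lower, upper = float(grid[i]), float(grid[j])
    interval_acc = float(correct[i, j] / n)

    # best single-threshold rule, either orientation
    below_each = below                      # values <= t
    below_h_each = below_h
    acc_low_healthy = (below_h_each + (n_a - (below_each - below_h_each))) / n   # healthy <= t
    acc_high_healthy = ((n_h - below_h_each) + (below_each - below_h_each)) / n  # healthy > t
    single = float(max(acc_low_healthy.max(), acc_high_healthy.max()))

    return BandedFit(
        lower=lower, upper=upper,
        interval_accuracy=interval_acc,
        best_single_threshold_accuracy=single,
        is_banded=bool(interval_acc > single + margin),
    )


def panel_correlations(
    ds: ExpressionDataset, features: Iterable[str], positive_label: str = "AD"
) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson r among panel features, overall and per diagnosis
    class. A zero-variance feature within a stratum yields NaN pairs."""
    features = list(features)
    out: dict[str, pd.DataFrame] = {}
    strata: list[tuple[str, pd.Index]] = [("all", ds.values.index)]
    for label in ds.sample_meta["diagnosis"].unique():
        strata.append((str(label), ds.values.index[ds.sample_meta["diagnosis"] == label]))
    for name, idx in strata:
        if len(idx) < 3:
            continue
        out[name] = ds.values.loc[idx, features].corr(method="pearson", min_periods=3)
    return out
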