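"""Preprocessing: floor-at-one, log2 transform, and robust age/gender correction.

Protein-microarray intensities are floored at 1 and log2-transformed, then
each feature is regressed on age and gender with a Huber M-estimator
(IRLS, tuning constant 1.345, MAD scale) and replaced by intercept +
residual. The correction removes linear covariate trends while the robust
loss keeps gross outliers — which in this setting are often the biology of
interest — from dragging the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_data import ExpressionDataset, TransformState

logger = logging.getLogger(__name__)

HUBER_T = 1.345
MAX_ITER = 50
TOL = 1e-8


def floor_log_transform(ds: ExpressionDataset) -> ExpressionDataset:
    """Set values < 1 to 1, then take log2. RAW -> LOG2."""
    if ds.transform_state is not TransformState.RAW:
        raise ValueError(f"floor_log_transform requires a RAW dataset, got {ds.transform_state.value}")
    arr = ds.values.to_numpy(dtype=float)
    out = np.log2(np.maximum(arr, 1.0))
    values = pd.DataFrame(out, index=ds.values.index, columns=ds.values.columns)
    return replace(ds, values=values, transform_state=TransformState.LOG2)


@dataclass
class CorrectionModel:
    """Per-feature robust-regression coefficients for age/gender correction.

    ``coefficients`` is indexed by feature id with columns ``intercept``,
    ``age_coef`` (log2 units per year), ``gender_coef`` (log2 units for the
    non-reference gender), ``n_used`` and ``converged``. ``gender_levels``
    records the indicator coding (reference level first).
    """

    coefficients: pd.DataFrame
    gender_levels: tuple[str, ...]

    def to_tsv(self, path: str | Path) -> None:
        out = self.coefficients.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def _design(ds: ExpressionDataset) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Complete-covariate mask, design matrix (const, age, gender) and coding."""
    age = pd.to_numeric(ds.sample_meta["age"], errors="coerce")
    gender = ds.sample_meta["gender"].astype("string")
    complete = age.notna().to_numpy() & gender.notna().to_numpy()
    levels = tuple(sorted(gender.dropna().unique()))
    if len(levels) > 2:
        raise ValueError(f"expected at most two gender levels, got {levels}")
    g = (gender == levels[-1]).astype(float).to_numpy() if len(levels) == 2 else np.zeros(len(gender))
    X = np.column_stack([np.ones(ds.n_samples), age.to_numpy(dtype=float), g])
    return complete, X, levels


def fit_robust_correction(ds: ExpressionDataset) -> CorrectionModel:
    """Fit, per feature, a Huber-IRLS regression of expression on age and gender.

    Only samples with complete age and gender enter the fit. A feature with
    a degenerate design (no covariate variation) is flagged not-converged
    and later passed through uncorrected.
    """
    if ds.transform_state is not TransformState.LOG2:
        raise ValueError("correction is fit on log2-transformed data")
    complete, X, levels = _design(ds)
    n_used = int(complete.sum())
    if n_used == 0:
        raise ValueError("no samples have complete age and gender")
    if n_used < 3:
        raise ValueError(f"need >= 3 samples with complete covariates, have {n_used}")

    Xc = X[complete]
    # drop constant covariate columns (single gender, constant age) from the fit
    varying = [0] + [j for j in (1, 2) if np.ptp(Xc[:, j]) > 0]
    degenerate = len(varying) == 1

    rows = []
    Y = ds.values.to_numpy(dtype=float)[complete]
    for j, fid in enumerate(ds.feature_ids):
        coef = {"intercept": float(np.median(Y[:, j])), "age_coef": 0.0, "gender_coef": 0.0}
        converged = False
        if not degenerate:
            try:
                res = sm.RLM(Y[:, j], Xc[:, varying], M=sm.robust.norms.HuberT(t=HUBER_T)).fit(
                    scale_est="mad", maxiter=MAX_ITER, tol=TOL, conv="coefs"
                )
                params = dict(zip(varying, res.params))
                coef = {
                    "intercept": float(params[0]),
                    "age_coef": float(params.get(1, 0.0)),
                    "gender_coef": float(params.get(2, 0.0)),
                }
                converged = bool(np.all(np.isfinite(res.params)))
            except Exception:  # zero-MAD or perfectly constant feature
                sd = float(np.std(Y[:, j]))
                coef = {"intercept": float(np.median(Y[:, j])), "age_coef": 0.0, "gender_coef": 0.0}
                converged = sd == 0.0  # a constant feature is trivially "fit"
        rows.append({**coef, "n_used": n_used, "converged": converged})
    table = pd.DataFrame(rows, index=pd.Index(ds.feature_ids, name="feature_id"))
    n_bad = int((~table["converged"]).sum())
    if n_bad:
        logger.warning("%d features not converged; passed through uncorrected", n_bad)
    return CorrectionModel(coefficients=table, gender_levels=levels)


def apply_correction(ds: ExpressionDataset, model: CorrectionModel) -> ExpressionDataset:
    """Replace each value by intercept + residual of the robust fit.

    Equivalently ``observed − age_coef·age − gender_coef·gender``. Samples
    with missing covariates, and features whose fit did not converge, keep
    their observed values. LOG2 -> CORRECTED.
    """
    if ds.transform_state is not TransformState.LOG2:
        raise ValueError("correction applies to log2-transformed data")
    if list(model.coefficients.index) != ds.feature_ids:
        raise ValueError("feature set of dataset and correction model differ")
    complete, X, levels = _design(ds)
    if levels != model.gender_levels and len(model.gender_levels) == 2:
        raise ValueError("gender coding of dataset and model differ")
    n_skipped = int((~complete).sum())
    if n_skipped:
        logger.warning("%d samples with missing covariates kept uncorrected", n_skipped)

    age_coef = model.coefficients["age_coef"].to_numpy()
    gender_coef = model.coefficients["gender_coef"].to_numpy()
    use = model.coefficients["converged"].to_numpy().astype(float)
    adjust = np.outer(X[:, 1], age_coef * use) + np.outer(X[:, 2], gender_coef * use)
    adjust[~complete] = 0.0
    values = pd.DataFrame(ds.values.to_numpy(dtype=float) - adjust,
                          index=ds.values.index, columns=ds.values.columns)
    return replace(ds, values=values, transform_state=TransformState.CORRECTED)


def correct_age_gender(ds: ExpressionDataset) -> tuple[ExpressionDataset, CorrectionModel]:
    """Convenience: fit and apply the covariate correction in one call."""
    model = fit_robust_correction(ds)
    return apply_correction(ds, model), model
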