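"""Local surrogate explanations (LIME-style) for a fitted grader.

For one case, features are perturbed independently around the training
distribution in standardized space, each perturbation is weighted by an RBF
proximity kernel, and a sparse weighted ridge surrogate is fitted to the
black-box class probability.  The signed surrogate coefficients are the
per-feature contributions to that grade's probability near the case.

Divergences from canonical LIME, chosen for determinism: feature screening
uses the largest absolute weighted correlation with the target probability
(not a LASSO path), and the surrogate is a weighted ridge regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

logger = logging.getLogger(__name__)

DEFAULT_N_SAMPLES = 5000
DEFAULT_TOP_K = 8
DEFAULT_RIDGE_PENALTY = 1.0


@dataclass
class ExplanationReport:
    """Signed per-feature contributions to one grade's probability for one case."""

    case_id: str
    explained_class: str
    contributions: dict[str, float]     # feature -> signed value, |.| descending
    intercept: float
    weighted_r2: float
    n_samples: int
    seed: int
    predicted_proba: dict[str, float] = field(default_factory=dict)
    slopes: dict[str, float] = field(default_factory=dict)  # raw surrogate coefficients

    def top_features(self, k: int | None = None) -> list[tuple[str, float]]:
        items = list(self.contributions.items())
        return items[:k] if k is not None else items


def kernel_width(n_features: int) -> float:
    """Classic proximity-kernel width: 0.75 * sqrt(p) in standardized space."""
    return 0.75 * math.sqrt(n_features)


def sample_perturbations(case_std: np.ndarray, n: int, seed: int = 0,
                         sigma: float | None = None,
                         fixed_mask: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` standardized perturbations around a case plus the case itself.

    Each feature is resampled independently from the training marginal — in
    standardized space, Normal(0, 1).  Row 0 is the case itself (distance 0,
    weight 1); weights are exp(-d^2 / sigma^2) with d the Euclidean distance
    from the case.  Features flagged in ``fixed_mask`` (zero training
    variance) are held at the case value.
    """
    if n < 100:
        raise ValueError("need at least 100 perturbation samples")
    case_std = np.asarray(case_std, dtype=np.float64)
    p = case_std.size
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal(size=(n, p))
    if fixed_mask is not None and fixed_mask.any():
        Z[:, fixed_mask] = case_std[fixed_mask]
    Z = np.vstack([case_std[None, :], Z])
    if sigma is None:
        sigma = kernel_width(p)
    d2 = ((Z - case_std) ** 2).sum(axis=1)
    weights = np.exp(-d2 / sigma**2)
    return Z, weights


def _weighted_corr(Z: np.ndarray, t: np.ndarray, w: np.ndarray) -> np.ndarray:
    w = w / w.sum()
    zm = Z - (w[:, None] * Z).sum(axis=0)
    tm = t - (w * t).sum()
    cov = (w[:, None] * zm * tm[:, None]).sum(axis=0)
    vz = (w[:, None] * zm**2).sum(axis=0)
    vt = (w * tm**2).sum()
    denom = np.sqrt(vz * vt)
    out = np.zeros_like(cov)
    ok = denom > 0
    out[ok] = cov[ok] / denom[ok]
    return out


def fit_local_surrogate(samples: np.ndarray, weights: np.ndarray,
                        target: np.ndarray, feature_names: list[str],
                        K: int = DEFAULT_TOP_K,
                        ridge_penalty: float = DEFAULT_RIDGE_PENALTY,
                        case_id: str = "", explained_class: str = "",
                        seed: int = 0) -> ExplanationReport:
    """Weighted sparse linear surrogate of the target-class probability.

    Screens to the ``K`` features with the largest absolute weighted
    correlation with the target, then fits a weighted ridge regression on the
    screened standardized features.  Coefficients are the signed
    contributions.
    """
    Z = np.asarray(samples, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    K = min(K, Z.shape[1])
    corr = _weighted_corr(Z, t, w)
    screened = np.argsort(-np.abs(corr), kind="stable")[:K]

    penalty = ridge_penalty
    for attempt in range(2):
        try:
            model = Ridge(alpha=penalty)
            model.fit(Z[:, screened], t, sample_weight=w)
            break
        except np.linalg.LinAlgError:
            if attempt == 1:
                raise
            penalty *= 10.0
            logger.warning("singular surrogate design; retrying with ridge "
                           "penalty %.3g", penalty)

    pred = model.predict(Z[:, screened])
    wsum = w.sum()
    tbar = (w * t).sum() / wsum
    ss_res = (w * (t - pred) ** 2).sum()
    ss_tot = (w * (t - tbar) ** 2).sum()
    r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 1.0

    contribs = {feature_names[idx]: float(coef)
                for idx, coef in zip(screened, model.coef_)}
    contribs = dict(sorted(contribs.items(), key=lambda kv: -abs(kv[1])))
    return ExplanationReport(
        case_id=case_id, explained_class=str(explained_class),
        contributions=contribs, intercept=float(model.intercept_),
        weighted_r2=r2, n_samples=Z.shape[0] - 1, seed=seed,
    )


def explain_case(case_id: str, fitted_model, table: pd.DataFrame,
                 feature_columns: list[str], n_samples: int = DEFAULT_N_SAMPLES,
                 top_k: int = DEFAULT_TOP_K, seed: int = 0,
                 ridge_penalty: float = DEFAULT_RIDGE_PENALTY,
                 label_column: str = "grade") -> dict[str, ExplanationReport]:
    """One explanation report per grade for one case of a feature table.

    ``fitted_model`` must expose ``predict_proba`` on raw feature rows (e.g.
    a tuned SVM pipeline); ``table`` supplies the training statistics used
    for standardization, which must come from training rows only.

    Per-case contributions are the surrogate coefficient times the case's
    standardized deviation from the training mean, so the sign answers "did
    this case's value of the feature push the probability of this grade up
    or down" (a low Ki-67 supports grade II with a positive bar even though
    the probability *slope* in Ki-67 is negative).  The raw local slopes are
    kept in ``slopes``.
    """
    rows = table.loc[table["case_id"] == case_id]
    if rows.empty:
        raise KeyError(f"unknown case_id {case_id!r}")
    x_case = rows.iloc[0][feature_columns].to_numpy(dtype=np.float64)

    mean = table[feature_columns].mean().to_numpy(dtype=np.float64)
    sd = table[feature_columns].std(ddof=0).to_numpy(dtype=np.float64)
    fixed = sd == 0
    if fixed.any():
        names = [feature_columns[i] for i in np.flatnonzero(fixed)]
        logger.warning("zero-variance features held fixed at case value: %s", names)
    safe_sd = np.where(fixed, 1.0, sd)
    case_std = (x_case - mean) / safe_sd

    Z, weights = sample_perturbations(case_std, n_samples, seed=seed, fixed_mask=fixed)
    X_raw = pd.DataFrame(Z * safe_sd + mean, columns=feature_columns)
    proba = fitted_model.predict_proba(X_raw)
    model_classes = (fitted_model.best_estimator_ if hasattr(fitted_model, "best_estimator_")
                     else fitted_model).classes_
    case_proba = {str(c): float(p) for c, p in zip(model_classes, proba[0])}

    std_by_name = dict(zip(feature_columns, case_std))
    reports: dict[str, ExplanationReport] = {}
    for ci, cls in enumerate(model_classes):
        rep = fit_local_surrogate(Z, weights, proba[:, ci], list(feature_columns),
                                  K=top_k, ridge_penalty=ridge_penalty,
                                  case_id=case_id, explained_class=str(cls), seed=seed)
        rep.predicted_proba = case_proba
        rep.slopes = dict(rep.contributions)
        contribs = {name: coef * std_by_name[name]
                    for name, coef in rep.slopes.items()}
        rep.contributions = dict(sorted(contribs.items(), key=lambda kv: -abs(kv[1])))
        reports[str(cls)] = rep
    return reports
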