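"""Feature scaling and logistic-regression association.

Each omic feature is scaled to mean 0 / sample SD 1 over its non-missing
entries, then its association with binary cancer-class membership (class
members vs the background set only) is estimated by maximum-likelihood
logistic regression. The coefficient of the scaled feature is the log odds
ratio per feature SD. GWAS classes are additionally adjusted for the
(scaled) genotyping probe count to control coverage confounding.

Fits use Newton/IRLS (statsmodels), tolerance 1e-8, at most 100 iterations.
Complete separation is flagged, the coefficient reported as NaN, and the
result excluded from score weighting downstream. Missing feature values are
dropped per fit (complete case per feature); imputation happens only at
scoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

from .features import FeatureMatrix, ValidationError

__all__ = [
    "AssociationResult",
    "FitDiagnostics",
    "GWAS_CLASSES",
    "scale_features",
    "fit_univariate",
    "fit_association_matrix",
    "fit_multivariate",
    "condition_number",
]

logger = logging.getLogger(__name__)

GWAS_CLASSES = ("gwas_single", "gwas_pleiotropic")

_SEPARATION_BETA = 25.0  # |beta| beyond this on scaled data => separation


@dataclass
class AssociationResult:
    feature: str
    class_name: str
    beta: float
    se: float
    p: float
    n_cases: int
    n_controls: int
    adjusted_for: tuple[str, ...] = ()
    separation: bool = False
    converged: bool = True


@dataclass
class FitDiagnostics:
    converged: bool
    separation_detected: bool
    n_iterations: int
    condition_number: float


def scale_features(matrix: FeatureMatrix) -> FeatureMatrix:
    """Scale each column to mean 0 / sample SD 1 over non-missing entries.

    Missing cells stay missing. Constant columns become all-zero and are
    recorded in ``constant_features`` (with a logged warning); an
    all-missing column is an error. Idempotent on already-scaled data.
    """
    values = matrix.values.copy()
    constant: list[str] = []
    for col in values.columns:
        x = values[col]
        if x.isna().all():
            raise ValidationError(f"feature {col!r} is entirely missing; cannot scale")
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            logger.warning("feature %r is constant; scaled to all-zero", col)
            values[col] = np.where(x.isna(), np.nan, 0.0)
            constant.append(col)
        else:
            values[col] = (x - x.mean()) / sd
    return FeatureMatrix(values=values, scaled=True, constant_features=tuple(constant))


def _logit_fit(y: np.ndarray, X: np.ndarray):
    """Newton ML fit; returns (result_or_None, separation_flag)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return None, True
    if np.any(np.abs(res.params) > _SEPARATION_BETA):
        return res, True
    return res, False


def fit_univariate(
    y: pd.Series | np.ndarray,
    x: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    feature: str = "x",
    class_name: str = "class",
) -> AssociationResult:
    """Logistic fit of y on intercept + x (+ covariates).

    Rows with a missing ``x`` (or covariate) are dropped for this fit.
    ``y`` must carry both levels after dropping; complete separation yields
    a flagged result with a NaN coefficient.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    keep = ~np.isnan(x)
    if cov is not None:
        keep &= ~np.isnan(cov).any(axis=1)
    y_, x_ = y[keep], x[keep]
    n_cases, n_controls = int(y_.sum()), int((1 - y_).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValidationError(f"outcome for {class_name!r} has a single level")

    X = np.column_stack([np.ones_like(x_), x_] + ([cov[keep]] if cov is not None else []))
    res, separated = _logit_fit(y_, X)
    adjusted = tuple(covariates.columns) if isinstance(covariates, pd.DataFrame) else (
        ("covariate",) if covariates is not None else ()
    )
    if res is None or separated:
        if res is not None:
            logger.warning("separation detected for %s ~ %s", class_name, feature)
        return AssociationResult(
            feature=feature, class_name=class_name, beta=float("nan"),
            se=float("nan"), p=float("nan"), n_cases=n_cases,
            n_controls=n_controls, adjusted_for=adjusted,
            separation=True, converged=False,
        )
    return AssociationResult(
        feature=feature, class_name=class_name,
        beta=float(res.params[1]), se=float(res.bse[1]), p=float(res.pvalues[1]),
        n_cases=n_cases, n_controls=n_controls, adjusted_for=adjusted,
        separation=False, converged=bool(res.mle_retvals.get("converged", True)),
    )


def fit_association_matrix(
    matrix: FeatureMatrix,
    class_assignment: pd.DataFrame,
    probe_counts: pd.Series | None = None,
    gwas_classes: tuple[str, ...] = GWAS_CLASSES,
) -> pd.DataFrame:
    """Univariate association of every feature with every cancer class.

    For each class, cases are its members and controls are the background
    set only (other cancer classes excluded from the fit). Classes named in
    ``gwas_classes`` are adjusted for the scaled probe count. Classes with
    fewer than 2 members are skipped with a warning.

    Returns a tidy DataFrame (feature, class, beta, se, p, n_cases,
    n_controls, adjusted_for, separation).
    """
    if not matrix.scaled:
        raise ValidationError("association requires a scaled feature matrix")
    by_class = class_assignment.groupby("class")["gene_id"].apply(set).to_dict()
    background = by_class.get("background", set())
    if not background:
        raise ValidationError("no background genes in class assignment")

    probe_scaled = None
    if probe_counts is not None:
        pc = probe_counts.reindex(matrix.gene_ids).astype(float)
        probe_scaled = (pc - pc.mean()) / pc.std(ddof=1)

    rows = []
    for cls in sorted(c for c in by_class if c != "background"):
        members = by_class[cls] & set(matrix.gene_ids)
        if len(members) < 2:
            logger.warning("class %r has <2 members; skipped", cls)
            continue
        fit_ids = sorted(members) + sorted(background & set(matrix.gene_ids))
        sub = matrix.values.loc[fit_ids]
        y = pd.Series(
            np.concatenate([np.ones(len(members)), np.zeros(len(fit_ids) - len(members))]),
            index=fit_ids,
        )
        cov = None
        if cls in gwas_classes and probe_scaled is not None:
            cov = probe_scaled.loc[fit_ids].to_frame("probe_n")
        for feat in matrix.feature_names:
            r = fit_univariate(y, sub[feat], covariates=cov,
                               feature=feat, class_name=cls)
            rows.append(r)
    return pd.DataFrame(
        {
            "feature": [r.feature for r in rows],
            "class": [r.class_name for r in rows],
            "beta": [r.beta for r in rows],
            "se": [r.se for r in rows],
            "p": [r.p for r in rows],
            "n_cases": [r.n_cases for r in rows],
            "n_controls": [r.n_controls for r in rows],
            "adjusted_for": [",".join(r.adjusted_for) for r in rows],
            "separation": [r.separation for r in rows],
        }
    )


def condition_number(X: np.ndarray | pd.DataFrame) -> float:
    """Ratio of the largest to the smallest singular value."""
    s = np.linalg.svd(np.asarray(X, dtype=float), compute_uv=False)
    if s[-1] == 0.0:
        return float("inf")
    return float(s[0] / s[-1])


def fit_multivariate(
    matrix: FeatureMatrix,
    class_assignment: pd.DataFrame,
    class_name: str,
) -> tuple[pd.Series, FitDiagnostics]:
    """Joint logistic fit of one class on all features simultaneously.

    Expects a complete (scaled, imputed) matrix; cases vs background only.
    Raises on rank deficiency, naming the offending columns. Returns the
    coefficient vector (indexed by feature, intercept dropped) and fit
    diagnostics including the condition number of the genes x features
    matrix used in the fit.
    """
    if matrix.values.isna().any().any():
        raise ValidationError("multivariate fit requires a complete matrix; impute first")
    by_class = class_assignment.groupby("class")["gene_id"].apply(set).to_dict()
    members = by_class.get(class_name, set()) & set(matrix.gene_ids)
    background = by_class.get("background", set()) & set(matrix.gene_ids)
    if len(members) < 2:
        raise ValidationError(f"class {class_name!r} has <2 members")
    fit_ids = sorted(members) + sorted(background)
    Xdf = matrix.values.loc[fit_ids]
    y = np.concatenate([np.ones(len(members)), np.zeros(len(background))])

    s = np.linalg.svd(Xdf.to_numpy(), compute_uv=False)
    if s[-1] < 1e-10 * s[0]:
        _, _, vt = np.linalg.svd(Xdf.to_numpy())
        null_vec = np.abs(vt[-1])
        offenders = list(Xdf.columns[null_vec > 0.3])
        raise ValidationError(f"rank-deficient design; offending columns: {offenders}")
    cond = float(s[0] / s[-1])

    X = sm.add_constant(Xdf.to_numpy(), prepend=True)
    res, separated = _logit_fit(y, X)
    if res is None:
        raise ValidationError(f"multivariate fit for {class_name!r} failed (separation)")
    coefs = pd.Series(res.params[1:], index=Xdf.columns, name=class_name)
    diag = FitDiagnostics(
        converged=bool(res.mle_retvals.get("converged", True)),
        separation_detected=separated,
        n_iterations=int(res.mle_retvals.get("iterations", 0)),
        condition_number=cond,
    )
    return coefs, diag
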