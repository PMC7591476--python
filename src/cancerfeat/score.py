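"""Cancer feature scores, Nagelkerke pseudo-R² and score correlations.

The score of a gene for a class is the weighted sum Score = Σ_i β_i x_i,
where x_i is the gene's scaled value of feature i and β_i the class's log
odds ratio for that feature. Missing feature values are imputed to the
feature's median (over the full gene universe) before scoring, so every
gene receives a finite score. Discrimination is summarized by Nagelkerke's
pseudo-R² of the logistic fit of class membership on the score:

    R²_CS = 1 - exp((2/n) (ll₀ - ll₁)),   R²_N = R²_CS / (1 - exp((2/n) ll₀))

with ll₀ the intercept-only and ll₁ the fitted log-likelihood. When the
score separates the classes perfectly, ll₁ is taken at its saturated limit
(0), giving R²_N = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import _logit_fit
from .features import FeatureMatrix, ValidationError

__all__ = [
    "ScoreEvaluation",
    "impute_median",
    "compute_scores",
    "nagelkerke_r2",
    "score_correlations",
    "compare_weighting_schemes",
]

logger = logging.getLogger(__name__)


@dataclass
class ScoreEvaluation:
    class_name: str
    nagelkerke_r2: float
    loglik_null: float
    loglik_model: float
    n: int
    converged: bool = True


def impute_median(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace every missing cell by its feature's median over non-missing
    values (across the whole gene universe, cases and controls alike).

    Even counts take the mean of the two middle order statistics. Non-
    missing cells are never altered.
    """
    values = matrix.values.copy()
    medians = values.median()
    values = values.fillna(medians)
    return FeatureMatrix(values=values, scaled=matrix.scaled,
                         constant_features=matrix.constant_features)


def compute_scores(matrix: FeatureMatrix, weights: pd.DataFrame) -> pd.DataFrame:
    """Per-gene scores for each class: score = Σ beta(feature, class) * x.

    ``weights`` is the tidy association table (feature, class, beta,
    [separation]). Separation-flagged or non-finite betas contribute zero
    weight, with a warning. A weight for a feature absent from the matrix
    is an error. Returns genes x classes.
    """
    if matrix.values.isna().any().any():
        raise ValidationError("score computation requires a complete matrix; impute first")
    missing = set(weights["feature"]) - set(matrix.feature_names)
    if missing:
        raise ValidationError(f"weights refer to features absent from the matrix: {sorted(missing)}")

    w = weights.copy()
    bad = ~np.isfinite(w["beta"])
    if "separation" in w.columns:
        bad |= w["separation"].astype(bool)
    if bad.any():
        logger.warning("%d degenerate betas contribute zero weight", int(bad.sum()))
        w.loc[bad, "beta"] = 0.0
    beta_mat = (
        w.pivot_table(index="feature", columns="class", values="beta", aggfunc="first")
        .reindex(matrix.feature_names)
        .fillna(0.0)
    )
    scores = matrix.values.to_numpy() @ beta_mat.to_numpy()
    return pd.DataFrame(scores, index=matrix.gene_ids, columns=beta_mat.columns)


def nagelkerke_r2(y: pd.Series | np.ndarray, score: pd.Series | np.ndarray,
                  class_name: str = "class") -> ScoreEvaluation:
    """Nagelkerke pseudo-R² of the logistic fit y ~ intercept + score."""
    y = np.asarray(y, dtype=float)
    s = np.asarray(score, dtype=float)
    n = len(y)
    n1 = y.sum()
    if n1 == 0 or n1 == n:
        raise ValidationError("outcome has a single level")
    p0 = n1 / n
    ll0 = n1 * np.log(p0) + (n - n1) * np.log(1 - p0)

    if np.std(s) == 0.0:
        logger.warning("constant score for %s; R² = 0", class_name)
        return ScoreEvaluation(class_name, 0.0, float(ll0), float(ll0), n)

    X = np.column_stack([np.ones(n), s])
    res, separated = _logit_fit(y, X)
    if res is None or separated:
        ll1, converged = 0.0, False  # saturated-likelihood limit
    else:
        ll1, converged = float(res.llf), bool(res.mle_retvals.get("converged", True))
    ll1 = min(ll1, 0.0)
    r2_cs = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    denom = 1.0 - np.exp((2.0 / n) * ll0)
    r2 = float(np.clip(r2_cs / denom, 0.0, 1.0)) if denom > 0 else 0.0
    return ScoreEvaluation(class_name, r2, float(ll0), ll1, n, converged)


def score_correlations(scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of class score columns over the gene universe.

    Zero-variance columns yield missing correlations for their pairs; the
    diagonal is 1 where defined.
    """
    if scores.shape[1] < 2:
        raise ValidationError("need at least 2 score columns")
    return scores.corr(method="pearson")


def compare_weighting_schemes(
    matrix: FeatureMatrix,
    class_assignment: pd.DataFrame,
    class_name: str,
    probe_counts: pd.Series | None = None,
) -> dict[str, float]:
    """In-sample comparison of univariate vs multivariate score weights.

    Computes both scores for ``class_name`` (class vs background),
    evaluates each by Nagelkerke R², and reports the squared Pearson
    correlation between the two score vectors.
    """
    from .assoc import fit_association_matrix, fit_multivariate

    complete = impute_median(matrix)
    assoc = fit_association_matrix(complete, class_assignment,
                                   probe_counts=probe_counts)
    assoc_cls = assoc[assoc["class"] == class_name]
    score_uni = compute_scores(complete, assoc_cls)[class_name]
    coefs, _ = fit_multivariate(complete, class_assignment, class_name)
    score_multi = complete.values @ coefs

    by_class = class_assignment.groupby("class")["gene_id"].apply(set).to_dict()
    members = by_class.get(class_name, set()) & set(complete.gene_ids)
    background = by_class.get("background", set()) & set(complete.gene_ids)
    fit_ids = sorted(members) + sorted(background)
    y = np.concatenate([np.ones(len(members)), np.zeros(len(background))])

    r2_uni = nagelkerke_r2(y, score_uni.loc[fit_ids], class_name).nagelkerke_r2
    r2_multi = nagelkerke_r2(y, score_multi.loc[fit_ids], class_name).nagelkerke_r2
    corr = float(np.corrcoef(score_uni.to_numpy(), score_multi.to_numpy())[0, 1])
    return {
        "r2_univariate_weights": r2_uni,
        "r2_multivariate_weights": r2_multi,
        "score_correlation_r2": corr**2,
    }
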