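"""Collinearity screening, candidate-set OLS fits, and AICc averaging.

Postfire attendance trends (the per-lek postfire slopes) are regressed on
standardized habitat covariates — vegetation height, cheatgrass fraction
and elevation, each measured at 0.8, 6.4 and 18 km — with ordinary least
squares.  The candidate set assigns each habitat variable one of
{absent, 0.8 km, 6.4 km, 18 km}, excluding the intercept-only model, i.e.
(s+1)^v - 1 = 63 models for three variables at three scales.  Models are
ranked by AICc and coefficients are averaged with Akaike weights; by
default the "full" average substitutes 0 (with zero variance) for a
coefficient in models that omit it, shrinking weakly supported terms
toward zero.

Screening follows standard practice: Spearman rank correlations between
all predictor pairs and variance inflation factors from the full model,
with |r| < 0.5 and VIF <= 3 as the retention rules.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreeningReport",
    "CandidateModel",
    "ModelAverageResult",
    "screen_collinearity",
    "standardize",
    "enumerate_candidates",
    "fit_ols_aicc",
    "akaike_weights",
    "model_average",
    "run_model_selection",
]

logger = logging.getLogger(__name__)

SPEARMAN_MAX = 0.5
VIF_MAX = 3.0
Z_95 = 1.959964  # normal 97.5% quantile; CIs are estimate +/- 1.96*SE


@dataclass
class ScreeningReport:
    predictors: list[str]
    spearman: pd.DataFrame  # symmetric, unit diagonal
    vif: pd.Series
    retained: list[str]
    dropped: dict[str, str]  # predictor -> reason


@dataclass
class CandidateModel:
    """One candidate OLS model: a term subset plus its fit summaries."""

    terms: tuple[str, ...]
    k: int = 0  # intercept + slopes + residual variance
    loglik: float = math.nan
    aicc: float = math.nan
    weight: float = math.nan
    coef: dict[str, float] = field(default_factory=dict)  # incl. 'intercept'
    coef_se: dict[str, float] = field(default_factory=dict)
    rss: float = math.nan


@dataclass
class ModelAverageResult:
    table: pd.DataFrame  # index = predictors; estimate, se, lower, upper, p
    n_models: int
    mode: str  # 'full' or 'conditional'


def screen_collinearity(covariates: pd.DataFrame) -> ScreeningReport:
    """Spearman/VIF screen of a numeric predictor table.

    VIF_j = 1/(1 - R^2_j) from regressing predictor j on all others (with
    intercept); a perfectly collinear predictor reports +inf.  Predictors
    are dropped greedily — highest VIF first, then the higher-VIF member of
    any remaining pair with |rho| >= 0.5 — until the retained set satisfies
    both rules.  Nothing is dropped silently: every removal is reported
    with its reason.
    """
    cols = list(covariates.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 predictors to screen")
    X = covariates.to_numpy(dtype=float)
    if np.any(np.nanstd(X, axis=0) == 0):
        raise ValueError("constant predictor column")

    rho = stats.spearmanr(X).statistic
    rho = np.atleast_2d(rho)
    spearman = pd.DataFrame(rho, index=cols, columns=cols)

    def vif_of(active: list[str]) -> pd.Series:
        A = covariates[active].to_numpy(dtype=float)
        out = {}
        n = A.shape[0]
        for j, name in enumerate(active):
            yj = A[:, j]
            others = np.delete(A, j, axis=1)
            D = np.column_stack([np.ones(n), others])
            coef, *_ = np.linalg.lstsq(D, yj, rcond=None)
            resid = yj - D @ coef
            tss = float(np.sum((yj - yj.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
            out[name] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return pd.Series(out)

    retained = list(cols)
    dropped: dict[str, str] = {}
    while True:
        v = vif_of(retained)
        worst = v.idxmax()
        if len(retained) > 2 and v[worst] > VIF_MAX:
            dropped[worst] = f"VIF {v[worst]:.3g} > {VIF_MAX}"
            retained.remove(worst)
            continue
        sub = spearman.loc[retained, retained].to_numpy()
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(sub)), sub.shape)
        if abs(sub[i, j]) >= SPEARMAN_MAX:
            a, b = retained[i], retained[j]
            loser = a if v[a] >= v[b] else b
            dropped[loser] = f"|spearman| {abs(sub[i, j]):.3g} >= {SPEARMAN_MAX} with partner"
            retained.remove(loser)
            if len(retained) < 2:
                break
            continue
        break
    for name, why in dropped.items():
        logger.info("screening dropped %s: %s", name, why)
    return ScreeningReport(cols, spearman, vif_of(cols), retained, dropped)


def standardize(covariates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center to mean 0 and scale to SD 1 (sample SD, ddof=1) per column."""
    mean = covariates.mean()
    sd = covariates.std(ddof=1)
    if np.any(sd <= 0):
        bad = sd.index[sd <= 0].tolist()
        raise ValueError(f"zero-variance columns cannot be standardized: {bad}")
    return (covariates - mean) / sd, pd.DataFrame({"mean": mean, "sd": sd})


def enumerate_candidates(
    variables: list[str] | int = 3, scales: list[str] | int = 3
) -> list[tuple[str, ...]]:
    """All term subsets with at most one scale per variable, minus the null.

    Each variable independently takes one of {absent, scale_1..scale_s};
    the all-absent (intercept-only) model is excluded, giving
    (s+1)^v - 1 subsets.  Term names are '<variable>_<scale>'.
    """
    if isinstance(variables, int):
        variables = [f"var{i + 1}" for i in range(variables)]
    if isinstance(scales, int):
        scales = [f"s{i + 1}" for i in range(scales)]
    if len(variables) < 1 or len(scales) < 1:
        raise ValueError("need at least one variable and one scale")
    choices = [(None, *scales)] * len(variables)
    out = []
    for combo in itertools.product(*choices):
        terms = tuple(
            f"{v}_{s}" for v, s in zip(variables, combo) if s is not None
        )
        if terms:
            out.append(terms)
    return out


def fit_ols_aicc(response: np.ndarray, X: pd.DataFrame, terms: tuple[str, ...]) -> CandidateModel:
    """OLS fit of one candidate model plus its AICc.

    The fit uses a QR-based least-squares solve.  The Gaussian log
    likelihood uses the ML variance RSS/n, and k counts the intercept, the
    slopes, and the residual variance, so AICc = -2 logL + 2k +
    2k(k+1)/(n-k-1).  Models with n <= k+1 are rejected (the correction
    term's denominator is nonpositive).
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    k = len(terms) + 2
    if n <= k + 1:
        raise ValueError(f"n={n} too small for k={k} (AICc undefined)")
    D = np.column_stack([np.ones(n)] + [X[t].to_numpy(dtype=float) for t in terms])
    coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    aicc = -2.0 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    # classical OLS coefficient covariance with the unbiased variance
    p = D.shape[1]
    dof = n - p
    s2 = rss / dof if dof > 0 else math.nan
    try:
        cov = s2 * np.linalg.inv(D.T @ D)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.full(p, math.nan)
    names = ("intercept", *terms)
    return CandidateModel(
        terms=terms,
        k=k,
        loglik=loglik,
        aicc=aicc,
        coef=dict(zip(names, coef.tolist())),
        coef_se=dict(zip(names, ses.tolist())),
        rss=rss,
    )


def akaike_weights(aicc: np.ndarray) -> np.ndarray:
    """exp(-delta/2) normalized; invariant to adding a constant to AICc."""
    aicc = np.asarray(aicc, dtype=float)
    if not np.all(np.isfinite(aicc)):
        raise ValueError("non-finite AICc in candidate set")
    delta = aicc - aicc.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def model_average(
    models: list[CandidateModel], mode: str = "full"
) -> ModelAverageResult:
    """Akaike-weight averaging of coefficients across the candidate set.

    ``mode='full'`` (default): a model omitting a term contributes 0 with
    zero within-model variance at that term's slot, so weakly supported
    terms shrink toward 0.  ``mode='conditional'``: the average runs only
    over models containing the term, with weights renormalized.

    The unconditional standard error follows Burnham & Anderson:
    SE = sum_i w_i * sqrt(var_i + (beta_i - beta_bar)^2).  95% CIs are
    estimate +/- 1.96*SE and p-values come from the normal approximation.
    """
    if not models:
        raise ValueError("empty model set")
    if mode not in ("full", "conditional"):
        raise ValueError("mode must be 'full' or 'conditional'")
    w = akaike_weights(np.array([m.aicc for m in models]))
    for m, wi in zip(models, w):
        m.weight = float(wi)

    predictors: list[str] = []
    for m in models:
        for t in m.terms:
            if t not in predictors:
                predictors.append(t)

    rows = {}
    for term in predictors:
        betas = np.array([m.coef.get(term, 0.0) for m in models])
        variances = np.array([m.coef_se.get(term, 0.0) ** 2 for m in models])
        has = np.array([term in m.terms for m in models])
        if mode == "conditional":
            wc = w[has] / w[has].sum()
            est = float(np.sum(wc * betas[has]))
            se = float(np.sum(wc * np.sqrt(variances[has] + (betas[has] - est) ** 2)))
        else:
            est = float(np.sum(w * betas))
            se = float(np.sum(w * np.sqrt(variances + (betas - est) ** 2)))
        z = abs(est) / se if se > 0 else math.inf
        rows[term] = {
            "estimate": est,
            "se": se,
            "lower": est - Z_95 * se,
            "upper": est + Z_95 * se,
            "p": 2.0 * (1.0 - stats.norm.cdf(z)) if math.isfinite(z) else 0.0,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return ModelAverageResult(table=table, n_models=len(models), mode=mode)


def run_model_selection(
    post_slopes: np.ndarray,
    covariates: pd.DataFrame,
    variables: list[str],
    scales: list[str],
    *,
    mode: str = "full",
) -> tuple[pd.DataFrame, ModelAverageResult, list[CandidateModel]]:
    """Standardize, enumerate, fit and average in one call.

    ``covariates`` must hold columns named '<variable>_<scale>' for every
    variable/scale pair.  Returns the ranked model table (terms, k, AICc,
    delta, weight), the averaged coefficients, and the fitted models.
    """
    std, _ = standardize(covariates)
    term_sets = enumerate_candidates(variables, scales)
    fitted = []
    for terms in term_sets:
        try:
            fitted.append(fit_ols_aicc(post_slopes, std, terms))
        except ValueError as exc:
            # AICc is undefined when n <= k+1; drop the model, keep going
            logger.warning("skipping model %s: %s", terms, exc)
    if not fitted:
        raise ValueError("no candidate model is estimable at this sample size")
    w = akaike_weights(np.array([m.aicc for m in fitted]))
    order = np.argsort([m.aicc for m in fitted], kind="stable")
    ranked = pd.DataFrame(
        {
            "terms": [" + ".join(fitted[i].terms) for i in order],
            "k": [fitted[i].k for i in order],
            "aicc": [fitted[i].aicc for i in order],
            "delta": [fitted[i].aicc - fitted[order[0]].aicc for i in order],
            "weight": [float(w[i]) for i in order],
        }
    )
    avg = model_average(fitted, mode=mode)
    return ranked, avg, fitted
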