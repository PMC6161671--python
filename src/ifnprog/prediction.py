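"""Prognostic modelling: multiple imputation, penalised logistic regression,
cross-validated penalty selection, and Rubin's-rules pooling.

The model of interest is an L1-penalised (lasso) logistic regression of
12-month progression on baseline covariates, fitted separately in each of
``m`` multiply-imputed datasets with the penalty chosen by leave-one-out
cross-validation and the one-standard-error rule, and the per-imputation
coefficients averaged.  Unpenalised univariable and multivariable fits are
pooled across imputations with Rubin's rules.

The lasso solver is glmnet-style cyclic coordinate descent on the
iteratively-reweighted least-squares (IRLS) quadratic approximation of

    (1/n) * negative log-likelihood + lambda * sum_j |beta_j|

with an unpenalised intercept and predictors standardised internally to unit
variance (coefficients are mapped back to the original scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.imputation.mice import MICEData

PREDICTORS = [
    "age",
    "ever_smoked",
    "family_history_ard",
    "n_ana_specificities",
    "c4",
    "lymphocytes",
    "us_positive_joints",
    "patient_vas",
    "physician_vas",
    "ifn_score_a",
    "ifn_score_b",
]

_EPS = 1e-8  # probability clip for deviance


class ConvergenceError(RuntimeError):
    pass


@dataclass
class CohortTable:
    """Baseline covariates and the binary 12-month progression outcome.

    Continuous interferon scores are stored as reflected −ΔCt so that larger
    values mean greater expression and odds ratios above 1 indicate risk.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "outcome" not in self.data.columns:
            raise ValueError("cohort table must contain an 'outcome' column")
        y = self.data["outcome"]
        if y.isna().any():
            raise ValueError("outcome must be non-missing for every sample")
        if not set(y.unique()) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")
        for col in ("patient_vas", "physician_vas"):
            if col in self.data:
                v = self.data[col].dropna()
                if ((v < 0) | (v > 100)).any():
                    raise ValueError(f"{col} must lie in [0, 100] mm")
        for col in ("n_ana_specificities", "us_positive_joints"):
            if col in self.data:
                v = self.data[col].dropna()
                if (v < 0).any():
                    raise ValueError(f"{col} must be non-negative")

    @property
    def predictors(self) -> list[str]:
        return [c for c in PREDICTORS if c in self.data.columns]


@dataclass
class ImputationSet:
    """``m`` completed copies of a cohort table (observed cells identical)."""

    m: int
    completed: list[pd.DataFrame]
    seeds: list[int]
    methods: dict[str, str] = field(default_factory=dict)


@dataclass
class LassoFit:
    """A lasso path fit (optionally with LOOCV deviance curves)."""

    feature_names: list[str]
    lambda_path: np.ndarray
    coef: np.ndarray  # (n_lambda, p) on the ORIGINAL predictor scale
    intercept: np.ndarray  # (n_lambda,)
    coef_std: np.ndarray  # per-SD (standardised) coefficients
    cv_deviance: np.ndarray | None = None
    cv_se: np.ndarray | None = None
    lambda_min: float | None = None
    lambda_1se: float | None = None

    def coef_at(self, lam: float) -> tuple[np.ndarray, float]:
        idx = int(np.argmin(np.abs(self.lambda_path - lam)))
        return self.coef[idx], float(self.intercept[idx])


@dataclass
class MIPooledFit:
    """Rubin's-rules pooled estimates across imputations."""

    names: list[str]
    estimate: np.ndarray  # pooled log-odds
    within_var: np.ndarray
    between_var: np.ndarray
    total_var: np.ndarray
    df: np.ndarray
    m: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.total_var)

    @property
    def odds_ratio(self) -> np.ndarray:
        return np.exp(self.estimate)

    def conf_int(self, conf: float = 0.95) -> np.ndarray:
        t = stats.t.ppf(0.5 + conf / 2, self.df)
        half = t * self.se
        return np.exp(np.column_stack([self.estimate - half, self.estimate + half]))

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = self.estimate / self.se
        return 2 * stats.t.sf(np.abs(tstat), self.df)

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "estimate": self.estimate,
                "or": self.odds_ratio,
                "or_low": ci[:, 0],
                "or_high": ci[:, 1],
                "p": self.p_values,
            },
            index=self.names,
        )


# ---------------------------------------------------------------------------
# multiple imputation
# ---------------------------------------------------------------------------


def mice_impute(
    table: CohortTable, m: int = 20, cycles: int = 10, seed: int = 0
) -> ImputationSet:
    """Multiple imputation by chained equations (predictive-mean matching).

    Produces ``m`` completed datasets from independent, seed-derived streams;
    observed cells are identical across datasets and the whole procedure is
    deterministic for a fixed seed.  Variables with missing values must be at
    least 50% observed; a fully missing variable is an error.
    """
    df = table.data.copy()
    cols = [c for c in df.columns]
    frac_obs = df.notna().mean()
    if (frac_obs == 0).any():
        bad = list(frac_obs.index[frac_obs == 0])
        raise ValueError(f"variable(s) with no observed values: {bad}")
    low = frac_obs[(frac_obs < 0.5)]
    if len(low):
        raise ValueError(f"variable(s) under 50% observed: {dict(low)}")
    rng = np.random.default_rng(seed)
    seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=m)]
    if not df.isna().any().any():
        return ImputationSet(m=m, completed=[df.copy() for _ in range(m)], seeds=seeds)
    completed = []
    for sub in seeds:
        np.random.seed(sub % (2**31 - 1))  # MICEData draws from the global stream
        md = MICEData(df.astype(float))
        md.update_all(cycles)
        out = md.data.copy()
        out.index = df.index
        completed.append(out[cols])
    methods = {c: "pmm" for c in df.columns[df.isna().any()]}
    return ImputationSet(m=m, completed=completed, seeds=seeds, methods=methods)


# ---------------------------------------------------------------------------
# lasso logistic regression by coordinate descent
# ---------------------------------------------------------------------------


def _soft_threshold(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


def _cd_fit_path(
    y: np.ndarray,
    xs: np.ndarray,
    lambda_path: np.ndarray,
    tol: float = 1e-7,
    max_irls: int = 100,
    max_sweeps: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate-descent lasso logistic over a decreasing lambda path.

    ``xs`` must already be standardised.  Returns (coefs, intercepts) with
    warm starts along the path.  Weights are floored to keep the IRLS system
    well conditioned near fitted probabilities of 0 or 1.
    """
    n, p = xs.shape
    beta = np.zeros(p)
    b0 = float(np.log(y.mean() / (1 - y.mean()))) if 0 < y.mean() < 1 else 0.0
    coefs = np.empty((lambda_path.size, p))
    intercepts = np.empty(lambda_path.size)
    for li, lam in enumerate(lambda_path):
        for _ in range(max_irls):
            eta = b0 + xs @ beta
            prob = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(prob * (1 - prob), 1e-5, None)
            z = eta + (y - prob) / w
            beta_old_outer = beta.copy()
            b0_old_outer = b0
            # inner coordinate sweeps on the fixed quadratic approximation
            for _ in range(max_sweeps):
                max_delta = 0.0
                r = z - b0 - xs @ beta
                for j in range(p):
                    bj = beta[j]
                    rho = np.dot(w, xs[:, j] * (r + xs[:, j] * bj)) / n
                    denom = np.dot(w, xs[:, j] ** 2) / n
                    new = _soft_threshold(rho, lam) / denom
                    if new != bj:
                        r += xs[:, j] * (bj - new)
                        max_delta = max(max_delta, abs(new - bj))
                        beta[j] = new
                new_b0 = b0 + np.dot(w, r) / w.sum()
                max_delta = max(max_delta, abs(new_b0 - b0))
                r += b0 - new_b0
                b0 = new_b0
                if max_delta < tol:
                    break
            else:
                raise ConvergenceError(
                    f"coordinate descent did not converge at lambda={lam:g}"
                )
            if max(np.max(np.abs(beta - beta_old_outer)), abs(b0 - b0_old_outer)) < tol:
                break
        else:
            raise ConvergenceError(f"IRLS did not converge at lambda={lam:g}")
        beta[np.abs(beta) < 1e-10] = 0.0  # snap FP dust so KKT zeros are exact
        coefs[li] = beta
        intercepts[li] = b0
    return coefs, intercepts


def lambda_max(y: np.ndarray, xs: np.ndarray) -> float:
    """Smallest penalty at which every slope is exactly zero (KKT bound)."""
    n = y.size
    return float(np.max(np.abs(xs.T @ (y - y.mean()))) / n)


def default_lambda_path(y: np.ndarray, xs: np.ndarray, n_lambda: int = 100,
                        ratio: float = 1e-3) -> np.ndarray:
    lmax = lambda_max(y, xs)
    return np.geomspace(lmax, ratio * lmax, n_lambda)


def _standardise(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant predictor; cannot standardise")
    return (x - mean) / sd, mean, sd


def lasso_logistic(
    y,
    x,
    feature_names: list[str] | None = None,
    lambda_path: np.ndarray | None = None,
    tol: float = 1e-7,
) -> LassoFit:
    """Fit the full lasso-logistic path.

    ``x`` is standardised internally; returned ``coef`` is per original unit
    of each predictor, ``coef_std`` per standard deviation.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least two events and two non-events")
    xs, mean, sd = _standardise(x)
    if lambda_path is None:
        lambda_path = default_lambda_path(y, xs)
    lambda_path = np.asarray(lambda_path, dtype=float)
    coef_std, icpt_std = _cd_fit_path(y, xs, lambda_path, tol=tol)
    coef = coef_std / sd
    intercept = icpt_std - coef @ mean
    names = feature_names or [f"x{j}" for j in range(x.shape[1])]
    return LassoFit(
        feature_names=list(names),
        lambda_path=lambda_path,
        coef=coef,
        intercept=intercept,
        coef_std=coef_std,
    )


def binomial_deviance(y: np.ndarray, prob: np.ndarray) -> np.ndarray:
    p = np.clip(prob, _EPS, 1 - _EPS)
    return -2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p))


def select_lambda_loocv(
    y, x, lambda_path: np.ndarray | None = None, tol: float = 1e-6
) -> LassoFit:
    """Leave-one-out cross-validated lasso path with the one-SE rule.

    For each fold the path is refitted without that observation and the
    held-out binomial deviance recorded per lambda.  ``lambda_min`` minimises
    the mean deviance; ``lambda_1se`` is the largest penalty whose mean
    deviance is within one standard error of that minimum.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("leave-one-out CV needs n >= 10")
    xs_full, _, _ = _standardise(x)
    if lambda_path is None:
        lambda_path = default_lambda_path(y, xs_full)
    lambda_path = np.asarray(lambda_path, dtype=float)
    fit = lasso_logistic(y, x, lambda_path=lambda_path, tol=tol)
    dev = np.empty((n, lambda_path.size))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        yi, xi = y[mask], x[mask]
        if yi.sum() < 2 or (1 - yi).sum() < 2:
            # degenerate fold: predict the prevalence at every lambda
            prob = np.full(lambda_path.size, yi.mean())
        else:
            f = lasso_logistic(yi, xi, lambda_path=lambda_path, tol=tol)
            eta = f.intercept + f.coef @ x[i]
            prob = 1.0 / (1.0 + np.exp(-eta))
        dev[i] = binomial_deviance(np.full(lambda_path.size, y[i]), prob)
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(n)
    i_min = int(np.argmin(cv_mean))
    threshold = cv_mean[i_min] + cv_se[i_min]
    ok = np.flatnonzero(cv_mean <= threshold)
    i_1se = int(ok[np.argmax(lambda_path[ok])])
    fit.cv_deviance = cv_mean
    fit.cv_se = cv_se
    fit.lambda_min = float(lambda_path[i_min])
    fit.lambda_1se = float(lambda_path[i_1se])
    return fit


# ---------------------------------------------------------------------------
# unpenalised logistic with separation fallback
# ---------------------------------------------------------------------------


def _newton_logistic(
    y: np.ndarray, x: np.ndarray, ridge: float = 0.0, max_iter: int = 200,
    tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Newton–Raphson MLE (optionally with a small ridge for separation).

    ``x`` includes the intercept column. Returns (coef, covariance).
    """
    n, p = x.shape
    beta = np.zeros(p)
    pen = ridge * np.eye(p)
    pen[0, 0] = 0.0  # never penalise the intercept
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30, 30)
        prob = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(prob * (1 - prob), 1e-10, None)
        grad = x.T @ (y - prob) - pen @ beta
        hess = (x * w[:, None]).T @ x + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise ConvergenceError("Newton-Raphson did not converge")
    eta = np.clip(x @ beta, -30, 30)
    prob = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(prob * (1 - prob), 1e-10, None)
    cov = np.linalg.inv((x * w[:, None]).T @ x + pen)
    return beta, cov


def logistic_fit(y, x) -> tuple[np.ndarray, np.ndarray]:
    """Unpenalised logistic MLE with a ridge fallback under separation.

    Returns coefficients (intercept first) and their variance estimates.
    A fit is deemed separated when any |coefficient| exceeds 15 on the
    standardised scale; it is then refitted with a light ridge and a warning.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    design = np.column_stack([np.ones(y.size), x])
    try:
        beta, cov = _newton_logistic(y, design)
        if np.max(np.abs(beta[1:] * design[:, 1:].std(axis=0))) > 15:
            raise ConvergenceError("separation suspected")
    except (ConvergenceError, np.linalg.LinAlgError):
        warnings.warn("separation detected; refitting with light ridge", stacklevel=2)
        beta, cov = _newton_logistic(y, design, ridge=1e-2)
    return beta, np.diag(cov)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------


def pool_rubin(
    estimates, variances, names: list[str] | None = None,
    df_complete: float | None = None,
) -> MIPooledFit:
    """Pool per-imputation estimates by Rubin's rules.

    Total variance T = W + (1 + 1/m)·B with W the mean within-imputation
    variance and B the between-imputation variance; degrees of freedom use
    the Barnard–Rubin small-sample adjustment when ``df_complete`` is given,
    otherwise the classical (m−1)(1 + W/((1+1/m)B))².
    """
    q = np.atleast_2d(np.asarray(estimates, dtype=float))
    u = np.atleast_2d(np.asarray(variances, dtype=float))
    if q.shape != u.shape:
        raise ValueError("estimates and variances must align")
    m = q.shape[0]
    if m < 2:
        raise ValueError("pooling requires m >= 2 imputations")
    qbar = q.mean(axis=0)
    w = u.mean(axis=0)
    b = q.var(axis=0, ddof=1)
    t = w + (1 + 1 / m) * b
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1 + 1 / m) * b / w
        df_old = (m - 1) * (1 + 1 / r) ** 2
    df_old = np.where(b <= 1e-12 * np.maximum(w, 1e-300), np.inf, df_old)
    if df_complete is not None:
        lam = (1 + 1 / m) * b / t
        df_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - lam)
        df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    else:
        df = df_old
    names = names or [f"b{j}" for j in range(q.shape[1])]
    return MIPooledFit(
        names=list(names), estimate=qbar, within_var=w, between_var=b,
        total_var=t, df=df, m=m,
    )


# ---------------------------------------------------------------------------
# screening and the full prognostic model
# ---------------------------------------------------------------------------


def univariable_screen(
    imputations: ImputationSet,
    predictors: list[str],
    alpha: float = 0.10,
    outcome: str = "outcome",
) -> tuple[list[str], pd.DataFrame]:
    """Single-covariate logistic fits pooled across imputations.

    Predictors whose pooled two-sided p exceeds ``alpha`` (default 10%) are
    excluded from the multivariable set. Returns (kept predictors, table of
    pooled univariable odds ratios).
    """
    rows = {}
    n = len(imputations.completed[0])
    for pred in predictors:
        est, var = [], []
        for df in imputations.completed:
            beta, v = logistic_fit(df[outcome].to_numpy(), df[[pred]].to_numpy())
            est.append(beta[1])
            var.append(v[1])
        pooled = pool_rubin(
            np.array(est)[:, None], np.array(var)[:, None], names=[pred],
            df_complete=n - 2,
        )
        rows[pred] = pooled.to_frame().iloc[0]
    table = pd.DataFrame(rows).T
    kept = [p for p in predictors if table.loc[p, "p"] <= alpha]
    return kept, table


def multivariable_pooled(
    imputations: ImputationSet, predictors: list[str], outcome: str = "outcome"
) -> MIPooledFit:
    """Unpenalised multivariable logistic fit pooled by Rubin's rules."""
    est, var = [], []
    for df in imputations.completed:
        beta, v = logistic_fit(df[outcome].to_numpy(), df[predictors].to_numpy())
        est.append(beta[1:])
        var.append(v[1:])
    n = len(imputations.completed[0])
    return pool_rubin(
        np.array(est), np.array(var), names=list(predictors),
        df_complete=n - len(predictors) - 1,
    )


def penalised_pooled(
    imputations: ImputationSet,
    predictors: list[str],
    outcome: str = "outcome",
    n_lambda: int = 100,
) -> pd.DataFrame:
    """Average the lasso coefficients selected by LOOCV + 1-SE in each imputation.

    Within every completed dataset the penalty is chosen by leave-one-out
    cross-validation with the one-standard-error rule; the per-imputation
    coefficients (original predictor scale) are averaged and reported
    alongside the corresponding odds ratio exp(coefficient).
    """
    coefs = []
    for df in imputations.completed:
        y = df[outcome].to_numpy(dtype=float)
        x = df[predictors].to_numpy(dtype=float)
        xs, _, _ = _standardise(x)
        path = default_lambda_path(y, xs, n_lambda=n_lambda)
        fit = select_lambda_loocv(y, x, lambda_path=path)
        beta, _ = fit.coef_at(fit.lambda_1se)
        coefs.append(beta)
    coefs = np.array(coefs)
    mean_coef = coefs.mean(axis=0)
    return pd.DataFrame(
        {
            "coefficient": mean_coef,
            "or": np.exp(mean_coef),
            "coef_min": coefs.min(axis=0),
            "coef_max": coefs.max(axis=0),
            "selected_fraction": (coefs != 0).mean(axis=0),
        },
        index=predictors,
    )
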