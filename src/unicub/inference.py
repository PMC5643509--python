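"""Mixed-effects models, simulation-based posteriors and variance shares.

Four preset attendance models (daily, hourly and their sex-specific
variants) are Gaussian linear mixed models fitted by maximum likelihood
with crossed variance components; the nest-success model is a
binomial-logit mixed model with a species random intercept, fitted by
adaptive Gauss-Hermite quadrature.  Posterior summaries draw from a
normal approximation around the ML fit (flat prior) and report medians
with 2.5/97.5 percentile credible intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import statsmodels.api as sm
from scipy.special import log_expit, logsumexp, roots_hermite
from scipy.stats import pearsonr, spearmanr

from unicub.data_model import TYPE_BIPARENTAL


class DegenerateDesignError(ValueError):
    """Raised when a grouping factor has fewer than two levels."""


@dataclass
class ModelSpec:
    """Declarative description of one mixed model.

    ``vc_intercepts`` name columns whose levels get crossed random
    intercepts; ``vc_slopes`` are ``(group_column, slope_column)`` pairs
    giving each group level its own random slope on the term.
    """

    response: str
    fixed: str
    vc_intercepts: tuple[str, ...] = ()
    vc_slopes: tuple[tuple[str, str], ...] = ()
    family: str = "gaussian"  # gaussian | binomial
    label: str = ""


@dataclass
class FitResult:
    """Point estimates, covariance and variance components of one fit."""

    label: str
    family: str
    params: pd.Series
    cov: pd.DataFrame
    vcomp: dict[str, float]
    resid_var: Optional[float]
    n_obs: int
    converged: bool
    notes: list[str] = field(default_factory=list)

    @property
    def flagged(self) -> bool:
        return bool(self.notes) or not self.converged


@dataclass
class PosteriorSummary:
    """Median and 95% credible interval per model term."""

    table: pd.DataFrame  # term, median, ci_low, ci_high
    n_draws: int
    seed: int


def add_composite_factors(records: pd.DataFrame) -> pd.DataFrame:
    """Add the nest x type and species x type crossed grouping columns.

    The two-level type factor collapses both uniparental labels, matching
    the random-effects structure of the attendance models.
    """
    out = records.copy()
    type2 = np.where(out["incubation_type"] == TYPE_BIPARENTAL, "bi", "uni")
    out["type2"] = type2
    out["nest_type"] = out["nest_id"].astype(str) + "|" + type2
    out["species_type"] = out["species"].astype(str) + "|" + type2
    return out


def daily_attendance_spec() -> ModelSpec:
    return ModelSpec(
        response="attendance_pct",
        fixed="day_fraction_pct * C(incubation_type)",
        vc_intercepts=("nest_type", "species_type"),
        vc_slopes=(("nest_id", "day_fraction_pct"),),
        label="daily",
    )


def hourly_attendance_spec() -> ModelSpec:
    return ModelSpec(
        response="attendance_pct",
        fixed="(sine + cosine) * C(incubation_type)",
        vc_intercepts=("nest_type", "species_type"),
        vc_slopes=(("nest_id", "sine"), ("nest_id", "cosine")),
        label="hourly",
    )


def sex_daily_spec() -> ModelSpec:
    return ModelSpec(
        response="attendance_pct",
        fixed="day_fraction_pct * C(sex)",
        vc_intercepts=("nest_id", "species"),
        vc_slopes=(("nest_id", "day_fraction_pct"),),
        label="sex-daily",
    )


def sex_hourly_spec() -> ModelSpec:
    return ModelSpec(
        response="attendance_pct",
        fixed="(sine + cosine) * C(sex)",
        vc_intercepts=("nest_id", "species"),
        vc_slopes=(("nest_id", "sine"), ("nest_id", "cosine")),
        label="sex-hourly",
    )


def success_spec() -> ModelSpec:
    return ModelSpec(
        response="success",
        fixed="start_fraction_pct + duration_d + median_daily_attendance_pct",
        vc_intercepts=("species",),
        family="binomial",
        label="success",
    )


PRESETS = {
    "daily": daily_attendance_spec,
    "hourly": hourly_attendance_spec,
    "sex-daily": sex_daily_spec,
    "sex-hourly": sex_hourly_spec,
    "success": success_spec,
}


def _check_grouping(records: pd.DataFrame, spec: ModelSpec) -> None:
    cols = list(spec.vc_intercepts) + [g for g, _ in spec.vc_slopes]
    for col in cols:
        if col not in records.columns:
            raise KeyError(f"grouping column {col!r} missing from records")
        n_levels = records[col].nunique()
        if n_levels < 2:
            raise DegenerateDesignError(
                f"grouping factor {col!r} has {n_levels} level(s); "
                "mixed-model fitting needs at least two"
            )


def fit_mixed_model(records: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Maximum-likelihood fit of the mixed model described by ``spec``."""
    if spec.response not in records.columns:
        raise KeyError(f"response column {spec.response!r} missing")
    _check_grouping(records, spec)
    if spec.family == "gaussian":
        return _fit_gaussian(records, spec)
    if spec.family == "binomial":
        return _fit_binomial(records, spec)
    raise ValueError(f"unknown family {spec.family!r}")


def _fit_gaussian(records: pd.DataFrame, spec: ModelSpec) -> FitResult:
    data = records.copy().reset_index(drop=True)
    data["_group"] = 1
    vcf = {col: f"0 + C({col})" for col in spec.vc_intercepts}
    for group, term in spec.vc_slopes:
        vcf[f"{group}_x_{term}"] = f"0 + C({group}):{term}"
    model = sm.MixedLM.from_formula(
        f"{spec.response} ~ {spec.fixed}",
        groups="_group",
        re_formula="0",
        vc_formula=vcf,
        data=data,
    )
    notes: list[str] = []
    # lbfgs occasionally sticks in a spurious optimum on variance-component
    # models; try a few optimizers and keep the best likelihood
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "lbfgs", "cg"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=500)
            except Exception:
                continue
            if np.isfinite(cand.llf) and (result is None or cand.llf > result.llf + 1e-6):
                result = cand
            if result is not None and result.converged:
                break
    if result is None:
        raise RuntimeError("mixed-model optimization failed for all methods")
    converged = bool(result.converged)
    if not converged:
        notes.append("optimizer did not report convergence")
    fe = result.fe_params
    cov = result.cov_params().loc[fe.index, fe.index]
    vcomp = {name: float(v) for name, v in zip(model.exog_vc.names, result.vcomp)}
    return FitResult(
        label=spec.label,
        family="gaussian",
        params=fe,
        cov=cov,
        vcomp=vcomp,
        resid_var=float(result.scale),
        n_obs=int(model.nobs),
        converged=converged,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# binomial-logit mixed model via Gauss-Hermite quadrature


def _glmm_nll_factory(y, X, codes, n_groups, nodes, log_weights):
    sign = 2.0 * y - 1.0

    def nll(theta: np.ndarray) -> float:
        beta, log_sd = theta[:-1], theta[-1]
        sd = np.exp(log_sd)
        eta = X @ beta
        shifted = eta[:, None] + np.sqrt(2.0) * sd * nodes[None, :]
        ll_obs = log_expit(sign[:, None] * shifted)  # (n, q)
        per_group = np.zeros((n_groups, len(nodes)))
        np.add.at(per_group, codes, ll_obs)
        return -float(np.sum(logsumexp(per_group + log_weights[None, :], axis=1)))

    return nll


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    k = len(x)
    h = rel_step * (1.0 + np.abs(x))
    hess = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return hess


def _fit_binomial(records: pd.DataFrame, spec: ModelSpec, n_quad: int = 21) -> FitResult:
    if len(spec.vc_intercepts) != 1 or spec.vc_slopes:
        raise ValueError("binomial fits support exactly one random intercept factor")
    group_col = spec.vc_intercepts[0]
    data = records.reset_index(drop=True)
    y = np.asarray(data[spec.response], dtype=float)
    notes: list[str] = []

    X_df = _design_matrix(data, spec.fixed)
    X = X_df.to_numpy(dtype=float)
    names = list(X_df.columns)
    codes, n_groups = pd.factorize(data[group_col])[0], data[group_col].nunique()

    separation = _detect_separation(y, X)
    if separation:
        notes.append(
            "complete or quasi-complete separation detected; estimates from a "
            "ridge-penalized fit, interpret credible intervals with caution"
        )
        params, cov = _penalized_logit(y, X)
        return FitResult(
            label=spec.label,
            family="binomial",
            params=pd.Series(params, index=names),
            cov=pd.DataFrame(cov, index=names, columns=names),
            vcomp={group_col: 0.0},
            resid_var=None,
            n_obs=len(y),
            converged=True,
            notes=notes,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start_beta = sm.GLM(y, X, family=sm.families.Binomial()).fit().params
    nodes, weights = roots_hermite(n_quad)
    log_weights = np.log(weights) - 0.5 * np.log(np.pi)
    nll = _glmm_nll_factory(y, X, codes, n_groups, nodes, log_weights)

    x0 = np.concatenate([start_beta, [np.log(0.5)]])
    bounds = [(None, None)] * len(start_beta) + [(np.log(1e-4), np.log(50.0))]
    opt = scipy.optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    converged = bool(opt.success)
    if not converged:
        notes.append(f"GLMM optimizer: {opt.message}")

    hess = _numerical_hessian(nll, opt.x)
    k = len(names)
    try:
        cov_full = scipy.linalg.pinvh(hess)
        cov_beta = cov_full[:k, :k]
    except Exception:  # pragma: no cover - degenerate Hessian
        cov_beta = np.full((k, k), np.nan)
        notes.append("Hessian inversion failed")
    sd = float(np.exp(opt.x[-1]))
    return FitResult(
        label=spec.label,
        family="binomial",
        params=pd.Series(opt.x[:k], index=names),
        cov=pd.DataFrame(cov_beta, index=names, columns=names),
        vcomp={group_col: sd**2},
        resid_var=None,
        n_obs=len(y),
        converged=converged,
        notes=notes,
    )


def _design_matrix(data: pd.DataFrame, fixed: str) -> pd.DataFrame:
    import formulaic

    return pd.DataFrame(formulaic.model_matrix(f"1 + {fixed}", data))


def _detect_separation(y: np.ndarray, X: np.ndarray) -> bool:
    if len(np.unique(y)) < 2:
        return True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        except Exception:
            return True
    fitted = res.fittedvalues
    return bool(np.abs(res.params).max() > 30.0 or np.all((fitted < 1e-8) | (fitted > 1 - 1e-8)))


def _penalized_logit(y: np.ndarray, X: np.ndarray, alpha: float = 0.5):
    """Ridge-penalized logistic fit used when separation blocks the MLE."""
    k = X.shape[1]

    def nll(beta):
        eta = X @ beta
        sign = 2.0 * y - 1.0
        return -float(np.sum(log_expit(sign * eta))) + 0.5 * alpha * float(beta @ beta)

    opt = scipy.optimize.minimize(nll, np.zeros(k), method="L-BFGS-B")
    hess = _numerical_hessian(nll, opt.x)
    cov = scipy.linalg.pinvh(hess)
    return opt.x, cov


# ---------------------------------------------------------------------------
# posterior simulation and variance shares


def posterior_summaries(
    fit: FitResult, n_draws: int = 5000, seed: int = 0
) -> PosteriorSummary:
    """Simulate the fitted sampling distribution and summarize it.

    Draws ``n_draws`` parameter vectors from a multivariate normal centred
    on the ML estimates with the estimated covariance (flat prior) and
    reports per-term medians with 2.5/97.5 percentiles.  Deterministic
    under ``seed``.
    """
    if n_draws < 100:
        warnings.warn(f"n_draws={n_draws} is low; summaries will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    mean = fit.params.to_numpy(dtype=float)
    cov = fit.cov.to_numpy(dtype=float)
    draws = rng.multivariate_normal(mean, cov, size=n_draws, method="svd")
    med = np.median(draws, axis=0)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    table = pd.DataFrame(
        {"term": fit.params.index, "median": med, "ci_low": lo, "ci_high": hi}
    )
    return PosteriorSummary(table=table, n_draws=n_draws, seed=seed)


def variance_components(fit: FitResult) -> pd.DataFrame:
    """Percent of total variance per random component (plus residual)."""
    if fit.family != "gaussian":
        raise ValueError("variance shares are defined for gaussian fits")
    comps = dict(fit.vcomp)
    comps["residual"] = fit.resid_var if fit.resid_var is not None else 0.0
    total = sum(comps.values())
    if total <= 0:
        raise ValueError("all variance components are zero; shares undefined")
    return pd.DataFrame(
        {
            "component": list(comps),
            "variance": list(comps.values()),
            "share_pct": [100.0 * v / total for v in comps.values()],
        }
    )


def fit_success_model(
    nest_table: pd.DataFrame, n_draws: int = 5000, seed: int = 0
) -> tuple[FitResult, PosteriorSummary, dict]:
    """Fit the nest-success model and report posterior + predictor checks.

    ``nest_table`` needs one row per uniparentally incubated nest with
    columns ``success`` (0/1), ``start_fraction_pct``, ``duration_d``,
    ``median_daily_attendance_pct`` and ``species``.
    Also reports pairwise Pearson and Spearman correlations between the
    three predictors.
    """
    spec = success_spec()
    fit = fit_mixed_model(nest_table, spec)
    summary = posterior_summaries(fit, n_draws=n_draws, seed=seed)
    preds = ["start_fraction_pct", "duration_d", "median_daily_attendance_pct"]
    corr: dict[str, float] = {}
    for i in range(len(preds)):
        for j in range(i + 1, len(preds)):
            a, b = nest_table[preds[i]], nest_table[preds[j]]
            corr[f"pearson[{preds[i]},{preds[j]}]"] = float(pearsonr(a, b)[0])
            corr[f"spearman[{preds[i]},{preds[j]}]"] = float(spearmanr(a, b)[0])
    diagnostics = {
        "correlations": corr,
        "max_abs_correlation": max(abs(v) for v in corr.values()) if corr else np.nan,
        "separation_flagged": any("separation" in n for n in fit.notes),
    }
    return fit, summary, diagnostics
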