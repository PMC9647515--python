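"""Two-level linear mixed-model estimation shared by all analysis modules.

Beeps (level 1) are nested in subjects (level 2).  Models are estimated by
maximum likelihood — never REML — so log-likelihoods, AIC and BIC remain
comparable across different mean structures.  Fixed-effect standard errors
come from the inverse observed information; an optional cluster-robust
(sandwich) covariance over subjects approximates robust-ML standard
errors.  Estimation is delegated to :class:`statsmodels` ``MixedLM``; a
model with no random effects reduces to ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import EstimationError

_OPTIMIZERS = ("bfgs", "lbfgs", "cg", "powell")


@dataclass
class FitResult:
    """Maximum-likelihood fit of one two-level (or pooled OLS) regression."""

    params: pd.Series
    cov_params: pd.DataFrame
    cov_re: pd.DataFrame | None
    scale: float
    llf: float
    aic: float
    bic: float
    n_obs: int
    n_groups: int
    k_params: int
    converged: bool
    boundary: bool
    formula: str
    engine: str  # "mixedlm" or "ols"
    cov_params_robust: pd.DataFrame | None = None

    def bse(self, robust: bool = False) -> pd.Series:
        cov = self.cov_params_robust if robust else self.cov_params
        if cov is None:
            raise ValueError("robust covariance was not computed")
        return pd.Series(np.sqrt(np.diag(cov)), index=self.params.index)

    def pvalues(self, robust: bool = False) -> pd.Series:
        z = self.params / self.bse(robust)
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def to_json(self) -> dict:
        return {
            "formula": self.formula,
            "engine": self.engine,
            "params": self.params.to_dict(),
            "bse": self.bse().to_dict(),
            "llf": self.llf,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "n_subjects": self.n_groups,
            "converged": self.converged,
            "boundary_variance": self.boundary,
        }


@dataclass
class ComparisonResult:
    """AIC/BIC deltas and, for caller-asserted nestings, the LR test."""

    d_aic: float
    d_bic: float
    lr_stat: float | None = None
    lr_df: int | None = None
    lr_p: float | None = None


def _check_rank(formula: str, data: pd.DataFrame) -> pd.DataFrame:
    """Return the complete-case frame, raising if the design is deficient."""
    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        _, r = np.linalg.qr(X.to_numpy())
        bad = [
            X.columns[j]
            for j in range(X.shape[1])
            if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))
        ]
        raise EstimationError(
            f"design matrix is rank deficient; collinear term(s): "
            f"{', '.join(bad) or 'undetermined'}"
        )
    if X.shape[0] == 0:
        raise EstimationError("no complete cases for formula " + formula)
    return data.loc[X.index]


def fit_two_level(
    formula: str,
    data: pd.DataFrame,
    groups: str = "subject_id",
    re_formula: str | None = "1",
    robust: bool = False,
) -> FitResult:
    """Fit ``formula`` with subject random effects by maximum likelihood.

    Parameters
    ----------
    formula : str
        patsy formula for the mean structure.
    data : DataFrame
        Long-format analysis frame; rows with missing values in the
        model's variables are dropped (available-case analysis).
    groups : str
        Level-2 cluster column.
    re_formula : str or None
        Random-effects design per subject (``"1"`` = random intercept).
        ``None`` fits pooled OLS — the zero between-subject-variance
        reduction used by the closed-form oracle tests.
    robust : bool
        Also compute a subject-clustered sandwich covariance.
    """
    frame = _check_rank(formula, data)
    if re_formula is None:
        res = smf.ols(formula, frame).fit()
        k = len(res.params) + 1  # + residual variance
        fit = FitResult(
            params=res.params,
            cov_params=res.cov_params(),
            cov_re=None,
            scale=float(res.scale),
            llf=float(res.llf),
            aic=-2 * res.llf + 2 * k,
            bic=-2 * res.llf + k * np.log(res.nobs),
            n_obs=int(res.nobs),
            n_groups=frame[groups].nunique(),
            k_params=k,
            converged=True,
            boundary=False,
            formula=formula,
            engine="ols",
        )
        if robust:
            rob = res.get_robustcov_results(
                cov_type="cluster", groups=frame[groups]
            )
            fit.cov_params_robust = pd.DataFrame(
                rob.cov_params(), index=res.params.index, columns=res.params.index
            )
        return fit

    model = smf.mixedlm(
        formula, frame, groups=frame[groups], re_formula=re_formula
    )
    res = None
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in _OPTIMIZERS:
            try:
                cand = model.fit(reml=False, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if cand is not None and not np.isfinite(cand.llf):
                continue  # optimizer failure masquerading as convergence
            if cand is not None and cand.converged:
                res, converged = cand, True
                break
            if res is None and cand is not None:
                res = cand
    if res is None:
        raise EstimationError(
            f"mixed-model estimation failed for formula {formula!r} "
            f"(optimizers tried: {', '.join(_OPTIMIZERS)})"
        )
    if not converged:
        raise EstimationError(
            f"mixed-model estimation did not converge for formula {formula!r}"
        )

    fe = res.fe_params
    cov_fe = res.cov_params().loc[fe.index, fe.index]
    cov_re = res.cov_re * 1.0
    boundary = bool(np.any(np.diag(cov_re.to_numpy()) < 1e-6 * res.scale))
    if boundary:
        warnings.warn(
            "a random-effect variance was estimated at the boundary (~0)",
            stacklevel=2,
        )
    k = len(fe) + cov_re.shape[0] * (cov_re.shape[0] + 1) // 2 + 1
    fit = FitResult(
        params=fe,
        cov_params=cov_fe,
        cov_re=cov_re,
        scale=float(res.scale),
        llf=float(res.llf),
        aic=-2 * res.llf + 2 * k,
        bic=-2 * res.llf + k * np.log(res.nobs),
        n_obs=int(res.nobs),
        n_groups=res.model.n_groups,
        k_params=k,
        converged=converged,
        boundary=boundary,
        formula=formula,
        engine="mixedlm",
    )
    if robust:
        fit.cov_params_robust = _cluster_sandwich(res)
    return fit


def _cluster_sandwich(res) -> pd.DataFrame:
    """Subject-clustered sandwich covariance of the fixed effects.

    With fitted marginal covariance V_i = Z_i G Z_i' + s2 I per subject,
    the bread is A = sum X_i' V_i^-1 X_i and the meat is the outer product
    of the per-subject GLS score contributions X_i' V_i^-1 r_i.
    """
    model = res.model
    X = model.exog
    Z = model.exog_re
    y = model.endog
    beta = res.fe_params.to_numpy()
    G = res.cov_re.to_numpy()
    s2 = res.scale
    p = X.shape[1]
    A = np.zeros((p, p))
    B = np.zeros((p, p))
    for _, idx in model.row_indices.items():
        idx = np.asarray(idx)
        Xi, Zi = X[idx], Z[idx]
        ri = y[idx] - Xi @ beta
        Vi = Zi @ G @ Zi.T + s2 * np.eye(len(idx))
        Vinv_Xi = np.linalg.solve(Vi, Xi)
        si = Xi.T @ np.linalg.solve(Vi, ri)
        A += Xi.T @ Vinv_Xi
        B += np.outer(si, si)
    Ainv = np.linalg.inv(A)
    cov = Ainv @ B @ Ainv
    names = res.fe_params.index
    return pd.DataFrame(cov, index=names, columns=names)


def compare_models(
    f_restricted: FitResult, f_full: FitResult, nested: bool = False
) -> ComparisonResult:
    """Compare two fits on the same observations.

    ``d_aic``/``d_bic`` are full minus restricted (negative favours the
    full model).  When the caller asserts ``nested``, the likelihood-ratio
    statistic, degrees of freedom and chi-square p-value are added.
    """
    if f_restricted.n_obs != f_full.n_obs:
        raise EstimationError(
            "model comparison requires identical observation sets "
            f"({f_restricted.n_obs} vs {f_full.n_obs} rows)"
        )
    out = ComparisonResult(
        d_aic=f_full.aic - f_restricted.aic,
        d_bic=f_full.bic - f_restricted.bic,
    )
    if nested:
        out.lr_stat = max(0.0, 2.0 * (f_full.llf - f_restricted.llf))
        out.lr_df = f_full.k_params - f_restricted.k_params
        out.lr_p = (
            float(stats.chi2.sf(out.lr_stat, out.lr_df))
            if out.lr_df and out.lr_df > 0
            else float("nan")
        )
    return out
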