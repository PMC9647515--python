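"""Longitudinal models on lagged beep pairs: AR baseline and cross-lagged panels.

The half-longitudinal mediation design estimates an indirect effect from
two measurement occasions: the product of the lagged X->M coefficient
(``axm``: X_{t-1} -> M_t) and the lagged M->Y coefficient (``bmy``:
M_{t-1} -> Y_t).  The reverse direction uses ``aym`` (Y_{t-1} -> M_t) and
``bmx`` (M_{t-1} -> X_t).  Group moderates every lagged path, including
the autoregressive ones.

Model variants (each a set of two-level regressions on the same
complete-case pair frame, so likelihoods are comparable):

``ar``
    X_t ~ X_{t-1};  M_t ~ M_{t-1};  Y_t ~ Y_{t-1}
``forward``
    M_t ~ M_{t-1} + X_{t-1};  Y_t ~ Y_{t-1} + M_{t-1} + X_{t-1};  X_t AR-only
``reverse``
    M_t ~ M_{t-1} + Y_{t-1};  X_t ~ X_{t-1} + M_{t-1} + Y_{t-1};  Y_t AR-only
``comprehensive``
    all three equations with all three lagged predictors

(all equations moderated by group and adjusted for age and gender, with
subject random intercepts and optionally random slopes).  The variants are
nested: ar within forward/reverse within comprehensive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GROUPS, LaggedDataset
from .errors import ConfigurationError, EstimationError
from .mediation import GROUP_PAIRS, _per_group
from .mixedlm import fit_two_level
from .montecarlo import IntervalResult, MonteCarloEngine, mc_interval

logger = logging.getLogger(__name__)

#: lagged-path name -> (equation outcome, lagged predictor)
_PATHS = {
    "rho_x": ("X", "X_lag"),
    "rho_m": ("M", "M_lag"),
    "rho_y": ("Y", "Y_lag"),
    "axm": ("M", "X_lag"),
    "bmy": ("Y", "M_lag"),
    "aym": ("M", "Y_lag"),
    "bmx": ("X", "M_lag"),
    "dxy": ("Y", "X_lag"),
    "dyx": ("X", "Y_lag"),
}

#: equation -> lagged predictors, per variant
VARIANT_EQUATIONS = {
    "ar": {"X": ["X_lag"], "M": ["M_lag"], "Y": ["Y_lag"]},
    "forward": {
        "X": ["X_lag"],
        "M": ["M_lag", "X_lag"],
        "Y": ["Y_lag", "M_lag", "X_lag"],
    },
    "reverse": {
        "X": ["X_lag", "M_lag", "Y_lag"],
        "M": ["M_lag", "Y_lag"],
        "Y": ["Y_lag"],
    },
    "comprehensive": {
        "X": ["X_lag", "M_lag", "Y_lag"],
        "M": ["M_lag", "X_lag", "Y_lag"],
        "Y": ["Y_lag", "M_lag", "X_lag"],
    },
}

_DIRECTIONS = {"forward": ("axm", "bmy"), "reverse": ("aym", "bmx")}


@dataclass
class ClpmEstimates:
    """Per-group lagged paths from one fitted variant."""

    variant: str
    paths: dict              # path name -> {group: estimate}
    path_cov: dict           # path name -> 3x3 group covariance (DataFrame)
    fits: dict               # equation name -> FitResult
    n_pairs: int = 0

    @property
    def loglik(self) -> float:
        return sum(f.llf for f in self.fits.values())

    @property
    def aic(self) -> float:
        return sum(f.aic for f in self.fits.values())

    @property
    def bic(self) -> float:
        return sum(f.bic for f in self.fits.values())

    @property
    def k_params(self) -> int:
        return sum(f.k_params for f in self.fits.values())

    def has_direction(self, direction: str) -> bool:
        p1, p2 = _DIRECTIONS[direction]
        return p1 in self.paths and p2 in self.paths


def _complete_pairs(lp: LaggedDataset | pd.DataFrame) -> pd.DataFrame:
    frame = lp.frame if isinstance(lp, LaggedDataset) else lp
    cols = ["X_lag", "M_lag", "Y_lag", "X_t", "M_t", "Y_t", "age", "gender"]
    work = frame.dropna(subset=[c for c in cols if c in frame.columns]).copy()
    work["W"] = pd.Categorical(work["group"], categories=GROUPS)
    work["gender"] = work["gender"].astype(str)
    for c in ("X_lag", "M_lag", "Y_lag", "X_t", "M_t", "Y_t", "age"):
        work[c] = pd.to_numeric(work[c])
    return work


def _fit_variant(
    work: pd.DataFrame, variant: str, random_slopes: bool = False
) -> ClpmEstimates:
    if not len(work):
        raise EstimationError("empty lagged dataset")
    equations = VARIANT_EQUATIONS[variant]
    fits, paths, path_cov = {}, {}, {}
    for eq, lags in equations.items():
        formula = f"{eq}_t ~ ({' + '.join(lags)}) * W + age + gender"
        re_formula = "1"
        if random_slopes:
            re_formula = "1 + " + " + ".join(lags)
        try:
            fit = fit_two_level(formula, work, re_formula=re_formula)
        except EstimationError:
            if re_formula == "1":
                raise
            logger.warning(
                "%s equation with random slopes did not converge; "
                "downgrading to random intercepts only", eq,
            )
            fit = fit_two_level(formula, work, re_formula="1")
        fits[eq] = fit
        for name, (eq_of, lag) in _PATHS.items():
            if eq_of == eq and lag in lags:
                est, cov = _per_group(fit.params, fit.cov_params, lag)
                paths[name], path_cov[name] = est, cov
    return ClpmEstimates(variant, paths, path_cov, fits, n_pairs=len(work))


def fit_autoregressive(
    lp: LaggedDataset | pd.DataFrame, random_slopes: bool = False
) -> ClpmEstimates:
    """Group-moderated AR(1) baseline for stress, negative affect and PE."""
    return _fit_variant(_complete_pairs(lp), "ar", random_slopes)


def fit_half_longitudinal(
    lp: LaggedDataset | pd.DataFrame,
    variant: str = "comprehensive",
    random_slopes: bool = False,
) -> ClpmEstimates:
    """Fit a half-longitudinal cross-lagged panel variant."""
    if variant not in VARIANT_EQUATIONS or variant == "ar":
        raise ConfigurationError(
            "variant must be one of 'forward', 'reverse', 'comprehensive'"
        )
    return _fit_variant(_complete_pairs(lp), variant, random_slopes)


def clpm_indirect(
    ce: ClpmEstimates, direction: str, group: str, engine: MonteCarloEngine
) -> IntervalResult:
    """Monte Carlo interval for the lagged indirect effect of one group."""
    if direction not in _DIRECTIONS:
        raise ConfigurationError("direction must be 'forward' or 'reverse'")
    if not ce.has_direction(direction):
        raise ConfigurationError(
            f"variant {ce.variant!r} does not estimate the {direction} paths"
        )
    if group not in GROUPS:
        raise ConfigurationError(f"unknown group {group!r}")
    p1, p2 = _DIRECTIONS[direction]
    theta = np.array([ce.paths[p1][group], ce.paths[p2][group]])
    V = np.diag(
        [ce.path_cov[p1].loc[group, group], ce.path_cov[p2].loc[group, group]]
    )
    return mc_interval(theta, V, ("product", 0, 1), engine)


def clpm_contrast(
    ce: ClpmEstimates, direction: str, ga: str, gb: str, engine: MonteCarloEngine
) -> IntervalResult:
    """Monte Carlo interval for the between-group indirect contrast."""
    if ga == gb:
        raise ConfigurationError("contrast requires two distinct groups")
    p1, p2 = _DIRECTIONS[direction]
    theta = np.array(
        [ce.paths[p1][ga], ce.paths[p2][ga], ce.paths[p1][gb], ce.paths[p2][gb]]
    )
    V = np.zeros((4, 4))
    V[np.ix_([0, 2], [0, 2])] = ce.path_cov[p1].loc[[ga, gb], [ga, gb]]
    V[np.ix_([1, 3], [1, 3])] = ce.path_cov[p2].loc[[ga, gb], [ga, gb]]
    return mc_interval(theta, V, ("diff_of_products", 0, 1, 2, 3), engine)


class CrossLaggedPanel:
    """Moderated cross-lagged panel model on within-day lagged pairs.

    Parameters
    ----------
    lagged : LaggedDataset or DataFrame
        Output of ``build_lagged_pairs``.
    variant : {"ar", "forward", "reverse", "comprehensive"}
    random_slopes : bool
        Random subject slopes on the lagged predictors, with automatic
        downgrade to random intercepts on non-convergence.
    """

    def __init__(self, lagged, variant: str = "comprehensive", random_slopes: bool = False):
        if variant not in VARIANT_EQUATIONS:
            raise ConfigurationError(
                f"unknown variant {variant!r}; choose from "
                + ", ".join(VARIANT_EQUATIONS)
            )
        self.variant = variant
        self.random_slopes = random_slopes
        self.frame = _complete_pairs(lagged)

    def fit(self, engine: MonteCarloEngine | None = None) -> "CrossLaggedPanelResults":
        engine = engine or MonteCarloEngine()
        est = _fit_variant(self.frame, self.variant, self.random_slopes)
        indirect, contrasts, totals = {}, {}, {}
        for direction in _DIRECTIONS:
            if not est.has_direction(direction):
                continue
            indirect[direction] = {
                g: clpm_indirect(est, direction, g, engine) for g in GROUPS
            }
            contrasts[direction] = {
                (ga, gb): clpm_contrast(est, direction, ga, gb, engine)
                for ga, gb in GROUP_PAIRS
            }
            totals[direction] = self._total_effect(direction)
        return CrossLaggedPanelResults(self, est, indirect, contrasts, totals)

    def _total_effect(self, direction: str) -> dict:
        """Total lagged effect from the no-mediator lagged equation."""
        out, src = ("Y", "X_lag") if direction == "forward" else ("X", "Y_lag")
        fit = fit_two_level(
            f"{out}_t ~ ({out}_lag + {src}) * W + age + gender", self.frame
        )
        est, cov = _per_group(fit.params, fit.cov_params, src)
        return {g: (est[g], float(np.sqrt(cov.loc[g, g]))) for g in GROUPS}


class CrossLaggedPanelResults:
    """Lagged paths, indirect effects and contrasts from one variant."""

    def __init__(self, model, estimates, indirect, contrasts, totals):
        self.model = model
        self.variant = model.variant
        self.estimates = estimates
        self.indirect = indirect
        self.contrasts = contrasts
        self.totals = totals

    def ar_table(self) -> pd.DataFrame:
        """Autoregressive coefficients per group (Table-4 shape)."""
        rows = []
        for name, var in (("rho_x", "stress"), ("rho_m", "negative affect"),
                          ("rho_y", "psychotic experiences")):
            if name not in self.estimates.paths:
                continue
            for g in GROUPS:
                est = self.estimates.paths[name][g]
                se = float(np.sqrt(self.estimates.path_cov[name].loc[g, g]))
                from scipy import stats as _st

                rows.append(
                    {
                        "measure": var,
                        "group": g,
                        "estimate": est,
                        "se": se,
                        "p": float(2 * _st.norm.sf(abs(est / se))),
                    }
                )
        return pd.DataFrame(rows)

    def table(self) -> pd.DataFrame:
        """Total / direct / indirect per direction (Table-5 shape)."""
        rows = []
        for direction, per_group in self.indirect.items():
            p_dir = "dxy" if direction == "forward" else "dyx"
            for g in GROUPS:
                ci = per_group[g]
                direct = self.estimates.paths.get(p_dir, {}).get(g, np.nan)
                tot = self.totals.get(direction, {}).get(g, (np.nan, np.nan))[0]
                rows.append(
                    {
                        "direction": direction,
                        "row": g,
                        "kind": "group",
                        "total": tot,
                        "direct": direct,
                        "indirect": ci.point,
                        "ci_lower": ci.lower,
                        "ci_upper": ci.upper,
                    }
                )
            for (ga, gb), ci in self.contrasts[direction].items():
                rows.append(
                    {
                        "direction": direction,
                        "row": f"{ga} v. {gb}",
                        "kind": "contrast",
                        "total": np.nan,
                        "direct": np.nan,
                        "indirect": ci.point,
                        "ci_lower": ci.lower,
                        "ci_upper": ci.upper,
                    }
                )
        return pd.DataFrame(rows)

    def fit_block(self) -> dict:
        e = self.estimates
        return {
            "variant": self.variant,
            "loglik": e.loglik,
            "aic": e.aic,
            "bic": e.bic,
            "k_params": e.k_params,
            "n_pairs": e.n_pairs,
        }

    def summary(self) -> str:
        from ._report import render_clpm_table

        return render_clpm_table(self)


def compare_clpm_variants(fits: dict) -> pd.DataFrame:
    """Model-fit comparison across variants fitted on identical pairs.

    ``fits`` maps variant name to :class:`ClpmEstimates` (or results
    objects exposing ``.estimates``).  Raises if the observation sets
    differ.  Rows report loglik/AIC/BIC plus deltas against the best AIC
    and, where the AR model nests the variant, the likelihood-ratio test.
    """
    from scipy import stats as _st

    ests = {
        k: (v.estimates if hasattr(v, "estimates") else v) for k, v in fits.items()
    }
    sizes = {k: e.n_pairs for k, e in ests.items()}
    if len(set(sizes.values())) > 1:
        raise EstimationError(
            f"variants fitted on different observation sets: {sizes}"
        )
    ar = ests.get("ar")
    rows = []
    for name, e in ests.items():
        row = {
            "variant": name,
            "loglik": e.loglik,
            "aic": e.aic,
            "bic": e.bic,
            "k_params": e.k_params,
        }
        if ar is not None and name != "ar":
            lr = max(0.0, 2.0 * (e.loglik - ar.loglik))
            df = e.k_params - ar.k_params
            row.update(
                lr_vs_ar=lr,
                lr_df=df,
                lr_p=float(_st.chi2.sf(lr, df)) if df > 0 else np.nan,
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    out["d_aic"] = out["aic"] - out["aic"].min()
    out["d_bic"] = out["bic"] - out["bic"].min()
    return out
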