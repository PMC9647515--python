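"""Cross-sectional multilevel moderated mediation (1-1-1 design).

Momentary stress (X), negative affect (M) and psychotic experiences (Y)
are all measured at beep level (level 1) within subjects (level 2); group
membership (patient / relative / control) is a level-2 moderator of the a
(X->M) and b (M->Y) paths, so the indirect effect a_g * b_g is conditional
on group.  Three mixed-effects equations are fitted per direction:

    mediator   M ~ X + W + X:W + age + gender
    outcome    Y ~ X + M + W + X:W + M:W + age + gender
    total      Y ~ X + W + X:W + age + gender

with subject random intercepts (optionally random a/b slopes).  Per-group
paths are assembled from the reference (control) coefficient plus the
group interaction.  Indirect effects use the product-of-coefficients
strategy with Monte Carlo percentile confidence intervals; between-group
contrasts of conditional indirect effects get Monte Carlo intervals over
the joint coefficient distribution, which is block-diagonal across the
separately fitted equations (the a-b sampling covariance is zero by
construction).

The reverse direction (Y -> M -> X) swaps the roles of stress and
psychotic experiences throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GROUPS, EsmDataset
from .errors import ConfigurationError, EstimationError
from .mixedlm import fit_two_level
from .montecarlo import IntervalResult, MonteCarloEngine, mc_interval

GROUP_PAIRS = (
    ("patient", "control"),
    ("relative", "control"),
    ("patient", "relative"),
)

_ROLES = {
    "x2y": ("stress", "negative_affect", "psychotic_experiences"),
    "y2x": ("psychotic_experiences", "negative_affect", "stress"),
}


def _per_group(params: pd.Series, cov: pd.DataFrame, base: str) -> tuple[dict, pd.DataFrame]:
    """Per-group coefficient and covariance for a W-moderated term."""
    names = [base, f"{base}:W[T.relative]", f"{base}:W[T.patient]"]
    L = pd.DataFrame(
        [[1, 0, 0], [1, 1, 0], [1, 0, 1]], index=GROUPS, columns=names, dtype=float
    )
    est = {g: float(L.loc[g] @ params[names]) for g in GROUPS}
    V = L.to_numpy() @ cov.loc[names, names].to_numpy() @ L.to_numpy().T
    return est, pd.DataFrame(V, index=GROUPS, columns=GROUPS)


@dataclass
class PathEstimates:
    """Per-group mediation paths with their sampling covariances."""

    direction: str
    a: dict
    b: dict
    c_prime: dict
    c_total: dict
    cov_a: pd.DataFrame
    cov_b: pd.DataFrame
    cov_c_prime: pd.DataFrame
    cov_c_total: pd.DataFrame
    fits: dict = field(default_factory=dict)

    def indirect_theta(self, group: str):
        """(a_g, b_g) with its 2x2 (diagonal) covariance."""
        if group not in self.a:
            raise ConfigurationError(f"unknown group {group!r}")
        V = np.diag([self.cov_a.loc[group, group], self.cov_b.loc[group, group]])
        return np.array([self.a[group], self.b[group]]), V

    def contrast_theta(self, ga: str, gb: str):
        """(a_A, b_A, a_B, b_B) with its joint covariance."""
        for g in (ga, gb):
            if g not in self.a:
                raise ConfigurationError(f"unknown group {g!r}")
        theta = np.array([self.a[ga], self.b[ga], self.a[gb], self.b[gb]])
        V = np.zeros((4, 4))
        V[np.ix_([0, 2], [0, 2])] = self.cov_a.loc[[ga, gb], [ga, gb]]
        V[np.ix_([1, 3], [1, 3])] = self.cov_b.loc[[ga, gb], [ga, gb]]
        return theta, V


def conditional_indirect(pe: PathEstimates, group: str) -> float:
    """Product-of-coefficients indirect effect a_g * b_g for one group."""
    if group not in pe.a:
        raise ConfigurationError(f"unknown group {group!r}")
    return pe.a[group] * pe.b[group]


def proportion_mediated(indirect: float, total: float) -> tuple[float, bool]:
    """P_M = indirect / total, with a suppression flag.

    The flag is set when the direct effect (total - indirect) has sign
    opposite to a nonzero indirect effect; P_M then exceeds 1 and is
    reported unclipped.  A zero total effect leaves P_M undefined (NaN).
    """
    if total == 0 or not math.isfinite(total):
        return float("nan"), False
    direct = total - indirect
    flag = indirect != 0 and direct != 0 and (direct > 0) != (indirect > 0)
    return indirect / total, flag


def contrast_indirect(
    pe: PathEstimates, ga: str, gb: str, engine: MonteCarloEngine
) -> IntervalResult:
    """Monte Carlo interval for a_A*b_A - a_B*b_B between two groups."""
    if ga == gb:
        raise ConfigurationError("contrast requires two distinct groups")
    theta, V = pe.contrast_theta(ga, gb)
    return mc_interval(theta, V, ("diff_of_products", 0, 1, 2, 3), engine)


class ModeratedMediation:
    """Cross-sectional multilevel moderated mediation model.

    Parameters
    ----------
    data : EsmDataset or DataFrame
        Filtered beep-level data (only valid beeps of an
        :class:`EsmDataset` are used).
    direction : {"x2y", "y2x"}
        ``x2y``: stress -> negative affect -> psychotic experiences;
        ``y2x``: the reverse chain.
    random_slopes : bool
        Add subject random slopes for the a and b paths.
    center_within : bool
        Person-mean center level-1 predictors before fitting.
    robust : bool
        Also compute subject-clustered sandwich covariances.
    groups_present : tuple, optional
        Declared subset of groups; by default all three are required.
    """

    def __init__(
        self,
        data,
        direction: str = "x2y",
        random_slopes: bool = False,
        center_within: bool = False,
        robust: bool = False,
        groups_present: tuple = GROUPS,
    ):
        if direction not in _ROLES:
            raise ConfigurationError("direction must be 'x2y' or 'y2x'")
        frame = data.valid_frame() if isinstance(data, EsmDataset) else data.copy()
        src, med, out = _ROLES[direction]
        work = pd.DataFrame(
            {
                "subject_id": frame["subject_id"],
                "W": pd.Categorical(frame["group"], categories=GROUPS),
                "src": frame[src],
                "med": frame[med],
                "out": frame[out],
                "age": frame["age"],
                "gender": frame["gender"].astype(str),
            }
        )
        present = set(work["W"].dropna().unique())
        missing = [g for g in groups_present if g not in present]
        if missing:
            raise EstimationError(
                f"group(s) absent from the data: {', '.join(missing)}"
            )
        if center_within:
            for col in ("src", "med"):
                work[col] = work[col] - work.groupby("subject_id")[col].transform("mean")
        self.direction = direction
        self.frame = work
        self.random_slopes = random_slopes
        self.robust = robust

    def fit_paths(self) -> PathEstimates:
        """Fit the three equations and assemble per-group paths."""
        re_med = "1 + src" if self.random_slopes else "1"
        re_out = "1 + med" if self.random_slopes else "1"
        f_med = fit_two_level(
            "med ~ src * W + age + gender", self.frame,
            re_formula=re_med, robust=self.robust,
        )
        f_out = fit_two_level(
            "out ~ src * W + med * W + age + gender", self.frame,
            re_formula=re_out, robust=self.robust,
        )
        f_tot = fit_two_level(
            "out ~ src * W + age + gender", self.frame, robust=self.robust,
        )
        a, cov_a = _per_group(f_med.params, f_med.cov_params, "src")
        b, cov_b = _per_group(f_out.params, f_out.cov_params, "med")
        cp, cov_cp = _per_group(f_out.params, f_out.cov_params, "src")
        ct, cov_ct = _per_group(f_tot.params, f_tot.cov_params, "src")
        return PathEstimates(
            direction=self.direction,
            a=a, b=b, c_prime=cp, c_total=ct,
            cov_a=cov_a, cov_b=cov_b, cov_c_prime=cov_cp, cov_c_total=cov_ct,
            fits={"mediator": f_med, "outcome": f_out, "total": f_tot},
        )

    def fit(self, engine: MonteCarloEngine | None = None) -> "ModeratedMediationResults":
        engine = engine or MonteCarloEngine()
        pe = self.fit_paths()
        indirect = {}
        for g in GROUPS:
            theta, V = pe.indirect_theta(g)
            indirect[g] = mc_interval(theta, V, ("product", 0, 1), engine)
        contrasts = {
            (ga, gb): contrast_indirect(pe, ga, gb, engine)
            for ga, gb in GROUP_PAIRS
        }
        return ModeratedMediationResults(self, pe, indirect, contrasts)


def fit_moderated_mediation(data, direction: str = "x2y", **options) -> PathEstimates:
    """Functional wrapper: fit the three equations, return the paths."""
    return ModeratedMediation(data, direction=direction, **options).fit_paths()


class ModeratedMediationResults:
    """Estimates, intervals and group contrasts from a fitted model."""

    def __init__(self, model, paths, indirect, contrasts):
        self.model = model
        self.direction = model.direction
        self.paths = paths
        self.indirect = indirect
        self.contrasts = contrasts
        self.prop_mediated = {
            g: proportion_mediated(
                conditional_indirect(paths, g), paths.c_total[g]
            )
            for g in GROUPS
        }

    def table(self) -> pd.DataFrame:
        """Publication-shaped table: one row per group and per contrast."""
        rows = []
        pe = self.paths
        sd_t = np.sqrt(np.diag(pe.cov_c_total))
        sd_d = np.sqrt(np.diag(pe.cov_c_prime))
        for i, g in enumerate(GROUPS):
            pm, supp = self.prop_mediated[g]
            ci = self.indirect[g]
            rows.append(
                {
                    "row": g,
                    "kind": "group",
                    "total": pe.c_total[g],
                    "total_se": sd_t[i],
                    "direct": pe.c_prime[g],
                    "direct_se": sd_d[i],
                    "indirect": ci.point,
                    "ci_lower": ci.lower,
                    "ci_upper": ci.upper,
                    "prop_mediated": pm,
                    "suppression": supp,
                }
            )
        for (ga, gb), ci in self.contrasts.items():
            rows.append(
                {
                    "row": f"{ga} v. {gb}",
                    "kind": "contrast",
                    "total": np.nan,
                    "total_se": np.nan,
                    "direct": np.nan,
                    "direct_se": np.nan,
                    "indirect": ci.point,
                    "ci_lower": ci.lower,
                    "ci_upper": ci.upper,
                    "prop_mediated": np.nan,
                    "suppression": False,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        from ._report import render_mediation_table

        return render_mediation_table(self)

    def to_json(self) -> dict:
        return {
            "direction": self.direction,
            "paths": {
                "a": self.paths.a,
                "b": self.paths.b,
                "c_prime": self.paths.c_prime,
                "c_total": self.paths.c_total,
            },
            "indirect": {g: ci.to_json() for g, ci in self.indirect.items()},
            "contrasts": {
                f"{ga}_vs_{gb}": ci.to_json()
                for (ga, gb), ci in self.contrasts.items()
            },
            "prop_mediated": {
                g: {"P_M": pm, "suppression": flag}
                for g, (pm, flag) in self.prop_mediated.items()
            },
        }
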