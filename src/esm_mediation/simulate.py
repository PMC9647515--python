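"""Synthetic experience-sampling data with known multilevel mediation structure.

The generator produces beep-level observations for three groups (patients,
first-degree relatives, controls) under the data-generating process the
package's models assume: subject random effects, group-specific structural
paths among momentary stress (X), negative affect (M) and psychotic
experiences (Y), first-order autoregressive and cross-lagged dynamics, and
missing-at-random nonresponse with realistic report latencies.  Every
dataset ships with a :class:`GroundTruth` record of the configured paths
and the true conditional indirect effects, so estimators can be judged
against a known answer.

Contemporaneous structure is generated recursively in one causal order per
dataset (either X -> M -> Y or Y -> M -> X); requesting both directions at
once would make the system cyclic and is rejected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GROUPS, EsmDataset, EsmDesign
from .errors import ConfigurationError

_BASE_DATE = pd.Timestamp("2024-01-01")


@dataclass(frozen=True)
class GroupPaths:
    """Structural paths for one group.

    Contemporaneous mediation paths: ``a`` (X->M), ``b`` (M->Y given X),
    ``c_prime`` (direct X->Y); ``a_rev``/``b_rev``/``c_prime_rev`` are the
    reverse-direction (Y->M->X) analogues.  Cross-lags: ``axm``
    (X_{t-1}->M_t), ``bmy`` (M_{t-1}->Y_t), ``aym`` (Y_{t-1}->M_t), ``bmx``
    (M_{t-1}->X_t) and the direct lagged paths ``dxy`` (X_{t-1}->Y_t),
    ``dyx`` (Y_{t-1}->X_t).
    """

    a: float = 0.0
    b: float = 0.0
    c_prime: float = 0.0
    a_rev: float = 0.0
    b_rev: float = 0.0
    c_prime_rev: float = 0.0
    axm: float = 0.0
    bmy: float = 0.0
    aym: float = 0.0
    bmx: float = 0.0
    dxy: float = 0.0
    dyx: float = 0.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of the synthetic data-generating process.

    Defaults encode the study conditions the package targets: group sizes
    245/165/244 (patients/relatives/controls), 10 beeps/day over 6 days in
    a 07:30-22:30 window with one uniform draw per 90-min block, and
    moderate missing-at-random nonresponse plus exponential report delays
    so the 15-min lateness rule has bite.
    """

    n_subjects: dict = field(
        default_factory=lambda: {"control": 244, "relative": 165, "patient": 245}
    )
    design: EsmDesign = field(default_factory=EsmDesign)
    paths: dict = field(
        default_factory=lambda: {g: GroupPaths() for g in GROUPS}
    )
    #: marginal target means of (X, M, Y) per group on the 1-7 scale
    means: dict = field(
        default_factory=lambda: {
            "control": (2.6, 2.4, 2.2),
            "relative": (3.0, 2.45, 2.25),
            "patient": (3.0, 2.9, 2.7),
        }
    )
    #: autoregressive coefficients (rho_X, rho_M, rho_Y), each |rho| < 1
    rho: tuple = (0.0, 0.0, 0.0)
    #: covariance of subject random intercepts for (X, M, Y)
    re_cov: tuple = (
        (0.1225, 0.0315, 0.0315),
        (0.0315, 0.0900, 0.0270),
        (0.0315, 0.0270, 0.0900),
    )
    #: s.d. of subject-level deviations of the a and b paths (0 disables)
    sd_a: float = 0.0
    sd_b: float = 0.0
    #: innovation s.d. of (X, M, Y)
    resid_sd: tuple = (0.6, 0.5, 0.5)
    #: per-year effect of (age - 40) on (X, M, Y)
    beta_age: tuple = (0.005, 0.003, 0.002)
    #: additive effect of female gender on (X, M, Y)
    beta_female: tuple = (0.10, 0.15, 0.0)
    #: mean subject age per group (s.d. 12, truncated to 18-75)
    age_mean: dict = field(
        default_factory=lambda: {"control": 40.0, "relative": 48.0, "patient": 38.0}
    )
    #: probability of being female per group
    p_female: dict = field(
        default_factory=lambda: {"control": 0.55, "relative": 0.60, "patient": 0.40}
    )
    #: baseline per-beep nonresponse probability and group offsets (logit)
    missing_base: float = 0.18
    missing_group_logit: dict = field(
        default_factory=lambda: {"control": 0.0, "relative": 0.1, "patient": 0.3}
    )
    missing_age_logit: float = 0.002
    #: exponential mean of the report delay in minutes
    delay_scale_min: float = 7.0
    #: clip observed composites to the 1-7 response scale
    clip: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        cov = np.asarray(self.re_cov, dtype=float)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ConfigurationError("re_cov must be a symmetric 3x3 matrix")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ConfigurationError("re_cov must be positive semi-definite")
        if any(abs(r) >= 1 for r in self.rho):
            raise ConfigurationError("autoregressive coefficients must have |rho| < 1")
        probs = [self.missing_base]
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        fwd = any(p.a != 0 or p.b != 0 or p.c_prime != 0 for p in self.paths.values())
        rev = any(
            p.a_rev != 0 or p.b_rev != 0 or p.c_prime_rev != 0
            for p in self.paths.values()
        )
        if fwd and rev:
            raise ConfigurationError(
                "contemporaneous paths may be nonzero in only one causal "
                "direction (X->M->Y or Y->M->X), not both"
            )

    @property
    def causal_order(self) -> str:
        """'y2x' if the reverse contemporaneous chain is active, else 'x2y'."""
        rev = any(
            p.a_rev != 0 or p.b_rev != 0 or p.c_prime_rev != 0
            for p in self.paths.values()
        )
        return "y2x" if rev else "x2y"


@dataclass(frozen=True)
class GroundTruth:
    """Configured paths and the indirect effects they imply, per group."""

    config: GeneratorConfig
    indirect_x2y: dict
    indirect_y2x: dict
    indirect_forward: dict   # axm * bmy
    indirect_reverse: dict   # aym * bmx

    def contrasts(self, table: str) -> dict:
        vals = getattr(self, f"indirect_{table}")
        pairs = [
            ("patient", "control"),
            ("relative", "control"),
            ("patient", "relative"),
        ]
        return {f"{a}_vs_{b}": vals[a] - vals[b] for a, b in pairs}

    def to_json(self) -> dict:
        return {
            "indirect_x2y": self.indirect_x2y,
            "indirect_y2x": self.indirect_y2x,
            "indirect_forward": self.indirect_forward,
            "indirect_reverse": self.indirect_reverse,
            "causal_order": self.config.causal_order,
        }


def _ground_truth(cfg: GeneratorConfig) -> GroundTruth:
    return GroundTruth(
        config=cfg,
        indirect_x2y={g: p.a * p.b for g, p in cfg.paths.items()},
        indirect_y2x={g: p.a_rev * p.b_rev for g, p in cfg.paths.items()},
        indirect_forward={g: p.axm * p.bmy for g, p in cfg.paths.items()},
        indirect_reverse={g: p.aym * p.bmx for g, p in cfg.paths.items()},
    )


def _simulate_subject(rng, cfg: GeneratorConfig, group: str):
    """Latent (x, m, y) deviations for one subject, all beeps, time order.

    Each day restarts the lag state and discards a short burn-in so
    within-day dynamics are near-stationary without overnight carry-over.
    """
    p: GroupPaths = cfg.paths[group]
    rhoX, rhoM, rhoY = cfg.rho
    sX, sM, sY = cfg.resid_sd
    u = rng.multivariate_normal(np.zeros(3), np.asarray(cfg.re_cov, float))
    a_i = p.a + (rng.normal(0.0, cfg.sd_a) if cfg.sd_a else 0.0)
    b_i = p.b + (rng.normal(0.0, cfg.sd_b) if cfg.sd_b else 0.0)
    a_rev_i = p.a_rev + (rng.normal(0.0, cfg.sd_a) if cfg.sd_a else 0.0)
    b_rev_i = p.b_rev + (rng.normal(0.0, cfg.sd_b) if cfg.sd_b else 0.0)
    order = cfg.causal_order

    burn = 3
    nb = cfg.design.beeps_per_day
    xs = np.empty(cfg.design.n_days * nb)
    ms = np.empty_like(xs)
    ys = np.empty_like(xs)
    k = 0
    for _ in range(cfg.design.n_days):
        x_ = m_ = y_ = 0.0
        for t in range(burn + nb):
            ex, em, ey = rng.normal(0.0, [sX, sM, sY])
            if order == "x2y":
                x = rhoX * x_ + p.bmx * m_ + p.dyx * y_ + ex
                m = a_i * x + rhoM * m_ + p.axm * x_ + p.aym * y_ + em
                y = b_i * m + p.c_prime * x + rhoY * y_ + p.bmy * m_ + p.dxy * x_ + ey
            else:
                y = rhoY * y_ + p.bmy * m_ + p.dxy * x_ + ey
                m = a_rev_i * y + rhoM * m_ + p.aym * y_ + p.axm * x_ + em
                x = (
                    b_rev_i * m + p.c_prime_rev * y + rhoX * x_
                    + p.bmx * m_ + p.dyx * y_ + ex
                )
            x_, m_, y_ = x, m, y
            if t >= burn:
                xs[k], ms[k], ys[k] = x, m, y
                k += 1
    return u, xs, ms, ys


def generate_dataset(
    cfg: GeneratorConfig, seed: int | None = None
) -> tuple[EsmDataset, GroundTruth]:
    """Simulate an :class:`EsmDataset` under ``cfg``.

    One root seed (``seed`` or ``cfg.seed``) fans out to an independent
    stream per subject, so identical seeds give identical datasets.
    Values are shifted to the configured group means, covariate effects
    added, and (optionally) clipped to the 1-7 response scale; nonresponse
    and report delays are applied afterwards, independent of the values
    themselves (missing at random given group and covariates).
    """
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    design = cfg.design
    n_total = sum(cfg.n_subjects.get(g, 0) for g in GROUPS)
    streams = root.spawn(n_total)

    block_min = _window_minutes(design) / design.beeps_per_day
    rows = []
    sid = itertools.count(1)
    si = 0
    for group in GROUPS:
        for _ in range(cfg.n_subjects.get(group, 0)):
            rng = np.random.default_rng(streams[si])
            si += 1
            subject = f"S{next(sid):04d}"
            age = float(np.clip(rng.normal(cfg.age_mean[group], 12.0), 18, 75))
            female = rng.random() < cfg.p_female[group]
            u, xs, ms, ys = _simulate_subject(rng, cfg, group)
            muX, muM, muY = cfg.means[group]
            adj = np.array(
                [
                    bage * (age - 40.0) + bfem * female
                    for bage, bfem in zip(cfg.beta_age, cfg.beta_female)
                ]
            )
            X = muX + adj[0] + u[0] + xs
            M = muM + adj[1] + u[1] + ms
            Y = muY + adj[2] + u[2] + ys
            if cfg.clip:
                X, M, Y = (np.clip(v, 1.0, 7.0) for v in (X, M, Y))

            if cfg.missing_base <= 0.0:
                p_miss = 0.0
            else:
                logit = (
                    np.log(cfg.missing_base / (1 - cfg.missing_base))
                    + cfg.missing_group_logit[group]
                    + cfg.missing_age_logit * (age - 40.0)
                )
                p_miss = 1.0 / (1.0 + np.exp(-logit))
            n_beeps = design.n_days * design.beeps_per_day
            responded = rng.random(n_beeps) >= p_miss
            delays = rng.exponential(cfg.delay_scale_min, n_beeps)
            offsets = rng.uniform(0.0, block_min, n_beeps)

            k = 0
            for day in range(1, design.n_days + 1):
                day_start = (
                    _BASE_DATE
                    + pd.Timedelta(days=day - 1)
                    + _clock_delta(design.day_start)
                )
                for beep in range(1, design.beeps_per_day + 1):
                    sched = day_start + pd.Timedelta(
                        minutes=(beep - 1) * block_min + offsets[k]
                    )
                    comp = (
                        sched + pd.Timedelta(minutes=delays[k])
                        if responded[k]
                        else pd.NaT
                    )
                    rows.append(
                        (
                            subject, group, day, beep, sched, comp,
                            X[k], M[k], Y[k], age,
                            "female" if female else "male",
                        )
                    )
                    k += 1

    frame = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "group", "day", "beep", "scheduled_time",
            "completed_time", "stress", "negative_affect",
            "psychotic_experiences", "age", "gender",
        ],
    )
    frame["group"] = pd.Categorical(frame["group"], categories=GROUPS)
    return (
        EsmDataset(frame, design, enforce_scale=cfg.clip),
        _ground_truth(cfg),
    )


def _window_minutes(design: EsmDesign) -> float:
    start = _clock_delta(design.day_start)
    end = _clock_delta(design.day_end)
    return (end - start).total_seconds() / 60.0


def _clock_delta(hhmm: str) -> pd.Timedelta:
    h, m = hhmm.split(":")
    return pd.Timedelta(hours=int(h), minutes=int(m))


# ---------------------------------------------------------------------------
# Scenario presets

def _paths_all(**kw) -> dict:
    return {g: GroupPaths(**kw) for g in GROUPS}


def scenario(name: str, **overrides) -> GeneratorConfig:
    """Return a documented preset :class:`GeneratorConfig`.

    Presets
    -------
    ``null_mediation``
        No mediation anywhere: a = 0 in every group (b nonzero), no
        autoregression.  For type-I-error / CI-coverage studies.
    ``paper_like_cross_sectional``
        Pure contemporaneous Y -> M -> X chain (psychotic experiences
        driving stress via negative affect) with group-ordered true
        indirect effects controls > relatives > patients
        (0.355 / 0.323 / 0.208) and positive direct paths.
    ``paper_like_longitudinal``
        Cross-lag-only dynamics with substantial autoregression and small,
        near-trivial lagged indirect effects in both directions.
    ``suppression``
        Direct effect of opposite sign to the (nonzero) indirect effect,
        so the proportion mediated exceeds 1.

    Keyword overrides replace any :class:`GeneratorConfig` field.
    """
    presets = {
        "null_mediation": dict(
            paths=_paths_all(a=0.0, b=0.4, c_prime=0.2),
            rho=(0.0, 0.0, 0.0),
        ),
        "paper_like_cross_sectional": dict(
            paths={
                "control": GroupPaths(a_rev=0.50, b_rev=0.71, c_prime_rev=0.19),
                "relative": GroupPaths(a_rev=0.475, b_rev=0.68, c_prime_rev=0.17),
                "patient": GroupPaths(a_rev=0.40, b_rev=0.52, c_prime_rev=0.10),
            },
            rho=(0.0, 0.0, 0.0),
        ),
        "paper_like_longitudinal": dict(
            paths={
                "control": GroupPaths(axm=0.05, bmy=0.04, aym=0.05, bmx=0.05),
                "relative": GroupPaths(axm=0.04, bmy=0.03, aym=0.04, bmx=0.04),
                "patient": GroupPaths(axm=0.05, bmy=0.05, aym=0.05, bmx=0.05),
            },
            rho=(0.4, 0.4, 0.4),
        ),
        "suppression": dict(
            paths=_paths_all(a=0.4, b=0.4, c_prime=-0.08),
            rho=(0.0, 0.0, 0.0),
        ),
    }
    if name not in presets:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(presets))}"
        )
    kw = presets[name]
    kw.update(overrides)
    return GeneratorConfig(**kw)
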