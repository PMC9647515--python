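"""Monte Carlo confidence intervals for functions of estimated coefficients.

The sampling distribution of the coefficient vector is approximated by a
multivariate normal centred at the estimates with the estimated asymptotic
covariance.  Draws are pushed through the target function (a product of two
paths, a difference of two such products, or a linear combination) and the
empirical percentiles form the interval — the standard Monte Carlo approach
to indirect effects in multilevel mediation, where the product of normal
coefficients is itself distinctly non-normal.

Percentile (not bias-corrected) intervals are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError


@dataclass
class MonteCarloEngine:
    """Reproducible source of Monte Carlo draws.

    Each interval computed through the engine consumes a fresh child seed
    derived from ``seed`` and an internal call counter, so a batch of
    intervals is reproducible end-to-end while individual intervals stay
    independent.
    """

    reps: int = 20_000
    alpha: float = 0.05
    seed: int = 0
    _calls: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if self.reps < 1000:
            raise ConfigurationError("reps must be at least 1000")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie strictly in (0, 1)")

    def child_rng(self) -> np.random.Generator:
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(self._calls,))
        self._calls += 1
        return np.random.default_rng(ss)


@dataclass(frozen=True)
class IntervalResult:
    """A point estimate with its Monte Carlo percentile interval."""

    point: float
    lower: float
    upper: float
    alpha: float
    reps: int

    @property
    def excludes_zero(self) -> bool:
        return not (self.lower <= 0.0 <= self.upper)

    def to_json(self) -> dict:
        return {
            "point": self.point,
            "ci_lower": self.lower,
            "ci_upper": self.upper,
            "alpha": self.alpha,
            "reps": self.reps,
            "excludes_zero": self.excludes_zero,
        }


def _apply(f, draws: np.ndarray) -> np.ndarray:
    kind = f[0]
    if kind == "product":
        _, i, j = f
        return draws[:, i] * draws[:, j]
    if kind == "diff_of_products":
        _, i, j, k, l = f
        return draws[:, i] * draws[:, j] - draws[:, k] * draws[:, l]
    if kind == "linear":
        w = np.asarray(f[1], dtype=float)
        return draws @ w
    raise ConfigurationError(
        f"unknown function descriptor {kind!r}; expected 'product', "
        "'diff_of_products' or 'linear'"
    )


def mc_interval(
    theta, V, f, engine: MonteCarloEngine
) -> IntervalResult:
    """Percentile Monte Carlo interval for ``f`` of coefficients ``theta``.

    Parameters
    ----------
    theta : array-like
        Coefficient estimates.
    V : array-like
        Their asymptotic covariance (symmetric positive semi-definite).
    f : tuple
        ``("product", i, j)``, ``("diff_of_products", i, j, k, l)`` or
        ``("linear", weights)``, indexing into ``theta``.
    engine : MonteCarloEngine
        Supplies reps, alpha and the reproducible random stream.
    """
    theta = np.asarray(theta, dtype=float)
    V = np.asarray(V, dtype=float)
    if V.shape != (theta.size, theta.size):
        raise ConfigurationError("covariance dimension does not match theta")
    if not np.allclose(V, V.T, atol=1e-10):
        raise ConfigurationError("covariance must be symmetric")
    evals = np.linalg.eigvalsh(V)
    if evals.min() < -1e-10 * max(1.0, evals.max()):
        raise ConfigurationError("covariance must be positive semi-definite")

    point = float(_apply(f, theta[None, :])[0])
    rng = engine.child_rng()
    draws = rng.multivariate_normal(theta, V, size=engine.reps, method="eigh")
    vals = _apply(f, draws)
    lo, hi = np.quantile(vals, [engine.alpha / 2, 1 - engine.alpha / 2])
    return IntervalResult(point, float(lo), float(hi), engine.alpha, engine.reps)
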