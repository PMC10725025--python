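"""Choice-proportion modelling and the randomization test.

The choice curve is a binomial generalized linear mixed model of per-trip
vertical-choice proportions against cumulative drinking visits, with a
random intercept per bee.  The likelihood is maximized directly with
Gauss-Hermite quadrature over the random effect; confidence intervals for
population-level predictions come from a parametric bootstrap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from beeforage.errors import ConfigError, ConvergenceError

_GH_POINTS = 25


def _gh_nodes(n: int = _GH_POINTS) -> tuple[np.ndarray, np.ndarray]:
    # Nodes/weights for E[f(Z)], Z ~ N(0, 1).
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * math.sqrt(2.0), w / math.sqrt(math.pi)


@dataclass
class ChoiceCurveFit:
    """Fitted binomial random-intercept model of choice proportions."""

    intercept: float
    slope: float
    sigma_u: float
    loglik: float
    n_bees: int
    n_trips: int
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_boot: int = 0

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Population-level predicted proportion (random effects at zero)."""
        return special.expit(self.intercept + self.slope * np.asarray(x, dtype=float))


def _stack_groups(
    groups: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    x = np.concatenate([g[0] for g in groups])
    k = np.concatenate([g[1] for g in groups])
    n = np.concatenate([g[2] for g in groups])
    starts = np.cumsum([0] + [len(g[0]) for g in groups[:-1]])
    return x, k, n, starts


def _neg_loglik(
    theta: np.ndarray,
    x: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    starts: np.ndarray,
    z: np.ndarray,
    log_w: np.ndarray,
) -> float:
    b0, b1, log_sigma = theta
    sigma = math.exp(log_sigma)
    # eta: (n_obs, n_nodes); binomial log-pmf without the constant term.
    eta = (b0 + b1 * x)[:, None] + sigma * z[None, :]
    logp = k[:, None] * eta - n[:, None] * np.logaddexp(0.0, eta)
    per_group = np.add.reduceat(logp, starts, axis=0)
    return -float(special.logsumexp(per_group + log_w[None, :], axis=1).sum())


def fit_choice_curve(
    data: pd.DataFrame,
    at: np.ndarray | list | None = None,
    n_boot: int = 10_000,
    seed: int | None = None,
    ci_level: float = 0.95,
    gh_points: int = _GH_POINTS,
) -> ChoiceCurveFit:
    """Fit the binomial random-intercept choice curve.

    Parameters
    ----------
    data
        Per-trip rows with columns ``bee_id``, ``cum_drinks`` (predictor:
        cumulative drinking visits at trip end), ``k_vertical`` and ``n``.
    at
        Predictor values at which to report population-level predicted
        proportions with bootstrap confidence intervals.
    n_boot
        Parametric-bootstrap replicates for the intervals (0 disables).

    Raises
    ------
    ConvergenceError
        If the optimizer fails; the optimizer message is carried.
    """
    required = {"bee_id", "cum_drinks", "k_vertical", "n"}
    missing = required - set(data.columns)
    if missing:
        raise ConfigError(f"choice-curve data missing column(s) {sorted(missing)}")
    if data["bee_id"].nunique() < 2:
        raise ConfigError("choice-curve fit needs at least 2 bees")
    groups = [
        (
            g["cum_drinks"].to_numpy(dtype=float),
            g["k_vertical"].to_numpy(dtype=float),
            g["n"].to_numpy(dtype=float),
        )
        for _, g in data.groupby("bee_id")
    ]
    z, w = _gh_nodes(gh_points)

    x_all, k_all, n_all, starts = _stack_groups(groups)
    log_w = np.log(w)
    # Start values: pooled GLM-style moment estimates.
    pooled_p = min(max(data["k_vertical"].sum() / data["n"].sum(), 1e-3), 1 - 1e-3)
    theta0 = np.array([special.logit(pooled_p), 0.0, math.log(0.5)])
    res = optimize.minimize(
        _neg_loglik,
        theta0,
        args=(x_all, k_all, n_all, starts, z, log_w),
        method="L-BFGS-B",
        bounds=[(-30, 30), (-5, 5), (-8, 3)],
    )
    if not res.success:
        raise ConvergenceError(f"choice-curve fit failed: {res.message}")
    b0, b1, log_sigma = res.x
    fit = ChoiceCurveFit(
        intercept=float(b0),
        slope=float(b1),
        sigma_u=float(math.exp(log_sigma)),
        loglik=-float(res.fun),
        n_bees=len(groups),
        n_trips=len(data),
    )
    if at is not None:
        at = np.asarray(at, dtype=float)
        point = fit.predict(at)
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            boot = _bootstrap_predictions(
                fit, groups, at, n_boot, rng, z, log_w
            )
            alpha = (1.0 - ci_level) / 2.0
            lo = np.nanquantile(boot, alpha, axis=0)
            hi = np.nanquantile(boot, 1 - alpha, axis=0)
            # Percentile intervals may not bracket the ML point estimate on
            # skewed small samples; widen to contain it.
            lo = np.minimum(lo, point)
            hi = np.maximum(hi, point)
        else:
            lo = np.full_like(point, np.nan)
            hi = np.full_like(point, np.nan)
        fit.predictions = pd.DataFrame(
            {"cum_drinks": at, "proportion": point, "ci_lo": lo, "ci_hi": hi}
        )
        fit.n_boot = n_boot
    return fit


def _bootstrap_predictions(
    fit: ChoiceCurveFit,
    groups: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    at: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    z: np.ndarray,
    log_w: np.ndarray,
) -> np.ndarray:
    """Parametric bootstrap: simulate from the fitted model, refit, predict."""
    out = np.full((n_boot, at.size), np.nan)
    theta_hat = np.array([fit.intercept, fit.slope, math.log(max(fit.sigma_u, 1e-6))])
    x_all, _, n_all, starts = _stack_groups(groups)
    sizes = np.diff(np.append(starts, len(x_all)))
    n_int = n_all.astype(int)
    for b in range(n_boot):
        u = np.repeat(rng.normal(0.0, fit.sigma_u, size=len(groups)), sizes)
        p = special.expit(fit.intercept + fit.slope * x_all + u)
        k = rng.binomial(n_int, p).astype(float)
        res = optimize.minimize(
            _neg_loglik,
            theta_hat,
            args=(x_all, k, n_all, starts, z, log_w),
            method="L-BFGS-B",
            bounds=[(-30, 30), (-5, 5), (-8, 3)],
        )
        if res.success:
            out[b] = special.expit(res.x[0] + res.x[1] * at)
    return out


# ---------------------------------------------------------------------------
# Randomization test


@dataclass(frozen=True)
class RandomizationResult:
    observed_stat: float  # mean(a) - mean(b)
    p_value: float
    n_resamples: int
    seed: int | None
    alternative: str
    method: str


def randomization_test(
    group_a,
    group_b,
    n_resamples: int = 100_000,
    seed: int | None = None,
    alternative: str = "two-sided",
    method: str = "montecarlo",
    max_exhaustive: int = 3_000_000,
) -> RandomizationResult:
    """Permutation test on the difference of group mean values.

    Pools both groups, repeatedly re-splits at the original group sizes
    without replacement and recomputes the mean difference.  The
    Monte-Carlo p-value uses the add-one correction
    ``(count + 1) / (n_resamples + 1)``; ``method="exhaustive"`` enumerates
    every split (no correction) when the number of splits is feasible.

    The pooled sample is sorted before resampling so the result is invariant
    to group labelling (for equal group sizes) under the same seed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigError("both groups must be non-empty")
    if n_resamples < 1 and method == "montecarlo":
        raise ConfigError("n_resamples must be >= 1")
    if alternative not in ("two-sided", "greater", "less"):
        raise ConfigError(f"unknown alternative {alternative!r}")
    observed = float(a.mean() - b.mean())
    pooled = np.sort(np.concatenate([a, b]))
    m, na, nb = pooled.size, a.size, b.size
    total = pooled.sum()

    def extremity(null: np.ndarray) -> np.ndarray:
        if alternative == "two-sided":
            return np.abs(null) >= abs(observed) - 1e-12
        if alternative == "greater":
            return null >= observed - 1e-12
        return null <= observed + 1e-12

    if method == "exhaustive":
        n_combos = math.comb(m, na)
        if n_combos > max_exhaustive:
            raise ConfigError(
                f"exhaustive enumeration needs {n_combos} splits "
                f"(> max_exhaustive={max_exhaustive})"
            )
        count = 0
        for idx in itertools.combinations(range(m), na):
            sa = pooled[list(idx)].sum()
            null = sa / na - (total - sa) / nb
            if extremity(np.array([null]))[0]:
                count += 1
        return RandomizationResult(
            observed_stat=observed,
            p_value=count / n_combos,
            n_resamples=n_combos,
            seed=seed,
            alternative=alternative,
            method="exhaustive",
        )

    if method != "montecarlo":
        raise ConfigError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    count = 0
    chunk = 20_000
    done = 0
    while done < n_resamples:
        n = min(chunk, n_resamples - done)
        order = np.argsort(rng.random((n, m)), axis=1)
        sa = pooled[order[:, :na]].sum(axis=1)
        null = sa / na - (total - sa) / nb
        count += int(extremity(null).sum())
        done += n
    p = (count + 1) / (n_resamples + 1)
    return RandomizationResult(
        observed_stat=observed,
        p_value=p,
        n_resamples=n_resamples,
        seed=seed,
        alternative=alternative,
        method="montecarlo",
    )
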