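"""Power frameworks for paired tumor-normal contrasts and survival scans.

Two distinct machineries, matching how each question is analyzed:

* Paired contrasts use a normal approximation to the paired t-test.  With
  standardized effect ``beta = E(delta)/sigma`` and ``n`` pairs, the test
  statistic has noncentrality ``xi = beta * sqrt(n)`` and two-sided power

      power = Phi(xi - C_alpha) + Phi(-xi - C_alpha),
      C_alpha = Phi^-1(1 - alpha/2).

  Both terms are retained, so ``beta = 0`` recovers exactly the level
  ``alpha``.  The minimum detectable effect inverts this at a target power.

* Survival scans are calibrated by simulation: a log-normal baseline
  (``log S ~ N(mu, sigma^2)``, fit by censoring-aware maximum likelihood),
  a standard-normal covariate, event times generated from the proportional
  hazards model by the inverse-probability method
  ``T = S0^-1(U^{exp(-beta z)})``, random censoring to a target fraction,
  and a Wald test from a Cox fit per replicate.  Power is the rejection
  fraction over replicates; the minimum detectable hazard ratio is found
  by bisection with common random numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .survival import _cox_newton


@dataclass
class PairedPowerSpec:
    """Paired-test power inputs: n pairs, two-sided alpha, effect, target."""

    n: int
    alpha: float
    beta: float = 0.0
    power_target: float = 0.80

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power_target < 1:
            raise ValueError("power_target must be in (0, 1)")


@dataclass
class SurvivalPowerSpec:
    """Survival power simulation inputs.

    ``mu`` and ``sigma`` parameterize the log-normal baseline survival
    distribution (log-years); ``beta`` is the log hazard ratio per standard
    deviation of the covariate; ``censor_fraction`` of subjects receive a
    random censoring time.
    """

    mu: float
    sigma: float
    n: int
    beta: float = 0.0
    censor_fraction: float = 0.0
    alpha: float = 0.01
    n_sims: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must be in [0, 1)")
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PowerResult:
    """Power estimate; for simulations, its Monte-Carlo uncertainty."""

    power: float
    n_sims: int | None = None
    n_rejections: int | None = None
    n_failed: int = 0

    @property
    def mc_se(self) -> float | None:
        if self.n_sims is None:
            return None
        p = self.power
        return math.sqrt(p * (1 - p) / self.n_sims)


# ---------------------------------------------------------------------------
# Paired-test power (closed form)
# ---------------------------------------------------------------------------


def paired_power(spec: PairedPowerSpec) -> float:
    """Two-sided power of the paired test under the normal approximation."""
    xi = spec.beta * math.sqrt(spec.n)
    c = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(xi - c) + stats.norm.cdf(-xi - c))


def min_detectable_effect(
    n: int, alpha: float, power_target: float = 0.80, tol: float = 1e-6
) -> float:
    """Smallest standardized effect reaching ``power_target`` at level alpha.

    Started from the one-term closed form ``(z_{1-alpha/2} + z_power)/sqrt(n)``
    and refined by bisection on the exact two-term formula to ``tol``.
    """
    c = stats.norm.ppf(1 - alpha / 2)
    approx = (c + stats.norm.ppf(power_target)) / math.sqrt(n)

    def gap(beta: float) -> float:
        return paired_power(PairedPowerSpec(n, alpha, beta, power_target)) - power_target

    lo, hi = 0.0, max(2 * approx, 1e-3)
    while gap(hi) < 0:
        hi *= 2
    return float(optimize.brentq(gap, lo, hi, xtol=tol))


# ---------------------------------------------------------------------------
# Log-normal baseline fitting
# ---------------------------------------------------------------------------


def fit_lognormal_survival(times, events) -> tuple[float, float]:
    """Censoring-aware ML fit of ``log T ~ N(mu, sigma^2)``.

    Event times contribute density terms, censored times survival terms.
    With no censoring this reduces to the sample mean and ML (1/n)
    variance of log times.  A degenerate fit (sigma -> 0) raises.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if d.sum() < 2:
        raise ValueError("need at least 2 events")
    logt = np.log(t)
    if d.all():
        mu = float(logt.mean())
        sigma = float(logt.std(ddof=0))
        if sigma == 0:
            raise ValueError("degenerate fit: all log-times equal (sigma -> 0)")
        return mu, sigma

    def nll(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        z = (logt - mu) / sigma
        ll = np.where(
            d == 1,
            stats.norm.logpdf(z) - log_sigma - logt,
            stats.norm.logsf(z),
        )
        return -ll.sum()

    start = np.array([logt[d == 1].mean(), math.log(logt.std(ddof=0) + 1e-6)])
    res = optimize.minimize(nll, start, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    mu, sigma = float(res.x[0]), float(math.exp(res.x[1]))
    if sigma < 1e-8:
        raise ValueError("degenerate fit: sigma -> 0")
    return mu, sigma


# ---------------------------------------------------------------------------
# Event-time generation (inverse-probability method)
# ---------------------------------------------------------------------------


def simulate_event_times(
    spec: SurvivalPowerSpec,
    z,
    u=None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """PH event times over a log-normal baseline: ``T = S0^-1(U^{exp(-beta z)})``.

    ``S0(t) = 1 - Phi((ln t - mu)/sigma)``, so
    ``S0^-1(s) = exp(mu + sigma * Phi^-1(1 - s))``.  ``u`` may be supplied
    for common-random-number designs; otherwise drawn from ``rng``.
    """
    z = np.asarray(z, dtype=float)
    if u is None:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        u = rng.uniform(size=z.shape)
    u = np.asarray(u, dtype=float)
    s = u ** np.exp(-spec.beta * z)
    # extreme linear predictors can underflow s to exactly 0 or 1; clip so
    # the generated times stay finite and positive
    s = np.clip(s, 1e-15, 1.0 - 1e-15)
    return np.exp(spec.mu + spec.sigma * stats.norm.ppf(1.0 - s))


def schoenfeld_power(beta: float, n_events: float, alpha: float) -> float:
    """Schoenfeld closed-form power for a N(0,1) covariate: an oracle for
    the simulation, not a replacement for it."""
    z_a = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(abs(beta) * math.sqrt(n_events) - z_a))


# ---------------------------------------------------------------------------
# Simulation-based survival power
# ---------------------------------------------------------------------------


def _simulate_replicate(spec: SurvivalPowerSpec, rng: np.random.Generator):
    """One replicate: returns the Wald p-value, or None on fit failure."""
    z = rng.standard_normal(spec.n)
    t = simulate_event_times(spec, z, rng=rng)
    event = np.ones(spec.n, dtype=int)
    n_censor = int(round(spec.censor_fraction * spec.n))
    if n_censor:
        who = rng.choice(spec.n, size=n_censor, replace=False)
        t = t.copy()
        t[who] = rng.uniform(0.0, t[who])
        event[who] = 0
    try:
        beta, se, _, converged, _, flags = _cox_newton(
            z.reshape(-1, 1), t, event, np.zeros(spec.n, dtype=int), "breslow"
        )
    except (np.linalg.LinAlgError, ValueError):
        return None
    if not converged or se[0] == 0:
        return None
    return 2 * stats.norm.sf(abs(beta[0] / se[0]))


def survival_power_sim(spec: SurvivalPowerSpec) -> PowerResult:
    """Rejection fraction of the per-replicate Wald test at ``spec.alpha``.

    Replicates whose Cox fit fails are dropped and counted; more than 5%
    failures aborts with an error.
    """
    rng = np.random.default_rng(spec.seed)
    rejections = 0
    failed = 0
    for _ in range(spec.n_sims):
        p = _simulate_replicate(spec, rng)
        if p is None:
            failed += 1
            continue
        if p < spec.alpha:
            rejections += 1
    if failed > 0.05 * spec.n_sims:
        raise RuntimeError(
            f"{failed}/{spec.n_sims} replicate fits failed; inputs likely degenerate"
        )
    n_ok = spec.n_sims - failed
    return PowerResult(rejections / n_ok, n_ok, rejections, failed)


def min_detectable_hr(
    spec: SurvivalPowerSpec,
    power_target: float = 0.80,
    tol: float = 0.01,
    max_iter: int = 30,
) -> float:
    """Smallest hazard ratio (per SD of the covariate) reaching the target.

    Bisection on ``beta >= 0``; every power evaluation reuses the same seed
    (common random numbers), which makes the empirical power curve monotone
    in ``beta`` within a run and the bisection well behaved.  By the
    symmetry of the standard-normal covariate, the protective-effect
    minimum is the reciprocal of the returned ratio.
    """
    if not 0 < power_target < 1:
        raise ValueError("power_target must be in (0, 1)")

    def power_at(beta: float) -> float:
        s = SurvivalPowerSpec(
            spec.mu, spec.sigma, spec.n, beta, spec.censor_fraction,
            spec.alpha, spec.n_sims, spec.seed,
        )
        return survival_power_sim(s).power

    lo, hi = 0.0, 0.5
    while power_at(hi) < power_target:
        hi *= 2
        if hi > 16:
            raise RuntimeError("bracket failure: power target unreachable "
                               f"(power at log-HR {hi/2:g} still below target)")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if power_at(mid) >= power_target:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return float(math.exp(hi))
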