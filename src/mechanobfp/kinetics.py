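"""Dwell-time kinetics and the joint-probability model of clamped unfolding.

Three fitted models live here, all in the Model/Results idiom:

* :class:`ExponentialDwellModel` — single-exponential times-to-unfold,
  p(t) = k exp(-k t), fitted either by the reciprocal sample mean (the MLE,
  with an exact gamma confidence interval) or by the slope of
  ln(survival) vs t.
* :class:`DualExponentialModel` — bond lifetimes distributed as a two-pathway
  mixture p(t) = w1 k1 exp(-k1 t) + (1-w1) k2 exp(-k2 t), fitted by direct
  maximum likelihood with random restarts (k1 >= k2 convention).
* :class:`BellModel` — exponential force dependence of a transition rate,
  k(f) = k0 exp(f x_dagger / kBT), fitted by log-linear regression.

On top of these sit the closed forms of the joint-probability model: if MSD
unfolding (rate k_u) and bond dissociation (dual-exponential lifetime) are
independent, the probability that unfolding is observed before dissociation
is

    Pu = w1 * ku/(ku + k1) + (1 - w1) * ku/(ku + k2),

the volume of the product density over the wedge 0 < t_u < t_b < inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .params import KBT_PN_NM

__all__ = [
    "ExpFit",
    "DualExpFit",
    "BellFit",
    "ExponentialDwellModel",
    "DualExponentialModel",
    "BellModel",
    "fit_exponential",
    "fit_dual_exponential",
    "fit_bell",
    "bell_rate",
    "predict_unfold_probability",
    "joint_density",
    "prob_at_least_one",
    "expected_unfold_count",
]


# ---------------------------------------------------------------------------
# single exponential
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpFit:
    """Single-exponential rate estimate with a 95% confidence interval."""

    rate: float
    ci95: tuple[float, float]
    n: int
    method: str

    def __post_init__(self):
        if not (self.ci95[0] <= self.rate <= self.ci95[1]):
            raise ValueError("confidence interval must bracket the rate")

    def summary(self) -> str:
        return (
            f"Exponential dwell fit ({self.method}, n={self.n})\n"
            f"  k = {self.rate:.4f} 1/s  [95% CI {self.ci95[0]:.4f}, {self.ci95[1]:.4f}]"
        )


class ExponentialDwellModel:
    """Exponential model for positive dwell times (times-to-unfold)."""

    def __init__(self, times):
        t = np.asarray(times, dtype=float)
        if t.ndim != 1 or t.size < 5:
            raise ValueError("need a 1-D sample of at least 5 dwell times")
        if np.any(t <= 0):
            raise ValueError("dwell times must be positive")
        self.times = t

    def fit(self, method: str = "reciprocal_mean") -> ExpFit:
        t = self.times
        n = t.size
        if method == "reciprocal_mean":
            k = 1.0 / t.mean()
            # exact interval: sum of n exponentials ~ Gamma(n, 1/k)
            s = t.sum()
            lo = stats.chi2.ppf(0.025, 2 * n) / (2 * s)
            hi = stats.chi2.ppf(0.975, 2 * n) / (2 * s)
            return ExpFit(rate=float(k), ci95=(float(lo), float(hi)), n=n, method=method)
        if method == "survival_slope":
            ts = np.sort(t)
            # survival just before each ordered failure; drop the last point
            # where the empirical survival hits 0
            surv = 1.0 - np.arange(1, n + 1) / n
            keep = surv > 0
            x, y = ts[keep], np.log(surv[keep])
            slope, _, _, _, se = stats.linregress(x, y)
            k = -slope
            z = stats.norm.ppf(0.975)
            lo, hi = k - z * se, k + z * se
            return ExpFit(rate=float(k), ci95=(float(min(lo, k)), float(max(hi, k))),
                          n=n, method=method)
        raise ValueError(f"unknown method {method!r}")


def fit_exponential(times, method: str = "reciprocal_mean") -> ExpFit:
    """Fit a single-exponential rate to dwell times."""
    return ExponentialDwellModel(times).fit(method=method)


# ---------------------------------------------------------------------------
# dual exponential
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DualExpFit:
    """Dual-exponential lifetime fit (k1 >= k2 convention).

    ``single_exponential`` flags degenerate convergence (k1 ~ k2 or a
    vanishing mixture weight), in which case the fit collapses to one rate.
    ``lrt_stat`` is the likelihood-ratio statistic against the nested
    single-exponential model (2 extra parameters).
    """

    w1: float
    k1: float
    k2: float
    loglike: float
    n: int
    bse: tuple[float, float, float]
    lrt_stat: float
    single_exponential: bool = False

    def __post_init__(self):
        if not (0.0 <= self.w1 <= 1.0):
            raise ValueError("w1 must lie in [0, 1]")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("rates must be positive")

    @property
    def mean(self) -> float:
        """Model mean lifetime w1/k1 + (1-w1)/k2."""
        return self.w1 / self.k1 + (1.0 - self.w1) / self.k2

    def summary(self) -> str:
        lines = [f"Dual-exponential lifetime fit (MLE, n={self.n})"]
        for name, val, se in zip(("w1", "k1", "k2"), (self.w1, self.k1, self.k2), self.bse):
            lines.append(f"  {name} = {val:.4f} +/- {se:.4f}")
        lines.append(f"  mean lifetime = {self.mean:.4f} s")
        lines.append(f"  log-likelihood = {self.loglike:.3f}; LRT vs single exp = {self.lrt_stat:.3f}")
        if self.single_exponential:
            lines.append("  WARNING: degenerate fit, collapsed to single exponential")
        return "\n".join(lines)


def _dual_exp_nll(theta, t):
    w1, lk1, lk2 = theta
    if not np.all(np.isfinite(theta)) or not (0.0 <= w1 <= 1.0):
        return np.inf
    if abs(lk1) > 25 or abs(lk2) > 25:
        return np.inf
    k1, k2 = np.exp(lk1), np.exp(lk2)
    pdf = w1 * k1 * np.exp(-k1 * t) + (1.0 - w1) * k2 * np.exp(-k2 * t)
    if np.any(pdf <= 0) or not np.all(np.isfinite(pdf)):
        return np.inf
    return -np.sum(np.log(pdf))


class DualExponentialModel:
    """Two-pathway exponential mixture for bond lifetimes, fit by MLE."""

    def __init__(self, lifetimes):
        t = np.asarray(lifetimes, dtype=float)
        if t.ndim != 1 or t.size < 20:
            raise ValueError("need a 1-D sample of at least 20 lifetimes")
        if np.any(t <= 0):
            raise ValueError("lifetimes must be positive")
        self.lifetimes = t

    def fit(self, n_restarts: int = 10, seed: int = 0) -> DualExpFit:
        t = self.lifetimes
        n = t.size
        rng = np.random.default_rng(seed)
        kbar = 1.0 / t.mean()
        best = None
        starts = [(0.5, np.log(4 * kbar), np.log(0.4 * kbar))]
        for _ in range(n_restarts - 1):
            starts.append((
                rng.uniform(0.1, 0.9),
                np.log(kbar * rng.uniform(1.0, 20.0)),
                np.log(kbar * rng.uniform(0.05, 1.0)),
            ))
        for x0 in starts:
            res = optimize.minimize(
                _dual_exp_nll, x0, args=(t,), method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-9},
            )
            if best is None or res.fun < best.fun:
                best = res
        w1 = float(np.clip(best.x[0], 0.0, 1.0))
        k1 = float(np.clip(np.exp(best.x[1]), 1e-10, 1e10))
        k2 = float(np.clip(np.exp(best.x[2]), 1e-10, 1e10))
        if k2 > k1:  # enforce fast/slow ordering
            k1, k2 = k2, k1
            w1 = 1.0 - w1
        loglike = -float(best.fun)

        # nested single-exponential comparison
        ll_single = n * np.log(kbar) - kbar * t.sum()
        lrt = 2.0 * (loglike - float(ll_single))

        degenerate = (k1 / k2 < 1.2) or (w1 < 0.01) or (w1 > 0.99)
        bse = self._standard_errors((w1, k1, k2), t)
        return DualExpFit(w1=w1, k1=k1, k2=k2, loglike=loglike, n=n,
                          bse=bse, lrt_stat=float(lrt),
                          single_exponential=bool(degenerate))

    @staticmethod
    def _standard_errors(theta, t):
        """Observed-information standard errors on (w1, k1, k2)."""
        def nll(p):
            w1, k1, k2 = p
            if not (0 < w1 < 1) or k1 <= 0 or k2 <= 0:
                return np.inf
            pdf = w1 * k1 * np.exp(-k1 * t) + (1 - w1) * k2 * np.exp(-k2 * t)
            return -np.sum(np.log(pdf))

        p = np.asarray(theta, dtype=float)
        eps = np.maximum(1e-5, 1e-4 * np.abs(p))
        h = np.zeros((3, 3))
        f0 = nll(p)
        for i in range(3):
            for j in range(i, 3):
                pi, pj = np.zeros(3), np.zeros(3)
                pi[i], pj[j] = eps[i], eps[j]
                fpp = nll(p + pi + pj)
                fpm = nll(p + pi - pj)
                fmp = nll(p - pi + pj)
                fmm = nll(p - pi - pj)
                h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps[i] * eps[j])
        if not np.all(np.isfinite(h)) or np.isinf(f0):
            return (np.nan, np.nan, np.nan)
        try:
            cov = np.linalg.inv(h)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            return tuple(float(s) for s in se)
        except np.linalg.LinAlgError:
            return (np.nan, np.nan, np.nan)


def fit_dual_exponential(lifetimes, n_restarts: int = 10, seed: int = 0) -> DualExpFit:
    """Maximum-likelihood dual-exponential fit of a lifetime sample."""
    return DualExponentialModel(lifetimes).fit(n_restarts=n_restarts, seed=seed)


# ---------------------------------------------------------------------------
# Bell model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BellFit:
    """Bell-equation parameters k(f) = k0 exp(f x_dagger / kBT)."""

    k0: float
    x_dagger: float
    kbt: float = KBT_PN_NM
    k0_se: float = float("nan")
    x_dagger_se: float = float("nan")

    def __post_init__(self):
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")

    def rate(self, force) -> np.ndarray | float:
        f = np.asarray(force, dtype=float)
        k = self.k0 * np.exp(f * self.x_dagger / self.kbt)
        return k if k.ndim else float(k)

    def summary(self) -> str:
        return (
            "Bell-model fit k(f) = k0 exp(f x/kBT)\n"
            f"  k0 = {self.k0:.4f} +/- {self.k0_se:.4f} 1/s\n"
            f"  x  = {self.x_dagger:.4f} +/- {self.x_dagger_se:.4f} nm\n"
            f"  kBT = {self.kbt:.3f} pN nm"
        )


def bell_rate(force, fit: BellFit):
    """Transition rate at the given force(s) under a Bell-model fit."""
    return fit.rate(force)


class BellModel:
    """Log-linear regression of rates on force (Bell equation)."""

    def __init__(self, forces, rates, kbt: float = KBT_PN_NM):
        f = np.asarray(forces, dtype=float)
        k = np.asarray(rates, dtype=float)
        if f.ndim != 1 or f.shape != k.shape or f.size < 2:
            raise ValueError("need at least 2 (force, rate) pairs")
        if np.unique(f).size < 2:
            raise ValueError("Bell fit is underdetermined with a single force level")
        if np.any(k <= 0):
            raise ValueError("rates must be positive")
        self.forces = f
        self.rates = k
        self.kbt = kbt

    def fit(self) -> BellFit:
        import statsmodels.api as sm

        y = np.log(self.rates)
        x = sm.add_constant(self.forces)
        res = sm.OLS(y, x).fit()
        intercept, slope = res.params
        k0 = float(np.exp(intercept))
        xd = float(slope * self.kbt)
        se_int, se_slope = res.bse if np.all(np.isfinite(res.bse)) else (np.nan, np.nan)
        return BellFit(k0=k0, x_dagger=xd, kbt=self.kbt,
                       k0_se=float(k0 * se_int), x_dagger_se=float(se_slope * self.kbt))


def fit_bell(forces, rates, kbt: float = KBT_PN_NM) -> BellFit:
    """Fit the Bell equation to (force, rate) pairs by log-linear regression."""
    return BellModel(forces, rates, kbt=kbt).fit()


# ---------------------------------------------------------------------------
# joint-probability model
# ---------------------------------------------------------------------------

def predict_unfold_probability(k_u: float, lifetime: DualExpFit | dict) -> float:
    """Probability of observing clamped unfolding before dissociation.

    Closed form of the volume of the independence product density
    p_u(t_u) p(t_b) over the wedge 0 < t_u < t_b:

        Pu = w1 * ku/(ku + k1) + (1 - w1) * ku/(ku + k2).
    """
    if isinstance(lifetime, dict):
        w1, k1, k2 = lifetime["w1"], lifetime["k1"], lifetime["k2"]
    else:
        w1, k1, k2 = lifetime.w1, lifetime.k1, lifetime.k2
    if k_u < 0 or k1 <= 0 or k2 <= 0:
        raise ValueError("rates must be positive (k_u non-negative)")
    return float(w1 * k_u / (k_u + k1) + (1.0 - w1) * k_u / (k_u + k2))


def joint_density(t_u, t_b, k_u: float, lifetime: DualExpFit | dict):
    """Independence product density p(t_u, t_b) = p_u(t_u) * p(t_b)."""
    if isinstance(lifetime, dict):
        w1, k1, k2 = lifetime["w1"], lifetime["k1"], lifetime["k2"]
    else:
        w1, k1, k2 = lifetime.w1, lifetime.k1, lifetime.k2
    tu = np.asarray(t_u, dtype=float)
    tb = np.asarray(t_b, dtype=float)
    if np.any(tu < 0) or np.any(tb < 0):
        raise ValueError("times must be non-negative")
    pu = k_u * np.exp(-k_u * tu)
    pb = w1 * k1 * np.exp(-k1 * tb) + (1.0 - w1) * k2 * np.exp(-k2 * tb)
    d = pu * pb
    return d if d.ndim else float(d)


def prob_at_least_one(p_event: float, n_events: float) -> float:
    """Probability of at least one success in n independent trials: 1-(1-p)^n."""
    if not (0.0 <= p_event <= 1.0):
        raise ValueError("p_event must lie in [0, 1]")
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    return float(1.0 - (1.0 - p_event) ** n_events)


def expected_unfold_count(n_lifetime_events: float, p_event: float,
                          n_se: float = 0.0, p_se: float = 0.0) -> tuple[float, float]:
    """Expected number of unfolding events n*p with Gaussian error propagation.

    se(np) = sqrt((p * se_n)^2 + (n * se_p)^2).
    """
    if n_lifetime_events < 0 or not (0.0 <= p_event <= 1.0):
        raise ValueError("invalid count or probability")
    value = n_lifetime_events * p_event
    se = float(np.hypot(p_event * n_se, n_lifetime_events * p_se))
    return float(value), se
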