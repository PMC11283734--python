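"""Parametric survival distributions, life-table mortality, and MLE fitting.

Five families are supported — exponential, Weibull, log-logistic, log-normal
and Gompertz — the set routinely screened when extrapolating trial survival
curves for decision models.  Each family exposes closed-form survival,
density, CDF and quantile functions, so event times can be generated by
inverse-transform sampling from recorded uniform draws (which keeps the
simulator reproducible and lets common random numbers be shared across
scenarios).

Parameterisations
-----------------
exponential   params = (scale,)            S(t) = exp(-t/scale); mean = scale
weibull       params = (shape, scale)      S(t) = exp(-(t/scale)^shape)
log-logistic  params = (shape, scale)      S(t) = 1 / (1 + (t/scale)^shape)
log-normal    params = (mu, sigma)         log T ~ Normal(mu, sigma^2)
gompertz      params = (shape, rate)       hazard h(t) = rate * exp(shape*t)

The Gompertz convention (shape ``b``, rate ``a``, hazard ``a*exp(b*t)``) is
stated explicitly because textbooks disagree; ``shape`` must be > 0 here
(the defective ``b < 0`` variant is not supported).

Fitting handles right-censored data: events contribute the log-density,
censored observations the log-survival.  Model choice uses AIC / BIC with
ties broken by parsimony and a fixed family order.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .errors import DomainError, FitError, InputError, ParameterError

FAMILIES = ("exponential", "weibull", "log-logistic", "log-normal", "gompertz")

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "log-logistic": 2,
    "log-normal": 2,
    "gompertz": 2,
}

_ALIASES = {
    "exp": "exponential",
    "loglogistic": "log-logistic",
    "llogis": "log-logistic",
    "lognormal": "log-normal",
    "lnorm": "log-normal",
}


def canonical_family(name: str) -> str:
    key = name.strip().lower().replace("_", "-")
    key = _ALIASES.get(key.replace("-", ""), _ALIASES.get(key, key))
    if key not in FAMILIES:
        raise ParameterError(f"unknown survival family: {name!r}")
    return key


def _check_params(family: str, params: Sequence[float]) -> tuple:
    p = tuple(float(v) for v in params)
    if len(p) != _N_PARAMS[family]:
        raise ParameterError(
            f"{family} takes {_N_PARAMS[family]} parameter(s), got {len(p)}"
        )
    if family == "log-normal":
        if p[1] <= 0:
            raise ParameterError("log-normal sigma must be positive")
    elif any(v <= 0 for v in p):
        raise ParameterError(f"{family} parameters must be positive, got {p}")
    return p


@dataclass(frozen=True)
class ParametricSurvival:
    """A frozen parametric time-to-event distribution.

    ``cap_years`` is carried as metadata for registry entries whose sampled
    times are overridden beyond a horizon (the 10-year post-transplant
    switch to background mortality); the distribution itself is uncapped.
    """

    family: str
    params: tuple
    cap_years: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "family", canonical_family(self.family))
        object.__setattr__(self, "params", _check_params(self.family, self.params))

    # -- closed forms -------------------------------------------------

    def sf(self, t: float) -> float:
        """Survival function S(t)."""
        if t <= 0:
            return 1.0
        f, p = self.family, self.params
        if f == "exponential":
            return math.exp(-t / p[0])
        if f == "weibull":
            return math.exp(-((t / p[1]) ** p[0]))
        if f == "log-logistic":
            return 1.0 / (1.0 + (t / p[1]) ** p[0])
        if f == "log-normal":
            return float(special.ndtr(-(math.log(t) - p[0]) / p[1]))
        # gompertz
        b, a = p
        return math.exp(-(a / b) * math.expm1(b * t))

    def cdf(self, t: float) -> float:
        return 1.0 - self.sf(t)

    def pdf(self, t: float) -> float:
        if t <= 0:
            return 0.0
        f, p = self.family, self.params
        if f == "exponential":
            return math.exp(-t / p[0]) / p[0]
        if f == "weibull":
            k, lam = p
            z = (t / lam) ** k
            return (k / lam) * (t / lam) ** (k - 1) * math.exp(-z)
        if f == "log-logistic":
            beta, alpha = p
            z = (t / alpha) ** beta
            return (beta / alpha) * (t / alpha) ** (beta - 1) / (1.0 + z) ** 2
        if f == "log-normal":
            mu, sigma = p
            z = (math.log(t) - mu) / sigma
            return math.exp(-0.5 * z * z) / (t * sigma * math.sqrt(2 * math.pi))
        b, a = p
        return a * math.exp(b * t) * self.sf(t)

    def quantile(self, p: float) -> float:
        """Inverse CDF; the workhorse of inverse-transform sampling.

        Accepts 0 <= p < 1 and returns a time in the same units as the
        scale parameter.  Strictly increasing in ``p``.
        """
        if not 0.0 <= p < 1.0:
            raise DomainError(f"quantile probability must be in [0, 1), got {p}")
        if p == 0.0:
            return 0.0
        f, par = self.family, self.params
        if f == "exponential":
            return -par[0] * math.log1p(-p)
        if f == "weibull":
            k, lam = par
            return lam * (-math.log1p(-p)) ** (1.0 / k)
        if f == "log-logistic":
            beta, alpha = par
            return alpha * (p / (1.0 - p)) ** (1.0 / beta)
        if f == "log-normal":
            mu, sigma = par
            return math.exp(mu + sigma * special.ndtri(p))
        b, a = par
        return math.log1p(-(b / a) * math.log1p(-p)) / b

    def sample_time(self, u: float) -> float:
        """Deterministic inverse-transform draw: equals ``quantile(u)``."""
        return self.quantile(u)

    def mean_restricted(self, horizon: float, n_grid: int = 4096) -> float:
        """Restricted mean survival time E[min(T, horizon)] by quadrature."""
        ts = np.linspace(0.0, horizon, n_grid + 1)
        s = np.array([self.sf(t) for t in ts])
        return float(np.trapezoid(s, ts))


# ----------------------------------------------------------------------
# Life table
# ----------------------------------------------------------------------


class LifeTable:
    """A national period life table: integer ages with annual death
    probabilities ``qx``.

    Ages must be contiguous and the final age class must have qx = 1, which
    closes the table.  Remaining-lifetime sampling treats deaths as uniform
    within the year of death (the sub-year timing is not identified by a
    table of annual probabilities).
    """

    def __init__(self, ages: Sequence[int], qx: Sequence[float]):
        ages = np.asarray(ages, dtype=int)
        qx = np.asarray(qx, dtype=float)
        if ages.size == 0 or ages.size != qx.size:
            raise InputError("life table needs matching, non-empty age and qx columns")
        if not np.all(np.diff(ages) == 1):
            raise InputError("life-table ages must be contiguous integers")
        if np.any(qx < 0) or np.any(qx > 1):
            raise InputError("life-table qx must lie in [0, 1]")
        if qx[-1] != 1.0:
            raise InputError("life table must close with qx = 1 at the final age")
        self.ages = ages
        self.qx = qx
        self._ladders: dict[int, np.ndarray] = {}
        self._fast: dict[int, tuple] = {}

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        if not {"age", "qx"} <= set(df.columns):
            raise InputError("life-table CSV must have columns 'age' and 'qx'")
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(path, index=False)

    def _ladder(self, age: int) -> np.ndarray:
        """Survival probabilities to successive birthdays, conditional on
        being alive at integer ``age``; cached per age."""
        lad = self._ladders.get(age)
        if lad is None:
            i = age - self.min_age
            lad = np.concatenate([[1.0], np.cumprod(1.0 - self.qx[i:])])
            self._ladders[age] = lad
        return lad

    def _fast_sampler(self, age: int):
        """Cached cumulative death-year probabilities for an integer age."""
        cached = self._fast.get(age)
        if cached is None:
            lad = self._ladder(age)
            probs = (lad[:-1] - lad[1:]).tolist()
            cum = np.concatenate([[0.0], np.cumsum(lad[:-1] - lad[1:])]).tolist()
            cached = (cum, probs, cum[-1])
            self._fast[age] = cached
        return cached

    def background_death_time(self, current_age: float, u: float) -> float:
        """Sample remaining lifetime in years for someone aged ``current_age``.

        A single uniform draw selects the year of death from the conditional
        survival ladder and places the death uniformly within that year.
        """
        if not 0.0 <= u < 1.0:
            raise DomainError(f"uniform draw must be in [0, 1), got {u}")
        a0 = int(math.floor(current_age))
        frac = current_age - a0
        if a0 < self.min_age or a0 > self.max_age:
            raise InputError(
                f"age {current_age} outside life-table range "
                f"[{self.min_age}, {self.max_age}]"
            )
        if frac == 0.0:
            cum, probs, total = self._fast_sampler(a0)
            uu = min(u, 1.0 - 1e-15) * total
            k = bisect.bisect_right(cum, uu) - 1
            k = min(k, len(probs) - 1)
            within = (uu - cum[k]) / probs[k] if probs[k] > 0 else 0.0
            return k + within
        lad = self._ladder(a0)
        if frac > 0.0:
            # condition on survival to current_age assuming uniform deaths
            # within [a0, a0+1)
            s_now = 1.0 - frac * self.qx[a0 - self.min_age]
            lad = np.minimum(lad / s_now, 1.0)
        # death-year probabilities and interval boundaries
        probs = lad[:-1] - lad[1:]
        bounds = np.concatenate([[0.0], (1.0 - frac) + np.arange(len(probs))])
        cum = np.concatenate([[0.0], np.cumsum(probs)])
        total = cum[-1]
        uu = min(u, 1.0 - 1e-15) * total  # final qx=1 makes total 1 up to rounding
        k = int(np.searchsorted(cum, uu, side="right")) - 1
        k = min(k, len(probs) - 1)
        within = (uu - cum[k]) / probs[k] if probs[k] > 0 else 0.0
        width = bounds[k + 1] - bounds[k] if k + 1 < len(bounds) else 1.0 - frac
        if k + 1 >= len(bounds):
            width = 1.0
        return float(bounds[k] + within * width)

    def remaining_life_expectancy(self, current_age: float) -> float:
        """E[remaining lifetime] consistent with the sampler (mid-year deaths)."""
        a0 = int(math.floor(current_age))
        frac = current_age - a0
        if a0 < self.min_age or a0 > self.max_age:
            raise InputError(f"age {current_age} outside life-table range")
        lad = self._ladder(a0)
        if frac > 0.0:
            s_now = 1.0 - frac * self.qx[a0 - self.min_age]
            lad = np.minimum(lad / s_now, 1.0)
        probs = lad[:-1] - lad[1:]
        lo = np.concatenate([[0.0], (1.0 - frac) + np.arange(len(probs) - 1)])
        hi = np.concatenate([[1.0 - frac], (1.0 - frac) + np.arange(1, len(probs))])
        return float(np.sum(probs * 0.5 * (lo + hi)))


def background_death_time(table: LifeTable, current_age: float, u: float) -> float:
    """Module-level convenience wrapper around
    :meth:`LifeTable.background_death_time`."""
    return table.background_death_time(current_age, u)


# ----------------------------------------------------------------------
# Maximum-likelihood fitting and information-criterion selection
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    family: str
    params: tuple
    loglik: float
    aic: float = field(default=math.nan)
    bic: float = field(default=math.nan)
    n: int = 0
    n_events: int = 0
    converged: bool = True

    @property
    def n_free_params(self) -> int:
        return _N_PARAMS[self.family]

    def distribution(self) -> ParametricSurvival:
        return ParametricSurvival(self.family, self.params)


def _loglik_vec(family: str, theta: np.ndarray, t: np.ndarray, d: np.ndarray) -> float:
    """Vectorised right-censored log-likelihood.

    ``theta`` is on the natural scale; invalid values return -inf so the
    optimiser (working on log-transformed coordinates) never sees them.
    """
    if family == "exponential":
        (s,) = theta
        if s <= 0:
            return -np.inf
        return float(np.sum(d * (-np.log(s)) - t / s))
    if family == "weibull":
        k, lam = theta
        if k <= 0 or lam <= 0:
            return -np.inf
        logz = k * (np.log(t) - math.log(lam))
        z = np.exp(logz)
        logpdf = math.log(k) - math.log(lam) + (k - 1) * (np.log(t) - math.log(lam)) - z
        return float(np.sum(np.where(d, logpdf, -z)))
    if family == "log-logistic":
        beta, alpha = theta
        if beta <= 0 or alpha <= 0:
            return -np.inf
        logz = beta * (np.log(t) - math.log(alpha))
        log1pz = np.logaddexp(0.0, logz)
        logpdf = (
            math.log(beta)
            - math.log(alpha)
            + (beta - 1) * (np.log(t) - math.log(alpha))
            - 2 * log1pz
        )
        return float(np.sum(np.where(d, logpdf, -log1pz)))
    if family == "log-normal":
        mu, sigma = theta
        if sigma <= 0:
            return -np.inf
        z = (np.log(t) - mu) / sigma
        logpdf = -0.5 * z * z - np.log(t) - math.log(sigma) - 0.5 * math.log(2 * math.pi)
        logsf = special.log_ndtr(-z)
        return float(np.sum(np.where(d, logpdf, logsf)))
    if family == "gompertz":
        b, a = theta
        if b <= 0 or a <= 0:
            return -np.inf
        cumh = (a / b) * np.expm1(b * t)
        logpdf = math.log(a) + b * t - cumh
        return float(np.sum(np.where(d, logpdf, -cumh)))
    raise ParameterError(f"unknown family {family}")


def _init_params(family: str, t: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Moment-style starting values; censoring is ignored at this stage."""
    te = t[d.astype(bool)]
    if te.size == 0:
        te = t
    logt = np.log(te)
    m, sd = float(np.mean(logt)), float(np.std(logt))
    sd = max(sd, 1e-3)
    if family == "exponential":
        return np.array([float(np.sum(t) / max(1, int(np.sum(d))))])
    if family == "weibull":
        k0 = math.pi / (sd * math.sqrt(6.0))
        return np.array([k0, math.exp(m + 0.5772 / k0)])
    if family == "log-logistic":
        return np.array([math.pi / (sd * math.sqrt(3.0)), math.exp(m)])
    if family == "log-normal":
        return np.array([m, sd])
    # gompertz
    mean_t = float(np.mean(te))
    return np.array([0.5 / mean_t, 1.0 / mean_t])


def fit_mle(
    times: Sequence[float],
    events: Sequence[bool],
    family: str,
) -> FitResult:
    """Fit one parametric family to right-censored data by maximum likelihood.

    ``events[i]`` is True for an observed event and False for a
    right-censored observation.  The exponential family uses its closed-form
    MLE; the others are optimised on log-transformed (or (mu, log sigma))
    coordinates with Nelder-Mead.
    """
    family = canonical_family(family)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.size != d.size:
        raise InputError("times and events must be 1-D and the same length")
    if t.size < 10:
        raise InputError(f"need at least 10 observations, got {t.size}")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise InputError("all times must be positive and finite")
    n, n_ev = int(t.size), int(np.sum(d))
    if n_ev == 0:
        raise InputError("all observations censored; parameters not identifiable")

    if family == "exponential":
        scale = float(np.sum(t) / n_ev)
        theta = np.array([scale])
        ll = _loglik_vec(family, theta, t, d.astype(float))
        return _finish(family, theta, ll, n, n_ev)

    dd = d.astype(float)
    theta0 = _init_params(family, t, d)

    if family == "log-normal":
        to_opt = lambda x: np.array([x[0], math.exp(x[1])])
        x0 = np.array([theta0[0], math.log(theta0[1])])
    else:
        to_opt = lambda x: np.exp(x)
        x0 = np.log(theta0)

    def nll(x):
        return -_loglik_vec(family, to_opt(x), t, dd)

    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    if not res.success or not np.isfinite(res.fun):
        raise FitError(
            f"{family} fit did not converge",
            diagnostics={"message": res.message, "nit": res.nit, "x": res.x.tolist()},
        )
    theta = to_opt(res.x)
    return _finish(family, theta, -float(res.fun), n, n_ev)


def _finish(family, theta, ll, n, n_ev) -> FitResult:
    k = _N_PARAMS[family]
    return FitResult(
        family=family,
        params=tuple(float(v) for v in theta),
        loglik=ll,
        aic=2 * k - 2 * ll,
        bic=k * math.log(n) - 2 * ll,
        n=n,
        n_events=n_ev,
    )


def select_model(fits: Sequence[FitResult], criterion: str = "aic") -> FitResult:
    """Pick the fit minimising AIC or BIC.

    Ties are broken by fewer free parameters, then by the fixed family order
    in :data:`FAMILIES`, so selection is deterministic.
    """
    if not fits:
        raise InputError("select_model needs at least one fit")
    if criterion not in ("aic", "bic"):
        raise InputError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    return min(
        fits,
        key=lambda f: (
            getattr(f, criterion),
            f.n_free_params,
            FAMILIES.index(f.family),
        ),
    )


def fit_all_families(times, events, families: Sequence[str] = FAMILIES):
    """Fit every requested family, skipping any that fail to converge."""
    out = []
    for fam in families:
        try:
            out.append(fit_mle(times, events, fam))
        except FitError:
            continue
    if not out:
        raise FitError("no family converged on this data")
    return out
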