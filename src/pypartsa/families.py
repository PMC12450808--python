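"""Parametric survival families in accelerated-failure-time form.

Six families cover the standard extrapolation toolbox for oncology
cost-effectiveness models.  Each family exposes the survival function
S(t), the log density, random sampling, and maps between the natural
parameters and an unconstrained internal scale used by the
maximum-likelihood optimizer (positive parameters are log-transformed).

Parameterizations (t > 0):

====================  =========================================================
exponential           S(t) = exp(-rate * t)
weibull               S(t) = exp(-(t/scale)^shape)
lognormal             S(t) = 1 - Phi((log t - mu) / sigma)
loglogistic           S(t) = 1 / (1 + (t/scale)^shape)
gompertz              S(t) = exp(-(rate/shape) * (exp(shape * t) - 1));
                      shape may be negative, giving a plateau exp(rate/shape)
gengamma              Prentice (mu, sigma, Q); Q -> 0 is lognormal,
                      Q = 1 is Weibull (shape 1/sigma, scale exp(mu)),
                      Q = sigma is the gamma distribution
====================  =========================================================
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np
from scipy import special, stats

__all__ = ["FAMILY_NAMES", "Family", "get_family"]

_GG_Q_EPS = 1e-6  # |Q| below this uses the lognormal limit


class Family(ABC):
    """A parametric survival family.

    Natural parameters are passed around as plain dicts keyed by
    :attr:`param_names`; the internal representation is an unconstrained
    real vector in the same order.
    """

    name: str
    param_names: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    # -- parameter transforms -------------------------------------------------
    @abstractmethod
    def to_internal(self, params: dict[str, float]) -> np.ndarray:
        """Map natural parameters to the unconstrained internal vector."""

    @abstractmethod
    def to_natural(self, x: np.ndarray) -> dict[str, float]:
        """Inverse of :meth:`to_internal`."""

    # -- distribution ---------------------------------------------------------
    @abstractmethod
    def log_sf(self, t: np.ndarray, params: dict[str, float]) -> np.ndarray:
        """log S(t) for t > 0."""

    @abstractmethod
    def log_pdf(self, t: np.ndarray, params: dict[str, float]) -> np.ndarray:
        """log f(t) for t > 0."""

    def sf(self, t, params: dict[str, float]) -> np.ndarray:
        """Survival function; defined as 1 at t = 0."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.ones_like(t)
        pos = t > 0
        if pos.any():
            with np.errstate(all="ignore"):
                out[pos] = np.exp(self.log_sf(t[pos], params))
        return np.clip(out, 0.0, 1.0)

    @abstractmethod
    def rvs(self, params: dict[str, float], size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw event times."""

    @abstractmethod
    def starts(self, times: np.ndarray, events: np.ndarray) -> list[np.ndarray]:
        """Deterministic internal-scale starting points for the optimizer."""

    def validate(self, params: dict[str, float]) -> None:
        missing = set(self.param_names) - set(params)
        if missing:
            raise ValueError(f"{self.name}: missing parameters {sorted(missing)}")
        for k in self.param_names:
            if not np.isfinite(params[k]):
                raise ValueError(f"{self.name}: parameter {k!r} is not finite")


def _event_logmoments(times, events):
    te = times[events == 1]
    if te.size == 0:
        te = times
    lt = np.log(te)
    mu = float(np.mean(lt))
    sd = float(np.std(lt))
    return mu, max(sd, 0.1)


class Exponential(Family):
    name = "exponential"
    param_names = ("rate",)

    def to_internal(self, p):
        return np.array([np.log(p["rate"])])

    def to_natural(self, x):
        return {"rate": float(np.exp(x[0]))}

    def log_sf(self, t, p):
        return -p["rate"] * t

    def log_pdf(self, t, p):
        return np.log(p["rate"]) - p["rate"] * t

    def rvs(self, p, size, rng):
        return rng.exponential(1.0 / p["rate"], size)

    def starts(self, times, events):
        rate = max(events.sum(), 1) / times.sum()
        return [np.array([np.log(rate)])]

    def validate(self, p):
        super().validate(p)
        if p["rate"] <= 0:
            raise ValueError("exponential: rate must be > 0")


class Weibull(Family):
    name = "weibull"
    param_names = ("scale", "shape")

    def to_internal(self, p):
        return np.log([p["scale"], p["shape"]])

    def to_natural(self, x):
        return {"scale": float(np.exp(x[0])), "shape": float(np.exp(x[1]))}

    def log_sf(self, t, p):
        return -((t / p["scale"]) ** p["shape"])

    def log_pdf(self, t, p):
        s, k = p["scale"], p["shape"]
        z = t / s
        return np.log(k / s) + (k - 1) * np.log(z) - z**k

    def rvs(self, p, size, rng):
        return p["scale"] * rng.weibull(p["shape"], size)

    def starts(self, times, events):
        mu, sd = _event_logmoments(times, events)
        # sd(log T) = (pi/sqrt(6)) / shape for Weibull
        k0 = min(max(1.2825 / sd, 0.2), 20.0)
        out = []
        for k in (k0, 1.0):
            out.append(np.array([mu + 0.5772 / k, np.log(k)]))
        return out

    def validate(self, p):
        super().validate(p)
        if p["scale"] <= 0 or p["shape"] <= 0:
            raise ValueError("weibull: scale and shape must be > 0")


class LogNormal(Family):
    name = "lognormal"
    param_names = ("mu", "sigma")

    def to_internal(self, p):
        return np.array([p["mu"], np.log(p["sigma"])])

    def to_natural(self, x):
        return {"mu": float(x[0]), "sigma": float(np.exp(x[1]))}

    def log_sf(self, t, p):
        return stats.norm.logsf((np.log(t) - p["mu"]) / p["sigma"])

    def log_pdf(self, t, p):
        z = (np.log(t) - p["mu"]) / p["sigma"]
        return -np.log(t * p["sigma"] * np.sqrt(2 * np.pi)) - 0.5 * z * z

    def rvs(self, p, size, rng):
        return rng.lognormal(p["mu"], p["sigma"], size)

    def starts(self, times, events):
        mu, sd = _event_logmoments(times, events)
        return [np.array([mu, np.log(sd)])]

    def validate(self, p):
        super().validate(p)
        if p["sigma"] <= 0:
            raise ValueError("lognormal: sigma must be > 0")


class LogLogistic(Family):
    name = "loglogistic"
    param_names = ("scale", "shape")

    def to_internal(self, p):
        return np.log([p["scale"], p["shape"]])

    def to_natural(self, x):
        return {"scale": float(np.exp(x[0])), "shape": float(np.exp(x[1]))}

    def log_sf(self, t, p):
        z = (t / p["scale"]) ** p["shape"]
        return -np.log1p(z)

    def log_pdf(self, t, p):
        s, k = p["scale"], p["shape"]
        lz = k * (np.log(t) - np.log(s))
        return np.log(k / s) + (k - 1) * (np.log(t) - np.log(s)) - 2 * np.logaddexp(0.0, lz)

    def rvs(self, p, size, rng):
        u = rng.uniform(size=size)
        return p["scale"] * (u / (1.0 - u)) ** (1.0 / p["shape"])

    def starts(self, times, events):
        mu, sd = _event_logmoments(times, events)
        # sd(log T) = (pi/sqrt(3)) / shape for log-logistic
        k0 = min(max(1.8138 / sd, 0.2), 20.0)
        return [np.array([mu, np.log(k0)]), np.array([mu, 0.0])]

    def validate(self, p):
        super().validate(p)
        if p["scale"] <= 0 or p["shape"] <= 0:
            raise ValueError("loglogistic: scale and shape must be > 0")


class Gompertz(Family):
    """Gompertz with hazard h(t) = rate * exp(shape * t); shape unconstrained."""

    name = "gompertz"
    param_names = ("shape", "rate")

    def to_internal(self, p):
        return np.array([p["shape"], np.log(p["rate"])])

    def to_natural(self, x):
        return {"shape": float(x[0]), "rate": float(np.exp(x[1]))}

    def _cumhaz(self, t, a, b):
        if abs(a) < 1e-9:
            return b * t
        return (b / a) * np.expm1(a * t)

    def log_sf(self, t, p):
        return -self._cumhaz(t, p["shape"], p["rate"])

    def log_pdf(self, t, p):
        a, b = p["shape"], p["rate"]
        return np.log(b) + a * t - self._cumhaz(t, a, b)

    def rvs(self, p, size, rng):
        a, b = p["shape"], p["rate"]
        u = rng.uniform(size=size)
        if abs(a) < 1e-9:
            return -np.log(u) / b
        arg = 1.0 + (a / b) * (-np.log(u))
        out = np.full(size, np.inf)
        ok = arg > 0
        out[ok] = np.log(arg[ok]) / a
        return out

    def starts(self, times, events):
        b0 = max(events.sum(), 1) / times.sum()
        tbar = float(np.mean(times))
        out = [np.array([a, np.log(b0)]) for a in (0.0, 0.3 / tbar, -0.3 / tbar, 1.0 / tbar)]
        return out

    def validate(self, p):
        super().validate(p)
        if p["rate"] <= 0:
            raise ValueError("gompertz: rate must be > 0")


class GenGamma(Family):
    """Generalized gamma, Prentice parameterization (mu, sigma, Q).

    With w = (log t - mu)/sigma and gamma = Q^-2:
      f(t) = |Q| / (sigma t Gamma(gamma)) * gamma^gamma * exp(gamma (Q w - e^{Q w}))
      S(t) = GammaQ(gamma, gamma e^{Q w})   for Q > 0  (upper regularized)
           = GammaP(gamma, gamma e^{Q w})   for Q < 0
           = Phi(-w)                        for Q = 0 (lognormal limit)
    """

    name = "gengamma"
    param_names = ("mu", "sigma", "Q")

    def to_internal(self, p):
        return np.array([p["mu"], np.log(p["sigma"]), p["Q"]])

    def to_natural(self, x):
        return {"mu": float(x[0]), "sigma": float(np.exp(x[1])), "Q": float(x[2])}

    def log_sf(self, t, p):
        mu, sigma, q = p["mu"], p["sigma"], p["Q"]
        w = (np.log(t) - mu) / sigma
        if abs(q) < _GG_Q_EPS:
            return stats.norm.logsf(w)
        gam = q**-2
        with np.errstate(over="ignore"):
            u = gam * np.exp(q * w)
        if q > 0:
            s = special.gammaincc(gam, u)
        else:
            s = special.gammainc(gam, u)
        with np.errstate(divide="ignore"):
            return np.log(np.clip(s, 0.0, 1.0))

    def log_pdf(self, t, p):
        mu, sigma, q = p["mu"], p["sigma"], p["Q"]
        w = (np.log(t) - mu) / sigma
        if abs(q) < _GG_Q_EPS:
            return -np.log(t * sigma * np.sqrt(2 * np.pi)) - 0.5 * w * w
        gam = q**-2
        with np.errstate(over="ignore"):
            return (
                np.log(abs(q))
                - np.log(sigma * t)
                - special.gammaln(gam)
                + gam * np.log(gam)
                + gam * (q * w - np.exp(q * w))
            )

    def rvs(self, p, size, rng):
        mu, sigma, q = p["mu"], p["sigma"], p["Q"]
        if abs(q) < _GG_Q_EPS:
            return rng.lognormal(mu, sigma, size)
        g = rng.gamma(q**-2, 1.0, size)
        w = np.log(q * q * g) / q
        return np.exp(mu + sigma * w)

    def starts(self, times, events):
        mu, sd = _event_logmoments(times, events)
        return [np.array([mu, np.log(sd), q]) for q in (1.0, 0.5, 1e-3, -0.5)]

    def validate(self, p):
        super().validate(p)
        if p["sigma"] <= 0:
            raise ValueError("gengamma: sigma must be > 0")


_REGISTRY: dict[str, Family] = {
    f.name: f
    for f in (Exponential(), Weibull(), LogNormal(), LogLogistic(), Gompertz(), GenGamma())
}

FAMILY_NAMES: tuple[str, ...] = tuple(_REGISTRY)


def get_family(name: str) -> Family:
    """Look up a family by name; raises ``ValueError`` for unknown names."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown survival family {name!r}; expected one of {sorted(_REGISTRY)}"
        ) from None
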