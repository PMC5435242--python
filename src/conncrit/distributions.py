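"""Candidate distribution models for thresholded degree and node-strength data.

Three continuous families are compared throughout the package:

``restricted``
    A power law in the *distance to an upper bound*,
    ``P(x) = ((gamma+1)/(x_max-x_min)) * ((x_max-x)/(x_max-x_min))**gamma``
    on the finite support ``[x_min, x_max]``.  It encodes scale-free behaviour
    under a hard ceiling on node connectedness (an energy/wiring constraint):
    the variable cannot exceed ``x_max``, and near that bound probability mass
    condenses (``gamma < 0``) or vanishes (``gamma > 0``).

``truncated``
    The exponentially truncated power law
    ``P(x) ∝ x**(alpha-1) * exp(-x/x_c)`` on ``[x_min, ∞)`` — a power law
    whose tail is cut off softly at scale ``x_c``.  The exponential factor is
    implemented with a *decaying* sign; the growing sign is not normalisable
    on an unbounded support (see docs/methods.md).

``powerlaw``
    The Pareto form ``P(x) = ((alpha-1)/x_min) * (x/x_min)**(-alpha)`` on
    ``[x_min, ∞)``, the pure scale-free reference model.

All families are treated as continuous, including when the data are integer
degrees; the same likelihood machinery is applied to both degree and strength
samples.  Each class is an immutable parameter record with ``pdf``, ``cdf``,
``icdf``, ``mean`` and ``sample`` methods; ``sample`` draws by inverse-CDF
transform of uniforms, which is also the simulation primitive used for the
network-cost stability analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import integrate, optimize, special, stats

from .errors import ConfigurationError, ParameterError

__all__ = [
    "RestrictedPowerLaw",
    "TruncatedPowerLaw",
    "PowerLaw",
    "make_model",
    "sample",
    "MODEL_IDS",
]

MODEL_IDS = ("restricted", "truncated", "powerlaw")


def _as_float_array(x):
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class RestrictedPowerLaw:
    """Bounded-support power law ``P(x) ∝ (x_max - x)**gamma`` on [x_min, x_max].

    Parameters
    ----------
    gamma : float
        Scaling exponent; must exceed -1 for the density to be normalisable.
        ``gamma = 0`` recovers the uniform density on the support.
    x_min, x_max : float
        Support bounds, ``x_min < x_max``.
    """

    gamma: float
    x_min: float
    x_max: float

    model_id = "restricted"
    n_params = 2  # gamma and x_max are fitted; x_min is plugged in from data

    def __post_init__(self):
        if not (self.x_min < self.x_max):
            raise ParameterError(
                f"restricted power law requires x_min < x_max, got "
                f"[{self.x_min}, {self.x_max}]"
            )
        if not self.gamma > -1:
            raise ParameterError(
                f"restricted power law requires gamma > -1, got {self.gamma}"
            )

    @property
    def _width(self) -> float:
        return self.x_max - self.x_min

    def pdf(self, x):
        x = _as_float_array(x)
        g, w = self.gamma, self._width
        with np.errstate(divide="ignore", invalid="ignore"):
            dens = (g + 1.0) / w * ((self.x_max - x) / w) ** g
        inside = (x >= self.x_min) & (x <= self.x_max)
        return np.where(inside, dens, 0.0)[()]

    def logpdf(self, x):
        x = _as_float_array(x)
        g, w = self.gamma, self._width
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = math.log(g + 1.0) - math.log(w) + g * np.log((self.x_max - x) / w)
        inside = (x >= self.x_min) & (x <= self.x_max)
        return np.where(inside, lp, -np.inf)[()]

    def cdf(self, x):
        x = _as_float_array(x)
        w = self._width
        core = 1.0 - ((self.x_max - np.clip(x, self.x_min, self.x_max)) / w) ** (
            self.gamma + 1.0
        )
        return np.where(x < self.x_min, 0.0, np.where(x > self.x_max, 1.0, core))[()]

    def icdf(self, u):
        u = _as_float_array(u)
        if np.any((u < 0) | (u > 1)):
            raise ParameterError("icdf argument must lie in [0, 1]")
        x = self.x_max - self._width * (1.0 - u) ** (1.0 / (self.gamma + 1.0))
        return np.clip(x, self.x_min, self.x_max)[()]

    def mean(self) -> float:
        """First moment: ``x_max - (x_max - x_min)*(gamma+1)/(gamma+2)``."""
        g = self.gamma
        return self.x_max - self._width * (g + 1.0) / (g + 2.0)

    def var(self) -> float:
        g, w = self.gamma, self._width
        # E[(x_max - X)^2] = w^2 (g+1)/(g+3); subtract squared first moment.
        return w**2 * (g + 1.0) / (g + 3.0) - (w * (g + 1.0) / (g + 2.0)) ** 2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.icdf(rng.uniform(size=int(n)))

    def to_dict(self) -> dict:
        return {"model": self.model_id, "params": asdict(self)}


def _log_upper_gamma(a: float, z0: float) -> float:
    """``log ∫_{z0}^∞ t**(a-1) e**(-t) dt`` for z0 > 0 and any real a.

    Uses the (log of the) regularised upper incomplete gamma for a > 0,
    an asymptotic expansion when that underflows, and adaptive quadrature
    for a <= 0 where scipy's incomplete gamma is unavailable.
    """
    if z0 <= 0:
        raise ParameterError("lower integration bound must be positive")
    if a > 0:
        q = special.gammaincc(a, z0)
        if q > 1e-280:
            return math.log(q) + special.gammaln(a)
        # Deep tail: Gamma(a, z) ~ z^(a-1) e^(-z) [1 + (a-1)/z + ...]
        corr = 1.0 + (a - 1.0) / z0 + (a - 1.0) * (a - 2.0) / z0**2
        return (a - 1.0) * math.log(z0) - z0 + math.log(max(corr, 1e-300))
    # a <= 0: scipy's incomplete gamma is unavailable.  Split at 1: the tail
    # is a well-behaved quadrature; the near-origin part (where t**(a-1) is
    # steep for small z0) is summed exactly via the alternating series of
    # exp(-t), integrated term by term.
    lower = max(z0, 1.0)
    tail, _ = integrate.quad(lambda t: t ** (a - 1.0) * math.exp(-t), lower, np.inf)
    head = 0.0
    if z0 < 1.0:
        term_sign = 1.0
        fact = 1.0
        for k in range(0, 40):
            if k > 0:
                fact *= k
                term_sign = -term_sign
            ak = a + k
            if ak == 0.0:
                integral = -math.log(z0)
            else:
                integral = (1.0 - z0**ak) / ak
            head += term_sign * integral / fact
    val = head + tail
    if not np.isfinite(val) or val <= 0:
        raise ParameterError(
            f"normalisation integral failed for a={a}, z0={z0}: {val}"
        )
    return math.log(val)


def truncated_log_norm(alpha: float, x_c: float, x_min: float) -> float:
    """Log normalising constant of ``x**(alpha-1) exp(-x/x_c)`` on [x_min, ∞)."""
    if x_c <= 0 or x_min <= 0:
        raise ParameterError("truncated power law requires x_c > 0 and x_min > 0")
    return alpha * math.log(x_c) + _log_upper_gamma(alpha, x_min / x_c)


@dataclass(frozen=True)
class TruncatedPowerLaw:
    """Exponentially truncated power law ``P(x) ∝ x**(alpha-1) e**(-x/x_c)``.

    Support is ``[x_min, ∞)`` with ``x_min > 0``.  For ``alpha > 0`` this is a
    gamma density conditioned on ``x >= x_min``; ``alpha <= 0`` is admissible
    too (the truncation at ``x_min`` keeps the integral finite) and is the
    regime that mimics a decaying pure power law when ``x_c`` is large.
    """

    alpha: float
    x_c: float
    x_min: float

    model_id = "truncated"
    n_params = 2  # alpha and x_c fitted; x_min plugged in from data

    def __post_init__(self):
        if self.x_c <= 0:
            raise ParameterError(f"x_c must be positive, got {self.x_c}")
        if self.x_min <= 0:
            raise ParameterError(f"x_min must be positive, got {self.x_min}")

    @property
    def _log_norm(self) -> float:
        return truncated_log_norm(self.alpha, self.x_c, self.x_min)

    def logpdf(self, x):
        x = _as_float_array(x)
        log_norm = self._log_norm
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = (self.alpha - 1.0) * np.log(x) - x / self.x_c - log_norm
        return np.where(x >= self.x_min, lp, -np.inf)[()]

    def pdf(self, x):
        lp = self.logpdf(x)
        return np.exp(lp)

    def _upper_ratio(self, x):
        """Survival function: Gamma(alpha, x/x_c) / Gamma(alpha, x_min/x_c)."""
        x = np.atleast_1d(_as_float_array(x))
        z0 = self.x_min / self.x_c
        log_g0 = _log_upper_gamma(self.alpha, z0)
        out = np.empty(x.shape)
        for i, xi in enumerate(x.ravel()):
            if xi <= self.x_min:
                out.flat[i] = 1.0
            else:
                lg = _log_upper_gamma(self.alpha, xi / self.x_c)
                out.flat[i] = math.exp(lg - log_g0)
        return out

    def cdf(self, x):
        x = _as_float_array(x)
        res = 1.0 - self._upper_ratio(x)
        return res.reshape(np.shape(x))[()]

    def icdf(self, u):
        u = np.atleast_1d(_as_float_array(u))
        if np.any((u < 0) | (u > 1)):
            raise ParameterError("icdf argument must lie in [0, 1]")
        if self.alpha > 0:
            # Gamma(alpha, scale=x_c) conditioned on x >= x_min; invert through
            # the survival function for accuracy when x_min is deep in the tail.
            g = stats.gamma(a=self.alpha, scale=self.x_c)
            sf0 = g.sf(self.x_min)
            out = g.isf(sf0 * (1.0 - u))
        else:
            out = np.array([self._icdf_root(ui) for ui in u.ravel()]).reshape(u.shape)
        out = np.maximum(out, self.x_min)
        return out[()]

    def _icdf_root(self, u: float) -> float:
        if u <= 0:
            return self.x_min
        hi = self.x_min + self.x_c
        while self.cdf(hi) < u:
            hi = self.x_min + 2.0 * (hi - self.x_min)
            if hi > 1e12 * max(self.x_min, self.x_c):  # pragma: no cover
                break
        return optimize.brentq(
            lambda x: self.cdf(x) - u, self.x_min, hi, xtol=1e-10, rtol=1e-12
        )

    def mean(self) -> float:
        z0 = self.x_min / self.x_c
        return self.x_c * math.exp(
            _log_upper_gamma(self.alpha + 1.0, z0) - _log_upper_gamma(self.alpha, z0)
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.icdf(rng.uniform(size=int(n)))

    def to_dict(self) -> dict:
        return {"model": self.model_id, "params": asdict(self)}


@dataclass(frozen=True)
class PowerLaw:
    """Pareto power law ``P(x) = ((alpha-1)/x_min) (x/x_min)**(-alpha)``."""

    alpha: float
    x_min: float

    model_id = "powerlaw"
    n_params = 1  # alpha fitted; x_min plugged in from data

    def __post_init__(self):
        if not self.alpha > 1:
            raise ParameterError(
                f"power law requires alpha > 1 for a proper density, got {self.alpha}"
            )
        if self.x_min <= 0:
            raise ParameterError(f"x_min must be positive, got {self.x_min}")

    def pdf(self, x):
        x = _as_float_array(x)
        dens = (self.alpha - 1.0) / self.x_min * (x / self.x_min) ** (-self.alpha)
        return np.where(x >= self.x_min, dens, 0.0)[()]

    def logpdf(self, x):
        x = _as_float_array(x)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = (
                math.log(self.alpha - 1.0)
                - math.log(self.x_min)
                - self.alpha * np.log(x / self.x_min)
            )
        return np.where(x >= self.x_min, lp, -np.inf)[()]

    def cdf(self, x):
        x = _as_float_array(x)
        core = 1.0 - (np.maximum(x, self.x_min) / self.x_min) ** (1.0 - self.alpha)
        return np.where(x < self.x_min, 0.0, core)[()]

    def icdf(self, u):
        u = _as_float_array(u)
        if np.any((u < 0) | (u > 1)):
            raise ParameterError("icdf argument must lie in [0, 1]")
        with np.errstate(divide="ignore"):
            out = self.x_min * (1.0 - u) ** (-1.0 / (self.alpha - 1.0))
        return out[()]

    def mean(self) -> float:
        if self.alpha <= 2:
            return math.inf
        return self.x_min * (self.alpha - 1.0) / (self.alpha - 2.0)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.icdf(rng.uniform(size=int(n)))

    def to_dict(self) -> dict:
        return {"model": self.model_id, "params": asdict(self)}


_MODEL_CLASSES = {
    "restricted": RestrictedPowerLaw,
    "truncated": TruncatedPowerLaw,
    "powerlaw": PowerLaw,
}


def make_model(model_id: str, params):
    """Instantiate a model from its identifier and a parameter record.

    ``params`` may be a mapping of field names or an already-built instance
    (returned unchanged after an identity check).
    """
    if isinstance(params, (RestrictedPowerLaw, TruncatedPowerLaw, PowerLaw)):
        if params.model_id != model_id:
            raise ConfigurationError(
                f"parameter record is for {params.model_id!r}, not {model_id!r}"
            )
        return params
    try:
        cls = _MODEL_CLASSES[model_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown model {model_id!r}; expected one of {MODEL_IDS}"
        ) from None
    try:
        return cls(**dict(params))
    except TypeError as exc:
        raise ConfigurationError(
            f"parameter record {params!r} inconsistent with model {model_id!r}: {exc}"
        ) from None


def sample(model_id: str, params, n: int, seed=None, rng=None) -> np.ndarray:
    """Draw ``n`` values from a named model by inverse-CDF sampling."""
    if n < 1:
        raise ParameterError(f"sample size must be >= 1, got {n}")
    model = make_model(model_id, params)
    if rng is None:
        rng = np.random.default_rng(seed)
    return model.sample(n, rng)
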