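"""Synthetic connectivity-matrix generator.

Real functional connectomes are correlation matrices between brain regions:
symmetric, zero-diagonal, entries in (-1, 1), with heterogeneous node
"connectedness" that makes thresholded degree/strength distributions
heavy-tailed yet bounded.  The generator reproduces exactly that structure
from a latent-propensity construction:

1. draw a nonnegative propensity ``f_i`` per node from a configured
   distribution (restricted / truncated / plain power law, or uniform) and
   rescale it to [0, 1];
2. form raw weights ``u_ij = f_i * f_j + eps_ij`` with additive Gaussian
   noise of scale ``noise_sd`` (the noise control: at low thresholds the
   network becomes noise-dominated, as in real data);
3. flip the sign of a configured fraction of entries, so that negative
   correlations occur and the ``|w_ij|`` thresholding rule is exercised;
4. map through the saturating odd function
   ``w = clip_limit * tanh(map_gain * u)``, which guarantees
   correlation-like range without rejection sampling; the gain sets how
   steeply propensity products translate into correlation magnitude, and its
   default keeps the synthetic networks densely connected through the
   intermediate threshold range (fragmentation sets in near r_c ~ 0.6-0.7,
   as in real connectome sweeps);
5. symmetrise and zero the diagonal.

Node strength after thresholding is then a monotone function of ``f_i``, so
a bounded-support propensity law produces bounded, heavy-tailed strength
distributions downstream — the regime the model-selection stage is built to
detect.  Per-matrix random streams are derived from ``(seed, matrix index)``
so collections are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import MODEL_IDS, make_model
from .errors import ConfigurationError
from .metrics import ConnectivityMatrix

__all__ = ["SyntheticConfig", "generate_connectivity", "generate_collection"]

#: Default propensity law: bounded power law at the strength-fit scale of the
#: reference analysis (gamma=2.22, support [0.546, 33.5], rescaled to [0,1]).
DEFAULT_PROPENSITY_PARAMS = {"gamma": 2.22, "x_min": 0.546, "x_max": 33.5}

_PROPENSITY_MODELS = MODEL_IDS + ("uniform",)


@dataclass
class SyntheticConfig:
    """Configuration of one synthetic connectivity-matrix collection.

    ``n_regions`` defaults to 177 (the region count of the reference corpus)
    and ``n_matrices`` to a desk-scale 20.  ``noise_sd`` is the additive
    weight-noise scale; ``sign_flip_fraction`` the share of entries whose
    sign is flipped; ``clip_limit`` bounds ``|w_ij|`` strictly below 1.
    """

    n_regions: int = 177
    n_matrices: int = 20
    propensity_model: str = "restricted"
    propensity_params: dict = field(
        default_factory=lambda: dict(DEFAULT_PROPENSITY_PARAMS)
    )
    noise_sd: float = 0.05
    sign_flip_fraction: float = 0.2
    map_gain: float = 5.0
    clip_limit: float = 0.999
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 3:
            raise ConfigurationError(f"n_regions must be >= 3, got {self.n_regions}")
        if self.n_matrices < 1:
            raise ConfigurationError(f"n_matrices must be >= 1, got {self.n_matrices}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0.0 < self.clip_limit <= 1.0):
            raise ConfigurationError(
                f"clip_limit must lie in (0, 1], got {self.clip_limit}"
            )
        if self.map_gain <= 0:
            raise ConfigurationError(f"map_gain must be positive, got {self.map_gain}")
        if not (0.0 <= self.sign_flip_fraction <= 1.0):
            raise ConfigurationError(
                f"sign_flip_fraction must lie in [0, 1], got {self.sign_flip_fraction}"
            )
        if self.propensity_model not in _PROPENSITY_MODELS:
            raise ConfigurationError(
                f"unknown propensity model {self.propensity_model!r}; "
                f"expected one of {_PROPENSITY_MODELS}"
            )
        # Validate the parameter record eagerly so misconfigurations fail here.
        if self.propensity_model == "uniform":
            low = self.propensity_params.get("low", 0.0)
            high = self.propensity_params.get("high", 1.0)
            if not (0.0 <= low <= high <= 1.0):
                raise ConfigurationError(
                    f"uniform propensity requires 0 <= low <= high <= 1, "
                    f"got [{low}, {high}]"
                )
            extra = set(self.propensity_params) - {"low", "high"}
            if extra:
                raise ConfigurationError(
                    f"unknown uniform propensity fields: {sorted(extra)}"
                )
        else:
            try:
                make_model(self.propensity_model, self.propensity_params)
            except Exception as exc:
                raise ConfigurationError(
                    f"propensity parameters inconsistent with "
                    f"{self.propensity_model!r}: {exc}"
                ) from None


def _matrix_rng(config: SyntheticConfig, index: int) -> np.random.Generator:
    """Independent per-matrix stream keyed by (seed, matrix index)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(int(index),))
    )


def _draw_propensities(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_regions
    if config.propensity_model == "uniform":
        low = config.propensity_params.get("low", 0.0)
        high = config.propensity_params.get("high", 1.0)
        if high == low:
            return np.full(n, float(low))
        return rng.uniform(low, high, size=n)
    model = make_model(config.propensity_model, config.propensity_params)
    x = model.sample(n, rng)
    if config.propensity_model == "restricted":
        # finite analytic support: affine rescale keeps the distribution shape
        return (x - model.x_min) / (model.x_max - model.x_min)
    # unbounded support: scale by the realised maximum
    return x / x.max()


def generate_connectivity(
    config: SyntheticConfig, matrix_index: int = 0
) -> ConnectivityMatrix:
    """Generate one synthetic connectivity matrix.

    Deterministic under ``(config, matrix_index)``; the returned matrix is
    exactly symmetric with zero diagonal and ``|w_ij| < clip_limit``.
    """
    rng = _matrix_rng(config, matrix_index)
    n = config.n_regions
    f = _draw_propensities(config, rng)
    u = np.outer(f, f)
    iu = np.triu_indices(n, k=1)
    upper = u[iu]
    if config.noise_sd > 0:
        upper = upper + rng.normal(0.0, config.noise_sd, size=upper.size)
    if config.sign_flip_fraction > 0:
        flips = rng.random(upper.size) < config.sign_flip_fraction
        upper = np.where(flips, -upper, upper)
    w_upper = config.clip_limit * np.tanh(config.map_gain * upper)
    w = np.zeros((n, n))
    w[iu] = w_upper
    w = w + w.T
    return ConnectivityMatrix(weights=w)


def generate_collection(config: SyntheticConfig) -> list[ConnectivityMatrix]:
    """Generate ``config.n_matrices`` matrices with per-matrix derived seeds."""
    return [
        generate_connectivity(config, matrix_index=i)
        for i in range(config.n_matrices)
    ]
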