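"""Quantile subsampling for noise reduction.

Raw node-statistic samples at low thresholds are noise-dominated.  The
scheme implemented here orders the ``N`` raw values ascending by absolute
value and extracts ``n`` of them at mid-quantile positions of the empirical
cumulative distribution: with step ``d = N/n`` the selected 1-based ranks are

    i' = round_half_up(d * (2i - 1) / 2),   i = 1..n,

clamped to ``[1, N]``, i.e. cumulative positions ``P_c = (2i-1)/(2n)``.
For ``n = 10`` that extracts the values at ``P_c = 0.05, 0.15, ..., 0.95``;
``n = N`` is the identity selection.  Extreme order statistics (the most
noise-sensitive points) are never selected, which is what makes the scheme a
noise-reduction device rather than a plain thinning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["SubsampleScheme", "subsample"]


@dataclass
class SubsampleScheme:
    """Bookkeeping for one subsampling operation."""

    n: int
    N: int
    d: float
    indices: list[int]  # selected 1-based ranks into the sorted sample

    @property
    def positions(self) -> np.ndarray:
        """Empirical cumulative positions ``i'/N`` of the selected ranks."""
        return np.asarray(self.indices, dtype=float) / self.N


def subsample(sample, n: int) -> tuple[np.ndarray, SubsampleScheme]:
    """Extract ``n`` mid-quantile values from a raw sample.

    The sample is sorted ascending by absolute value (stable, so ties keep
    input order) and the ranks described in the module docstring are
    selected.  Returns the selected values and the scheme record.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 1:
        raise ValidationError("subsample expects a one-dimensional sample")
    N = sample.size
    if not (1 <= n <= N):
        raise ValidationError(f"subsample size must satisfy 1 <= n <= N={N}, got {n}")
    order = np.argsort(np.abs(sample), kind="stable")
    sorted_vals = sample[order]
    d = N / n
    i = np.arange(1, n + 1, dtype=float)
    ranks = np.floor(d * (2.0 * i - 1.0) / 2.0 + 0.5).astype(int)  # round half up
    ranks = np.clip(ranks, 1, N)
    values = sorted_vals[ranks - 1]
    scheme = SubsampleScheme(n=int(n), N=int(N), d=float(d), indices=ranks.tolist())
    return values, scheme
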