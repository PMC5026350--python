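"""State duration models.

Three duration families cover the states of the segmentation model:

* motif states occupy exactly their PWM width (a point mass),
* the inter-module (global) background follows a geometric law,
* the intra-module (local) background — the spacer between neighbouring
  binding sites inside a module — follows a negative binomial with an integer
  stopping count r, i.e. the number of Bernoulli trials needed to collect r
  successes of probability 1−π.

For dynamic programming every pmf is truncated at a finite ``max_duration``
and renormalized to sum to one over 1..max_duration.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "motif_duration_pmf",
    "geometric_duration_pmf",
    "negbin_duration_pmf",
    "truncated_geometric_log_pmf",
    "truncated_negbin_log_pmf",
    "geometric_quantile",
    "negbin_quantile",
]


def motif_duration_pmf(w_m: int, u: int) -> float:
    """Point-mass duration of a motif state: 1 iff u equals the width."""
    if w_m < 1 or u < 1:
        raise ValueError("w_m and u must be positive integers")
    return 1.0 if u == w_m else 0.0


def geometric_duration_pmf(p_g: float, u: int) -> float:
    """Geometric duration (1-p_g)^(u-1) * p_g of the global background."""
    if not 0.0 < p_g <= 1.0:
        raise ValueError(f"p_g must be in (0, 1], got {p_g}")
    if u < 1:
        raise ValueError("u must be a positive integer")
    return float(stats.geom.pmf(u, p_g))


def negbin_duration_pmf(r: int, pi: float, u: int) -> float:
    """Negative-binomial duration C(u-1, r-1) pi^(u-r) (1-pi)^r.

    u counts the Bernoulli trials needed for r successes of probability
    1-pi; the pmf is zero for u < r.
    """
    if r < 1 or int(r) != r:
        raise ValueError(f"r must be a positive integer, got {r}")
    if not 0.0 <= pi < 1.0:
        raise ValueError(f"pi must be in [0, 1), got {pi}")
    if u < 1:
        raise ValueError("u must be a positive integer")
    if u < r:
        return 0.0
    # scipy's nbinom counts failures before the r-th success
    return float(stats.nbinom.pmf(u - r, r, 1.0 - pi))


def _renormalized_log(pmf: np.ndarray) -> np.ndarray:
    total = pmf.sum()
    if total <= 0.0:
        raise ValueError("duration pmf has no mass below max_duration")
    with np.errstate(divide="ignore"):
        return np.log(pmf / total)


def truncated_geometric_log_pmf(p_g: float, max_duration: int) -> np.ndarray:
    """log pmf over u = 1..max_duration, renormalized to sum to 1."""
    if max_duration < 1:
        raise ValueError("max_duration must be positive")
    u = np.arange(1, max_duration + 1)
    return _renormalized_log(stats.geom.pmf(u, p_g))


def truncated_negbin_log_pmf(r: int, pi: float, max_duration: int) -> np.ndarray:
    """log pmf over u = 1..max_duration, renormalized to sum to 1."""
    if max_duration < 1:
        raise ValueError("max_duration must be positive")
    if max_duration < r:
        raise ValueError("max_duration below the negative-binomial minimum r")
    u = np.arange(1, max_duration + 1)
    pmf = np.where(u >= r, stats.nbinom.pmf(u - r, r, 1.0 - pi), 0.0)
    return _renormalized_log(pmf)


def geometric_quantile(p_g: float, mass: float = 1.0 - 1e-6) -> int:
    """Smallest u whose cumulative geometric mass reaches ``mass``."""
    return int(stats.geom.ppf(mass, p_g))


def negbin_quantile(r: int, pi: float, mass: float = 1.0 - 1e-6) -> int:
    return int(stats.nbinom.ppf(mass, r, 1.0 - pi)) + r
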