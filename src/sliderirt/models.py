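"""Measurement models for bounded slider responses.

A single-slider (VAS) response partitions the response scale into two
segments (left of the slider, right of the slider); a dual-range slider
(DRS) response partitions it into three (left of the lower bound, the
interval itself, right of the upper bound).  Normalising the segments by
the scale length yields a point on the 2- or 3-simplex, which is modelled
by a beta distribution (beta response model, BRM) or a Dirichlet
distribution (Dirichlet dual-response model, DDRM) whose mean is driven
by latent person parameters through logistic item response functions.

These functions are the single source of truth for both the synthetic
data generator and the inference engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, expit, gammaln

__all__ = [
    "BrmItemParams",
    "DdrmItemParams",
    "vas_components",
    "drs_components",
    "compress",
    "brm_mean",
    "brm_logpdf",
    "ddrm_mean",
    "ddrm_logpdf",
]

_SIMPLEX_ATOL = 1e-12


@dataclass(frozen=True)
class BrmItemParams:
    """Item parameters of the beta response model.

    Attributes
    ----------
    alpha : float
        Scaling (discrimination-like) parameter, > 0.
    delta : float
        Difficulty on the latent scale.
    tau : float
        Precision of the beta distribution, > 0.
    """

    alpha: float
    delta: float
    tau: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


@dataclass(frozen=True)
class DdrmItemParams:
    """Item parameters of the Dirichlet dual-response model.

    The location submodel (driven by the person parameter theta) has
    scaling ``alpha_loc`` and difficulty ``delta_loc``; the width
    submodel (driven by eta) has ``alpha_wid`` and ``delta_wid``.  A
    single precision ``tau`` is shared across the three components.
    """

    alpha_loc: float
    delta_loc: float
    alpha_wid: float
    delta_wid: float
    tau: float

    def __post_init__(self) -> None:
        for name in ("alpha_loc", "alpha_wid", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


def vas_components(value: float, scale_max: float = 100.0) -> np.ndarray:
    """Decompose a single-slider response into its two scale segments.

    Parameters
    ----------
    value : float
        Raw response in ``[0, scale_max]``.
    scale_max : float
        Upper end of the response scale.

    Returns
    -------
    ndarray of shape (2,)
        ``(value/scale_max, 1 - value/scale_max)``.  May touch the
        simplex boundary; apply :func:`compress` before evaluating a
        density.
    """
    value = float(value)
    if not 0.0 <= value <= scale_max:
        raise ValueError(f"value {value} outside [0, {scale_max}]")
    p = value / scale_max
    return np.array([p, 1.0 - p])


def drs_components(low: float, high: float, scale_max: float = 100.0) -> np.ndarray:
    """Decompose a dual-range slider response into its three segments.

    Returns ``(low, high - low, scale_max - high) / scale_max``: the gap
    below the interval, the interval width, and the gap above.  The
    interval midpoint ``(low + high)/2`` and width ``high - low`` are
    recoverable from the components.
    """
    low, high = float(low), float(high)
    if low > high:
        raise ValueError(f"lower bound {low} exceeds upper bound {high}")
    if not (0.0 <= low and high <= scale_max):
        raise ValueError(f"bounds ({low}, {high}) outside [0, {scale_max}]")
    return np.array([low, high - low, scale_max - high]) / scale_max


def compress(components: np.ndarray, n: int, K: int | None = None) -> np.ndarray:
    """Shrink simplex points away from the boundary.

    Applies ``x' = (x * (n - 1) + 1/K) / n`` component-wise, the standard
    remedy for responses at the ends of a bounded scale.  ``n`` is
    conventionally the number of observations in the dataset.

    Works on a single simplex vector or an array whose last axis holds
    the components.
    """
    components = np.asarray(components, dtype=float)
    if n < 2:
        raise ValueError(f"compression requires n >= 2, got {n}")
    if K is None:
        K = components.shape[-1]
    return (components * (n - 1) + 1.0 / K) / n


def brm_mean(theta, item: BrmItemParams):
    """Expected response proportion under the BRM: logistic(alpha * (theta - delta))."""
    return expit(item.alpha * (np.asarray(theta, dtype=float) - item.delta))


def brm_logpdf(x, theta, item: BrmItemParams):
    """Log-density of a compressed VAS response proportion under the BRM.

    ``x ~ Beta(mu * tau, (1 - mu) * tau)`` with ``mu = brm_mean(theta)``,
    so ``E[x] = mu`` and ``tau`` acts as a precision.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("x at or beyond the simplex boundary; apply compress() first")
    mu = brm_mean(theta, item)
    a = mu * item.tau
    b = (1.0 - mu) * item.tau
    return (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - betaln(a, b)


def ddrm_mean(theta, eta, item: DdrmItemParams) -> np.ndarray:
    """Expected simplex components of a DRS response under the DDRM.

    With location ``mu = logistic(alpha_loc * (theta - delta_loc))`` and
    width ``omega = logistic(alpha_wid * (eta - delta_wid))`` the expected
    components are ``(mu * (1 - omega), omega, (1 - mu) * (1 - omega))``.
    The expected midpoint ``mu * (1 - omega) + omega / 2`` increases in
    theta and, as omega approaches 1, is pulled towards the scale centre
    — reproducing the inherent location–width dependency of interval
    responses.
    """
    theta, eta = np.broadcast_arrays(
        np.asarray(theta, dtype=float), np.asarray(eta, dtype=float)
    )
    mu = expit(item.alpha_loc * (theta - item.delta_loc))
    omega = expit(item.alpha_wid * (eta - item.delta_wid))
    return np.stack(
        [mu * (1.0 - omega), omega, (1.0 - mu) * (1.0 - omega)], axis=-1
    )


def ddrm_logpdf(x, theta, eta, item: DdrmItemParams):
    """Log-density of compressed DRS components under the DDRM.

    ``x ~ Dirichlet(m * tau)`` where ``m = ddrm_mean(theta, eta)``, so
    ``E[x] = m``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != 3:
        raise ValueError("DRS components must have three entries on the last axis")
    if np.any(x <= 0.0):
        raise ValueError("component at or beyond the simplex boundary; apply compress() first")
    if np.any(np.abs(x.sum(axis=-1) - 1.0) > 1e-9):
        raise ValueError("components must sum to one")
    shapes = ddrm_mean(theta, eta, item) * item.tau
    return (
        np.sum((shapes - 1.0) * np.log(x), axis=-1)
        - np.sum(gammaln(shapes), axis=-1)
        + gammaln(np.sum(shapes, axis=-1))
    )
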