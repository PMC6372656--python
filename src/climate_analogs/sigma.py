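"""Sigma dissimilarity: ICV-scaled Mahalanobis distance as a chi percentile.

The statistic proceeds in three steps:

1. The Mahalanobis distance ``D = sqrt((x - y)' Σ⁻¹ (x - y))`` between two
   climate 12-vectors, where Σ is the interannual climatic variability (ICV)
   covariance of the focal city. Scaling by ICV makes D unitless and
   independent of the scales of the climate variables.
2. For climates drawn from the ICV distribution itself, D follows a chi
   distribution (square root of chi-squared) with ``n`` degrees of freedom,
   ``n`` being the number of climate dimensions retained in the ICV model.
   ``chi_percentile`` converts D to its percentile under that distribution.
3. The percentile is mapped back to the sigma scale — the chi quantile with
   one degree of freedom — so dissimilarities from ICV models of any
   dimensionality live on a common z-score-like scale. 2σ is the 95th
   percentile of the chi distribution; 4σ the 99.994th.

Percentiles saturate to 1.0 in double precision around 8–9σ, so the
conversion also carries the log survival function, computed in log space,
and inverts from it; past a configured cap (default 12σ) the value is the
cap with ``saturated=True`` rather than a meaningless large number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.special import erfinv, gammaln, ndtri_exp
from scipy.stats import chi

from .errors import SingularityError
from .grids import SeasonalClimateVector, VARIABLE_KEYS
from .stations import ICVModel

_LOG2 = np.log(2.0)

#: Default saturation cap on the sigma scale.
SIGMA_CAP = 12.0


@dataclass(frozen=True)
class Dissimilarity:
    """One sigma-dissimilarity evaluation: D, its percentile, and σ."""

    mahalanobis_d: float
    dof: int
    percentile: float
    log_survival: float
    sigma: float
    saturated: bool


def _as_diff(x, y) -> np.ndarray:
    xv = x.values if isinstance(x, SeasonalClimateVector) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, SeasonalClimateVector) else np.asarray(y, dtype=float)
    return xv - yv


def _cho_factor(icv: ICVModel, ridge: float = 0.0):
    cov = icv.covariance
    if ridge > 0:
        cov = cov + ridge * np.eye(cov.shape[0])
    try:
        return linalg.cho_factor(cov, lower=True)
    except linalg.LinAlgError as exc:
        # name the most collinear variable pair to point at the culprit
        sd = np.sqrt(np.clip(np.diag(cov), 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = cov / np.outer(sd, sd)
        np.fill_diagonal(corr, 0.0)
        corr = np.nan_to_num(corr)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        names = (
            (VARIABLE_KEYS[i], VARIABLE_KEYS[j])
            if icv.basis is None and cov.shape[0] == 12
            else (f"axis {i}", f"axis {j}")
        )
        raise SingularityError(
            "ICV covariance is not positive definite (most collinear pair: "
            f"{names[0]} vs {names[1]}, r = {corr[i, j]:.4f}); "
            "apply PCA truncation or a ridge jitter"
        ) from exc


def mahalanobis_batch(diffs: np.ndarray, icv: ICVModel, ridge: float = 0.0) -> np.ndarray:
    """Mahalanobis distances for an (N, 12) array of climate differences.

    Uses a Cholesky solve, never an explicit inverse. With a PCA-truncated
    ICV model the differences are first projected onto the retained axes.
    """
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    if icv.basis is not None:
        diffs = diffs @ icv.basis
    factor = _cho_factor(icv, ridge)
    solved = linalg.cho_solve(factor, diffs.T)
    return np.sqrt(np.einsum("ij,ji->i", diffs, solved))


def mahalanobis(x, y, icv: ICVModel, ridge: float = 0.0) -> float:
    """ICV-standardized Mahalanobis distance between two climate vectors."""
    return float(mahalanobis_batch(_as_diff(x, y)[None, :], icv, ridge)[0])


def _chi_logsf(d: np.ndarray, n: int) -> np.ndarray:
    """log of the chi survival function, finite even deep in the tail.

    scipy's chi.logsf underflows to -inf once the survival probability drops
    below the smallest double (~D > 38); there an asymptotic expansion of the
    upper incomplete gamma function Q(a, x) ~ x^{a-1} e^{-x} / Γ(a) with
    a = n/2, x = D²/2 keeps the log-survival channel informative.
    """
    d = np.asarray(d, dtype=float)
    out = np.array(chi.logsf(d, n), dtype=float)
    bad = ~np.isfinite(out) & (d > 0)
    if np.any(bad):
        a = n / 2.0
        x = np.atleast_1d(d)[np.atleast_1d(bad)] ** 2 / 2.0
        tail = (a - 1) * np.log(x) - x - gammaln(a) + np.log1p((a - 1) / x + (a - 1) * (a - 2) / x**2)
        if out.ndim == 0:
            out = np.array(tail[0], dtype=float)
        else:
            out[bad] = tail
    return out


def chi_percentile(d, n: int):
    """Percentile of a Mahalanobis distance under the chi distribution.

    Returns ``(p, log_sf)``: the CDF of the chi distribution with ``n``
    degrees of freedom at ``d``, and the log survival function computed in
    log space so that extreme distances remain distinguishable after the CDF
    saturates at 1.0. Scalar in, scalar out.
    """
    if n < 1:
        raise ValueError("degrees of freedom must be >= 1")
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("Mahalanobis distance must be nonnegative")
    p = chi.cdf(d_arr, n)
    log_sf = _chi_logsf(d_arr, n)
    if np.isscalar(d) or d_arr.ndim == 0:
        return float(p), float(log_sf)
    return p, log_sf


def percentile_to_sigma(p=None, log_sf=None, cap: float = SIGMA_CAP):
    """Convert a chi percentile (or its log-survival companion) to sigma.

    σ is the chi quantile with 1 dof of the percentile: the half-normal
    quantile. Two branches keep the full double-precision range: below the
    median, σ = √2·erfinv(p) with p recovered as -expm1(log_sf), accurate
    down to σ ~ 1e-300 (so near-perfect analogs never collapse to exactly
    0σ); above it, the inversion runs in log space
    (σ = -ndtri_exp(log_sf - log 2)), which stays accurate long after ``p``
    rounds to 1.0. Values beyond ``cap`` return the cap with
    ``saturated=True``. Returns ``(sigma, saturated)``; vectorized.
    """
    if log_sf is None:
        if p is None:
            raise ValueError("provide p or log_sf")
        p_arr = np.asarray(p, dtype=float)
        if np.any((p_arr < 0) | (p_arr > 1)):
            raise ValueError("percentile must lie in [0, 1]")
        with np.errstate(divide="ignore"):
            ls = np.log1p(-p_arr)  # -inf where p == 1: handled by the cap below
    else:
        ls = np.asarray(log_sf, dtype=float)
    ls = np.minimum(ls, 0.0)
    scalar = ls.ndim == 0
    ls = np.atleast_1d(ls)

    sigma = np.empty_like(ls)
    finite = np.isfinite(ls)
    p_from_ls = -np.expm1(ls[finite])
    small = p_from_ls < 0.5
    branch = np.empty(p_from_ls.shape)
    branch[small] = np.sqrt(2.0) * erfinv(p_from_ls[small])
    branch[~small] = -ndtri_exp(ls[finite][~small] - _LOG2)
    sigma[finite] = branch
    sigma[~finite] = np.inf
    sigma = np.maximum(sigma, 0.0)
    saturated = sigma > cap
    sigma = np.where(saturated, cap, sigma)
    if scalar:
        return float(sigma[0]), bool(saturated[0])
    return sigma, saturated


def sigma_from_distance(d, n: int, cap: float = SIGMA_CAP):
    """Vectorized D → (sigma, percentile, log_sf, saturated) for ``n`` dof.

    For ``n == 1`` the chi percentile/quantile round trip is the identity,
    so σ = D exactly (capped).
    """
    d_arr = np.asarray(d, dtype=float)
    p = chi.cdf(d_arr, n)
    log_sf = _chi_logsf(d_arr, n)
    if n == 1:
        saturated = d_arr > cap
        sigma = np.where(saturated, cap, d_arr)
    else:
        sigma, saturated = percentile_to_sigma(log_sf=log_sf, cap=cap)
        sigma = np.atleast_1d(sigma)
        saturated = np.atleast_1d(saturated)
        sigma = sigma.reshape(d_arr.shape) if d_arr.ndim else sigma[0]
        saturated = saturated.reshape(d_arr.shape) if d_arr.ndim else saturated[0]
    return sigma, p, log_sf, saturated


def sigma_dissimilarity(x, y, icv: ICVModel, cap: float = SIGMA_CAP) -> Dissimilarity:
    """Full sigma-dissimilarity evaluation between two climate vectors.

    Identical climates give exactly 0σ (a perfect analog); σ ≤ 2 marks a
    representative analog and σ > 4 a novel climate under the thresholds
    used downstream.
    """
    d = mahalanobis(x, y, icv)
    n = icv.retained_dims
    sigma, p, log_sf, saturated = sigma_from_distance(d, n, cap)
    return Dissimilarity(
        mahalanobis_d=d,
        dof=n,
        percentile=float(p),
        log_survival=float(log_sf),
        sigma=float(sigma),
        saturated=bool(saturated),
    )
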