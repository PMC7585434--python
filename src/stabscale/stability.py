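"""Temporal stability and asynchrony partitioning across spatial scales.

Stability at any scale is the temporal mean of a quantity divided by its
temporal standard deviation (invariability).  Writing ``m_ik``/``w_ij,kl``
for the temporal mean of species i's cover in subplot k and the covariance
between the cover series of (i, k) and (j, l), and ``mu_k``/``v_kl`` for the
mean and covariance of community biomass per subplot, the five statistics
for one site-treatment-duration window are::

    species stability    = sum_ik m_ik / sum_ik sqrt(w_ii,kk)
    species asynchrony   = sum_ik sqrt(w_ii,kk) / sum_k sqrt(sum_ij w_ij,kk)
    alpha stability      = sum_k mu_k / sum_k sqrt(v_kk)
    spatial asynchrony   = sum_k sqrt(v_kk) / sqrt(sum_kl v_kl)
    gamma stability      = sum_k mu_k / sqrt(sum_kl v_kl)

Both asynchrony indices are variance-weighted (in)coherence ratios, >= 1 by
the Cauchy-Schwarz inequality, with 1 meaning perfect synchrony.  They chain
the scales multiplicatively: alpha x spatial asynchrony = gamma (same
currency), and species stability x species asynchrony equals the cover-based
alpha stability.  The species asynchrony denominator sums, per subplot, the
full within-subplot species covariance matrix — i.e. the variance of total
community cover in that subplot — which is the only reading that preserves
the multiplicative chain.

Species-level statistics use percent cover; community-level statistics use
live biomass.  A cover-currency mode exists for identity testing.

Optionally each series is detrended by removing its least-squares linear
trend in time; variances/covariances are then computed from residuals while
the means in the numerators remain raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core_io import CommunityTensor
from .exceptions import InsufficientDataError, StabscaleError


class Currency(str, Enum):
    """Which measurement the community-level statistics are computed on."""

    BIOMASS = "biomass"
    COVER = "cover"


@dataclass(frozen=True)
class TemporalMoments:
    """Temporal means and covariances for one window.

    ``m`` has shape (S, K); ``w`` has shape (S, K, S, K) and is symmetric
    under the joint swap (i,k) <-> (j,l); ``mu`` has shape (K,), ``v``
    shape (K, K).  Covariances use the sample denominator n-1.  When
    ``detrended`` is set, ``w`` and ``v`` come from per-series linear-trend
    residuals while ``m`` and ``mu`` stay raw.
    """

    m: np.ndarray
    w: np.ndarray
    mu: np.ndarray
    v: np.ndarray
    n_years: int
    detrended: bool
    community_currency: Currency

    @property
    def n_species(self) -> int:
        return self.m.shape[0]

    @property
    def n_subplots(self) -> int:
        return self.m.shape[1]


@dataclass(frozen=True)
class StabilitySet:
    """The five stability/asynchrony statistics for one window.

    Zero denominators are flagged as ``inf`` rather than raised: a constant
    total series means infinite invariability, which the log-transform step
    later drops with a counted warning.
    """

    species_stability: float
    species_asynchrony: float
    alpha_stability: float
    spatial_asynchrony: float
    gamma_stability: float
    detrended: bool
    community_currency: Currency

    def as_dict(self) -> dict:
        return {
            "species_stability": self.species_stability,
            "species_asynchrony": self.species_asynchrony,
            "alpha_stability": self.alpha_stability,
            "spatial_asynchrony": self.spatial_asynchrony,
            "gamma_stability": self.gamma_stability,
        }

    @property
    def has_nonfinite(self) -> bool:
        return not all(np.isfinite(list(self.as_dict().values())))


def detrend_series(series) -> np.ndarray:
    """Residuals of an ordinary least-squares fit of value on year index.

    Requires at least 3 time points; residuals have mean 0 by construction.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise InsufficientDataError(
            f"detrending needs >= 3 time points, got {y.size}"
        )
    t = np.arange(y.size, dtype=float)
    coef = np.polynomial.polynomial.polyfit(t, y, 1)
    return y - np.polynomial.polynomial.polyval(t, coef)


def _residual_matrix(series: np.ndarray) -> np.ndarray:
    """Detrend each row of a (series, time) matrix in one least-squares solve."""
    n = series.shape[1]
    t = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), t])
    # hat residual-maker applied from the right: R = Y (I - X (X'X)^-1 X')
    proj = X @ np.linalg.solve(X.T @ X, X.T)
    return series @ (np.eye(n) - proj)


def temporal_moments(
    tensor: CommunityTensor,
    detrend: bool = False,
    community_currency: Currency = Currency.BIOMASS,
) -> TemporalMoments:
    """Compute all temporal means and (co)variances for one window.

    Covariances use denominator n-1.  With ``community_currency=COVER`` the
    community series are the per-subplot totals of summed cover instead of
    biomass (used for identity checks between the species- and
    community-level statistics).
    """
    community_currency = Currency(community_currency)
    S, K, Y = tensor.cover.shape
    if Y < 2:
        raise InsufficientDataError("need >= 2 years for temporal moments")

    flat = tensor.cover.reshape(S * K, Y)
    m = flat.mean(axis=1).reshape(S, K)

    if community_currency is Currency.BIOMASS:
        comm = tensor.biomass.astype(float)
    else:
        comm = tensor.cover.sum(axis=0).astype(float)
    mu = comm.mean(axis=1)

    if detrend:
        if Y < 3:
            raise InsufficientDataError("detrending needs >= 3 years")
        flat_c = _residual_matrix(flat)
        comm_c = _residual_matrix(comm)
    else:
        flat_c = flat - flat.mean(axis=1, keepdims=True)
        comm_c = comm - comm.mean(axis=1, keepdims=True)

    w = (flat_c @ flat_c.T) / (Y - 1)
    v = (comm_c @ comm_c.T) / (Y - 1)
    return TemporalMoments(
        m=m,
        w=w.reshape(S, K, S, K),
        mu=mu,
        v=v,
        n_years=Y,
        detrended=detrend,
        community_currency=community_currency,
    )


def _safe_ratio(num: float, den: float) -> float:
    if den <= 0.0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def stability_partition(moments: TemporalMoments) -> StabilitySet:
    """Assemble the five stability/asynchrony statistics from moments.

    Raises if a summed covariance is numerically below -1e-12 (impossible for
    a variance of a sum); tiny negative round-off is clipped to zero.
    """
    S, K = moments.n_species, moments.n_subplots
    w = moments.w.reshape(S * K, S * K)
    diag_w = np.diag(w).copy()
    diag_w[diag_w < 0] = 0.0
    sd_species = np.sqrt(diag_w)

    # within-subplot community cover variance: sum_ij w_ij,kk
    w4 = moments.w
    comm_cover_var = np.array([w4[:, k, :, k].sum() for k in range(K)])
    if np.any(comm_cover_var < -1e-12):
        raise StabscaleError(
            "within-subplot community cover variance is negative: "
            f"{comm_cover_var.min()!r}"
        )
    comm_cover_var = np.clip(comm_cover_var, 0.0, None)

    v = moments.v
    diag_v = np.clip(np.diag(v), 0.0, None)
    total_v = float(v.sum())
    if total_v < -1e-12:
        raise StabscaleError(f"total community covariance negative: {total_v!r}")
    total_v = max(total_v, 0.0)

    species_stability = _safe_ratio(float(moments.m.sum()), float(sd_species.sum()))
    species_asynchrony = _safe_ratio(
        float(sd_species.sum()), float(np.sqrt(comm_cover_var).sum())
    )
    alpha_stability = _safe_ratio(float(moments.mu.sum()), float(np.sqrt(diag_v).sum()))
    spatial_asynchrony = _safe_ratio(
        float(np.sqrt(diag_v).sum()), float(np.sqrt(total_v))
    )
    gamma_stability = _safe_ratio(float(moments.mu.sum()), float(np.sqrt(total_v)))

    return StabilitySet(
        species_stability=species_stability,
        species_asynchrony=species_asynchrony,
        alpha_stability=alpha_stability,
        spatial_asynchrony=spatial_asynchrony,
        gamma_stability=gamma_stability,
        detrended=moments.detrended,
        community_currency=moments.community_currency,
    )


def stability_set(
    tensor: CommunityTensor,
    detrend: bool = False,
    community_currency: Currency = Currency.BIOMASS,
) -> StabilitySet:
    """Convenience wrapper: moments then partition for one tensor."""
    return stability_partition(
        temporal_moments(tensor, detrend=detrend, community_currency=community_currency)
    )


def log_transform_set(values):
    """Natural-log transform stability/asynchrony values for analysis.

    Accepts a :class:`StabilitySet`, a mapping, or an array of positive
    reals.  Non-finite or non-positive entries become NaN; a single warning
    reports how many were dropped.  Returns the same shape/keys as the
    input (a dict for a StabilitySet).
    """
    if isinstance(values, StabilitySet):
        values = values.as_dict()
    if isinstance(values, dict):
        keys = list(values)
        arr = np.array([values[k] for k in keys], dtype=float)
    else:
        keys = None
        arr = np.asarray(values, dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        bad = ~np.isfinite(arr) | (arr <= 0)
        out = np.where(bad, np.nan, np.log(np.where(bad, 1.0, arr)))
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(
            f"log transform dropped {n_bad} non-positive/non-finite value(s)",
            stacklevel=2,
        )
    if keys is not None:
        return dict(zip(keys, out.tolist()))
    return out
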