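"""Local (alpha) diversity indices and the multiplicative beta/gamma partition.

Each 1 m^2 subplot is a "community"; the replicated subplots of a site are
the "larger scale".  Local indices (richness, Shannon-Weaver H in nats,
inverse Simpson D, Pielou evenness J) are computed per subplot and averaged,
giving one value per site-treatment-duration.  Abundance-based gamma
diversity is the inverse Simpson of the subplots pooled by summing cover,
and multiplicative beta diversity is gamma divided by the mean local inverse
Simpson, so 1 <= beta <= K with beta = 1 for identical relative compositions.

Two bases are offered for abundance-weighted indices, because "one value per
duration window" can be reached by either route:

* ``TIME_MEAN_COVER`` (default): indices on each subplot's species-wise
  temporal mean cover over the window.
* ``ANNUAL_THEN_AVERAGE``: indices per subplot-year, then averaged over years.

Richness is always the annual species count averaged over years and subplots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core_io import CommunityTensor
from .exceptions import DegenerateInputError


class Basis(str, Enum):
    """Averaging basis for abundance-weighted diversity indices."""

    TIME_MEAN_COVER = "time-mean"
    ANNUAL_THEN_AVERAGE = "annual"


@dataclass(frozen=True)
class DiversitySet:
    """Diversity indices for one site-treatment-duration window."""

    richness: float
    shannon: float
    inv_simpson: float
    evenness: float
    gamma_inv_simpson: float
    beta_multiplicative: float
    basis: Basis


def _relative(abundances: np.ndarray) -> np.ndarray:
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise DegenerateInputError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero abundance vector")
    return a / total


def shannon_index(relative_abundances) -> float:
    """Shannon-Weaver index H = -sum(p ln p), in nats; zeros are skipped."""
    p = _relative(relative_abundances)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def inverse_simpson(relative_abundances) -> float:
    """Inverse Simpson index D = 1 / sum(p^2); 1 <= D <= number of species."""
    p = _relative(relative_abundances)
    return float(1.0 / (p**2).sum())


def _per_subplot_abundances(tensor: CommunityTensor, basis: Basis):
    """Yield per-subplot abundance vectors on the chosen basis.

    TIME_MEAN_COVER yields one vector per subplot (temporal means);
    ANNUAL_THEN_AVERAGE yields (subplot, list-of-annual-vectors).
    """
    if basis is Basis.TIME_MEAN_COVER:
        return [tensor.cover[:, k, :].mean(axis=1) for k in range(tensor.n_subplots)]
    return [
        [tensor.cover[:, k, y] for y in range(tensor.n_years)]
        for k in range(tensor.n_subplots)
    ]


def local_diversity(
    tensor: CommunityTensor, basis: Basis = Basis.TIME_MEAN_COVER
) -> tuple[float, float, float, float]:
    """Mean local richness, Shannon H, inverse Simpson D, and evenness J.

    Richness is the number of species with positive cover, averaged over
    subplot-years.  H and D are averaged over subplots (and over years first
    under ``ANNUAL_THEN_AVERAGE``).  Evenness is J = mean H / ln(mean
    richness); it is undefined (NaN, with a warning) when mean richness is 1.
    """
    basis = Basis(basis)
    richness = float((tensor.cover > 0).sum(axis=0).mean())

    h_vals, d_vals = [], []
    if basis is Basis.TIME_MEAN_COVER:
        for vec in _per_subplot_abundances(tensor, basis):
            h_vals.append(shannon_index(vec))
            d_vals.append(inverse_simpson(vec))
    else:
        for annual in _per_subplot_abundances(tensor, basis):
            h_vals.append(float(np.mean([shannon_index(v) for v in annual])))
            d_vals.append(float(np.mean([inverse_simpson(v) for v in annual])))
    shannon = float(np.mean(h_vals))
    inv_simp = float(np.mean(d_vals))

    if richness <= 1.0:
        warnings.warn(
            "mean richness <= 1: Pielou evenness undefined, returning NaN",
            stacklevel=2,
        )
        evenness = float("nan")
    else:
        evenness = shannon / float(np.log(richness))
    return richness, shannon, inv_simp, evenness


def gamma_beta_diversity(
    tensor: CommunityTensor, basis: Basis = Basis.TIME_MEAN_COVER
) -> tuple[float, float]:
    """Abundance-based gamma diversity and multiplicative beta diversity.

    Gamma is the inverse Simpson of species covers pooled (summed) across
    subplots; beta = gamma / mean local inverse Simpson.
    """
    basis = Basis(basis)
    if basis is Basis.TIME_MEAN_COVER:
        per = _per_subplot_abundances(tensor, basis)
        pooled = np.sum(per, axis=0)
        gamma = inverse_simpson(pooled)
        local = float(np.mean([inverse_simpson(v) for v in per]))
    else:
        gammas, locals_ = [], []
        for y in range(tensor.n_years):
            vecs = [tensor.cover[:, k, y] for k in range(tensor.n_subplots)]
            gammas.append(inverse_simpson(np.sum(vecs, axis=0)))
            locals_.append(np.mean([inverse_simpson(v) for v in vecs]))
        gamma = float(np.mean(gammas))
        local = float(np.mean(locals_))
    return gamma, gamma / local


def diversity_set(
    tensor: CommunityTensor, basis: Basis = Basis.TIME_MEAN_COVER
) -> DiversitySet:
    """All diversity indices for one window, as a :class:`DiversitySet`."""
    basis = Basis(basis)
    richness, shannon, inv_simp, evenness = local_diversity(tensor, basis)
    gamma, beta = gamma_beta_diversity(tensor, basis)
    return DiversitySet(
        richness=richness,
        shannon=shannon,
        inv_simpson=inv_simp,
        evenness=evenness,
        gamma_inv_simpson=gamma,
        beta_multiplicative=beta,
        basis=basis,
    )
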