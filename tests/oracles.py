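"""Independent brute-force reference implementations used by the tests.

Everything here is written with explicit loops and textbook formulas,
deliberately sharing no code path with the package (no reshapes, no matrix
covariance calls), so agreement is a real cross-check.
"""

from __future__ import annotations

import math

import numpy as np


def mean(xs):
    return sum(xs) / len(xs)


def cov(a, b):
    """Sample covariance with denominator n - 1, by explicit summation."""
    n = len(a)
    ma, mb = mean(a), mean(b)
    return sum((a[t] - ma) * (b[t] - mb) for t in range(n)) / (n - 1)


def ols_residuals(y):
    """Residuals of y on time index via closed-form simple regression."""
    n = len(y)
    t = list(range(n))
    mt, my = mean(t), mean(y)
    sxx = sum((ti - mt) ** 2 for ti in t)
    slope = sum((t[i] - mt) * (y[i] - my) for i in range(n)) / sxx
    intercept = my - slope * mt
    return [y[i] - (intercept + slope * t[i]) for i in range(n)]


def brute_stability(cover, biomass, detrend=False):
    """All five stability/asynchrony statistics by covariance expansion.

    cover: (S, K, Y) array; biomass: (K, Y) array.  Species statistics use
    cover, community statistics use biomass.
    """
    S, K, Y = cover.shape

    def series(i, k):
        s = [float(cover[i, k, t]) for t in range(Y)]
        return ols_residuals(s) if detrend else s

    def bseries(k):
        s = [float(biomass[k, t]) for t in range(Y)]
        return ols_residuals(s) if detrend else s

    # species-level: numerators from raw means even when detrending
    m_sum = sum(float(cover[i, k, t]) for i in range(S) for k in range(K)
                for t in range(Y)) / Y
    sd_sum = 0.0
    for i in range(S):
        for k in range(K):
            s = series(i, k)
            sd_sum += math.sqrt(max(cov(s, s), 0.0))
    species_stability = m_sum / sd_sum if sd_sum > 0 else float("inf")

    comm_sd_sum = 0.0
    for k in range(K):
        var_k = 0.0
        for i in range(S):
            for j in range(S):
                var_k += cov(series(i, k), series(j, k))
        comm_sd_sum += math.sqrt(max(var_k, 0.0))
    species_asynchrony = sd_sum / comm_sd_sum if comm_sd_sum > 0 else float("inf")

    mu_sum = sum(float(biomass[k, t]) for k in range(K) for t in range(Y)) / Y
    v_sd_sum = 0.0
    total_v = 0.0
    for k in range(K):
        v_sd_sum += math.sqrt(max(cov(bseries(k), bseries(k)), 0.0))
        for l in range(K):
            total_v += cov(bseries(k), bseries(l))
    total_sd = math.sqrt(max(total_v, 0.0))
    alpha_stability = mu_sum / v_sd_sum if v_sd_sum > 0 else float("inf")
    gamma_stability = mu_sum / total_sd if total_sd > 0 else float("inf")
    spatial_asynchrony = v_sd_sum / total_sd if total_sd > 0 else float("inf")

    return {
        "species_stability": species_stability,
        "species_asynchrony": species_asynchrony,
        "alpha_stability": alpha_stability,
        "spatial_asynchrony": spatial_asynchrony,
        "gamma_stability": gamma_stability,
    }


def brute_diversity(cover):
    """Richness / Shannon / inverse Simpson / evenness / gamma / beta on
    time-mean covers, by explicit per-subplot loops."""
    S, K, Y = cover.shape
    richness = mean(
        [sum(1 for i in range(S) if cover[i, k, t] > 0)
         for k in range(K) for t in range(Y)]
    )
    h_list, d_list, pooled = [], [], [0.0] * S
    for k in range(K):
        tm = [mean([float(cover[i, k, t]) for t in range(Y)]) for i in range(S)]
        tot = sum(tm)
        p = [x / tot for x in tm]
        h_list.append(-sum(pi * math.log(pi) for pi in p if pi > 0))
        d_list.append(1.0 / sum(pi * pi for pi in p))
        for i in range(S):
            pooled[i] += tm[i]
    tot = sum(pooled)
    pp = [x / tot for x in pooled]
    gamma = 1.0 / sum(pi * pi for pi in pp)
    local_d = mean(d_list)
    shannon = mean(h_list)
    evenness = shannon / math.log(richness) if richness > 1 else float("nan")
    return {
        "richness": richness,
        "shannon": shannon,
        "inv_simpson": local_d,
        "evenness": evenness,
        "gamma": gamma,
        "beta": gamma / local_d,
    }


def zscore(x):
    x = np.asarray(x, dtype=float)
    return (x - x.mean()) / x.std(ddof=1)


def normal_equation_fit(y, X_cols):
    """Standardized coefficients and SEs by direct normal-equation solve."""
    yz = zscore(y)
    Xz = np.column_stack([np.ones(len(yz))] + [zscore(c) for c in X_cols])
    beta = np.linalg.solve(Xz.T @ Xz, Xz.T @ yz)
    resid = yz - Xz @ beta
    n, p = Xz.shape
    sigma2 = float(resid @ resid) / (n - p)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(Xz.T @ Xz)))
    return beta[1:], se[1:]


def random_tensor(rng, n_species=None, n_subplots=None, n_years=None):
    """A random positive CommunityTensor for property tests."""
    from stabscale import CommunityTensor

    S = n_species or int(rng.integers(2, 11))
    K = n_subplots or int(rng.integers(2, 4))
    Y = n_years or int(rng.integers(4, 10))
    cover = rng.lognormal(1.0, 0.8, size=(S, K, Y))
    biomass = rng.lognormal(5.0, 0.4, size=(K, Y))
    return CommunityTensor(
        site_id="t",
        treatment="Control",
        duration_years=Y,
        species_list=tuple(f"sp{i}" for i in range(S)),
        subplots=tuple(range(1, K + 1)),
        cover=cover,
        biomass=biomass,
    )


def synchronous_tensor(rng, n_species=3, n_subplots=3, n_years=6):
    """Perfectly synchronous construction: every series proportional to one
    positive year profile, so both asynchrony indices equal exactly 1."""
    from stabscale import CommunityTensor

    profile = rng.lognormal(0.0, 0.5, size=n_years)
    sp_scale = rng.lognormal(1.0, 0.5, size=(n_species, n_subplots))
    k_scale = rng.lognormal(4.0, 0.3, size=n_subplots)
    cover = sp_scale[:, :, None] * profile[None, None, :]
    biomass = k_scale[:, None] * profile[None, :]
    return CommunityTensor(
        site_id="sync",
        treatment="Control",
        duration_years=n_years,
        species_list=tuple(f"sp{i}" for i in range(n_species)),
        subplots=tuple(range(1, n_subplots + 1)),
        cover=cover,
        biomass=biomass,
    )
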