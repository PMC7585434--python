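"""Synthetic multi-site grassland cover/biomass generator with ground truth.

Emulates the data structure of a replicated nutrient-addition experiment:
~42 sites x 3 subplots x 2 treatments (Control vs. NPK) x 4-9 post-treatment
years, with a richness gradient across sites, compositional turnover among
subplots, shared interannual environmental fluctuation with species-specific
responses, and configurable fertilization effects (loss of rare species,
biomass increase, homogenization of species responses, and a
richness-dependent amplification of the shared environmental response that
destabilizes species dynamics most in species-rich communities).

Generative model, per site and treatment arm::

    ln cover[i,k,t] = ln(mean[i,k]) - V/2 + e[k,t] + tau * eta[i,t]
                      + sigma * z[i,k,t]

where ``V`` is the arm's total log-scale variance, so the generative
expectation of cover is exactly ``mean[i,k]`` (times the fertilized
multiplier) in every arm.

* ``mean_i`` — lognormal species mean covers (percent; totals may exceed
  100 and are never renormalized).
* ``e[k,t]`` — subplot-year environment, sd ``env_sd``, correlated across
  the K subplots with coefficient ``rho_space`` (a site-level fluctuation
  shared by all subplots plus a subplot-specific part).
* ``eta[i,t]`` — species-specific response to the year, shared by every
  subplot where species i occurs; its weight ``tau_b`` is the species
  response heterogeneity.  A shared environmental series merely *scaled*
  per species would leave all log-series perfectly correlated, so the
  heterogeneous response must enter as an additive species-year component;
  this is what makes richer communities more asynchronous and makes
  compositionally distinct subplots fluctuate out of phase.
* ``z[i,k,t]`` — independent residual noise, sd ``sigma``.

Each subplot's community is a weighted sample from the site pool: a core
drawn once and shared by all subplots (fraction ``omega`` of the local
richness) plus subplot-specific extras; ``omega = 1`` gives identical
compositions.  Because abundance-based beta diversity is driven by turnover
of the *dominant* species (presence turnover of rare extras barely moves
it), compositional overlap also controls which species occupy the abundant
niches: per subplot, each species joins a reshuffle set with probability
``1 - omega`` and the mean covers are permuted within that set.  Every
subplot then carries the same abundance spectrum (equal expected totals and
community variances, so the variance-weighted asynchrony indices respond to
correlation rather than scale imbalance) but different species in the
dominant roles.  Lower overlap thus raises multiplicative beta diversity
and — through the species-specific responses — decorrelates subplot
dynamics.  The niche assignment is shared between arms.
Fertilized communities drop the rarest species (expected
count ``richness_loss`` per subplot), have species means multiplied by
``biomass_multiplier``, response heterogeneity shrunk by ``1 - homogenization``,
and their shared environmental response amplified by ``fert_destabilization``
scaled to the site's position on the richness gradient: a built-in
treatment x richness interaction that lowers species stability (and, because
the added variance is common to all species, synchronizes them) most at
species-rich sites.

Subplot biomass is proportional to summed cover with small multiplicative
noise.  Environmental series are drawn independently for the two arms, so
treatment contrasts are well calibrated under a null configuration.

The random draw order is fixed and documented (per site: pool -> overlap ->
compositions -> niche assignment -> per arm [environment -> species
responses -> richness-loss counts -> cover noise -> biomass noise];
climate covariates last), and each
site consumes an independent child stream of the seed, so outputs are
byte-identical for a given config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import BIOMASS_COLUMNS, COVER_COLUMNS
from .exceptions import ConfigError

PRESETS = ("control_like", "fertilized_like", "null_world")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the generator; defaults are the study-like
    conditions (42 sites, 3 subplots, 9 years, fertilization effects on)."""

    n_sites: int = 42
    n_subplots: int = 3
    n_years: int = 9
    richness_range: tuple = (8, 28)  # site species-pool sizes (inclusive)
    local_fraction: float = 0.75  # subplot richness as a fraction of the pool
    abundance_meanlog: float = 1.3  # lognormal species mean cover (percent)
    abundance_sdlog: float = 1.0
    env_sd: float = 0.15  # interannual environmental sd (log scale)
    rho_space: float = 0.15  # cross-subplot environmental correlation
    tau_b: float = 0.8  # species response heterogeneity
    sigma: float = 0.15  # residual noise sd (log scale)
    omega: tuple = (0.3, 0.95)  # compositional overlap among subplots
    richness_loss: float = 1.8  # expected species dropped per fertilized subplot
    biomass_multiplier: float = 1.3  # fertilized mean-cover multiplier
    homogenization: float = 0.8  # shrinkage of tau_b under fertilization
    fert_destabilization: float = 1.0  # richness-scaled env amplification when fertilized
    drop_rarest: bool = True  # drop rarest first (False: drop at random)
    mass_per_cover: float = 4.0  # g m^-2 biomass per percent summed cover
    biomass_noise: float = 0.1  # multiplicative biomass noise sd
    seed: int = 0

    def __post_init__(self):
        lo, hi = self._omega_range()
        checks = [
            (self.n_sites >= 1, "n_sites >= 1"),
            (self.n_subplots >= 2, "n_subplots >= 2"),
            (self.n_years >= 2, "n_years >= 2"),
            (2 <= self.richness_range[0] <= self.richness_range[1],
             "richness_range increasing, min >= 2"),
            (0 < self.local_fraction <= 1, "local_fraction in (0, 1]"),
            (0 <= lo <= hi <= 1, "omega in [0, 1]"),
            (0 <= self.rho_space <= 1, "rho_space in [0, 1]"),
            (self.tau_b >= 0, "tau_b >= 0"),
            (self.sigma >= 0, "sigma >= 0"),
            (self.env_sd >= 0, "env_sd >= 0"),
            (self.richness_loss >= 0, "richness_loss >= 0"),
            (self.biomass_multiplier > 0, "biomass_multiplier > 0"),
            (0 <= self.homogenization <= 1, "homogenization in [0, 1]"),
            (self.fert_destabilization >= 0, "fert_destabilization >= 0"),
            (self.mass_per_cover > 0, "mass_per_cover > 0"),
            (self.biomass_noise >= 0, "biomass_noise >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(f"invalid SyntheticConfig: requires {msg}")

    def _omega_range(self) -> tuple:
        if isinstance(self.omega, (int, float)):
            return (float(self.omega), float(self.omega))
        lo, hi = self.omega
        return (float(lo), float(hi))

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated tables plus the ground truth that produced them."""

    cover: pd.DataFrame
    biomass: pd.DataFrame
    climate: pd.DataFrame
    truth: dict

    def truth_json(self) -> str:
        return json.dumps(self.truth, indent=2, sort_keys=True)


def preset(name: str) -> SyntheticConfig:
    """Named study conditions.

    * ``control_like`` — strong species-response heterogeneity, no
      fertilization effects in either arm (the NPK arm is a statistical
      replicate of the control): diversity stabilizes at both scales.
    * ``fertilized_like`` — the NPK arm loses ~1.8 species per subplot,
      gains 30% biomass, has response heterogeneity shrunk by 80%, and is
      destabilized in proportion to site richness.
    * ``null_world`` — no response heterogeneity and full compositional
      overlap: no diversity-stability relationship and no treatment effect.
    """
    if name == "control_like":
        return SyntheticConfig(
            richness_loss=0.0,
            biomass_multiplier=1.0,
            homogenization=0.0,
            fert_destabilization=0.0,
        )
    if name == "fertilized_like":
        return SyntheticConfig()
    if name == "null_world":
        return SyntheticConfig(
            tau_b=0.0,
            omega=1.0,
            richness_loss=0.0,
            biomass_multiplier=1.0,
            homogenization=0.0,
            fert_destabilization=0.0,
        )
    raise ConfigError(
        f"unknown preset {name!r}; available presets: {', '.join(PRESETS)}"
    )


def _weighted_sample(rng, candidates, weights, size):
    w = np.asarray(weights, dtype=float)
    p = w / w.sum()
    return rng.choice(candidates, size=size, replace=False, p=p)


def _site_environment(rng, cfg: SyntheticConfig):
    """Subplot-year environment with cross-subplot correlation rho_space."""
    K, T = cfg.n_subplots, cfg.n_years
    shared = rng.normal(0.0, 1.0, size=T)
    own = rng.normal(0.0, 1.0, size=(K, T))
    r = cfg.rho_space
    return cfg.env_sd * (np.sqrt(r) * shared[None, :] + np.sqrt(1.0 - r) * own)


def _arm_cover(
    rng,
    cfg: SyntheticConfig,
    mean_surface: np.ndarray,
    communities: list,
    fertilized: bool,
    rich_norm: float,
):
    """Cover array (P, K, T) for one treatment arm; absent species are 0.

    ``mean_surface`` is the (P, K) matrix of per-subplot species mean covers.
    """
    P, K = mean_surface.shape
    T = cfg.n_years
    site_means = mean_surface.mean(axis=1)  # for rarest-first dropping
    tau = cfg.tau_b * ((1.0 - cfg.homogenization) if fertilized else 1.0)
    sigma = cfg.sigma
    env_amp = (
        1.0 + cfg.fert_destabilization * rich_norm if fertilized else 1.0
    )
    mean_mult = cfg.biomass_multiplier if fertilized else 1.0

    # draw order within an arm: environment -> species responses ->
    # richness-loss counts -> residual noise -> biomass noise
    env = env_amp * _site_environment(rng, cfg)  # (K, T)
    eta = rng.normal(0.0, 1.0, size=(P, T))  # species-year responses

    communities = [np.array(sorted(c), dtype=int) for c in communities]
    if fertilized and cfg.richness_loss > 0:
        kept = []
        for comm in communities:
            n_drop = min(int(rng.poisson(cfg.richness_loss)), comm.size - 2)
            if n_drop > 0:
                if cfg.drop_rarest:
                    order = comm[np.argsort(site_means[comm])]  # rarest first
                    drop = set(order[:n_drop].tolist())
                else:
                    drop = set(rng.choice(comm, size=n_drop, replace=False).tolist())
                comm = np.array([s for s in comm if s not in drop], dtype=int)
            kept.append(comm)
        communities = kept

    noise = rng.normal(0.0, 1.0, size=(P, K, T))
    cover = np.zeros((P, K, T))
    for k, comm in enumerate(communities):
        log_cov = (
            np.log(mean_surface[comm, k] * mean_mult)[:, None]
            - 0.5 * ((env_amp * cfg.env_sd) ** 2 + tau**2 + sigma**2)
            + env[k][None, :]
            + tau * eta[comm, :]
            + sigma * noise[comm, k, :]
        )
        cover[comm, k, :] = np.exp(log_cov)

    bnoise = rng.normal(0.0, 1.0, size=(K, T))
    total = cover.sum(axis=0)
    biomass = (
        cfg.mass_per_cover
        * total
        * np.exp(cfg.biomass_noise * bnoise - 0.5 * cfg.biomass_noise**2)
    )
    return cover, biomass, [c.tolist() for c in communities]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate cover, biomass, and climate tables plus ground truth.

    Both treatment arms are always generated; fertilization-effect fields of
    the config apply to the NPK arm only.  Within a site the species pool,
    overlap, and subplot compositions are shared between arms, while
    environments, responses, and noise are drawn independently per arm.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    site_seeds = ss.spawn(cfg.n_sites + 1)
    lo, hi = cfg.richness_range
    olo, ohi = cfg._omega_range()

    cover_rows, biomass_rows = [], []
    truth_sites = {}
    for s in range(cfg.n_sites):
        rng = np.random.default_rng(site_seeds[s])
        site = f"site{s + 1:02d}"

        # 1. species pool
        P = int(rng.integers(lo, hi + 1))
        means = rng.lognormal(cfg.abundance_meanlog, cfg.abundance_sdlog, size=P)
        rich_norm = (P - lo) / (hi - lo) if hi > lo else 0.5

        # 2. compositional overlap and subplot communities
        omega_s = float(rng.uniform(olo, ohi))
        n_local = max(2, int(round(cfg.local_fraction * P)))
        n_core = min(int(round(omega_s * n_local)), n_local)
        pool = np.arange(P)
        core = (
            _weighted_sample(rng, pool, means, n_core)
            if n_core
            else np.array([], dtype=int)
        )
        communities = []
        for _k in range(cfg.n_subplots):
            remaining = np.setdiff1d(pool, core)
            n_extra = min(n_local - n_core, remaining.size)
            extras = (
                _weighted_sample(rng, remaining, means[remaining], n_extra)
                if n_extra
                else np.array([], dtype=int)
            )
            communities.append(np.concatenate([core, extras]))

        # 3. niche assignment: permute mean covers within a per-subplot
        # reshuffle set of expected fraction (1 - omega); shared by both arms
        mean_surface = np.tile(means[:, None], (1, cfg.n_subplots))
        for k in range(cfg.n_subplots):
            reshuffle = np.flatnonzero(rng.random(P) < (1.0 - omega_s))
            if reshuffle.size > 1:
                mean_surface[reshuffle, k] = means[
                    rng.permutation(reshuffle)
                ]

        # 4. per-arm dynamics (control first, then NPK)
        arms = {}
        for trt, fert in (("Control", False), ("NPK", True)):
            arms[trt] = _arm_cover(
                rng, cfg, mean_surface, communities, fert, rich_norm
            )

        taxa = [f"{site}.sp{i + 1:03d}" for i in range(P)]
        for trt, (cov, bm, comms) in arms.items():
            present = np.nonzero(cov)
            for i, k, t in zip(*present):
                cover_rows.append(
                    (site, k + 1, trt, t + 1, taxa[i], cov[i, k, t])
                )
            for k in range(cfg.n_subplots):
                for t in range(cfg.n_years):
                    biomass_rows.append((site, k + 1, trt, t + 1, bm[k, t]))

        truth_sites[site] = {
            "pool_size": P,
            "species_means": means.tolist(),
            "mean_surface": mean_surface.tolist(),
            "omega": omega_s,
            "richness_norm": rich_norm,
            "communities_control": [c.tolist() for c in communities],
            "communities_npk": arms["NPK"][2],
        }

    # 5. climate covariates (independent of the dynamics)
    crng = np.random.default_rng(site_seeds[-1])
    climate = pd.DataFrame(
        {
            "site_code": [f"site{s + 1:02d}" for s in range(cfg.n_sites)],
            "MAP_VAR": crng.uniform(0.1, 0.8, size=cfg.n_sites),
            "MAT_VAR": crng.uniform(0.1, 0.9, size=cfg.n_sites),
        }
    )

    cover = pd.DataFrame(cover_rows, columns=list(COVER_COLUMNS))
    biomass = pd.DataFrame(biomass_rows, columns=list(BIOMASS_COLUMNS))
    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "sites": truth_sites,
    }
    return SyntheticDataset(cover=cover, biomass=biomass, climate=climate, truth=truth)


def expected_species_means(truth: dict, site: str, treatment: str) -> np.ndarray:
    """Recompute each pool species' expected mean cover per subplot (P, K).

    The log-cover draw is variance-adjusted, so the generative expectation
    of ``cover[i,k,t]`` for a present species is exactly
    ``mean_surface[i,k]`` times the fertilized multiplier.
    """
    cfgd = truth["config"]
    rec = truth["sites"][site]
    surface = np.asarray(rec["mean_surface"], dtype=float)
    mult = cfgd["biomass_multiplier"] if treatment == "NPK" else 1.0
    return surface * mult
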