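"""End-to-end pipeline: ingest or simulate, metric tables, inference tables.

Stages
------
1. **ingest** — read the cover/biomass CSVs (or generate a synthetic preset).
2. **metrics** — for every site x treatment x duration window, compute the
   diversity indices and the five stability/asynchrony statistics
   (``diversity.csv``, ``stability.csv``).
3. **analyze** — merge the metric tables, log-transform stability and
   asynchrony, drop windows with non-finite values (counted in the run
   report), fit the standardized path model per duration and treatment
   (``path_coefficients.csv``), pool across durations (``meta_paths.csv``),
   contrast treatments per path (``treatment_q.csv``), fit bivariate
   diversity-stability slopes with AR(1) errors (``slopes.csv``), and
   compute per-site fertilization log response ratios (``lrr.csv``).

Everything is deterministic given the inputs and seed; a JSON run report
records row counts, dropped windows, and the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import CommunityTensor, read_long_tables, validate_biomass, validate_cover
from .diversity import Basis, diversity_set
from .exceptions import (
    ConfigError,
    DegenerateInputError,
    InsufficientDataError,
    StabscaleError,
)
from .inference import (
    PathModelSpec,
    log_response_ratio,
    meta_combine,
    slope_with_ar1,
    standardized_path_fit,
    treatment_difference_q,
)
from .stability import stability_set
from .synthetic import SyntheticConfig, generate_dataset, preset

logger = logging.getLogger("stabscale")

#: Bivariate relationships reported in slopes.csv (x, y); y is on the log scale.
SLOPE_RELATIONSHIPS = (
    ("richness", "alpha_stability"),
    ("richness", "gamma_stability"),
    ("beta_diversity", "spatial_asynchrony"),
    ("beta_diversity", "gamma_stability"),
)

#: Variables whose fertilized/control log response ratio goes to lrr.csv.
LRR_VARIABLES = (
    "richness",
    "beta_diversity",
    "species_asynchrony",
    "spatial_asynchrony",
    "alpha_stability",
    "gamma_stability",
)

STABILITY_VARS = (
    "species_stability",
    "species_asynchrony",
    "alpha_stability",
    "spatial_asynchrony",
    "gamma_stability",
)

OUTPUT_FILES = (
    "diversity.csv",
    "stability.csv",
    "slopes.csv",
    "path_coefficients.csv",
    "meta_paths.csv",
    "treatment_q.csv",
    "lrr.csv",
)


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: either file inputs or a synthetic preset."""

    cover_path: str | None = None
    biomass_path: str | None = None
    climate_path: str | None = None
    preset: str | None = None
    synthetic: SyntheticConfig | None = None
    seed: int = 0
    durations: tuple = (4, 9)
    detrend: bool = False
    basis: Basis = Basis.TIME_MEAN_COVER
    out_dir: str | None = None

    def __post_init__(self):
        has_files = self.cover_path is not None and self.biomass_path is not None
        has_synth = self.preset is not None or self.synthetic is not None
        if not has_files and not has_synth:
            raise ConfigError(
                "RunConfig needs either cover_path+biomass_path or a synthetic "
                "preset/config"
            )
        lo, hi = self.durations
        if not (2 <= lo <= hi):
            raise ConfigError("durations must satisfy 2 <= lo <= hi")


def _load_tables(config: RunConfig):
    if config.cover_path is not None:
        cover, biomass = read_long_tables(config.cover_path, config.biomass_path)
        climate = (
            pd.read_csv(config.climate_path)
            if config.climate_path is not None
            else None
        )
        return cover, biomass, climate
    synth = config.synthetic
    if synth is None:
        synth = preset(config.preset)
    synth = synth.replace(seed=config.seed)
    ds = generate_dataset(synth)
    return validate_cover(ds.cover), validate_biomass(ds.biomass), ds.climate


def _site_window_tensors(cover, biomass, durations):
    """Yield (site, trt, duration, tensor) windows, pivoting each site-arm once.

    Nested duration windows (years 1..d) are slices of the full pivot;
    species with no cover inside a window are trimmed so the result equals a
    direct per-window assembly.
    """
    lo, hi = durations
    cov_g = dict(iter(cover.groupby(["site_code", "trt"], sort=True)))
    for (site, trt), bm in sorted(
        biomass.groupby(["site_code", "trt"], sort=True), key=lambda kv: kv[0]
    ):
        years = sorted(bm["year_trt"].unique())
        t_max = 0
        blocks = sorted(bm["block"].unique())
        if len(blocks) < 2:
            continue
        have = set(zip(bm["block"], bm["year_trt"]))
        while all((k, t_max + 1) in have for k in blocks):
            t_max += 1
        if t_max < lo:
            continue
        if t_max < hi:
            logger.warning(
                "site %s %s: only %d complete years; clipping durations to %d-%d",
                site, trt, t_max, lo, t_max,
            )
        bm_arr = (
            bm[bm["year_trt"] <= t_max]
            .pivot(index="block", columns="year_trt", values="live_mass")
            .loc[blocks, list(range(1, t_max + 1))]
            .to_numpy(dtype=float)
        )
        cv = cov_g.get((site, trt))
        if cv is None:
            continue
        cv = cv[cv["year_trt"] <= t_max]
        species = sorted(cv["Taxon"].unique())
        si = {s: i for i, s in enumerate(species)}
        ki = {k: i for i, k in enumerate(blocks)}
        full = np.zeros((len(species), len(blocks), t_max))
        full[
            cv["Taxon"].map(si).to_numpy(),
            cv["block"].map(ki).to_numpy(),
            cv["year_trt"].to_numpy() - 1,
        ] = cv["max_cover"].to_numpy(dtype=float)
        for d in range(lo, min(hi, t_max) + 1):
            window = full[:, :, :d]
            keep = np.nonzero(window.sum(axis=(1, 2)) > 0)[0]
            yield site, trt, d, CommunityTensor(
                site_id=site,
                treatment=trt,
                duration_years=d,
                species_list=tuple(species[i] for i in keep),
                subplots=tuple(int(b) for b in blocks),
                cover=window[keep].copy(),
                biomass=bm_arr[:, :d].copy(),
            )


def compute_metric_tables(cover, biomass, durations=(4, 9), detrend=False,
                          basis=Basis.TIME_MEAN_COVER):
    """Stage 2: diversity and stability tables, one row per window."""
    div_rows, stab_rows = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # evenness/log warnings surface in report
        for site, trt, d, tensor in _site_window_tensors(cover, biomass, durations):
            ds = diversity_set(tensor, basis)
            st = stability_set(tensor, detrend=detrend)
            div_rows.append(
                (site, trt, d, ds.richness, ds.shannon, ds.evenness,
                 ds.inv_simpson, ds.gamma_inv_simpson, ds.beta_multiplicative)
            )
            stab_rows.append(
                (site, trt, d, int(detrend), st.species_stability,
                 st.species_asynchrony, st.alpha_stability,
                 st.spatial_asynchrony, st.gamma_stability)
            )
    diversity = pd.DataFrame(
        div_rows,
        columns=["site_code", "trt", "duration", "richness", "shannon",
                 "evenness", "inv_simpson", "gamma_D", "beta_D"],
    )
    stability = pd.DataFrame(
        stab_rows,
        columns=["site_code", "trt", "duration", "detrended", *STABILITY_VARS],
    )
    return diversity, stability


def merged_metrics(diversity: pd.DataFrame, stability: pd.DataFrame) -> pd.DataFrame:
    """Merge metric tables and put stability/asynchrony on the natural-log scale.

    Non-positive or non-finite stability values become NaN (windows carrying
    them are excluded from inference, with counts in the run report).
    """
    df = diversity.merge(
        stability.drop(columns=["detrended"]),
        on=["site_code", "trt", "duration"],
        validate="one_to_one",
    ).rename(columns={"beta_D": "beta_diversity"})
    for col in STABILITY_VARS:
        vals = df[col].to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals <= 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            df[col] = np.where(bad, np.nan, np.log(np.where(bad, 1.0, vals)))
    return df


def analyze_metrics(
    diversity: pd.DataFrame,
    stability: pd.DataFrame,
    path_spec: PathModelSpec = PathModelSpec(),
):
    """Stage 3: path fits, meta-analysis, treatment contrasts, slopes, LRRs.

    Returns a dict of output DataFrames plus bookkeeping counts.
    """
    metrics = merged_metrics(diversity, stability)
    analysis_vars = list(path_spec.variables)
    finite = metrics.dropna(subset=analysis_vars)
    n_dropped = len(metrics) - len(finite)

    path_rows = []
    fits = {}
    for (trt, d), sub in finite.groupby(["trt", "duration"], sort=True):
        try:
            fit = standardized_path_fit(
                sub, path_spec, duration_years=int(d), treatment=trt
            )
        except (InsufficientDataError, DegenerateInputError) as exc:
            logger.warning("path fit skipped for %s duration %s: %s", trt, d, exc)
            continue
        fits[(trt, int(d))] = fit
        for resp, preds in path_spec.paths:
            for p in preds:
                edge = f"{p}->{resp}"
                coef, se = fit.coefficients[edge]
                path_rows.append(
                    (edge, trt, int(d), coef, se, fit.r_squared[resp], fit.n)
                )
    path_coefficients = pd.DataFrame(
        path_rows,
        columns=["path", "trt", "duration", "coef", "se", "r2", "n"],
    )

    meta_rows, pooled = [], {}
    for trt in sorted({t for t, _ in fits}):
        durs = sorted(d for t, d in fits if t == trt)
        for edge in path_spec.edge_names():
            est = [fits[(trt, d)].coefficients[edge] for d in durs]
            if not est:
                continue
            if len(est) == 1:
                # single duration: the lone estimate stands in for the pool
                (coef, se), z = est[0], 1.959963984540054
                pooled[(edge, trt)] = (coef, se)
                meta_rows.append(
                    (edge, trt, coef, se, coef - z * se, coef + z * se,
                     float("nan"), 0, float("nan"), coef, se, 1)
                )
                continue
            me = meta_combine(est)
            pooled[(edge, trt)] = (me.pooled, me.se)
            meta_rows.append(
                (edge, trt, me.pooled, me.se, me.ci_low, me.ci_high,
                 me.q_heterogeneity, me.df, me.p_heterogeneity,
                 me.pooled_random, me.se_random, me.k)
            )
    meta_paths = pd.DataFrame(
        meta_rows,
        columns=["path", "trt", "pooled", "se", "ci_lo", "ci_hi",
                 "Q_het", "df_het", "p_het", "pooled_re", "se_re", "k"],
    )

    q_rows = []
    for edge in path_spec.edge_names():
        pc, pf = pooled.get((edge, "Control")), pooled.get((edge, "NPK"))
        if pc is None or pf is None:
            continue
        q, dfree, p = treatment_difference_q(pc, pf)
        q_rows.append((edge, q, dfree, p))
    treatment_q = pd.DataFrame(q_rows, columns=["path", "Q", "df", "p"])

    slope_rows = []
    for trt, sub in finite.groupby("trt", sort=True):
        sub = sub.sort_values(["site_code", "duration"])
        for x_var, y_var in SLOPE_RELATIONSHIPS:
            pair = sub.dropna(subset=[x_var, y_var])
            if pair["site_code"].nunique() < 3 or len(pair) < 8:
                continue
            fit = slope_with_ar1(
                pair[y_var].to_numpy(dtype=float),
                pair[x_var].to_numpy(dtype=float),
                series_id=pair["site_code"].to_numpy(),
            )
            slope_rows.append(
                (f"{x_var}~{y_var}", trt, fit.slope, fit.se, fit.ci_low,
                 fit.ci_high, fit.rho, fit.n)
            )
    slopes = pd.DataFrame(
        slope_rows,
        columns=["relationship", "trt", "slope", "se", "ci_lo", "ci_hi",
                 "rho", "n"],
    )

    lrr_rows = []
    raw = diversity.merge(
        stability.drop(columns=["detrended"]),
        on=["site_code", "trt", "duration"],
        validate="one_to_one",
    ).rename(columns={"beta_D": "beta_diversity"})
    wide = raw.pivot(index=["site_code", "duration"], columns="trt")
    for (site, d), row in wide.iterrows():
        for var in LRR_VARIABLES:
            try:
                f, c = row[(var, "NPK")], row[(var, "Control")]
                lrr = log_response_ratio(f, c)
            except (KeyError, StabscaleError):
                continue
            lrr_rows.append((site, int(d), var, lrr))
    lrr = pd.DataFrame(lrr_rows, columns=["site_code", "duration", "variable", "lrr"])

    return {
        "path_coefficients": path_coefficients,
        "meta_paths": meta_paths,
        "treatment_q": treatment_q,
        "slopes": slopes,
        "lrr": lrr,
        "n_windows_dropped": n_dropped,
        "n_windows": len(metrics),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run ingest -> metrics -> analyze; write CSVs and a JSON run report.

    Returns the run report (also written to ``run_report.json`` when
    ``config.out_dir`` is set).
    """
    cover, biomass, climate = _load_tables(config)
    diversity, stability = compute_metric_tables(
        cover, biomass, durations=config.durations, detrend=config.detrend,
        basis=config.basis,
    )
    results = analyze_metrics(diversity, stability)

    tables = {
        "diversity": diversity,
        "stability": stability,
        "slopes": results["slopes"],
        "path_coefficients": results["path_coefficients"],
        "meta_paths": results["meta_paths"],
        "treatment_q": results["treatment_q"],
        "lrr": results["lrr"],
    }
    report = {
        "stabscale_version": __version__,
        "seed": config.seed,
        "preset": config.preset,
        "detrend": config.detrend,
        "basis": str(Basis(config.basis).value),
        "durations": list(config.durations),
        "n_sites": int(biomass["site_code"].nunique()),
        "sites_per_duration": diversity.groupby("duration")["site_code"]
        .nunique()
        .to_dict(),
        "n_windows": results["n_windows"],
        "n_windows_dropped_nonfinite": results["n_windows_dropped"],
        "rows": {name: int(len(df)) for name, df in tables.items()},
        "climate_provided": climate is not None,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.12g")
        (out / "run_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    report["tables"] = tables
    return report
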