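"""Reading, validation, and reshaping of long-format cover/biomass tables.

The analysis operates on one :class:`CommunityTensor` per site x treatment x
duration window: a dense ``(species, subplot, year)`` percent-cover array plus
an aligned ``(subplot, year)`` live-biomass array.  Input tables follow the
standardized grassland-experiment layout: areal percent cover per taxon per
1 m^2 subplot per post-treatment year, and clipped aboveground live biomass
(g m^-2) per subplot-year.  Summed cover within a subplot-year may exceed
100% (multilayer canopies); absent species are true zeros within a window.

Conventions applied here:

* Sites sampled twice in a year are collapsed to a single annual record by
  taking the seasonal maximum (per species for cover; per subplot for
  biomass — a seasonal SUM is available for biomass via ``how="sum"``).
* Taxa inconsistently identified across years can be aggregated to a common
  label (typically genus); covers of merged taxa are summed within a
  subplot-year, preserving total summed cover.
* Years are indexed 1..d post-treatment; calendar years are metadata only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    IncompleteWindowError,
    SchemaError,
    SizeError,
    ValidationError,
)

#: Canonical column names of the cover table.
COVER_COLUMNS = ("site_code", "block", "trt", "year_trt", "Taxon", "max_cover")
#: Canonical column names of the biomass table.
BIOMASS_COLUMNS = ("site_code", "block", "trt", "year_trt", "live_mass")
#: Optional sub-annual sampling key; collapsed by :func:`collapse_seasonal`.
SEASON_COLUMN = "season"

#: Recognized treatment labels (unmanipulated control vs. NPK+micronutrients).
TREATMENTS = ("Control", "NPK")

_COVER_KEYS = ["site_code", "block", "trt", "year_trt", "Taxon"]
_BIOMASS_KEYS = ["site_code", "block", "trt", "year_trt"]

_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class CommunityTensor:
    """Cover and biomass for one site-treatment-duration window.

    Attributes
    ----------
    site_id : str
        Site label.
    treatment : str
        ``"Control"`` or ``"NPK"``.
    duration_years : int
        Window length d; the window spans post-treatment years 1..d.
    species_list : tuple of str
        Taxa observed anywhere in the window, in fixed order (axis 0 of
        ``cover``).
    subplots : tuple of int
        Block/subplot indices (axis 1 of ``cover``, axis 0 of ``biomass``).
    cover : numpy.ndarray
        Percent cover, shape ``(S, K, d)``; zero where a species is absent.
    biomass : numpy.ndarray
        Live aboveground biomass (g m^-2), shape ``(K, d)``.
    """

    site_id: str
    treatment: str
    duration_years: int
    species_list: tuple
    subplots: tuple
    cover: np.ndarray = field(repr=False)
    biomass: np.ndarray = field(repr=False)

    def __post_init__(self):
        S, K, Y = self.cover.shape
        if K < 2:
            raise SizeError(f"need >= 2 subplots, got {K}")
        if Y < 2:
            raise SizeError(f"need >= 2 years, got {Y}")
        if Y != self.duration_years:
            raise SizeError(
                f"cover year axis {Y} != duration_years {self.duration_years}"
            )
        if self.biomass.shape != (K, Y):
            raise SizeError(
                f"biomass shape {self.biomass.shape} does not match (K, Y)=({K}, {Y})"
            )
        if len(self.species_list) != S or len(self.subplots) != K:
            raise SizeError("label lengths do not match array shape")
        if np.any(self.cover < 0) or np.any(self.biomass < 0):
            raise ValidationError("negative cover or biomass in tensor")

    @property
    def n_species(self) -> int:
        return self.cover.shape[0]

    @property
    def n_subplots(self) -> int:
        return self.cover.shape[1]

    @property
    def n_years(self) -> int:
        return self.cover.shape[2]


def _normalize_taxon(label) -> str:
    return _WS.sub(" ", str(label).strip())


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing required column {col!r}")


def _reject_negative(df: pd.DataFrame, col: str, what: str) -> None:
    bad = df.index[df[col] < 0]
    if len(bad):
        raise ValidationError(
            f"negative {col} in {what} table at row {bad[0]} "
            f"(value {df.loc[bad[0], col]!r})"
        )


def validate_cover(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an in-memory cover table."""
    _require_columns(df, COVER_COLUMNS, "cover")
    df = df.copy()
    df["max_cover"] = pd.to_numeric(df["max_cover"])
    _reject_negative(df, "max_cover", "cover")
    df["Taxon"] = df["Taxon"].map(_normalize_taxon)
    df["block"] = df["block"].astype(int)
    df["year_trt"] = df["year_trt"].astype(int)
    return df


def validate_biomass(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an in-memory biomass table."""
    _require_columns(df, BIOMASS_COLUMNS, "biomass")
    df = df.copy()
    df["live_mass"] = pd.to_numeric(df["live_mass"])
    _reject_negative(df, "live_mass", "biomass")
    df["block"] = df["block"].astype(int)
    df["year_trt"] = df["year_trt"].astype(int)
    return df


def read_long_tables(cover_path, biomass_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the cover and biomass CSV tables.

    Parameters
    ----------
    cover_path, biomass_path : path-like
        CSV files with the canonical columns (see :data:`COVER_COLUMNS` and
        :data:`BIOMASS_COLUMNS`); an optional ``season`` column marks
        sub-annual samplings.

    Returns
    -------
    (cover, biomass) : tuple of pandas.DataFrame
        Validated tables with whitespace-normalized taxa and integer keys.

    Raises
    ------
    SchemaError
        If a required column is absent (the message names it).
    ValidationError
        If any cover or biomass value is negative (the message cites the row).
    """
    cover = validate_cover(pd.read_csv(cover_path))
    biomass = validate_biomass(pd.read_csv(biomass_path))
    return cover, biomass


def collapse_seasonal(
    df: pd.DataFrame, value_col: str | None = None, how: str = "max"
) -> pd.DataFrame:
    """Collapse multi-season records to one annual record per key.

    For sites sampled more than once per year, the annual value is the
    seasonal maximum (default) of each species' cover, and likewise of
    biomass; ``how="sum"`` sums seasons instead (biomass only — summing
    cover would double-count standing vegetation).  Single-season input
    passes through unchanged (idempotent).
    """
    if value_col is None:
        value_col = "max_cover" if "Taxon" in df.columns else "live_mass"
    if how not in ("max", "sum"):
        raise ValueError(f"unknown seasonal collapse rule {how!r}")
    if how == "sum" and value_col == "max_cover":
        raise ValueError("seasonal SUM is not defined for cover; use 'max'")
    keys = _COVER_KEYS if "Taxon" in df.columns else _BIOMASS_KEYS
    if SEASON_COLUMN not in df.columns:
        # Already annual, but enforce key uniqueness by the same reduction.
        if not df.duplicated(keys).any():
            return df.copy()
    drop = [c for c in (SEASON_COLUMN,) if c in df.columns]
    out = (
        df.drop(columns=drop)
        .groupby(keys, as_index=False, sort=True)[value_col]
        .agg(how)
    )
    return out


def aggregate_taxa(cover: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    """Aggregate taxa to coarser labels, summing cover within subplot-years.

    ``mapping`` sends observed taxon labels to group labels (typically genus);
    unmapped taxa map to themselves.  Total summed cover per subplot-year is
    conserved.
    """
    out = cover.copy()
    out["Taxon"] = out["Taxon"].map(lambda t: _normalize_taxon(mapping.get(t, t)))
    keys = [k for k in _COVER_KEYS if k in out.columns]
    extra = [c for c in out.columns if c not in keys + ["max_cover"]]
    grouped = out.groupby(keys, as_index=False, sort=True)["max_cover"].sum()
    if extra:
        first = out.groupby(keys, as_index=False, sort=True)[extra].first()
        grouped = grouped.merge(first, on=keys)
    return grouped


def assemble_tensor(
    cover: pd.DataFrame,
    biomass: pd.DataFrame,
    site_id: str,
    treatment: str,
    duration_years: int,
) -> CommunityTensor:
    """Build the dense community tensor for one site-treatment-duration.

    The window spans post-treatment years ``1..duration_years``; every
    subplot must have a biomass record for every year in the window
    (biomass is the completeness authority — a subplot-year with no cover
    rows is a legal all-zero community only if biomass was recorded).
    Cover is zero-filled over the union of taxa observed in the window.

    Raises
    ------
    IncompleteWindowError
        If any subplot-year in the window lacks a biomass record; the
        error lists the gaps.
    SizeError
        If fewer than 2 subplots or ``duration_years`` < 2.
    """
    if duration_years < 2:
        raise SizeError(f"duration_years must be >= 2, got {duration_years}")
    years = list(range(1, duration_years + 1))
    bm = biomass[
        (biomass["site_code"] == site_id)
        & (biomass["trt"] == treatment)
        & biomass["year_trt"].isin(years)
    ]
    subplots = sorted(bm["block"].unique())
    if len(subplots) < 2:
        raise SizeError(
            f"site {site_id!r} treatment {treatment!r}: "
            f"found {len(subplots)} subplot(s), need >= 2"
        )
    have = set(zip(bm["block"], bm["year_trt"]))
    gaps = [(k, y) for k in subplots for y in years if (k, y) not in have]
    if gaps:
        raise IncompleteWindowError(
            f"site {site_id!r} treatment {treatment!r}: missing subplot-years "
            f"{gaps}",
            gaps=gaps,
        )
    if bm.duplicated(["block", "year_trt"]).any():
        raise ValidationError(
            f"site {site_id!r} treatment {treatment!r}: duplicate biomass "
            "records per subplot-year (collapse seasons first)"
        )
    bm_arr = (
        bm.pivot(index="block", columns="year_trt", values="live_mass")
        .loc[subplots, years]
        .to_numpy(dtype=float)
    )

    cv = cover[
        (cover["site_code"] == site_id)
        & (cover["trt"] == treatment)
        & cover["year_trt"].isin(years)
        & cover["block"].isin(subplots)
    ]
    if cv.duplicated(["block", "year_trt", "Taxon"]).any():
        raise ValidationError(
            f"site {site_id!r} treatment {treatment!r}: duplicate cover "
            "records per subplot-year-taxon (collapse seasons / aggregate taxa first)"
        )
    species = sorted(cv["Taxon"].unique())
    S, K, Y = len(species), len(subplots), len(years)
    cov_arr = np.zeros((S, K, Y), dtype=float)
    if S:
        si = {s: i for i, s in enumerate(species)}
        ki = {k: i for i, k in enumerate(subplots)}
        yi = {y: i for i, y in enumerate(years)}
        idx_s = cv["Taxon"].map(si).to_numpy()
        idx_k = cv["block"].map(ki).to_numpy()
        idx_y = cv["year_trt"].map(yi).to_numpy()
        cov_arr[idx_s, idx_k, idx_y] = cv["max_cover"].to_numpy(dtype=float)

    return CommunityTensor(
        site_id=site_id,
        treatment=treatment,
        duration_years=duration_years,
        species_list=tuple(species),
        subplots=tuple(int(k) for k in subplots),
        cover=cov_arr,
        biomass=bm_arr,
    )


def tensor_to_long(tensor: CommunityTensor) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write a tensor back to the long cover/biomass layout (round-trip safe).

    Zero-cover entries are omitted, matching field data where only present
    species are recorded; re-assembly restores them as zeros.
    """
    S, K, Y = tensor.cover.shape
    rows = []
    for i, sp in enumerate(tensor.species_list):
        for k, block in enumerate(tensor.subplots):
            for y in range(Y):
                val = tensor.cover[i, k, y]
                if val > 0:
                    rows.append(
                        (tensor.site_id, block, tensor.treatment, y + 1, sp, val)
                    )
    cover = pd.DataFrame(rows, columns=list(COVER_COLUMNS))
    brows = [
        (tensor.site_id, block, tensor.treatment, y + 1, tensor.biomass[k, y])
        for k, block in enumerate(tensor.subplots)
        for y in range(Y)
    ]
    biomass = pd.DataFrame(brows, columns=list(BIOMASS_COLUMNS))
    return cover, biomass


def iter_site_tensors(
    cover: pd.DataFrame,
    biomass: pd.DataFrame,
    durations,
    treatments=TREATMENTS,
):
    """Yield ``(site, treatment, duration, CommunityTensor)`` for every complete
    window.

    Durations a site cannot supply (too few years) are skipped silently;
    structurally broken windows (a hole inside an otherwise long series)
    are skipped as well — callers wanting strictness should call
    :func:`assemble_tensor` directly.
    """
    for site_id in sorted(biomass["site_code"].unique()):
        for trt in treatments:
            for d in durations:
                try:
                    yield site_id, trt, d, assemble_tensor(
                        cover, biomass, site_id, trt, d
                    )
                except (IncompleteWindowError, SizeError):
                    continue
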