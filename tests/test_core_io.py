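import numpy as np
import pandas as pd
import pytest

from stabscale import (
    aggregate_taxa,
    assemble_tensor,
    collapse_seasonal,
    read_long_tables,
    tensor_to_long,
)
from stabscale.exceptions import (
    IncompleteWindowError,
    SchemaError,
    SizeError,
    ValidationError,
)


def _write(tmp_path, cover, biomass):
    cp, bp = tmp_path / "cover.csv", tmp_path / "biomass.csv"
    cover.to_csv(cp, index=False)
    biomass.to_csv(bp, index=False)
    return cp, bp


class TestReadLongTables:
    def test_identity_read(self, tmp_path, cover_biomass_frames):
        cover, biomass = cover_biomass_frames
        cp, bp = _write(tmp_path, cover, biomass)
        cov, bm = read_long_tables(cp, bp)
        assert len(cov) == len(cover)
        assert len(bm) == len(biomass)
        assert list(cov.columns) == list(cover.columns)

    def test_missing_column_names_it(self, tmp_path, cover_biomass_frames):
        cover, biomass = cover_biomass_frames
        cp, bp = _write(tmp_path, cover.drop(columns=["year_trt"]), biomass)
        with pytest.raises(SchemaError, match="year_trt"):
            read_long_tables(cp, bp)

    def test_negative_value_cites_row(self, tmp_path, cover_biomass_frames):
        cover, biomass = cover_biomass_frames
        cover = cover.copy()
        cover.loc[3, "max_cover"] = -3.0
        cp, bp = _write(tmp_path, cover, biomass)
        with pytest.raises(ValidationError, match="row 3"):
            read_long_tables(cp, bp)

    def test_taxa_whitespace_normalized(self, tmp_path, cover_biomass_frames):
        cover, biomass = cover_biomass_frames
        cover = cover.copy()
        cover["Taxon"] = "  Poa   pratensis "
        cp, bp = _write(tmp_path, cover, biomass)
        cov, _ = read_long_tables(cp, bp)
        assert set(cov["Taxon"]) == {"Poa pratensis"}


class TestCollapseSeasonal:
    def _seasonal_cover(self):
        return pd.DataFrame(
            {
                "site_code": ["s1"] * 2,
                "block": [1, 1],
                "trt": ["Control"] * 2,
                "year_trt": [1, 1],
                "season": ["spring", "autumn"],
                "Taxon": ["A", "A"],
                "max_cover": [10.0, 25.0],
            }
        )

    def test_cover_max_over_seasons(self):
        out = collapse_seasonal(self._seasonal_cover())
        assert len(out) == 1
        assert out["max_cover"].iloc[0] == 25.0

    def test_biomass_max_and_sum_rules(self):
        bm = pd.DataFrame(
            {
                "site_code": ["s1"] * 2,
                "block": [1, 1],
                "trt": ["Control"] * 2,
                "year_trt": [1, 1],
                "season": ["spring", "autumn"],
                "live_mass": [120.0, 80.0],
            }
        )
        assert collapse_seasonal(bm)["live_mass"].iloc[0] == 120.0
        assert collapse_seasonal(bm, how="sum")["live_mass"].iloc[0] == 200.0

    def test_single_season_identity_and_idempotence(self, cover_biomass_frames):
        cover, _ = cover_biomass_frames
        once = collapse_seasonal(cover)
        pd.testing.assert_frame_equal(
            once.sort_values(list(once.columns)).reset_index(drop=True),
            cover.sort_values(list(once.columns)).reset_index(drop=True)[
                once.columns
            ],
        )
        twice = collapse_seasonal(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_sum_rule_rejected_for_cover(self):
        with pytest.raises(ValueError):
            collapse_seasonal(self._seasonal_cover(), how="sum")


class TestAggregateTaxa:
    def test_congeners_summed(self, cover_biomass_frames):
        cover, _ = cover_biomass_frames
        mapping = {"Poa pratensis": "Poa", "Festuca rubra": "Poa"}
        out = aggregate_taxa(cover, mapping)
        merged = out[(out.block == 1) & (out.year_trt == 1)]
        assert list(merged["Taxon"]) == ["Poa"]
        assert merged["max_cover"].iloc[0] == pytest.approx(12.0 + 6.0)

    def test_identity_mapping_unchanged(self, cover_biomass_frames):
        cover, _ = cover_biomass_frames
        out = aggregate_taxa(cover, {})
        assert len(out) == len(cover)
        assert out["max_cover"].sum() == pytest.approx(cover["max_cover"].sum())

    def test_total_cover_conserved(self, rng):
        cover = pd.DataFrame(
            {
                "site_code": "s1",
                "block": 1,
                "trt": "Control",
                "year_trt": 1,
                "Taxon": [f"t{i}" for i in range(9)],
                "max_cover": rng.uniform(0, 30, 9),
            }
        )
        mapping = {f"t{i}": f"g{i % 3}" for i in range(9)}
        out = aggregate_taxa(cover, mapping)
        assert out["max_cover"].sum() == pytest.approx(cover["max_cover"].sum())
        assert len(out) == 3


class TestAssembleTensor:
    def test_shape_and_zero_fill(self, cover_biomass_frames):
        cover, biomass = cover_biomass_frames
        t = assemble_tensor(cover, biomass, "s1", "Control", 3)
        assert t.cover.shape == (2, 2, 3)
        # Festuca only recorded in subplot 1 -> zeros in subplot 2
        i = t.species_list.index("Festuca rubra")
        assert np.all(t.cover[i, 1, :] == 0)

    def test_missing_year_raises_with_gaps(self, cover_biomass_frames):
        cover, biomass = cover_biomass_frames
        bm = biomass[~((biomass.block == 2) & (biomass.year_trt == 3))]
        with pytest.raises(IncompleteWindowError) as err:
            assemble_tensor(cover, bm, "s1", "Control", 3)
        assert (2, 3) in err.value.gaps

    def test_too_small_windows_raise(self, cover_biomass_frames):
        cover, biomass = cover_biomass_frames
        with pytest.raises(SizeError):
            assemble_tensor(cover, biomass[biomass.block == 1], "s1", "Control", 3)
        with pytest.raises(SizeError):
            assemble_tensor(cover, biomass, "s1", "Control", 1)

    def test_round_trip_exact(self, cover_biomass_frames):
        cover, biomass = cover_biomass_frames
        t = assemble_tensor(cover, biomass, "s1", "Control", 3)
        cov2, bm2 = tensor_to_long(t)
        t2 = assemble_tensor(cov2, bm2, "s1", "Control", 3)
        assert t2.species_list == t.species_list
        np.testing.assert_array_equal(t2.cover, t.cover)
        np.testing.assert_array_equal(t2.biomass, t.biomass)
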