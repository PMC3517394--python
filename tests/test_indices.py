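import networkx as nx
import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import blockscape as bs
from blockscape.indices import (
    INDEX_COLUMNS,
    aggregate_to_windows,
    block_variable_counts,
    correlate_indices,
    domain_index,
    summarize_roster,
    vacancy_flags,
    wide_table,
)
from blockscape.registry import SchemaError
from blockscape.spatial import CommunityWindow
from conftest import build_city_products


def parcel_frame(rows, columns):
    return pd.DataFrame(rows, columns=["parcel_id", "block_id", *columns])


class TestVariableCounts:
    def test_presences_sum_within_block(self, registry):
        parcels = parcel_frame(
            [("p1", "A", 1), ("p2", "A", 1), ("p3", "A", 0)], ["litter"]
        )
        counts = block_variable_counts(parcels, None, registry, ["A", "B"])
        assert counts.loc["A", "litter"] == 2

    def test_empty_block_gets_zero_row_not_missing(self, registry):
        parcels = parcel_frame([("p1", "A", 1)], ["litter"])
        counts = block_variable_counts(parcels, None, registry, ["A", "B"])
        assert "B" in counts.index and counts.loc["B"].sum() == 0

    def test_text_variable_counts_nonempty_entries(self, registry):
        parcels = parcel_frame(
            [("p1", "A", "leaning porch"), ("p2", "A", ""), ("p3", "A", None)],
            ["other_condition"],
        )
        counts = block_variable_counts(parcels, None, registry, ["A"])
        assert counts.loc["A", "other_condition"] == 1

    def test_unknown_observation_column_rejected(self, registry):
        parcels = parcel_frame([("p1", "A", 1)], ["flying_cars"])
        with pytest.raises(SchemaError, match="flying_cars"):
            block_variable_counts(parcels, None, registry, ["A"])

    def test_wrong_applicability_column_rejected(self, registry):
        nuisances = pd.DataFrame(
            {"nuisance_id": ["n1"], "block_id": ["A"], "litter": [1]}
        )
        with pytest.raises(SchemaError, match="applicability"):
            block_variable_counts(
                parcel_frame([], []), nuisances, registry, ["A"]
            )

    def test_nonbinary_value_in_binary_variable_rejected(self, registry):
        parcels = parcel_frame([("p1", "A", 3)], ["litter"])
        with pytest.raises(SchemaError, match="litter"):
            block_variable_counts(parcels, None, registry, ["A"])

    def test_conservation_against_raw_presences(self, registry, small_city):
        counts = block_variable_counts(
            small_city["parcels"], small_city["nuisances"], registry,
            list(small_city["city"].blocks),
        )
        for var in ("boarded_windows", "litter", "security_sign"):
            assert counts[var].sum() == small_city["parcels"][var].sum()
        for var in ("litter_public", "cigarette_butts"):
            assert counts[var].sum() == small_city["nuisances"][var].sum()


class TestVacancyFlags:
    @pytest.mark.parametrize(
        "occupancy,ptype,expected",
        [
            ("occupied", "residential", 0),
            ("unoccupied", "residential", 1),
            ("demolished", "residential", 1),
            ("unoccupied", "commercial", 1),
            ("unoccupied", "religious", 1),
            ("unoccupied", "community", 1),
            ("occupied", "unoccupied_lot", 1),  # vacant lots always count
        ],
    )
    def test_flag_rules(self, occupancy, ptype, expected):
        parcels = pd.DataFrame(
            {"occupancy": [occupancy], "property_type": [ptype]}
        )
        assert vacancy_flags(parcels).iloc[0] == expected


class TestDomainIndex:
    def test_sums_domain_variables_only(self, registry):
        counts = pd.DataFrame(
            {"boarded_windows": [2], "roof_damage": [1], "litter": [5]},
            index=pd.Index(["A"], name="block_id"),
        )
        assert domain_index(counts, registry, "housing_damage").loc["A"] == 3
        assert domain_index(counts, registry, "property_disorder").loc["A"] == 5

    def test_all_zero_block_scores_zero(self, registry):
        counts = pd.DataFrame(
            0, index=pd.Index(["A"], name="block_id"), columns=registry.names
        )
        assert domain_index(counts, registry, "territoriality").loc["A"] == 0

    def test_matches_brute_force_resum_over_raw_records(self, registry, small_city):
        counts = block_variable_counts(
            small_city["parcels"], small_city["nuisances"], registry,
            list(small_city["city"].blocks),
        )
        got = domain_index(counts, registry, "housing_damage")
        hd_vars = [v.name for v in registry.domain_variables("housing_damage")
                   if v.name in small_city["parcels"].columns]
        oracle = (
            small_city["parcels"].groupby("block_id")[hd_vars].sum().sum(axis=1)
        )
        expected = oracle.reindex(got.index, fill_value=0)
        assert (got == expected).all()


class TestWindowAggregation:
    def path_windows(self):
        return {
            "B": CommunityWindow("B", 1, frozenset({"A", "B", "C"})),
        }

    def test_path_pac_sums_members(self):
        block_index = pd.DataFrame(
            {"v": [1, 2, 3]}, index=pd.Index(["A", "B", "C"], name="block_id")
        )
        out = aggregate_to_windows(block_index, self.path_windows())
        assert out.loc["B", "v"] == 6

    def test_order_zero_is_identity(self, small_city):
        graph = small_city["graph"]
        windows = bs.all_windows(graph, 0)
        out = aggregate_to_windows(small_city["block_indices"], windows)
        pd.testing.assert_frame_equal(
            out.sort_index(), small_city["block_indices"].sort_index()
        )

    def test_all_ones_grid_center_values(self):
        graph = bs.build_adjacency(
            {
                f"G{iy}{ix}": box(ix, iy, ix + 1, iy + 1)
                for iy in range(5)
                for ix in range(5)
            }
        )
        ones = pd.DataFrame(
            {"v": 1}, index=pd.Index(sorted(graph.nodes), name="block_id")
        )
        pac = aggregate_to_windows(ones, bs.all_windows(graph, 1))
        sac = aggregate_to_windows(ones, bs.all_windows(graph, 2))
        assert pac.loc["G22", "v"] == 9
        assert sac.loc["G22", "v"] == 25

    def test_missing_member_raises(self):
        block_index = pd.DataFrame(
            {"v": [1]}, index=pd.Index(["B"], name="block_id")
        )
        with pytest.raises(KeyError, match="missing"):
            aggregate_to_windows(block_index, self.path_windows())

    def test_monotone_block_pac_sac(self, small_city):
        table = small_city["index_table"]
        w = {lvl: wide_table(table, lvl) for lvl in ("block", "pac", "sac")}
        assert (w["block"] <= w["pac"]).all().all()
        assert (w["pac"] <= w["sac"]).all().all()

    def test_block_level_conserves_raw_totals(self, small_city):
        table = small_city["index_table"]
        block = wide_table(table, "block")
        assert block["crime"].sum() == len(small_city["city"].crimes)
        assert block["tenure"].sum() == (
            small_city["tenure_calls"]["call"] == "renter_occupied"
        ).sum()
        assert block["vacancy"].sum() == vacancy_flags(small_city["parcels"]).sum()


class TestCorrelations:
    def _table(self, wide):
        rows = [
            (bid, "block", col, int(v), 1, float(v))
            for col in wide.columns
            for bid, v in wide[col].items()
        ]
        return pd.DataFrame(
            rows, columns=["block_id", "level", "index", "value", "n_parcels", "rate"]
        )

    def test_unit_diagonal_and_symmetry(self, small_city):
        corr = correlate_indices(small_city["index_table"], "block")
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T, equal_nan=True)
        assert ((corr.fillna(0) >= -1) & (corr.fillna(0) <= 1)).all().all()

    def test_exact_negatives_correlate_minus_one(self):
        wide = pd.DataFrame(
            {"vacancy": [1, 2, 3, 4], "tenure": [4, 3, 2, 1]},
            index=pd.Index(list("ABCD"), name="block_id"),
        )
        corr = correlate_indices(self._table(wide), "block")
        assert corr.loc["vacancy", "tenure"] == pytest.approx(-1.0)

    def test_zero_variance_index_flagged_undefined_not_zero(self):
        wide = pd.DataFrame(
            {"vacancy": [1, 2, 3], "crime": [5, 5, 5]},
            index=pd.Index(list("ABC"), name="block_id"),
        )
        corr = correlate_indices(self._table(wide), "block")
        assert corr.attrs["degenerate"] == ["crime"]
        assert corr.loc["crime"].isna().all()

    def test_too_few_blocks_rejected(self):
        wide = pd.DataFrame(
            {"vacancy": [1, 2]}, index=pd.Index(list("AB"), name="block_id")
        )
        with pytest.raises(ValueError, match="3 blocks"):
            correlate_indices(self._table(wide), "block")

    def test_unknown_method_rejected(self, small_city):
        with pytest.raises(ValueError, match="pearson"):
            correlate_indices(small_city["index_table"], "block", method="kendall")

    def test_spearman_supported(self, small_city):
        corr = correlate_indices(small_city["index_table"], "block", method="spearman")
        assert np.allclose(np.diag(corr), 1.0)


class TestRosterAccounting:
    def test_small_roster(self):
        roster = pd.DataFrame(
            {
                "excluded": [True, False, False, False, False],
                "property_type": ["", "residential", "residential", "commercial",
                                  "other"],
                "property_subtype": ["", "single_family", "apartment", "", ""],
            }
        )
        summary = summarize_roster(roster)
        assert summary["assessable_parcels"] == 4
        assert summary["other_parcels"] == 1
        assert summary["residual_residential_parcels"] == 0


def test_rates_missing_for_zero_parcel_windows(registry):
    # one isolated block with no parcels: count 0, rate NaN (never 0)
    graph = nx.Graph()
    graph.add_node("A")
    block_index = pd.DataFrame(
        {**{c: [0] for c in INDEX_COLUMNS}, "n_parcels": [0]},
        index=pd.Index(["A"], name="block_id"),
    )
    table = bs.build_index_table(block_index, graph, levels=["block"])
    assert (table["value"] == 0).all()
    assert table["rate"].isna().all()
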