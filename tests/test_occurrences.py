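"""Parsing, cleaning and checklist summaries of occurrence records."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from endegrid.occurrences import (
    ChecklistError,
    ColumnMappingError,
    DEFAULT_RULE_ORDER,
    clean_occurrences,
    parse_occurrences,
    summarize_checklist,
)

from conftest import make_records


class TestParsing:
    def test_simple_row_maps_fields(self):
        df = parse_occurrences(
            io.StringIO("species,decimalLongitude,decimalLatitude\nNolana mollis,-70.2,-23.5\n")
        )
        row = df.iloc[0]
        assert row["species"] == "Nolana mollis"
        assert row["genus"] == "Nolana"
        assert row["longitude"] == -70.2
        assert row["latitude"] == -23.5
        assert not row[["introduced", "ex_situ", "hybrid"]].any()

    def test_unparseable_coordinate_is_flagged_not_fatal(self):
        df = parse_occurrences(
            io.StringIO("species,decimalLongitude,decimalLatitude\nNolana mollis,abc,-23.5\n")
        )
        assert bool(df.iloc[0]["invalid_coordinates"])
        assert len(df) == 1

    def test_out_of_range_coordinate_is_flagged(self):
        df = parse_occurrences(
            io.StringIO("species,decimalLongitude,decimalLatitude\nNolana mollis,-200.0,-23.5\n")
        )
        assert bool(df.iloc[0]["invalid_coordinates"])

    def test_header_only_gives_empty_frame(self):
        df = parse_occurrences(
            io.StringIO("species,decimalLongitude,decimalLatitude\n")
        )
        assert len(df) == 0
        assert "species" in df.columns

    def test_missing_mandatory_column_names_it(self):
        with pytest.raises(ColumnMappingError, match="longitude"):
            parse_occurrences(io.StringIO("species,decimalLatitude\nA b,1\n"))

    def test_column_map_remaps_names(self):
        df = parse_occurrences(
            io.StringIO("taxon,x,y\nSolanum acaule,-65.0,-22.0\n"),
            column_map={"species": "taxon", "longitude": "x", "latitude": "y"},
        )
        assert df.iloc[0]["species"] == "Solanum acaule"

    def test_darwin_core_quality_columns_set_flags(self):
        text = (
            "species,decimalLongitude,decimalLatitude,establishmentMeans,"
            "identificationQualifier,taxonRank\n"
            "Solanum acaule,-65,-22,introduced,,species\n"
            "Solanum sp.,-65,-22,,,genus\n"
            "Nolana mollis,-70,-23,cultivated,cf.,species\n"
        )
        df = parse_occurrences(io.StringIO(text))
        assert bool(df.iloc[0]["introduced"])
        assert bool(df.iloc[1]["incomplete_id"])
        assert bool(df.iloc[2]["ex_situ"]) and bool(df.iloc[2]["doubtful_id"])

    def test_row_order_preserved(self):
        text = "species,decimalLongitude,decimalLatitude\n" + "".join(
            f"Sp n{i},-{60 + i},-{20 + i}\n" for i in range(5)
        )
        df = parse_occurrences(io.StringIO(text))
        assert list(df["longitude"]) == [-60.0, -61.0, -62.0, -63.0, -64.0]


class TestCleaning:
    def test_duplicate_coordinates_keep_first(self):
        records = make_records(
            [("Nolana mollis", -70.2, -23.5), ("Nolana mollis", -70.2, -23.5)]
        )
        result = clean_occurrences(records)
        assert len(result.records) == 1
        assert result.report.n_removed_by_rule["duplicate_coordinates"] == 1

    def test_same_coordinates_different_species_both_kept(self):
        records = make_records(
            [("Nolana mollis", -70.2, -23.5), ("Nolana villosa", -70.2, -23.5)]
        )
        assert len(clean_occurrences(records).records) == 2

    def test_flagged_records_removed_under_their_rule(self):
        records = make_records(
            [
                ("Solanum acaule", -65.0, -22.0, "", {"hybrid": True}),
                ("Solanum acaule", -65.0, -22.0, "", {"introduced": True}),
                ("Solanum acaule", -66.0, -22.0, "", {"doubtful_id": True}),
                ("Solanum acaule", -67.0, -22.0, "", {"invalid_coordinates": True}),
                ("Solanum acaule", -68.0, -22.0),
            ]
        )
        report = clean_occurrences(records).report
        assert report.n_removed_by_rule == {
            "introduced_ex_situ": 1,
            "hybrid": 1,
            "doubtful_or_incomplete_id": 1,
            "invalid_coordinates": 1,
            "duplicate_coordinates": 0,
        }
        assert report.n_output == 1

    def test_rule_order_gives_unique_cause(self):
        # a record that is both ex-situ and a hybrid is counted once, under
        # the earlier rule
        records = make_records(
            [("Solanum acaule", -65.0, -22.0, "", {"ex_situ": True, "hybrid": True})]
        )
        report = clean_occurrences(records).report
        assert report.n_removed_by_rule["introduced_ex_situ"] == 1
        assert report.n_removed_by_rule["hybrid"] == 0

    def test_identity_on_already_clean_input(self):
        records = make_records(
            [("Solanum acaule", -65.0, -22.0), ("Nolana mollis", -70.2, -23.5)]
        )
        result = clean_occurrences(records)
        assert result.report.n_output == result.report.n_input == 2

    def test_rejects_carry_removal_reason(self):
        records = make_records(
            [("Solanum acaule", -65.0, -22.0, "", {"hybrid": True})]
        )
        rejects = clean_occurrences(records).rejects
        assert list(rejects["removal_reason"]) == ["hybrid"]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_report_reconciles_and_cleaning_is_idempotent(self, data):
        n = data.draw(st.integers(0, 40))
        rows = []
        for i in range(n):
            flags = {
                f: data.draw(st.booleans())
                for f in ("introduced", "hybrid", "doubtful_id", "invalid_coordinates")
            }
            rows.append(
                (
                    f"Genus{data.draw(st.integers(0, 3))} sp{data.draw(st.integers(0, 5))}",
                    float(data.draw(st.integers(-75, -60))),
                    float(data.draw(st.integers(-40, -20))),
                    "",
                    flags,
                )
            )
        records = make_records(rows)
        first = clean_occurrences(records)
        assert first.report.reconciles()
        again = clean_occurrences(first.records)
        assert again.report.n_output == first.report.n_output
        pd.testing.assert_frame_equal(again.records, first.records)
        assert sum(again.report.n_removed_by_rule.values()) == 0


class TestChecklist:
    def _two_country_records(self):
        return make_records(
            [
                ("Solanum acaule", -65.0, -22.0, "Argentina"),
                ("Solanum acaule", -69.0, -22.0, "Chile"),
                ("Nolana mollis", -70.2, -23.5, "Chile"),
                ("Fabiana denudata", -66.0, -27.0, "Argentina"),
            ]
        )

    def test_shared_species_counted_once_in_union(self):
        summary = summarize_checklist(self._two_country_records())
        assert summary.n_shared_species == 1
        assert summary.n_union_species == 3
        assert (
            summary.n_union_species
            == summary.per_country["Argentina"]["n_species"]
            + summary.per_country["Chile"]["n_species"]
            - summary.n_shared_species
        )

    def test_single_species_single_country(self):
        summary = summarize_checklist(make_records([("Nolana mollis", -70.2, -23.5, "Chile")]))
        assert summary.n_union_species == 1
        assert summary.n_shared_species == 0

    def test_endemism_is_an_external_attribute(self):
        summary = summarize_checklist(
            self._two_country_records(),
            endemic_species={"Nolana mollis", "Solanum acaule"},
        )
        # the shared species is endemic to the study area, not to one country
        assert summary.per_country["Chile"]["n_endemic_species"] == 1
        assert summary.per_country["Argentina"]["n_endemic_species"] == 0
        assert summary.n_shared_endemic_species == 1

    def test_missing_country_raises_listing_species(self):
        records = make_records([("Nolana mollis", -70.2, -23.5)])
        with pytest.raises(ChecklistError, match="Nolana mollis"):
            summarize_checklist(records)

    def test_counts_match_brute_force_set_algebra(self, rng):
        # random 3-country-style fixture checked against exhaustive enumeration
        countries = ["A", "B", "C"]
        rows = []
        for i in range(60):
            sp = f"Genus{i % 7:02d} species{rng.integers(0, 25):03d}"
            rows.append((sp, -70.0 + i * 0.1, -30.0, countries[rng.integers(0, 3)]))
        records = make_records(rows)
        summary = summarize_checklist(records)

        memb = {c: set() for c in countries}
        for sp, _, _, c in [(r[0], r[1], r[2], r[3]) for r in rows]:
            memb[c].add(sp)
        union = memb["A"] | memb["B"] | memb["C"]
        shared = {s for s in union if sum(s in m for m in memb.values()) > 1}
        assert summary.n_union_species == len(union)
        assert summary.n_shared_species == len(shared)
        for c in countries:
            if memb[c]:
                assert summary.per_country[c]["n_species"] == len(memb[c])
                assert summary.per_country[c]["n_genera"] == len(
                    {s.split()[0] for s in memb[c]}
                )
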