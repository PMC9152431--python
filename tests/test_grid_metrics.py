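"""Gridding, presence matrices and the SR/WE/CWE endemism metrics."""

import numpy as np
import pandas as pd
import pytest

from endegrid.grid_metrics import (
    EmptyMatrixError,
    GridSpec,
    OutOfExtentError,
    PresenceMatrix,
    assign_cell,
    build_presence_matrix,
    corrected_weighted_endemism,
    diversity_scores,
    percentile_trim,
    presence_from_triplets,
    presence_to_triplets,
    species_richness,
    weighted_endemism,
)

from conftest import brute_force_scores, make_records, random_presence_matrix


class TestAssignCell:
    def test_hand_computed_cell(self):
        # floor((-70.2 + 180)/1) = 109, floor((-23.5 + 90)/1) = 66
        assert assign_cell(-70.2, -23.5, GridSpec()) == (109, 66)

    def test_lower_left_corner_belongs_to_cell(self):
        grid = GridSpec()
        assert assign_cell(-70.0, -23.0, grid) == (110, 67)
        # just inside the previous cell
        assert assign_cell(-70.0 - 1e-9, -23.0 - 1e-9, grid) == (109, 66)

    def test_refinement_nests_cells(self):
        coarse = assign_cell(-70.2, -23.5, GridSpec(cell_size=1.0))
        fine = assign_cell(-70.2, -23.5, GridSpec(cell_size=0.5))
        assert fine[0] // 2 == coarse[0] and fine[1] // 2 == coarse[1]

    def test_out_of_extent_raises(self):
        grid = GridSpec(extent=(-75.0, -40.0, -60.0, -25.0))
        with pytest.raises(OutOfExtentError):
            assign_cell(-50.0, -30.0, grid)

    def test_cell_bounds_roundtrip(self):
        grid = GridSpec()
        w, s, e, n = grid.cell_bounds(109, 66)
        assert (w, s, e, n) == (-71.0, -24.0, -70.0, -23.0)
        assert assign_cell(w, s, grid) == (109, 66)


class TestPresenceMatrix:
    def test_three_records_one_species_one_cell(self):
        records = make_records(
            [("Nolana mollis", -70.2, -23.5), ("Nolana mollis", -70.4, -23.1), ("Nolana mollis", -70.9, -23.9)]
        )
        m = build_presence_matrix(records, GridSpec())
        assert (m.n_cells, m.n_species) == (1, 1)
        assert m.row_sums.tolist() == [1] and m.col_sums.tolist() == [1]

    def test_marginals_match_hand_count_on_ten_records(self):
        # brute-force tally: sp A in cells (0.5,0.5) and (1.5,0.5); sp B in
        # (0.5,0.5); sp C in (2.5,2.5)
        rows = [
            ("A a", 0.5, 0.5), ("A a", 0.6, 0.4), ("A a", 1.5, 0.5),
            ("B b", 0.5, 0.5), ("B b", 0.2, 0.8), ("B b", 0.9, 0.1),
            ("C c", 2.5, 2.5), ("C c", 2.1, 2.9), ("C c", 2.2, 2.2), ("C c", 2.8, 2.6),
        ]
        m = build_presence_matrix(make_records(rows), GridSpec(origin_lon=0, origin_lat=0))
        assert m.n_cells == 3
        tally = {}
        for sp, lon, lat in rows:
            tally.setdefault(sp, set()).add((int(lon), int(lat)))
        for j, sp in enumerate(m.species):
            assert m.col_sums[j] == len(tally[sp])
        cell_species = {}
        for sp, lon, lat in rows:
            cell_species.setdefault((int(lon), int(lat)), set()).add(sp)
        for i, (cx, cy) in enumerate(m.cells):
            assert m.row_sums[i] == len(cell_species[(cx, cy)])

    def test_record_order_invariance(self, rng):
        records = make_records(
            [(f"S p{i % 5}", float(-70 + rng.integers(0, 6)), float(-30 + rng.integers(0, 6)))
             for i in range(40)]
        )
        m1 = build_presence_matrix(records, GridSpec())
        m2 = build_presence_matrix(records.sample(frac=1.0, random_state=3), GridSpec())
        assert np.array_equal(m1.incidence, m2.incidence)
        assert np.array_equal(m1.cells, m2.cells)

    def test_empty_records_raise(self):
        with pytest.raises(EmptyMatrixError):
            build_presence_matrix(make_records([]), GridSpec())

    def test_binary_and_no_empty_margins_enforced(self):
        with pytest.raises(ValueError):
            PresenceMatrix(
                np.array([[0, 0]]), np.array(["a", "b"], dtype=object),
                np.array([[1, 0]]),  # species b never occurs
            )

    def test_triplet_roundtrip(self, rng):
        m = random_presence_matrix(rng, 8, 12)
        again = presence_from_triplets(presence_to_triplets(m))
        assert np.array_equal(m.incidence, again.incidence)
        assert list(m.species) == list(again.species)


class TestMetrics:
    def test_single_endemic_cell(self):
        m = PresenceMatrix(np.array([[0, 0]]), np.array(["a"], dtype=object), np.array([[1]]))
        assert weighted_endemism(m)[0] == 1.0
        assert corrected_weighted_endemism(m)[0] == 1.0

    def test_hand_summed_we_and_cwe(self):
        # focal cell holds species with ranges 1, 2, 4
        incidence = np.array(
            [
                [1, 1, 1],
                [0, 1, 1],
                [0, 0, 1],
                [0, 0, 1],
            ],
            dtype=np.uint8,
        )
        cells = np.column_stack([np.arange(4), np.zeros(4, int)])
        m = PresenceMatrix(cells, np.array(["a", "b", "c"], dtype=object), incidence)
        we = weighted_endemism(m)
        cwe = corrected_weighted_endemism(m)
        assert we[0] == pytest.approx(1 + 0.5 + 0.25)
        assert cwe[0] == pytest.approx(1.75 / 3)

    def test_sr_matches_record_level_recount(self, rng):
        rows = [
            (f"Genus{i % 4} sp{i % 9}", float(-75 + rng.uniform(0, 10)), float(-35 + rng.uniform(0, 10)))
            for i in range(120)
        ]
        records = make_records(rows)
        m = build_presence_matrix(records, GridSpec())
        sr = species_richness(m)
        for i, (cx, cy) in enumerate(m.cells):
            seen = {
                sp
                for sp, lon, lat in rows
                if int(np.floor(lon + 180)) == cx and int(np.floor(lat + 90)) == cy
            }
            assert sr[i] == len(seen)

    @pytest.mark.parametrize("trial", range(10))
    def test_vectorized_equals_triple_loop_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        m = random_presence_matrix(rng, int(rng.integers(2, 21)), int(rng.integers(2, 31)))
        sr_o, we_o, cwe_o = brute_force_scores(m.incidence)
        assert np.array_equal(species_richness(m), sr_o)
        np.testing.assert_allclose(weighted_endemism(m), we_o, rtol=1e-12)
        np.testing.assert_allclose(corrected_weighted_endemism(m), cwe_o, rtol=1e-12)

    def test_we_sums_to_species_count(self, rng):
        for _ in range(20):
            m = random_presence_matrix(rng, int(rng.integers(2, 25)), int(rng.integers(2, 40)))
            assert weighted_endemism(m).sum() == pytest.approx(m.n_species, rel=1e-9)

    def test_adding_single_cell_endemic_raises_we_by_one(self, rng):
        m = random_presence_matrix(rng, 10, 15)
        target = 4
        extended = np.hstack([m.incidence, np.zeros((10, 1), dtype=np.uint8)])
        extended[target, -1] = 1
        m2 = PresenceMatrix(
            m.cells, np.append(m.species, "zz new endemic"), extended
        )
        we1, we2 = weighted_endemism(m), weighted_endemism(m2)
        assert we2[target] == pytest.approx(we1[target] + 1.0, rel=1e-12)
        others = np.arange(10) != target
        np.testing.assert_allclose(we2[others], we1[others], rtol=1e-12)

    def test_window_widens_neighborhood(self):
        # two adjacent cells, one species each; with a 3×3 window each cell
        # sees both species and window richness is 2
        incidence = np.eye(2, dtype=np.uint8)
        cells = np.array([[0, 0], [1, 0]])
        m = PresenceMatrix(cells, np.array(["a", "b"], dtype=object), incidence)
        we = weighted_endemism(m, window=1)
        cwe = corrected_weighted_endemism(m, window=1)
        np.testing.assert_allclose(we, [2.0, 2.0])
        np.testing.assert_allclose(cwe, [1.0, 1.0])

    def test_diversity_scores_table_consistency(self, rng):
        m = random_presence_matrix(rng, 12, 18)
        scores = diversity_scores(m)
        np.testing.assert_allclose(
            scores["CWE"] * scores["SR"], scores["WE"], rtol=1e-12
        )


class TestPercentileTrim:
    def test_scores_1_to_100(self):
        trim = percentile_trim(np.arange(1, 101, dtype=float))
        assert trim.low_cutoff == pytest.approx(5.95)
        assert trim.high_cutoff == pytest.approx(95.05)
        assert trim.trimmed_max == 95.0
        assert trim.trimmed_min == 6.0

    def test_single_score_unchanged(self):
        trim = percentile_trim([3.5])
        assert trim.trimmed_max == trim.trimmed_min == 3.5

    def test_identity_at_full_band(self):
        values = np.array([2.0, 9.0, 4.0, 7.0])
        trim = percentile_trim(values, 0, 100)
        assert trim.trimmed_max == 9.0 and trim.trimmed_min == 2.0
        assert trim.retained.all()

    def test_constant_scores(self):
        trim = percentile_trim([4.0, 4.0, 4.0])
        assert trim.trimmed_max == trim.trimmed_min == 4.0
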