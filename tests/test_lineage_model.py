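"""Forest construction, validation, and genealogy queries."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from microlineage.lineage import (
    DataError,
    LineageForest,
    NoCommonAncestorError,
    StructuralError,
    ancestors_of,
    build_forest,
    coefficient_of_relationship,
    generations_to_common_ancestor,
    number_of_generations,
    subtree_cells_at,
)

from _oracles import (
    naive_ancestor_chain,
    naive_generation_count,
    naive_generations_to_lca,
    naive_subtree_at,
)
from conftest import cousin_forest, exp_series, make_cell, two_generation_forest


class TestBuildForest:
    def test_single_root_identity(self):
        cells = pd.DataFrame(
            [{"cell_id": "a", "microcolony_id": "m0", "parent_id": None,
              "birth_time_min": None, "division_time_min": None, "fate": "censored"}]
        )
        series = pd.DataFrame({"cell_id": "a", "time_min": [0.0, 10.0], "area_um2": [2.0, 2.1]})
        f = build_forest(cells, series)
        assert f.roots == ["a"] and len(f) == 1 and f.children_of("a") == []

    def test_one_division_links_children_to_parent_division(self):
        f = two_generation_forest()
        assert len(f.roots) == 1
        kids = f.children_of("r")
        assert len(kids) == 2
        for k in kids:
            assert f[k].birth_time == f["r"].division_time

    def test_missing_parent_is_structural_error(self):
        cells = pd.DataFrame(
            [{"cell_id": "a", "microcolony_id": "m0", "parent_id": "ghost",
              "birth_time_min": 5.0, "division_time_min": None, "fate": "censored"}]
        )
        series = pd.DataFrame({"cell_id": "a", "time_min": [10.0], "area_um2": [2.0]})
        with pytest.raises(StructuralError, match="ghost"):
            build_forest(cells, series)

    def test_missing_column_is_named(self):
        with pytest.raises(DataError, match="fate"):
            build_forest(pd.DataFrame({"cell_id": ["a"]}))

    @pytest.mark.parametrize(
        "mutate, exc",
        [
            (lambda c: setattr(c["p0c0"], "parent_id", None), StructuralError),  # 1 child left
            (lambda c: setattr(c["p0"], "birth_time", 130.0), StructuralError),  # birth != division
            (lambda c: c["g"].area_series.__setitem__((1, 0), 0.0), DataError),  # non-monotone
            (lambda c: c["g"].area_series.__setitem__((0, 1), -1.0), DataError),  # negative area
            (lambda c: setattr(c["p0"], "fate", "censored"), DataError),  # divided w/o fate
        ],
    )
    def test_single_field_mutations_are_rejected(self, mutate, exc):
        f = cousin_forest()
        mutate(f.cells)
        with pytest.raises((StructuralError, DataError)):
            LineageForest("m0", list(f.cells.values()))

    def test_simulated_colony_passes_validation(self, sim_colony):
        forest, _, _ = sim_colony
        forest.validate()  # must not raise


class TestAncestors:
    def test_undivided_cell_is_its_own_chain(self):
        f = two_generation_forest()
        chain = ancestors_of(f, "r", 0.0, 100.0)
        assert chain.cells == ["r"] and not chain.truncated

    def test_grandchild_chain_spans_three_generations(self):
        f = cousin_forest()
        chain = ancestors_of(f, "p0c1", 0.0)
        assert chain.cells == ["g", "p0", "p0c1"]

    def test_truncated_flag_when_root_born_late(self):
        cells = [make_cell("a", birth=50.0, series=exp_series(50, 200, 2.0, 0.001))]
        f = LineageForest("m0", cells)
        chain = ancestors_of(f, "a", 0.0)
        assert chain.truncated and chain.cells == ["a"]

    def test_chains_tile_the_window(self, sim_colony):
        forest, schedule, _ = sim_colony
        t0 = schedule.low[0]
        for sid in sorted(forest.alive_at(schedule.recovery[0]))[:20]:
            chain = ancestors_of(forest, sid, t0)
            cells = [forest[c] for c in chain.cells]
            for a, b in zip(cells, cells[1:]):
                assert b.parent_id == a.cell_id
                assert b.birth_time == a.division_time  # no gap, no overlap
            assert chain.truncated or cells[0].start_time <= t0

    def test_matches_bruteforce_walk(self, sim_colony):
        forest, schedule, _ = sim_colony
        for sid in sorted(forest.alive_at(schedule.recovery[0]))[:25]:
            got = ancestors_of(forest, sid, schedule.high[0]).cells
            assert got == naive_ancestor_chain(forest, sid, schedule.high[0])


class TestSubtree:
    def test_before_division_only_root(self):
        f = two_generation_forest()
        assert subtree_cells_at(f, "r", 60.0) == {"r"}

    def test_two_generations_four_leaves(self):
        f = cousin_forest()
        assert subtree_cells_at(f, "g", 300.0) == {"p0c0", "p0c1", "p1c0", "p1c1"}

    def test_outside_window_errors(self):
        f = two_generation_forest()
        with pytest.raises(DataError):
            subtree_cells_at(f, "r", 1e6)

    def test_partition_by_children(self, sim_colony):
        forest, schedule, _ = sim_colony
        t = schedule.low[0] + 200.0
        for root in forest.roots:
            if forest[root].fate != "divided":
                continue
            whole = subtree_cells_at(forest, root, t)
            parts = [subtree_cells_at(forest, k, t) for k in forest.children_of(root)]
            assert parts[0].isdisjoint(parts[1])
            assert whole == parts[0] | parts[1]

    def test_matches_exhaustive_scan(self, sim_colony):
        forest, schedule, _ = sim_colony
        for t in (100.0, schedule.low[0] + 500.0, schedule.recovery[1]):
            for root in sorted(forest.cells)[:15]:
                assert subtree_cells_at(forest, root, t) == naive_subtree_at(forest, root, t)


class TestRelatedness:
    def test_sisters_and_cousins(self):
        f = cousin_forest()
        assert generations_to_common_ancestor(f, "p0c0", "p0c1") == 1
        assert generations_to_common_ancestor(f, "p0c0", "p1c1") == 2
        assert coefficient_of_relationship(2) == 0.25
        assert coefficient_of_relationship(1) == 0.5
        assert coefficient_of_relationship(0) == 1.0

    def test_symmetry_and_oracle(self, sim_colony):
        forest, _, _ = sim_colony
        ids = sorted(forest.cells)[:14]
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                n = generations_to_common_ancestor(forest, a, b)
                assert n == generations_to_common_ancestor(forest, b, a)
                assert n == naive_generations_to_lca(forest, a, b)

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_relationship(-1)

    def test_disjoint_roots_raise(self):
        cells = [
            make_cell("a", series=exp_series(0, 100, 2.0, 0.001)),
            make_cell("b", series=exp_series(0, 100, 2.0, 0.001)),
        ]
        f = LineageForest("m0", cells)
        with pytest.raises(NoCommonAncestorError):
            generations_to_common_ancestor(f, "a", "b")

    @given(n=st.integers(min_value=0, max_value=40))
    @settings(deadline=None)
    def test_cr_non_increasing_in_n(self, n):
        assert coefficient_of_relationship(n + 1) < coefficient_of_relationship(n)


class TestGenerationCount:
    def test_no_divisions_is_zero(self):
        f = two_generation_forest()
        assert number_of_generations(f, "r", (0.0, 100.0)) == 0

    def test_counts_divisions_strictly_inside(self):
        f = cousin_forest()
        assert number_of_generations(f, "p0c0", (0.0, 300.0)) == 2
        assert number_of_generations(f, "p0c0", (120.0, 300.0)) == 1  # boundary excluded

    def test_matches_bruteforce(self, sim_colony):
        forest, schedule, _ = sim_colony
        window = schedule.low
        for sid in sorted(forest.alive_at(schedule.recovery[0]))[:25]:
            assert number_of_generations(forest, sid, window) == naive_generation_count(
                forest, sid, window
            )
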