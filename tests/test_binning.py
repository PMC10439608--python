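import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magcurate import (
    BinningPlan,
    ColumnSpec,
    PlanError,
    build_table,
    edit_plan,
    search_contigs,
    select_polygon,
    set_flag,
    summarize_plan,
)
from magcurate.binning import point_in_polygon, read_plan_tsv, write_plan_tsv
from oracles import brute_point_in_polygon

UNIT_SQUARE = [(0, 0), (1, 0), (1, 1), (0, 1)]


class TestPlanEdits:
    @pytest.fixture
    def plan(self):
        return BinningPlan.from_assignment(
            {"c1": "B1", "c2": "B1", "c3": "B2"}, name="test"
        )

    def test_assign_then_unassign_restores(self, plan):
        start = dict(plan.assignment)
        plan.create_bin("B3")
        plan.assign({"c1"}, "B3")
        plan.unassign({"c1"})
        plan.assign({"c1"}, "B1")
        assert plan.assignment == start

    def test_assign_moves_between_bins_atomically(self, plan):
        plan.assign({"c3"}, "B1")
        assert plan.assignment["c3"] == "B1"
        plan.undo()
        assert plan.assignment["c3"] == "B2"
        values = list(plan.assignment.values())
        assert all(values.count(b) == len(plan.members(b)) for b in plan.bins)

    def test_merge_unions_members_and_drops_source(self, plan):
        plan.merge(["B1", "B2"], into="B1")
        assert plan.members("B1") == {"c1", "c2", "c3"}
        assert "B2" not in plan.bins

    def test_undo_restores_deleted_bin(self, plan):
        members = plan.members("B1")
        plan.delete_bin("B1")
        assert "B1" not in plan.bins and "c1" not in plan.assignment
        plan.undo()
        assert plan.members("B1") == members

    def test_rename_collision_rejected(self, plan):
        with pytest.raises(PlanError):
            plan.rename_bin("B1", "B2")

    def test_assign_to_unknown_bin_rejected(self, plan):
        with pytest.raises(PlanError):
            plan.assign({"c1"}, "nope")

    def test_undo_empty_history_rejected(self, plan):
        with pytest.raises(PlanError):
            plan.undo()

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=30), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_random_edit_sequences_keep_single_membership_and_undo_all(self, ops, seed):
        rng = np.random.default_rng(seed)
        plan = BinningPlan.from_assignment(
            {f"c{i}": f"B{i % 3}" for i in range(9)}, name="prop"
        )
        initial_assignment = dict(plan.assignment)
        initial_bins = set(plan.bins)
        n_edits = 0
        for op in ops:
            bins = sorted(plan.bins)
            try:
                if op == 0:
                    plan.create_bin(f"new{n_edits}")
                elif op == 1 and bins:
                    ids = [f"c{rng.integers(9)}" for _ in range(2)]
                    plan.assign(ids, bins[rng.integers(len(bins))])
                elif op == 2:
                    plan.unassign({f"c{rng.integers(9)}"})
                elif op == 3 and len(bins) >= 2:
                    pair = [bins[0], bins[-1]]
                    plan.merge(pair, into=pair[0])
                elif op == 4 and bins:
                    plan.delete_bin(bins[rng.integers(len(bins))])
                elif op == 5 and bins:
                    plan.rename_bin(bins[0], f"ren{n_edits}")
                else:
                    continue
            except PlanError:
                continue
            n_edits += 1
            # single membership holds after every edit by construction
            assert len(plan.assignment) == len(set(plan.assignment))
            assert set(plan.assignment.values()) <= plan.bins
        for _ in range(n_edits):
            plan.undo()
        assert plan.assignment == initial_assignment
        assert plan.bins == initial_bins

    def test_edit_plan_dispatch(self, plan):
        edit_plan(plan, "create", bin="B9")
        edit_plan(plan, "assign", ids=["c1"], bin="B9")
        assert plan.assignment["c1"] == "B9"
        edit_plan(plan, "undo")
        edit_plan(plan, "undo")
        assert "B9" not in plan.bins


class TestPolygon:
    def test_unit_square_membership(self):
        coords = {"in": (0.5, 0.5), "out": (1.5, 0.5)}
        assert select_polygon(coords, UNIT_SQUARE) == ["in"]

    def test_boundary_point_included(self):
        assert point_in_polygon(1.0, 0.5, UNIT_SQUARE)
        assert point_in_polygon(0.0, 0.0, UNIT_SQUARE)  # vertex

    def test_winding_order_irrelevant(self):
        assert point_in_polygon(0.5, 0.5, list(reversed(UNIT_SQUARE)))

    def test_concave_star_matches_oracle(self, rng):
        # five-pointed star (self-intersecting): even-odd rule territory
        angles = np.linspace(0, 4 * np.pi, 5, endpoint=False)
        star = [(np.cos(a), np.sin(a)) for a in angles]
        pts = rng.uniform(-1.2, 1.2, size=(300, 2))
        for x, y in pts:
            assert point_in_polygon(x, y, star) == brute_point_in_polygon(x, y, star)

    def test_random_polygons_match_oracle(self, rng):
        for _ in range(30):
            n_vert = int(rng.integers(3, 9))
            poly = [tuple(v) for v in rng.uniform(-5, 5, size=(n_vert, 2))]
            for x, y in rng.uniform(-6, 6, size=(30, 2)):
                assert point_in_polygon(x, y, poly) == brute_point_in_polygon(x, y, poly)

    def test_masked_contigs_excluded(self, toy_table):
        coords = {cid: (0.5, 0.5) for cid in toy_table.ids}
        set_flag(toy_table, {"c1"}, "mask", True)
        got = select_polygon(coords, UNIT_SQUARE, table=toy_table)
        assert "c1" not in got and len(got) == 4

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            select_polygon({}, [(0, 0), (1, 1)])


class TestSearch:
    def test_categorical_equals(self, toy_table):
        got = search_contigs(toy_table, {"column": "genus", "op": "equals", "value": "Escherichia"})
        assert got == ["c1", "c2"]

    def test_numeric_between_is_inclusive(self, toy_table):
        got = search_contigs(
            toy_table, {"column": "length", "op": "between", "value": (2000, 5000)}
        )
        assert got == ["c3", "c4"]

    def test_feature_has(self, toy_table):
        got = search_contigs(toy_table, {"column": "ko", "op": "has", "value": "dsrA"})
        assert got == ["c4"]

    def test_conjunction(self, toy_table):
        got = search_contigs(
            toy_table,
            {"column": "genus", "op": "equals", "value": "Escherichia"},
            {"column": "coverage", "op": ">", "value": 15},
        )
        assert got == ["c2"]

    def test_regex_and_contains(self, toy_table):
        assert search_contigs(
            toy_table, {"column": "genus", "op": "regex", "value": "^Esch"}
        ) == ["c1", "c2"]
        assert search_contigs(
            toy_table, {"column": "genus", "op": "contains", "value": "acter"}
        ) == ["c3"]

    def test_masked_never_match(self, toy_table):
        set_flag(toy_table, {"c1"}, "mask", True)
        got = search_contigs(toy_table, {"column": "genus", "op": "equals", "value": "Escherichia"})
        assert got == ["c2"]

    def test_predicate_dtype_mismatch_rejected(self, toy_table):
        with pytest.raises(Exception):
            search_contigs(toy_table, {"column": "genus", "op": ">", "value": 1})


class TestSummarizePlan:
    def test_length_weighted_abundance(self, toy_table):
        plan = BinningPlan.from_assignment({"c1": "B", "c2": "B"})
        (summary,) = summarize_plan(plan, toy_table, ["coverage"], length_column="length")
        assert summary.n_contigs == 2
        assert summary.total_length == 400
        assert summary.abundance["coverage"] == pytest.approx(17.5)

    def test_mass_mode(self, toy_table):
        plan = BinningPlan.from_assignment({"c1": "B", "c2": "B"})
        (summary,) = summarize_plan(plan, toy_table, ["coverage"], mode="mass")
        assert summary.abundance["coverage"] == pytest.approx(100 * 10 + 300 * 20)

    def test_empty_bin(self, toy_table):
        plan = BinningPlan(name="p", bins={"empty"})
        (summary,) = summarize_plan(plan, toy_table, ["coverage"])
        assert summary.n_contigs == 0 and summary.total_length == 0
        assert np.isnan(summary.abundance["coverage"])

    def test_masked_member_excluded(self, toy_table):
        plan = BinningPlan.from_assignment({"c1": "B", "c2": "B"})
        set_flag(toy_table, {"c2"}, "mask", True)
        (summary,) = summarize_plan(plan, toy_table, ["coverage"])
        assert summary.n_contigs == 1 and summary.total_length == 100

    def test_binned_length_bounded_by_total(self, toy_table):
        plan = BinningPlan.from_assignment({c: "B" for c in toy_table.ids})
        (summary,) = summarize_plan(plan, toy_table, [])
        assert summary.total_length == toy_table.numeric("length").sum()


class TestPlanIO:
    def test_roundtrip_two_column(self, tmp_path):
        plan = BinningPlan.from_assignment({"c1": "B1", "c2": "B1", "c3": "B 2"}, name="p")
        path = tmp_path / "plan.tsv"
        write_plan_tsv(plan, path)
        back = read_plan_tsv(path)
        assert back.assignment == plan.assignment

    def test_member_list_shape(self, tmp_path):
        path = tmp_path / "members.tsv"
        path.write_text("#bin\tmembers\nB1\tc1,c2\nB2\tc3\n")
        plan = read_plan_tsv(path)
        assert plan.assignment == {"c1": "B1", "c2": "B1", "c3": "B2"}

    def test_double_assignment_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#contig\tbin\nc1\tB1\nc1\tB2\n")
        with pytest.raises(PlanError, match="c1"):
            read_plan_tsv(path)
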