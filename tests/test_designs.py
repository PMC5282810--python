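import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import krigdoe as kd
from krigdoe import presets
from krigdoe.designs import (DesignMatrix, Factor, FactorSpace, add_reference_replicates,
                             fractional_factorial, full_factorial, nested_round3_design,
                             plates_required, reduce_components, snap_to_pipetting_grid)


def _space(k, lo=0.5, hi=1.7):
    return FactorSpace([Factor(f"f{i}", lo, hi) for i in range(k)])


# ---------------------------------------------------------------------------
# reduce_components
# ---------------------------------------------------------------------------

class TestReduceComponents:
    def test_packaged_table_yields_nine_free_variables(self):
        space = reduce_components(presets.COMPONENT_TABLE)
        assert space.k == 9
        assert set(space.names) == {"MES", "phosphate", "NaNO3", "MgSO4", "NaCl",
                                    "CaCl2", "trace", "FeSO4", "Na2EDTA"}
        assert space.tied_groups["FeSO4"] == ("H2SO4",)
        assert space.tied_groups["Na2EDTA"] == ("KOH",)
        assert set(space.tied_groups["trace"]) == {"ZnSO4", "MnCl2", "Na2MoO4",
                                                   "CuSO4", "CoSO4", "H3BO3"}
        assert ("penicillin_G", 1.0) in space.fixed

    def test_all_fixed_gives_empty_space(self):
        table = [{"name": f"c{i}", "decision": "fix"} for i in range(5)]
        space = reduce_components(table)
        assert space.k == 0
        assert len(space.fixed) == 5

    def test_cluster_counting(self):
        table = [{"name": "a", "decision": "vary"},
                 {"name": "b", "decision": "cluster", "with": "g"},
                 {"name": "c", "decision": "cluster", "with": "g"}]
        space = reduce_components(table)
        assert space.k == 2
        assert space.names == ["a", "g"]

    def test_tie_to_unvaried_component_is_an_error(self):
        table = [{"name": "a", "decision": "fix"},
                 {"name": "b", "decision": "tie", "with": "a"}]
        with pytest.raises(ValueError, match="not a varied component"):
            reduce_components(table)

    def test_unknown_decision_is_an_error(self):
        with pytest.raises(ValueError, match="unknown decision"):
            reduce_components([{"name": "a", "decision": "mangle"}])

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            reduce_components([{"name": "a", "decision": "vary"},
                               {"name": "a", "decision": "vary"}])


# ---------------------------------------------------------------------------
# full factorial
# ---------------------------------------------------------------------------

class TestFullFactorial:
    def test_five_factors_give_32_corner_runs(self):
        design = full_factorial(_space(5))
        assert len(design) == 32
        assert set(design.roles) == {"factorial"}

    def test_single_factor(self):
        design = full_factorial(_space(1))
        assert sorted(design.coded().ravel()) == [-1.0, 1.0]

    def test_zero_factors_yield_single_empty_row(self):
        design = full_factorial(_space(0))
        assert len(design) == 1

    @pytest.mark.parametrize("k", range(2, 10))
    def test_balance_and_orthogonality_by_enumeration(self, k):
        coded = full_factorial(_space(k)).coded()
        assert coded.shape == (2 ** k, k)
        # every level combination appears exactly once
        assert len(np.unique(coded, axis=0)) == 2 ** k
        assert np.allclose(coded.sum(axis=0), 0.0)
        gram = coded.T @ coded
        assert np.allclose(gram, 2 ** k * np.eye(k))


# ---------------------------------------------------------------------------
# fractional factorial
# ---------------------------------------------------------------------------

def _focus_model_matrix(coded, focus):
    """Intercept + mains + focus two-factor interactions (oracle helper)."""
    k = coded.shape[1]
    cols = [np.ones(len(coded))] + [coded[:, j] for j in range(k)]
    cols += [coded[:, focus] * coded[:, j] for j in range(k) if j != focus]
    return np.column_stack(cols)


class TestFractionalFactorial:
    def test_nine_factors_thirty_two_runs_full_rank(self):
        space = _space(9)
        design = fractional_factorial(space, "f3")
        assert len(design) == 32
        M = _focus_model_matrix(design.coded(), 3)
        # independent alias check: full column rank by enumeration
        assert np.linalg.matrix_rank(M) == M.shape[1] == 18
        # regular fraction: the restricted model matrix is orthogonal
        assert np.allclose(M.T @ M, 32 * np.eye(18))
        assert "defining_relation" in design.meta

    def test_three_factors_fall_back_to_full_factorial(self):
        design = fractional_factorial(_space(3), "f0")
        assert len(design) == 8
        # brute force: no regular 4-run fraction (c = +-ab) estimates all
        # mains plus both focus interactions (6 columns > 4 rows)
        base = np.array(list(itertools.product((-1.0, 1.0), repeat=2)))
        for sign in (1.0, -1.0):
            coded = np.column_stack([base, sign * base[:, 0] * base[:, 1]])
            M = _focus_model_matrix(coded, 0)
            assert np.linalg.matrix_rank(M) < M.shape[1]

    def test_two_factors_return_plain_full_factorial(self):
        design = fractional_factorial(_space(2), "f1")
        assert len(design) == 4
        assert len(np.unique(design.coded(), axis=0)) == 4

    def test_capacity_deficit_error(self):
        with pytest.raises(ValueError, match="exceeding plate capacity 20 by 17"):
            fractional_factorial(_space(9), "f0", capacity=20, reserve=5)

    def test_unknown_focus_rejected(self):
        with pytest.raises(ValueError, match="focus factor"):
            fractional_factorial(_space(3), "nope")

    @pytest.mark.parametrize("k,focus", [(4, 0), (5, 2), (6, 5), (7, 3), (8, 0), (9, 8)])
    def test_estimability_holds_across_sizes(self, k, focus):
        design = fractional_factorial(_space(k), f"f{focus}")
        M = _focus_model_matrix(design.coded(), focus)
        assert np.linalg.matrix_rank(M) == 2 * k
        assert len(design) <= 2 ** k


# ---------------------------------------------------------------------------
# nested round-3 design
# ---------------------------------------------------------------------------

class TestNestedDesign:
    def test_default_row_count_is_35(self, core_space):
        design = nested_round3_design(core_space, presets.ROUND3_MG_LEVELS)
        assert len(design) == 35
        counts = design.roles.value_counts()
        assert counts["factorial"] == 24
        assert counts["center"] == 2
        assert counts["space_filling"] == 9

    def test_single_level_reduces_to_plain_cube(self, core_space):
        design = nested_round3_design(core_space, [1.7], n_centers=0, n_edge=0)
        assert len(design) == 8
        cube = design.coded()[:, [i for i, n in enumerate(core_space.names) if n != "MgSO4"]]
        assert len(np.unique(cube, axis=0)) == 8

    def test_edge_points_sit_on_cube_edges(self, core_space):
        design = nested_round3_design(core_space, presets.ROUND3_MG_LEVELS)
        mg_idx = core_space.names.index("MgSO4")
        cube_idx = [i for i in range(4) if i != mg_idx]
        mg_inner = design.frame[design.frame["role"] == "factorial"].iloc[8][core_space.names[mg_idx]]
        for _, row in design.frame[design.frame["role"] == "space_filling"].iterrows():
            cube = np.array([row[core_space.names[i]] for i in cube_idx])
            half = 0.5 if np.isclose(row[core_space.names[mg_idx]], mg_inner) else 1.0
            at_bound = np.isclose(np.abs(cube), half)
            assert at_bound.sum() == 2 and np.abs(cube[~at_bound])[0] < half

    def test_inner_cube_uses_half_ranges(self, core_space):
        design = nested_round3_design(core_space, presets.ROUND3_MG_LEVELS)
        cube_cols = [n for n in core_space.names if n != "MgSO4"]
        fact = design.frame[design.frame["role"] == "factorial"]
        inner = fact.iloc[8:16][cube_cols].to_numpy()
        assert np.allclose(np.abs(inner), 0.5)

    def test_decreasing_levels_rejected(self, core_space):
        with pytest.raises(ValueError, match="strictly increasing"):
            nested_round3_design(core_space, [2.0, 1.0, 3.0])

    def test_wrong_dimensionality_rejected(self):
        with pytest.raises(ValueError, match="exactly 4"):
            nested_round3_design(_space(3), [0.5, 1.0, 1.5])


# ---------------------------------------------------------------------------
# reference replicates and plates
# ---------------------------------------------------------------------------

class TestReferenceAndPlates:
    def test_fraction_plus_five_references_is_37(self, base_space):
        design = fractional_factorial(base_space, "MgSO4")
        total = add_reference_replicates(design, 5)
        assert len(total) == 37
        refs = total.natural_frame().query("role == 'reference'")
        assert len(refs) == 5
        assert np.allclose(refs[base_space.names].to_numpy(), 1.0)

    def test_zero_references_leave_design_unchanged(self, base_space):
        design = fractional_factorial(base_space, "MgSO4")
        assert add_reference_replicates(design, 0) is design

    def test_capacity_overflow_reports_count(self, base_space):
        big = full_factorial(_space(5)).append(
            DesignMatrix.from_coded(_space(5), np.zeros((14, 5)), "center", 2))
        assert len(big) == 46
        with pytest.raises(ValueError, match="by 3"):
            add_reference_replicates(big, 5, capacity=48)

    @pytest.mark.parametrize("n,cap,expected", [(512, 48, 11), (48, 48, 1), (49, 48, 2),
                                                (0, 48, 0), (1, 1, 1)])
    def test_plates_required(self, n, cap, expected):
        assert plates_required(n, cap) == expected

    def test_plates_required_errors(self):
        with pytest.raises(ValueError):
            plates_required(-1, 48)
        with pytest.raises(ValueError):
            plates_required(10, 0)


# ---------------------------------------------------------------------------
# pipetting grid
# ---------------------------------------------------------------------------

class TestSnapping:
    def test_realizable_level_untouched(self):
        space = _space(1, lo=0.0, hi=2.0)
        design = DesignMatrix.from_natural(space, [[0.4]], "factorial", 1)
        res = snap_to_pipetting_grid(design)  # step = 10 uL * 0.002 = 0.02 xRef
        assert np.isclose(res.design.natural()[0, 0], 0.4)
        assert res.max_abs_error < 1e-12

    def test_sub_aliquot_level_snaps_to_zero(self):
        space = _space(1, lo=0.0, hi=2.0)
        design = DesignMatrix.from_natural(space, [[0.001]], "factorial", 1)
        res = snap_to_pipetting_grid(design)
        assert res.design.natural()[0, 0] == 0.0
        assert np.isclose(res.errors["abs_f0"].iloc[0], 0.001)

    def test_snap_error_bounded_by_half_increment(self):
        rng = np.random.default_rng(7)
        space = _space(3, lo=0.0, hi=2.0)
        design = DesignMatrix.from_natural(space, rng.uniform(0, 2, (40, 3)), "factorial", 1)
        res = snap_to_pipetting_grid(design)
        for name, step in res.increments.items():
            assert (res.errors[f"abs_{name}"] <= step / 2 + 1e-12).all()


# ---------------------------------------------------------------------------
# coding, validation, serialization
# ---------------------------------------------------------------------------

class TestFactorSpace:
    @given(st.floats(min_value=0.5, max_value=1.7, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_coded_natural_roundtrip(self, x):
        space = _space(1)
        assert abs(space.decode(space.code(np.array([x])))[0] - x) < 1e-12

    def test_code_endpoints(self):
        space = _space(2, lo=0.5, hi=1.7)
        assert np.allclose(space.code(np.array([0.5, 1.7])), [-1.0, 1.0])

    def test_reference_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="reference level"):
            FactorSpace([Factor("a", 1.2, 2.0)])
        FactorSpace([Factor("a", 1.2, 2.0)], require_reference_inside=False)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            Factor("a", 1.0, 0.5)
        with pytest.raises(ValueError):
            Factor("a", -0.1, 1.5)

    def test_subset_moves_rest_to_fixed(self, base_space):
        sub = base_space.subset(["MgSO4", "NaNO3"])
        assert sub.names == ["MgSO4", "NaNO3"]
        assert ("MES", 1.0) in sub.fixed


class TestDesignCsv:
    def test_roundtrip(self, tmp_path, base_space):
        design = add_reference_replicates(fractional_factorial(base_space, "MgSO4"), 5)
        path = tmp_path / "design.csv"
        design.to_csv(path)
        back = DesignMatrix.from_csv(path, base_space)
        assert back.round_id == design.round_id
        assert list(back.frame["run_id"]) == list(design.frame["run_id"])
        assert list(back.roles) == list(design.roles)
        assert np.allclose(back.coded(), design.coded(), atol=1e-12)

    def test_well_labels_follow_plate_map(self, base_space):
        design = add_reference_replicates(fractional_factorial(base_space, "MgSO4"), 5)
        table = design.to_frame()
        assert table["well"].iloc[0] == "A1"
        assert table["well"].iloc[8] == "B1"
        assert table["plate"].nunique() == 1

    def test_all_rows_respect_bounds(self, base_space, core_space):
        for design in (fractional_factorial(base_space, "MgSO4"),
                       full_factorial(base_space),
                       nested_round3_design(core_space, presets.ROUND3_MG_LEVELS)):
            nat = design.natural()
            assert np.all(nat >= design.space.lower - 1e-12)
            assert np.all(nat <= design.space.upper + 1e-12)
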