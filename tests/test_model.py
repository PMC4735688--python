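import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarecoal.model import (
    Branch,
    DemographyModel,
    JoinEvent,
    ModelSyntaxError,
    ParameterMap,
    UnitScale,
    parse_model_file,
    to_real,
    validate_model,
    write_model_file,
)
from rarecoal.simulate import random_tree_model

TWO_POP = """
# two populations
branch A 1.0 4
branch B 0.5 4
join 0.002 A B 2.0
scale 20000 1.25e-8 29
"""


class TestParsing:
    def test_two_branch_file(self):
        m = parse_model_file(TWO_POP)
        assert len(m.branches) == 2
        assert len(m.joins) == 1
        assert m.joins[0].time == 0.002
        assert m.scale.n_ref == 20000

    def test_missing_join_is_not_a_tree(self):
        text = "branch A 1 2\nbranch B 1 2\nbranch C 1 2\njoin 0.01 A B\n"
        with pytest.raises(ValueError, match="not a rooted tree"):
            parse_model_file(text)

    def test_round_trip_identity(self):
        m = parse_model_file(TWO_POP)
        again = parse_model_file(write_model_file(m))
        assert write_model_file(again) == write_model_file(m)
        assert again.branches == m.branches
        assert again.joins == m.joins

    @pytest.mark.parametrize(
        "bad, err",
        [
            ("branch A\n", "expected"),
            ("branch A 1 2\nbranch A 1 2\njoin 0.1 A A\n", "duplicate"),
            ("frobnicate 1 2\n", "unknown directive"),
        ],
    )
    def test_syntax_errors_carry_line_numbers(self, bad, err):
        with pytest.raises((ModelSyntaxError, ValueError), match=err):
            parse_model_file(bad)


class TestValidation:
    def test_six_branch_nested_tree_is_valid(self):
        branches = [Branch(f"P{i}", 1.0, 4) for i in range(6)]
        joins = [
            JoinEvent(0.001, "P0", "P1"),
            JoinEvent(0.002, "P2", "P3"),
            JoinEvent(0.003, "P0", "P2"),
            JoinEvent(0.004, "P4", "P5"),
            JoinEvent(0.005, "P0", "P4"),
        ]
        assert validate_model(DemographyModel(branches, joins)) == []

    def test_zero_join_time(self):
        m = DemographyModel(
            [Branch("A", 1, 2), Branch("B", 1, 2)], [JoinEvent(0.0, "A", "B")]
        )
        assert any("time > 0" in v for v in validate_model(m))

    def test_sample_age_after_join(self):
        m = DemographyModel(
            [Branch("A", 1, 2), Branch("B", 1, 2, sample_age=0.01)],
            [JoinEvent(0.002, "A", "B")],
        )
        assert any("sample_age" in v for v in validate_model(m))

    def test_random_models_are_valid(self):
        for seed in range(20):
            m = random_tree_model(2 + seed % 5, seed=seed, with_ancient=seed % 3 == 0)
            assert validate_model(m) == []

    @pytest.mark.parametrize(
        "mutate",
        [
            lambda m: setattr(m.branches[0], "lam", -1.0),
            lambda m: setattr(m.branches[0], "sample_size", -1),
            lambda m: setattr(m.joins[0], "time", 0.0),
            lambda m: setattr(m.joins[0], "into", m.joins[0].from_),
            lambda m: m.joins.pop(),
            lambda m: setattr(m.joins[-1], "from_", "no-such-branch"),
        ],
    )
    def test_single_field_mutations_are_rejected(self, mutate):
        m = random_tree_model(4, seed=7)
        mutate(m)
        assert validate_model(m) != []


class TestUnits:
    def test_scaled_time_to_years(self):
        u = UnitScale(n_ref=20000, gen_years=29)
        assert u.scaled_to_years(0.003) == pytest.approx(3480.0)
        assert u.scaled_to_years(0.0) == 0.0

    def test_lambda_to_diploids(self):
        u = UnitScale(n_ref=20000)
        assert u.lambda_to_diploids(0.6) == pytest.approx(12000.0)

    @given(
        years=st.floats(1.0, 1e6),
        diploids=st.floats(1.0, 1e7),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_linear_and_invertible(self, years, diploids):
        u = UnitScale()
        assert u.scaled_to_years(u.years_to_scaled(years)) == pytest.approx(
            years, rel=1e-12
        )
        assert u.lambda_to_diploids(u.diploids_to_lambda(diploids)) == pytest.approx(
            diploids, rel=1e-12
        )

    def test_report_structure(self, two_pop_model):
        rep = to_real(two_pop_model, UnitScale())
        assert rep["joins"][0]["time_years"] == pytest.approx(0.002 * 40000 * 29)
        assert rep["branches"][1]["diploid_size"] == pytest.approx(10000.0)


class TestParameterMap:
    def test_pack_unpack_round_trip(self, five_pop_model):
        pmap = ParameterMap.free_all(five_pop_model)
        x = pmap.pack()
        m2 = pmap.unpack(x)
        for b1, b2 in zip(five_pop_model.branches, m2.branches):
            assert b2.lam == pytest.approx(b1.lam)
        for j1, j2 in zip(five_pop_model.sorted_joins(), m2.sorted_joins()):
            assert j2.time == pytest.approx(j1.time)

    def test_increments_keep_tree_order(self, five_pop_model):
        pmap = ParameterMap.free_all(five_pop_model)
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = pmap.pack() + rng.normal(0, 0.5, len(pmap))
            x = np.clip(x, [b[0] for b in pmap.bounds], [b[1] for b in pmap.bounds])
            assert validate_model(pmap.unpack(x)) == []

    def test_unknown_name_rejected(self, two_pop_model):
        with pytest.raises(ValueError, match="matches no"):
            ParameterMap(two_pop_model, ["t_B_A"])

    def test_log_transform_for_sizes(self, two_pop_model):
        pmap = ParameterMap(two_pop_model, ["lambda_B"])
        assert pmap.pack()[0] == pytest.approx(math.log(0.5))
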