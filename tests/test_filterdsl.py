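"""Filter language: grammar, evaluation semantics, algebraic properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import survfig as sf
from survfig.filterdsl import (BinOp, Compare, EmptyFilterResultError,
                               FilterNameError, FilterSyntaxError,
                               FilterTypeError, Logical, Neg, Not, Number,
                               Var, unparse)


@pytest.fixture()
def toy_ds():
    return sf.SurvivalDataset(pd.DataFrame({
        "a": [0.0, 1.0, 2.0, 3.0],
        "b": [3.0, 2.0, 1.0, 0.0],
    }))


class TestParse:
    def test_simple_comparison(self):
        assert sf.parse_filter("filtervar<2") == Compare("<", Var("filtervar"),
                                                         Number(2.0))

    def test_parenthesized_conjunction(self):
        expr = sf.parse_filter("(a>1) & (b<=3)")
        assert expr == Logical("AND", Compare(">", Var("a"), Number(1.0)),
                               Compare("<=", Var("b"), Number(3.0)))

    def test_word_operators_case_insensitive(self):
        assert sf.parse_filter("a<1 AND b>2") == sf.parse_filter("a<1 & b>2")
        assert sf.parse_filter("not a=1") == sf.parse_filter("~ a=1")
        assert sf.parse_filter("a<1 or b>2") == sf.parse_filter("a<1 | b>2")

    def test_comparison_synonyms(self):
        assert sf.parse_filter("a==1") == sf.parse_filter("a=1")
        assert sf.parse_filter("a!=1") == sf.parse_filter("a~=1")

    def test_precedence_arithmetic_over_comparison_over_logic(self):
        expr = sf.parse_filter("a+1*2<4 | b>1 & a<2")
        # * binds over +, comparison over &/|, AND over OR
        assert expr == Logical(
            "OR",
            Compare("<", BinOp("+", Var("a"), BinOp("*", Number(1.0), Number(2.0))),
                    Number(4.0)),
            Logical("AND", Compare(">", Var("b"), Number(1.0)),
                    Compare("<", Var("a"), Number(2.0))))

    @pytest.mark.parametrize("text,offset", [
        ("a >", 3),          # dangling operator
        ("(a>1", 4),         # unbalanced parenthesis
        ("a ? 1", 2),        # unknown token
        ("", 0),             # empty
    ])
    def test_syntax_errors_carry_offset(self, text, offset):
        with pytest.raises(FilterSyntaxError) as err:
            sf.parse_filter(text)
        assert err.value.offset == offset


class TestEvaluate:
    def test_worked_example_filter_counts(self, default_ds):
        mask = sf.evaluate_filter(sf.parse_filter("filtervar<2"), default_ds)
        assert int(mask.sum()) == 360
        assert int((~mask).sum()) == 70

    def test_tautology_and_contradiction(self, default_ds):
        assert sf.evaluate_filter(sf.parse_filter("timevar>=0"), default_ds).all()
        assert not sf.evaluate_filter(sf.parse_filter("timevar<0"), default_ds).any()

    def test_unknown_variable_lists_available(self, toy_ds):
        with pytest.raises(FilterNameError, match="a, b"):
            sf.evaluate_filter(sf.parse_filter("zz>1"), toy_ds)

    def test_arithmetic_inside_comparison(self, toy_ds):
        mask = sf.evaluate_filter(sf.parse_filter("a+b = 3"), toy_ds)
        assert mask.tolist() == [True, True, True, True]
        mask2 = sf.evaluate_filter(sf.parse_filter("a*2 > b"), toy_ds)
        assert mask2.tolist() == [False, False, True, True]

    def test_missing_values_compare_false(self):
        ds = sf.SurvivalDataset(pd.DataFrame({"x": [1.0, float("nan")]}))
        for text in ["x<2", "x>=0", "x~=1", "x=1"]:
            assert not sf.evaluate_filter(sf.parse_filter(text), ds)[1]

    def test_bare_numeric_expression_rejected(self, toy_ds):
        with pytest.raises(FilterTypeError):
            sf.evaluate_filter(sf.parse_filter("a+1"), toy_ds)


class TestApply:
    def test_worked_example_row_count(self, default_ds):
        filtered, removed = sf.apply_filter(default_ds,
                                            sf.parse_filter("filtervar<2"))
        assert filtered.n_rows == 360 and removed == 70

    def test_all_true_is_identity(self, toy_ds):
        filtered, removed = sf.apply_filter(toy_ds, sf.parse_filter("a>=0"))
        assert removed == 0 and filtered.equals(toy_ds)

    def test_empty_result_is_an_error(self, toy_ds):
        with pytest.raises(EmptyFilterResultError):
            sf.apply_filter(toy_ds, sf.parse_filter("a<0"))


# -- recursive AST strategy for property tests ------------------------------

_numeric = st.deferred(lambda: st.one_of(
    st.builds(Number, st.floats(min_value=0, max_value=100,
                                allow_nan=False).map(lambda v: round(v, 3))),
    st.builds(Var, st.sampled_from(["a", "b"])),
    st.builds(Neg, _numeric),
    st.builds(BinOp, st.sampled_from(["+", "-", "*", "/"]), _numeric, _numeric),
))

_boolean = st.deferred(lambda: st.one_of(
    st.builds(Compare, st.sampled_from(["<", "<=", ">", ">=", "=", "~="]),
              _numeric, _numeric),
    st.builds(Not, _boolean),
    st.builds(Logical, st.sampled_from(["AND", "OR"]), _boolean, _boolean),
))


class TestProperties:
    @given(expr=_boolean)
    def test_unparse_reparse_round_trip(self, expr):
        assert sf.parse_filter(unparse(expr)) == expr

    @given(expr=_boolean)
    def test_not_is_complement(self, expr):
        ds = sf.SurvivalDataset(pd.DataFrame(
            {"a": [0.0, 1.5, -2.0], "b": [1.0, 1.0, 4.0]}))
        mask = sf.evaluate_filter(expr, ds)
        neg = sf.evaluate_filter(Not(expr), ds)
        assert (mask ^ neg).all()

    @given(e1=_boolean, e2=_boolean)
    def test_conjunction_equals_sequential_filtering(self, e1, e2):
        ds = sf.SurvivalDataset(pd.DataFrame(
            {"a": [0.0, 1.0, 2.0, 5.0], "b": [2.0, 0.5, -1.0, 3.0]}))
        try:
            combined, _ = sf.apply_filter(ds, Logical("AND", e1, e2))
            step1, _ = sf.apply_filter(ds, e1)
            step2, _ = sf.apply_filter(step1, e2)
        except EmptyFilterResultError:
            return  # contract only constrains the error-free path
        assert combined.equals(step2)
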