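"""Tests of the constrained bivariate rational family and its model libraries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tabrom import rational
from tabrom.rational import (
    ModelCombination,
    RationalParams,
    compaction_triple_library,
    eq16_pair_library,
    eval_rational,
    get_variant,
    limit_values,
    normalize,
    pair_library,
    param_count,
)

positive = st.floats(1e-4, 1e3)


def random_params(rng) -> RationalParams:
    v = 10.0 ** rng.uniform(-3, 2, size=7)
    return RationalParams(p1=v[0], p4=v[1], q1=v[2], q2=v[3], q3=v[4], q5=v[5], q6=v[6])


class TestNormalization:
    def test_anchor_values(self):
        assert normalize(0.0, 2.0, 1.0) == 0.0
        assert normalize(1.0, 2.0, 1.0) == pytest.approx(1.0)
        assert normalize(1.5, 2.0, 1.0) == pytest.approx(3.0)

    def test_monotone_and_singular(self):
        v = np.linspace(0.0, 1.9, 50)
        x = normalize(v, 2.0, 0.7)
        assert np.all(np.diff(x) > 0)
        with pytest.raises(ValueError):
            normalize(2.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            normalize(-0.1, 2.0, 1.0)


class TestEvaluation:
    def test_origin_is_p4_for_every_variant(self):
        rng = np.random.default_rng(0)
        for vid in range(1, 16):
            for _ in range(20):
                p = random_params(rng)
                assert eval_rational(vid, p, 0.0, 0.0) == pytest.approx(p.p4)

    def test_constant_variant(self):
        p = RationalParams(p4=0.37)
        assert eval_rational(9, p, 3.0, 7.0) == 0.37

    def test_variant8_hand_value(self):
        p = RationalParams(p1=2.0, p4=1.0, q1=1.0)
        assert eval_rational(8, p, 1.0, 1.0) == pytest.approx(1.5)

    def test_constraint_elimination_identity(self):
        # the unconstrained first-degree form with p2 = p4 q2, p3 = p4 q3
        # equals the constrained form to near machine precision
        rng = np.random.default_rng(1)
        X, Y = rng.uniform(0, 5, 40), rng.uniform(0, 5, 40)
        for _ in range(50):
            p = random_params(rng)
            p2, p3 = p.p4 * p.q2, p.p4 * p.q3
            unconstrained = (p.p1 * X * Y + p2 * X + p3 * Y + p.p4) / (
                p.q1 * X * Y + p.q2 * X + p.q3 * Y + 1.0
            )
            constrained = eval_rational(2, p, X, Y)
            np.testing.assert_allclose(constrained, unconstrained, rtol=1e-12)

    def test_limits_analytic_and_numeric(self):
        rng = np.random.default_rng(2)
        big = 1e6
        for vid in range(1, 16):
            variant = get_variant(vid)
            for _ in range(70):  # ~1000 draws across the 15 variants
                p = random_params(rng)
                lims = limit_values(variant, p)
                assert lims["f(0,0)"] == p.p4
                # constrained single-variable infinities collapse to p4
                assert eval_rational(variant, p, big, 0.0) == pytest.approx(p.p4, rel=1e-5)
                assert eval_rational(variant, p, 0.0, big) == pytest.approx(p.p4, rel=1e-5)
                if variant.base is rational.RationalBase.FIRST_DEGREE:
                    assert lims["f(inf,inf)"] == pytest.approx(p.p1 / p.q1)
                    # diagonal convergence is O(q/(q1 X)); probe far out
                    assert eval_rational(variant, p, 1e12, 1e12) == pytest.approx(
                        lims["f(inf,inf)"], rel=1e-4
                    )

    def test_first_degree_monotone_second_degree_not(self):
        rng = np.random.default_rng(3)
        grid = np.linspace(0.0, 10.0, 60)
        for _ in range(40):
            p = random_params(rng)
            for vid in (1, 3, 5, 7):
                for ypin in (0.3, 2.0):
                    vals = eval_rational(vid, p, grid, ypin)
                    diffs = np.diff(vals)
                    assert np.all(diffs >= -1e-10) or np.all(diffs <= 1e-10)
        # a known non-monotone witness for the second-degree family
        p = RationalParams(p1=14.21, p4=0.17, q1=51.58, q5=0.17)
        vals = eval_rational(13, p, grid[1:], 1.0)
        diffs = np.diff(vals)
        assert np.any(diffs > 0) and np.any(diffs < 0)

    def test_invalid_inputs(self):
        with pytest.raises(KeyError):
            get_variant(16)
        with pytest.raises(ValueError):
            eval_rational(2, RationalParams(p1=1, p4=1, q1=1), -1.0, 0.0)
        with pytest.raises(ValueError):
            RationalParams(q1=-0.5)


class TestLibraries:
    def test_pair_library_size_and_membership(self):
        pairs = pair_library()
        assert len(pairs) == 43
        assert (9, 9) in pairs and (9, 15) in pairs and (1, 9) in pairs
        assert (1, 2) not in pairs
        assert pairs == sorted(pairs)

    def test_eq16_restriction(self):
        pairs = eq16_pair_library()
        assert len(pairs) == 25
        assert (3, 3) in pairs and (9, 5) in pairs
        assert all(a <= 9 and b <= 9 for a, b in pairs)

    def test_full_cartesian_reference(self):
        assert len(rational.VARIANTS) == 15
        assert 15 * 15 == 225  # the unrestricted combination space

    def test_compaction_triples(self):
        triples = compaction_triple_library()
        for printed in [(9, 3, 3), (3, 9, 3), (1, 9, 1), (9, 5, 5), (9, 1, 1),
                        (6, 9, 6), (8, 9, 8), (9, 9, 9), (9, 8, 8), (8, 9, 9)]:
            assert printed in triples
        # never both a and 1/b coupled simultaneously
        assert all(t[0] == 9 or t[1] == 9 for t in triples)

    def test_library_json_serializes(self):
        import json

        payload = json.loads(rational.library_to_json())
        assert len(payload["variants"]) == 15
        assert len(payload["pair_library"]) == 43


class TestParamCount:
    @pytest.mark.parametrize(
        "vid,expected",
        [(1, 7), (2, 5), (3, 6), (4, 4), (5, 6), (6, 4), (7, 5), (8, 3),
         (9, 1), (10, 7), (11, 5), (12, 6), (13, 4), (14, 6), (15, 4)],
    )
    def test_single_variant_counts(self, vid, expected):
        assert get_variant(vid).n_parameters == expected
        assert param_count(ModelCombination("bulk_density", (vid,))) == expected

    @pytest.mark.parametrize(
        "stage,ids,extras,expected",
        [
            # compaction triples
            ("compaction", (9, 3, 3), (), 11),
            ("compaction", (3, 9, 3), (), 11),
            ("compaction", (1, 9, 1), (), 13),
            ("compaction", (9, 5, 5), (), 11),
            ("compaction", (9, 1, 1), (), 13),
            ("compaction", (6, 9, 6), (), 9),
            ("compaction", (8, 9, 8), (), 7),
            ("compaction", (9, 9, 9), (), 3),
            ("compaction", (9, 8, 8), (), 7),
            ("compaction", (8, 9, 9), (), 5),
            # elastic recovery pairs carry the exponent n
            ("elastic_recovery", (5, 5), ("n_exp",), 11),
            ("elastic_recovery", (6, 9), ("n_exp",), 6),
            ("elastic_recovery", (7, 9), ("n_exp",), 7),
            ("elastic_recovery", (2, 9), ("n_exp",), 7),
            ("elastic_recovery", (9, 8), ("n_exp",), 5),
            ("elastic_recovery", (9, 9), ("n_exp",), 3),
            ("elastic_recovery", (8, 9), ("n_exp",), 5),
            ("elastic_recovery", (4, 9), ("n_exp",), 6),
            # tensile pairs
            ("tensile_strength", (3, 3), (), 10),
            ("tensile_strength", (1, 1), (), 12),
            ("tensile_strength", (7, 7), (), 8),
            ("tensile_strength", (5, 5), (), 10),
            ("tensile_strength", (3, 9), (), 7),
            ("tensile_strength", (9, 5), (), 7),
            ("tensile_strength", (9, 7), (), 6),
            ("tensile_strength", (8, 8), (), 6),
        ],
    )
    def test_combination_counts_match_reference_tables(self, stage, ids, extras, expected):
        assert param_count(ModelCombination(stage, ids, extra_params=extras)) == expected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    vid=st.integers(1, 15),
    p1=positive, p4=positive, q1=positive, q2=positive, q3=positive,
    q5=positive, q6=positive,
    X=st.floats(0.0, 1e4), Y=st.floats(0.0, 1e4),
)
def test_rational_values_finite_and_positive(vid, p1, p4, q1, q2, q3, q5, q6, X, Y):
    p = RationalParams(p1=p1, p4=p4, q1=q1, q2=q2, q3=q3, q5=q5, q6=q6)
    val = eval_rational(vid, p, X, Y)
    assert np.isfinite(val) and val > 0
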