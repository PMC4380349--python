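"""Structure learning (class-conditional Chow-Liu) and CPT estimation."""

import numpy as np
import pandas as pd
import pytest
from _oracles import all_spanning_trees, cmi_triple_loop, full_joint, random_table

from tanfv.schema import CohortTable, VariableSpec
from tanfv.tan import (
    ParameterizedTAN,
    conditional_mutual_information,
    estimate_cpts,
    fit_tan,
    learn_tan_structure,
)


def _table(cols: dict) -> CohortTable:
    schema = [
        VariableSpec(n, tuple(str(j) for j in range(max(v) + 1 if max(v) else 2)),
                     role="class" if n == "c" else "attribute")
        for n, v in cols.items()
    ]
    return CohortTable(schema, pd.DataFrame(cols))


class TestConditionalMutualInformation:
    def test_copied_variable_gives_one_bit(self):
        """X identically equal to Y, uniform binary within each class:
        I(X;Y|S) = H(X|S) = 1 bit."""
        x = [0, 1, 0, 1, 0, 1, 0, 1]
        c = [0, 0, 0, 0, 1, 1, 1, 1]
        t = _table({"x": x, "y": list(x), "c": c})
        assert conditional_mutual_information("x", "y", t) == pytest.approx(1.0)

    def test_constant_variable_gives_zero(self):
        t = _table({"x": [0, 0, 0, 1], "y": [0, 0, 0, 0], "c": [0, 1, 0, 1]})
        assert conditional_mutual_information("x", "y", t) == 0.0

    def test_matches_triple_loop_oracle(self, rng):
        t = random_table(rng, 20, 2)
        got = conditional_mutual_information("x0", "x1", t)
        want = cmi_triple_loop(
            t.data["x0"].to_numpy(), t.data["x1"].to_numpy(), t.data["c"].to_numpy()
        )
        assert got == pytest.approx(want, abs=1e-12)

    def test_symmetric_and_nonnegative(self, rng):
        for _ in range(10):
            t = random_table(rng, 25, 3)
            a = conditional_mutual_information("x0", "x1", t)
            b = conditional_mutual_information("x1", "x0", t)
            assert a == pytest.approx(b, abs=1e-12)
            assert a >= 0.0


class TestLearnStructure:
    def test_chain_dependency_recovered(self, rng):
        """A -> B -> C given the class: the learned tree must be the
        A-B, B-C chain, the best of the three possible spanning trees."""
        n = 2000
        c = rng.integers(0, 2, n)
        a = (rng.random(n) < 0.3 + 0.4 * c).astype(int)
        b = np.where(rng.random(n) < 0.9, a, 1 - a)
        d = np.where(rng.random(n) < 0.9, b, 1 - b)
        t = _table({"a": list(a), "b": list(b), "d": list(d), "c": list(c)})
        s = learn_tan_structure(t)
        undirected = {frozenset(e) for e in s.edges}
        assert undirected == {frozenset({"a", "b"}), frozenset({"b", "d"})}
        assert s.parent["a"] is None  # rooted at the first attribute

    @pytest.mark.parametrize("n_attrs", [3, 4, 5])
    def test_tree_weight_matches_exhaustive_search(self, rng, n_attrs):
        """The Chow-Liu tree attains the maximum total CMI over every
        labeled spanning tree (Prüfer enumeration oracle)."""
        t = random_table(rng, 60, n_attrs)
        names = [v.name for v in t.attributes]
        w = {}
        for i in range(n_attrs):
            for j in range(i + 1, n_attrs):
                w[(i, j)] = conditional_mutual_information(names[i], names[j], t)
        s = learn_tan_structure(t)
        got = sum(
            w[tuple(sorted((names.index(a), names.index(b))))] for a, b in s.edges
        )
        best = max(
            sum(w[e] for e in tree) for tree in all_spanning_trees(n_attrs)
        )
        assert got == pytest.approx(best, abs=1e-12)

    def test_equal_weights_tie_break_is_lexicographic(self):
        """All-equal CMI weights: the greedy rule keeps the name-sorted
        first edges, so attributes chain off the lexicographic order."""
        # all attributes mutually independent and uniform -> all CMIs ~0
        rows = {"a": [0, 1] * 4, "b": [0, 0, 1, 1] * 2, "c": [0, 1, 1, 0] * 2}
        rows["s"] = [0, 0, 0, 0, 1, 1, 1, 1]
        schema = [
            VariableSpec("a", ("0", "1")),
            VariableSpec("b", ("0", "1")),
            VariableSpec("c", ("0", "1")),
            VariableSpec("s", ("0", "1"), role="class"),
        ]
        t = CohortTable(schema, pd.DataFrame(rows))
        s = learn_tan_structure(t)
        assert set(s.edges) == {("a", "b"), ("a", "c")}

    def test_record_order_invariance(self, rng):
        t = random_table(rng, 50, 4)
        perm = rng.permutation(50)
        shuffled = CohortTable(t.schema, t.data.iloc[perm].reset_index(drop=True))
        assert learn_tan_structure(t).edges == learn_tan_structure(shuffled).edges

    def test_empty_table_rejected(self):
        schema = [
            VariableSpec("a", ("0", "1")),
            VariableSpec("b", ("0", "1")),
            VariableSpec("s", ("0", "1"), role="class"),
        ]
        t = CohortTable(schema, pd.DataFrame({"a": [], "b": [], "s": []}))
        with pytest.raises(ValueError, match="empty"):
            learn_tan_structure(t)


class TestEstimateCpts:
    def test_ml_fit_is_empirical_frequency(self):
        t = _table({"x": [0, 0, 1, 1], "y": [0, 1, 1, 1], "c": [0, 0, 1, 1]})
        model = fit_tan(t, alpha=0.0)
        # class prior 2/4, 2/4
        assert model.class_prior == pytest.approx([0.5, 0.5])
        root = model.structure.roots[0]
        emp = t.data.groupby("c")[root].mean()
        cpt = np.asarray(model.cpts[root])
        for s in (0, 1):
            assert cpt[s, 0, 1] == pytest.approx(emp[s])

    def test_laplace_smoothing_of_unseen_state(self):
        """Zero count, alpha=1, binary variable, context count 3 ->
        probability (0+1)/(3+2) = 1/5."""
        from tanfv.tan import TanStructure

        t = _table({"x": [0, 0, 0, 1], "y": [0, 0, 0, 1], "c": [0, 0, 0, 1]})
        forced = TanStructure("c", ("x", "y"), {"x": None, "y": "x"})
        model = estimate_cpts(forced, t, alpha=1.0)
        # context (c=0, x=0) seen 3 times, y=1 never observed there
        assert np.asarray(model.cpts["y"])[0, 0, 1] == pytest.approx(1 / 5)

    def test_unseen_context_at_ml_warns_uniform(self):
        from tanfv.tan import TanStructure

        forced = TanStructure("c", ("x", "y"), {"x": None, "y": "x"})
        t = _table({"x": [0, 0, 0, 1], "y": [0, 1, 1, 0], "c": [0, 0, 1, 0]})
        with pytest.warns(UserWarning, match="unobserved parent"):
            model = estimate_cpts(forced, t, alpha=0.0)
        # the (c=1, x=1) context never occurs: uniform fallback
        assert np.asarray(model.cpts["y"])[1, 1] == pytest.approx([0.5, 0.5])

    def test_ml_fit_preserves_pairwise_class_marginals(self, rng):
        """Chow-Liu property: at alpha=0 the model joint reproduces every
        empirical (class, attribute) marginal (full-joint oracle)."""
        t = random_table(rng, 40, 4)
        model = fit_tan(t, alpha=0.0)
        joint = full_joint(model)
        names = list(model.structure.attributes)
        n = t.n_records
        for a in names:
            ax = names.index(a) + 1
            model_marg = joint.sum(axis=tuple(
                i for i in range(joint.ndim) if i not in (0, ax)
            ))
            emp = np.zeros_like(model_marg)
            for s, v in zip(t.data["c"], t.data[a]):
                emp[s, v] += 1 / n
            assert model_marg == pytest.approx(emp, abs=1e-12)

    def test_negative_alpha_rejected(self, rng):
        t = random_table(rng, 10, 2)
        with pytest.raises(ValueError, match="alpha"):
            fit_tan(t, alpha=-0.5)


class TestSerialization:
    def test_json_round_trip_bit_exact(self, replica_model):
        again = ParameterizedTAN.from_json(replica_model.to_json())
        assert again.structure == replica_model.structure
        assert again.class_states == replica_model.class_states
        np.testing.assert_array_equal(again.class_prior, replica_model.class_prior)
        for a in replica_model.structure.attributes:
            np.testing.assert_array_equal(
                np.asarray(again.cpts[a]), np.asarray(replica_model.cpts[a])
            )
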