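import math
from itertools import product

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import chi2

from cminet.datamodel import CminetError, Dag, DiscretizedMatrix
from cminet.mit_score import (ScoreCache, delta_move, dof_sequence,
                              empirical_mi, local_mit, total_mit)
from cminet.search import random_dag


def dmatrix(rows, cardinality=None) -> DiscretizedMatrix:
    rows = np.asarray(rows, dtype=int)
    genes = [f"G{i + 1}" for i in range(rows.shape[0])]
    samples = [f"S{j + 1}" for j in range(rows.shape[1])]
    card = cardinality or {g: int(rows[i].max()) for i, g in enumerate(genes)}
    return DiscretizedMatrix(genes, samples, rows, card)


def contingency_mi(x_lv, y_codes) -> float:
    """Independent contingency-table MI oracle (explicit triple loop)."""
    n = len(x_lv)
    total = 0.0
    for a in set(x_lv):
        for b in set(y_codes):
            nij = sum(1 for u, v in zip(x_lv, y_codes) if u == a and v == b)
            if nij == 0:
                continue
            ni = sum(1 for u in x_lv if u == a)
            nj = sum(1 for v in y_codes if v == b)
            total += nij * math.log(n * nij / (ni * nj))
    return total / n


class TestEmpiricalMI:
    def test_product_table_gives_zero(self):
        # node level independent of parent level by construction
        d = dmatrix([[1, 1, 2, 2], [1, 2, 1, 2]])
        assert empirical_mi("G1", ["G2"], d) == pytest.approx(0.0, abs=1e-12)

    def test_identical_binary_pair_gives_ln2(self):
        d = dmatrix([[1, 1, 1, 1, 2, 2, 2, 2], [1, 1, 1, 1, 2, 2, 2, 2]])
        assert empirical_mi("G1", ["G2"], d) == pytest.approx(math.log(2))

    def test_duplicate_parent_does_not_change_mi(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 4, size=30)
        b = rng.integers(1, 3, size=30)
        d = dmatrix([a, b, b])
        assert empirical_mi("G1", ["G2", "G3"], d) == pytest.approx(
            empirical_mi("G1", ["G2"], d))

    def test_matches_contingency_oracle(self):
        rng = np.random.default_rng(9)
        rows = rng.integers(1, 4, size=(3, 25))
        d = dmatrix(rows)
        joint = [tuple(p) for p in rows[1:].T]
        codes = [sorted(set(joint)).index(t) for t in joint]
        assert empirical_mi("G1", ["G2", "G3"], d) == pytest.approx(
            contingency_mi(list(rows[0]), codes), abs=1e-12)

    def test_empty_parents_zero(self):
        d = dmatrix([[1, 2], [1, 2]])
        assert empirical_mi("G1", [], d) == 0.0


class TestDofSequence:
    def test_binary_node_binary_parent(self):
        d = dmatrix([[1, 2, 1, 2], [1, 1, 2, 2]])
        assert dof_sequence("G1", ["G2"], d) == [1]

    def test_cardinalities_3_2_canonical_order(self):
        d = dmatrix([[1, 2, 1, 2, 1, 2],    # node, 2 levels
                     [1, 2, 3, 1, 2, 3],    # parent, 3 levels
                     [1, 1, 1, 2, 2, 2]])   # parent, 2 levels
        assert dof_sequence("G1", ["G2", "G3"], d) == [2, 3]

    def test_invariant_under_input_parent_order(self):
        d = dmatrix([[1, 2, 1, 2, 1, 2], [1, 2, 3, 1, 2, 3],
                     [1, 1, 1, 2, 2, 2]])
        assert dof_sequence("G1", ["G2", "G3"], d) == \
            dof_sequence("G1", ["G3", "G2"], d)


def chi2_quantile_oracle(alpha: float, dof: int) -> float:
    """Inverse CDF by root finding, independent of chi2.ppf."""
    return brentq(lambda x: chi2.cdf(x, dof) - alpha, 1e-9, 1e4)


class TestLocalMIT:
    D8 = [[1, 1, 1, 1, 2, 2, 2, 2], [1, 1, 1, 1, 2, 2, 2, 2]]

    def test_no_parents_scores_zero(self):
        score = local_mit("G1", [], dmatrix(self.D8), 0.999)
        assert score.value == 0.0 and score.mi_term == 0.0

    def test_perfect_binary_pair_alpha_0999(self):
        score = local_mit("G1", ["G2"], dmatrix(self.D8), 0.999)
        assert score.mi_term == pytest.approx(16 * math.log(2))
        assert score.penalty_term == pytest.approx(
            chi2_quantile_oracle(0.999, 1), abs=1e-6)
        assert score.penalty_term == pytest.approx(10.8276, abs=1e-4)
        assert score.value == pytest.approx(16 * math.log(2) - 10.8276, abs=1e-4)

    def test_cardinality_one_parent_changes_nothing(self):
        d = dmatrix([[1, 2, 1, 2], [1, 1, 2, 2], [1, 1, 1, 1]])
        with_extra = local_mit("G1", ["G2", "G3"], d, 0.99)
        without = local_mit("G1", ["G2"], d, 0.99)
        assert with_extra.value == pytest.approx(without.value)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(CminetError, match="alpha_score"):
            local_mit("G1", ["G2"], dmatrix(self.D8), 1.5)


def random_discrete_data(n_genes, n_samples, seed, levels=3):
    rng = np.random.default_rng(seed)
    return dmatrix(rng.integers(1, levels + 1, size=(n_genes, n_samples)))


class TestTotalAndDelta:
    def test_empty_dag_scores_zero(self):
        d = random_discrete_data(3, 20, 0)
        assert total_mit(Dag(d.genes), d, 0.999) == 0.0

    def test_total_equals_sum_of_locals(self):
        d = random_discrete_data(4, 30, 1)
        dag = Dag(d.genes, [("G1", "G2"), ("G1", "G3"), ("G2", "G4")])
        total = total_mit(dag, d, 0.99)
        parts = sum(local_mit(v, dag.parents(v), d, 0.99).value
                    for v in dag.vertices)
        assert total == pytest.approx(parts, abs=1e-12)

    def test_add_then_delete_deltas_cancel(self):
        d = random_discrete_data(3, 20, 2)
        dag = Dag(d.genes)
        up = delta_move(dag, "add", "G1", "G2", d, 0.99)
        dag.add_edge("G1", "G2")
        down = delta_move(dag, "delete", "G1", "G2", d, 0.99)
        assert up + down == pytest.approx(0.0, abs=1e-12)

    def test_reverse_equals_delete_plus_add_sequentially(self):
        d = random_discrete_data(3, 40, 3)
        dag = Dag(d.genes, [("G1", "G2"), ("G3", "G2")])
        rev = delta_move(dag, "reverse", "G1", "G2", d, 0.99)
        step = dag.copy()
        d1 = delta_move(step, "delete", "G1", "G2", d, 0.99)
        step.remove_edge("G1", "G2")
        d2 = delta_move(step, "add", "G2", "G1", d, 0.99)
        assert rev == pytest.approx(d1 + d2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_delta_matches_full_rescore_oracle(self, seed):
        d = random_discrete_data(5, 50, seed)
        rng = np.random.default_rng(seed + 100)
        dag = random_dag(d.genes, seed, max_parents=2)
        moves = []
        for x in d.genes:
            for y in d.genes:
                if x == y:
                    continue
                if dag.has_edge(x, y):
                    moves.append(("delete", x, y))
                    if dag.would_be_acyclic_after_reversal(x, y):
                        moves.append(("reverse", x, y))
                elif not dag.has_edge(y, x) and not dag.reachable(y, x):
                    moves.append(("add", x, y))
        move, x, y = moves[rng.integers(len(moves))]
        before = total_mit(dag, d, 0.99)
        delta = delta_move(dag, move, x, y, d, 0.99)
        after = dag.copy()
        if move == "add":
            after.add_edge(x, y)
        elif move == "delete":
            after.remove_edge(x, y)
        else:
            after.remove_edge(x, y)
            after.add_edge(y, x)
        assert delta == pytest.approx(total_mit(after, d, 0.99) - before,
                                      abs=1e-9)

    def test_illegal_moves_rejected(self):
        d = random_discrete_data(3, 10, 5)
        dag = Dag(d.genes, [("G1", "G2")])
        with pytest.raises(CminetError):
            delta_move(dag, "add", "G1", "G2", d, 0.99)
        with pytest.raises(CminetError):
            delta_move(dag, "delete", "G1", "G3", d, 0.99)

    def test_cache_returns_bit_identical_results(self):
        d = random_discrete_data(3, 30, 6)
        cache = ScoreCache(d, 0.99)
        first = cache.local("G1", ["G2"])
        second = cache.local("G1", ["G2"])
        assert first is second and cache.hits == 1


def test_score_not_invariant_under_reversal():
    """MIT is not score-equivalent: with a third variable involved the
    orientation of an edge changes the total."""
    rng = np.random.default_rng(12)
    z = rng.integers(1, 4, size=60)
    x = np.where(rng.random(60) < 0.8, z, rng.integers(1, 4, size=60))
    y = np.where(rng.random(60) < 0.8, x, rng.integers(1, 4, size=60))
    d = dmatrix([x, y, z], cardinality={"G1": 3, "G2": 3, "G3": 3})
    base = [("G3", "G1")]
    fwd = total_mit(Dag(d.genes, base + [("G1", "G2")]), d, 0.99)
    rev = total_mit(Dag(d.genes, base + [("G2", "G1")]), d, 0.99)
    assert fwd != pytest.approx(rev, abs=1e-9)
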