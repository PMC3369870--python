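"""Machine construction, generation, parsing, re-estimation, canonicalization."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from structdrift import (
    Machine,
    MachineError,
    UnparseableSampleError,
    canonical_machine,
    word_distribution,
)


def power_iteration_stationary(m, iters=2000):
    """Independent oracle: power-iterate the state-to-state matrix."""
    states = sorted(m.recurrent_states())
    idx = {s: i for i, s in enumerate(states)}
    P = np.zeros((len(states), len(states)))
    for (s, _a), (t, p) in m.transitions.items():
        if s in idx:
            P[idx[s], idx[t]] += p
    v = np.full(len(states), 1.0 / len(states))
    for _ in range(iters):
        v = v @ P
        v /= v.sum()
    return {s: v[i] for s, i in idx.items()}


class TestCanonicalLibrary:
    @pytest.mark.parametrize(
        "name,params,n_states,n_edges",
        [
            ("alternating", {}, 2, 2),
            ("fair_coin", {}, 1, 2),
            ("biased_coin", {"p": 0.3}, 1, 2),
            ("fixed_coin", {"symbol": "0"}, 1, 1),
            ("golden_mean", {"p": 0.5}, 2, 3),
            ("even", {"p": 0.5}, 2, 3),
            ("period_n", {"phase": "011"}, 3, 3),
        ],
    )
    def test_structure(self, name, params, n_states, n_edges):
        m = canonical_machine(name, **params)
        assert m.n_states == n_states
        assert m.n_edges == n_edges
        # row-stochasticity
        for s in m.states:
            assert math.isclose(
                sum(p for _a, _t, p in m.out_edges(s)), 1.0, abs_tol=1e-12
            )

    def test_degenerate_bias_is_fixed_coin(self):
        m = canonical_machine("biased_coin", p=1.0)
        assert m.n_states == 1 and m.n_edges == 1
        assert ("A", "1") in m.transitions

    def test_unknown_name_and_bad_params(self):
        with pytest.raises(MachineError):
            canonical_machine("nope")
        with pytest.raises(MachineError):
            canonical_machine("golden_mean", p=0.0)
        with pytest.raises(MachineError):
            canonical_machine("biased_coin", p=1.5)


class TestStationary:
    def test_alternating_symmetric(self, alternating):
        pi = alternating.stationary_distribution()
        assert pi == {"A": 0.5, "B": 0.5}

    def test_single_state(self, fair_coin):
        assert fair_coin.stationary_distribution() == {"A": 1.0}

    def test_golden_mean_vs_power_iteration(self, golden_mean):
        pi = golden_mean.stationary_distribution()
        oracle = power_iteration_stationary(golden_mean)
        for s in pi:
            assert pi[s] == pytest.approx(oracle[s], abs=1e-10)
        assert pi["A"] == pytest.approx(2 / 3, abs=1e-12)


class TestGenerate:
    def test_alternating_phases(self, alternating, rng):
        s = alternating.generate(6, rng).as_string()
        assert s in ("010101", "101010")

    def test_fixed_coin_homogeneous(self, fixed_coin, rng):
        assert fixed_coin.generate(4, rng).as_string() == "1111"

    def test_biased_coin_frequency(self, rng):
        m = canonical_machine("biased_coin", p=0.3)
        n = 10**5
        s = m.generate(n, rng)
        k = s.as_string().count("1")
        sigma = math.sqrt(n * 0.3 * 0.7)
        assert abs(k - 0.3 * n) < 3 * sigma

    def test_length_validation(self, fair_coin):
        with pytest.raises(MachineError):
            fair_coin.generate(0)


class TestParse:
    def test_alternating_exact(self, alternating):
        pr = alternating.parse("0101", start="A")
        assert pr.log_likelihood == 0.0
        assert pr.edge_counts == {("A", "0"): 2, ("B", "1"): 2}
        assert pr.state_path == ("A", "B", "A", "B", "A")

    def test_forbidden_word(self, alternating):
        assert alternating.parse("0011").log_likelihood == -math.inf

    def test_fair_coin_all_words_length8(self, fair_coin):
        # enumeration oracle: every length-8 word has likelihood 2^-8
        for word in itertools.product("01", repeat=8):
            assert fair_coin.parse("".join(word)).log_likelihood == -8.0

    def test_best_start_beats_fixed_start(self, alternating):
        best = alternating.parse("1010", start="best")
        assert best.log_likelihood == 0.0
        assert best.start_state == "B"

    def test_symbol_outside_alphabet(self, fair_coin):
        with pytest.raises(MachineError):
            fair_coin.parse("01x")


class TestReestimate:
    def test_fair_coin_counts(self, fair_coin):
        m = fair_coin.reestimate("1110")
        assert m.transitions[("A", "1")] == ("A", 0.75)
        assert m.transitions[("A", "0")] == ("A", 0.25)

    def test_golden_mean_topology_preserved(self, golden_mean, rng):
        s = golden_mean.generate(200, rng)
        m = golden_mean.reestimate(s)
        pr = golden_mean.parse(s, "best")
        k = pr.edge_counts.get(("A", "1"), 0)
        j = pr.edge_counts.get(("A", "0"), 0)
        assert k > 0 and j > 0
        assert m.transitions[("A", "1")] == ("B", k / (k + j))
        assert m.transitions[("A", "0")] == ("A", j / (k + j))
        assert m.transitions[("B", "0")] == ("A", 1.0)

    def test_unused_edge_removed(self, golden_mean):
        m = golden_mean.reestimate("0000")
        assert ("A", "1") not in m.transitions
        assert m.transitions[("A", "0")] == ("A", 1.0)

    def test_unvisited_state_kept_transient(self):
        # C ties with A on "00"; the tie-break starts at A, leaving C unvisited
        m = Machine(
            ("0", "1"),
            {
                ("A", "0"): ("A", 0.5),
                ("A", "1"): ("A", 0.5),
                ("C", "0"): ("A", 0.5),
                ("C", "1"): ("C", 0.5),
            },
        )
        m2 = m.reestimate("00")
        assert "C" in m2.transient_flags
        # C's old distribution is untouched
        assert m2.transitions[("C", "0")] == ("A", 0.5)
        assert m2.transitions[("C", "1")] == ("C", 0.5)
        assert ("A", "1") not in m2.transitions

    def test_unparseable_raises(self, alternating):
        with pytest.raises(UnparseableSampleError):
            alternating.reestimate("0011")


class TestCanonicalize:
    def test_golden_mean_without_selfloop_is_alternating(self, golden_mean, alternating):
        # removing the self-loop leaves the period-2 machine
        trans = {
            ("A", "1"): ("B", 1.0),
            ("B", "0"): ("A", 1.0),
        }
        m = Machine(("0", "1"), trans)
        assert m.canonicalize() == alternating.canonicalize()

    def test_duplicate_states_merge(self):
        trans = {
            ("X", "0"): ("Y", 0.4),
            ("X", "1"): ("X", 0.6),
            ("Y", "0"): ("X", 0.4),
            ("Y", "1"): ("Y", 0.6),
        }
        m = Machine(("0", "1"), trans)
        assert m.canonicalize().n_states == 1

    @pytest.mark.parametrize(
        "name,params",
        [
            ("alternating", {}),
            ("golden_mean", {"p": 0.5}),
            ("even", {"p": 0.3}),
            ("period_n", {"phase": "0110"}),
        ],
    )
    def test_idempotent(self, name, params):
        m = canonical_machine(name, **params)
        c = m.canonicalize()
        assert c.canonicalize() == c

    def test_relabeling_invariance(self, golden_mean):
        relabeled = Machine(
            golden_mean.alphabet,
            {
                (s.replace("A", "Q").replace("B", "R"), a): (
                    t.replace("A", "Q").replace("B", "R"),
                    p,
                )
                for (s, a), (t, p) in golden_mean.transitions.items()
            },
        )
        assert relabeled.canonicalize() == golden_mean.canonicalize()

    def test_preserves_word_distribution(self, golden_mean):
        c = golden_mean.canonicalize()
        for L in range(1, 9):
            d1 = word_distribution(golden_mean, L)
            d2 = word_distribution(c, L)
            assert set(d1) == set(d2)
            for w in d1:
                assert d1[w] == pytest.approx(d2[w], abs=1e-10)


class TestInvariantsUnderOperations:
    def test_edge_frequencies_converge(self, golden_mean):
        # law of large numbers: parsed edge frequencies -> T^(a)
        rng = np.random.default_rng(99)
        M = 10**5
        s = golden_mean.generate(M, rng)
        pr = golden_mean.parse(s, "best")
        totals = {}
        for (st, _a), c in pr.edge_counts.items():
            totals[st] = totals.get(st, 0) + c
        for (st, a), (t, p) in golden_mean.transitions.items():
            c = pr.edge_counts.get((st, a), 0)
            n = totals[st]
            sigma = math.sqrt(n * p * (1 - p)) if 0 < p < 1 else 0.0
            assert abs(c - n * p) <= 3 * sigma + 1e-9

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 2**20),
        name=st.sampled_from(["golden_mean", "even", "fair_coin"]),
        p=st.floats(0.1, 0.9),
    )
    def test_reestimate_preserves_invariants(self, seed, name, p):
        params = {} if name == "fair_coin" else {"p": p}
        m = canonical_machine(name, **params)
        rng = np.random.default_rng(seed)
        s = m.generate(80, rng)
        m2 = m.reestimate(s)
        # unifilarity is structural; check stochasticity and positivity
        for st_ in m2.states:
            outs = m2.out_edges(st_)
            assert outs, f"state {st_} lost all edges"
            assert math.isclose(sum(x[2] for x in outs), 1.0, abs_tol=1e-9)
            assert all(x[2] > 0 for x in outs)
        assert m2.recurrent_states()


class TestSerialization:
    def test_json_roundtrip_exact(self, golden_mean):
        text = golden_mean.to_json()
        m = Machine.from_json(text)
        assert m == golden_mean
        assert m.to_json() == text

    def test_dot_contains_edges(self, alternating):
        dot = alternating.to_dot()
        assert '"A" -> "B"' in dot and "0 | 1" in dot
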