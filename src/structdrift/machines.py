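"""Unifilar probabilistic finite-state population generators (epsilon-machines).

A machine is a finite set of causal states over a finite allele alphabet.
From each state, each symbol labels at most one outgoing transition
(*unifilarity*), each transition carries a positive probability, and the
probabilities leaving a state sum to one.  Generating a population means
walking the machine: at each step a symbol is drawn from the current state's
outgoing distribution and the (unique) transition it labels is taken.  The
ordered string of emitted symbols is one generation of ``M`` haploid
individuals.

This module provides the data structure, a library of canonical processes
(alternating, fair/biased/fixed coin, golden mean, even, period-n), string
generation, parsing/likelihood, maximum-likelihood re-estimation, and a
canonicalization routine (transient trimming + state merging + canonical
relabeling) used for topology signatures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx
import numpy as np

ROW_SUM_TOL = 1e-12
DEFAULT_PROB_TOL = 1e-9

Symbol = str
State = str
Edge = tuple[State, Symbol]

_NEG_INF = float("-inf")


class MachineError(ValueError):
    """Invalid machine specification or operation."""


class ReducibleMachineError(MachineError):
    """The recurrent part splits into several terminal components."""


class UnparseableSampleError(MachineError):
    """No start state yields a finite-likelihood parse of the sample."""


def as_generator(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class PopulationSample:
    """One generation: an ordered length-M string of alleles.

    ``ploidy_convention`` records whether M counts individuals (haploid,
    M = N) or alleles of N diploid individuals (M = 2N); it does not affect
    the symbol content.
    """

    symbols: tuple[Symbol, ...]
    ploidy_convention: str = "haploid"

    def __post_init__(self):
        if len(self.symbols) < 1:
            raise MachineError("a population needs at least one individual")
        if self.ploidy_convention not in ("haploid", "diploid"):
            raise MachineError("ploidy_convention must be 'haploid' or 'diploid'")

    def __len__(self) -> int:
        return len(self.symbols)

    def as_string(self) -> str:
        return "".join(self.symbols)


def as_sample(s: Union[PopulationSample, str, Sequence[Symbol]]) -> PopulationSample:
    """Coerce a string or symbol sequence into a :class:`PopulationSample`."""
    if isinstance(s, PopulationSample):
        return s
    if isinstance(s, str):
        return PopulationSample(tuple(s))
    return PopulationSample(tuple(s))


@dataclass(frozen=True)
class ParseResult:
    """Outcome of feeding a sample through a machine from one start state.

    ``log_likelihood`` is base-2; ``-inf`` means the walk hit a missing
    transition, in which case ``edge_counts`` cover only the parsed prefix.
    """

    start_state: State
    state_path: tuple[State, ...]
    edge_counts: dict[Edge, int]
    log_likelihood: float


class Machine:
    """A unifilar probabilistic finite-state generator.

    Parameters
    ----------
    alphabet : iterable of symbols (the alleles).
    transitions : mapping ``(state, symbol) -> (next_state, probability)``.
        Unifilarity is structural: the mapping admits one target per
        (state, symbol).  Every stored probability must be positive; rows
        must sum to 1 within ``1e-12``.
    states : optional explicit state ordering; inferred (sorted) otherwise.
    notes : free-form provenance string.
    transient_flags : states known not to be revisited (bookkeeping from
        re-estimation; excluded from nothing here — recurrence is always
        recomputed from the support graph).
    """

    __slots__ = (
        "alphabet",
        "states",
        "transitions",
        "notes",
        "transient_flags",
        "_cache",
    )

    def __init__(
        self,
        alphabet: Iterable[Symbol],
        transitions: Mapping[Edge, tuple[State, float]],
        states: Sequence[State] | None = None,
        notes: str = "",
        transient_flags: frozenset[State] = frozenset(),
        validate: bool = True,
    ):
        self.alphabet: tuple[Symbol, ...] = tuple(alphabet)
        self.transitions: dict[Edge, tuple[State, float]] = {
            (s, a): (t, float(p)) for (s, a), (t, p) in transitions.items()
        }
        if states is None:
            found = {s for (s, _a) in self.transitions} | {
                t for (t, _p) in self.transitions.values()
            }
            states = sorted(found)
        self.states: tuple[State, ...] = tuple(states)
        self.notes = notes
        self.transient_flags = frozenset(transient_flags)
        self._cache: dict = {}
        if validate:
            self._validate()

    # ------------------------------------------------------------------ basics

    def _validate(self) -> None:
        if len(set(self.alphabet)) != len(self.alphabet) or not self.alphabet:
            raise MachineError("alphabet must be a nonempty set of distinct symbols")
        stateset = set(self.states)
        if len(stateset) != len(self.states) or not stateset:
            raise MachineError("states must be a nonempty set of distinct identifiers")
        row_sums: dict[State, float] = {}
        for (s, a), (t, p) in self.transitions.items():
            if s not in stateset or t not in stateset:
                raise MachineError(f"transition ({s},{a})->{t} uses unknown state")
            if a not in self.alphabet:
                raise MachineError(f"symbol {a!r} not in alphabet")
            if not (p > 0.0):
                raise MachineError(
                    f"transition ({s},{a}) has non-positive probability {p}"
                )
            if p > 1.0 + ROW_SUM_TOL:
                raise MachineError(f"transition ({s},{a}) has probability {p} > 1")
            row_sums[s] = row_sums.get(s, 0.0) + p
        for s in self.states:
            total = row_sums.get(s, 0.0)
            if abs(total - 1.0) > 1e-9:
                raise MachineError(
                    f"outgoing probabilities of state {s} sum to {total}, not 1"
                )
        if not self.recurrent_states():
            raise MachineError("machine has an empty recurrent part")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_edges(self) -> int:
        return len(self.transitions)

    def out_edges(self, state: State) -> list[tuple[Symbol, State, float]]:
        """Outgoing (symbol, target, probability) triples, symbol-sorted."""
        out = [
            (a, t, p) for (s, a), (t, p) in self.transitions.items() if s == state
        ]
        out.sort(key=lambda x: x[0])
        return out

    def support_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        for (s, _a), (t, _p) in self.transitions.items():
            g.add_edge(s, t)
        return g

    def support_key(self) -> tuple:
        """Hashable key identifying the topology (edge support, no probabilities)."""
        key = self._cache.get("support_key")
        if key is None:
            key = (
                self.alphabet,
                frozenset((s, a, t) for (s, a), (t, _p) in self.transitions.items()),
            )
            self._cache["support_key"] = key
        return key

    def terminal_components(self) -> list[frozenset[State]]:
        """Terminal (no out-edge in the condensation) strongly-connected components."""
        comps = self._cache.get("terminal_components")
        if comps is None:
            g = self.support_graph()
            cond = nx.condensation(g)
            comps = [
                frozenset(cond.nodes[n]["members"])
                for n in cond.nodes
                if cond.out_degree(n) == 0
            ]
            comps.sort(key=lambda c: min(c))
            self._cache["terminal_components"] = comps
        return comps

    def recurrent_states(self) -> frozenset[State]:
        rec = self._cache.get("recurrent")
        if rec is None:
            rec = frozenset().union(*self.terminal_components()) if self.terminal_components() else frozenset()
            self._cache["recurrent"] = rec
        return rec

    def recurrent_part(self) -> "Machine":
        """The machine restricted to its recurrent states (terminal components)."""
        rec = self.recurrent_states()
        if set(self.states) == rec:
            return self
        trans = {
            (s, a): (t, p) for (s, a), (t, p) in self.transitions.items() if s in rec
        }
        return Machine(
            self.alphabet,
            trans,
            states=[s for s in self.states if s in rec],
            notes=self.notes,
        )

    # --------------------------------------------------------------- stationary

    def stationary_distribution(self) -> dict[State, float]:
        """Stationary state distribution pi on the recurrent part.

        pi is the left unit eigenvector of the state-to-state transition
        matrix (transition probabilities summed over symbols), normalized to
        sum to 1.  Raises :class:`ReducibleMachineError` when the recurrent
        part has several terminal components (pi is then not unique).
        """
        pi = self._cache.get("stationary")
        if pi is not None:
            return pi
        comps = self.terminal_components()
        if len(comps) != 1:
            names = [sorted(c) for c in comps]
            raise ReducibleMachineError(
                f"multiple terminal components {names}; restrict to one first"
            )
        rec = sorted(comps[0])
        idx = {s: i for i, s in enumerate(rec)}
        n = len(rec)
        if n == 1:
            pi = {rec[0]: 1.0}
        else:
            P = np.zeros((n, n))
            for (s, _a), (t, p) in self.transitions.items():
                if s in idx:
                    P[idx[s], idx[t]] += p
            # solve pi (P - I) = 0 with sum(pi) = 1
            A = (P.T - np.eye(n))
            A[-1, :] = 1.0
            b = np.zeros(n)
            b[-1] = 1.0
            v = np.linalg.solve(A, b)
            v = np.clip(v, 0.0, None)
            v = v / v.sum()
            pi = {s: float(v[i]) for s, i in idx.items()}
        self._cache["stationary"] = pi
        return pi

    # --------------------------------------------------------------- generation

    def _gen_tables(self):
        tab = self._cache.get("gen_tables")
        if tab is None:
            tab = {}
            for s in self.states:
                outs = self.out_edges(s)
                cum, syms, tgts = [], [], []
                acc = 0.0
                for a, t, p in outs:
                    acc += p
                    cum.append(acc)
                    syms.append(a)
                    tgts.append(t)
                cum[-1] = 1.0 + 1e-15  # guard against roundoff at the top
                tab[s] = (cum, syms, tgts)
            self._cache["gen_tables"] = tab
        return tab

    def generate(self, length: int, rng=None) -> PopulationSample:
        """Generate one length-``length`` population.

        The start state is sampled from the stationary distribution, then
        each symbol is drawn from the current state's outgoing distribution.
        """
        if length < 1:
            raise MachineError("length must be >= 1")
        rng = as_generator(rng)
        pi = self.stationary_distribution()
        pstates = sorted(pi)
        u0 = rng.random()
        acc = 0.0
        state = pstates[-1]
        for s in pstates:
            acc += pi[s]
            if u0 <= acc:
                state = s
                break
        tab = self._gen_tables()
        u = rng.random(length)
        out = []
        append = out.append
        for x in u:
            cum, syms, tgts = tab[state]
            k = 0
            while x > cum[k]:
                k += 1
            append(syms[k])
            state = tgts[k]
        return PopulationSample(tuple(out))

    # ------------------------------------------------------------------ parsing

    def _log2_table(self) -> dict[Edge, float]:
        tab = self._cache.get("log2p")
        if tab is None:
            tab = {e: math.log2(p) for e, (_t, p) in self.transitions.items()}
            self._cache["log2p"] = tab
        return tab

    def parse(
        self, sample: Union[PopulationSample, str, Sequence[Symbol]], start: State | str = "best"
    ) -> ParseResult:
        """Follow the unique unifilar path of ``sample`` from a start state.

        ``start="best"`` evaluates every start state and returns the
        maximum-likelihood parse (ties broken by state-identifier order).
        A missing transition yields log-likelihood ``-inf`` with edge counts
        covering only the parsed prefix.
        """
        sample = as_sample(sample)
        for a in sample.symbols:
            if a not in self.alphabet:
                raise MachineError(f"symbol {a!r} outside machine alphabet")
        if start == "best":
            candidates = sorted(self.states)
        else:
            if start not in self.states:
                raise MachineError(f"unknown start state {start!r}")
            candidates = [start]
        trans = self.transitions
        log2p = self._log2_table()
        best: ParseResult | None = None
        for s0 in candidates:
            path = [s0]
            counts: dict[Edge, int] = {}
            ll = 0.0
            s = s0
            for a in sample.symbols:
                e = (s, a)
                nxt = trans.get(e)
                if nxt is None:
                    ll = _NEG_INF
                    break
                counts[e] = counts.get(e, 0) + 1
                ll += log2p[e]
                s = nxt[0]
                path.append(s)
            res = ParseResult(s0, tuple(path), counts, ll)
            if best is None or res.log_likelihood > best.log_likelihood:
                best = res
        assert best is not None
        return best

    # ------------------------------------------------------------ re-estimation

    def reestimate(self, sample: Union[PopulationSample, str, Sequence[Symbol]]) -> "Machine":
        """Maximum-likelihood update of the transition probabilities.

        The sample is fed through the machine (best start state); edge counts
        are normalized per state to give the new probabilities.  Edges of a
        traversed state that received zero counts are deleted.  States whose
        outgoing edges were never traversed keep their old distribution; of
        those, states never visited at all are flagged transient, and states
        that cannot even reach the visited set are dropped (their edges to
        dropped states are removed and the survivors renormalized).
        """
        sample = as_sample(sample)
        pr = self.parse(sample, "best")
        if pr.log_likelihood == _NEG_INF:
            raise UnparseableSampleError(
                "sample has no finite-likelihood parse under this machine"
            )
        totals: dict[State, int] = {}
        for (s, _a), c in pr.edge_counts.items():
            totals[s] = totals.get(s, 0) + c
        visited = set(pr.state_path)
        # states that can reach the visited set (reverse BFS over support)
        rev: dict[State, set[State]] = {s: set() for s in self.states}
        for (s, _a), (t, _p) in self.transitions.items():
            rev[t].add(s)
        keep = set(visited)
        frontier = list(visited)
        while frontier:
            nxt = []
            for t in frontier:
                for s in rev[t]:
                    if s not in keep:
                        keep.add(s)
                        nxt.append(s)
            frontier = nxt
        newtrans: dict[Edge, tuple[State, float]] = {}
        pending_renorm: dict[State, float] = {}
        for (s, a), (t, p) in self.transitions.items():
            if s not in keep:
                continue
            if totals.get(s, 0) > 0:
                c = pr.edge_counts.get((s, a), 0)
                if c:
                    newtrans[(s, a)] = (t, c / totals[s])
            else:
                if t in keep:
                    newtrans[(s, a)] = (t, p)
                    pending_renorm[s] = pending_renorm.get(s, 0.0) + p
        for s, total in pending_renorm.items():
            if abs(total - 1.0) > ROW_SUM_TOL:
                for (s2, a), (t, p) in list(newtrans.items()):
                    if s2 == s:
                        newtrans[(s2, a)] = (t, p / total)
        transient = frozenset(s for s in keep if s not in visited)
        return Machine(
            self.alphabet,
            newtrans,
            states=[s for s in self.states if s in keep],
            notes=self.notes,
            transient_flags=transient,
        )

    # ---------------------------------------------------------- canonicalization

    def canonicalize(self, tol: float = DEFAULT_PROB_TOL) -> "Machine":
        """Minimal canonical presentation of the recurrent process.

        Trims transient states, merges states whose future word distributions
        agree (probabilities compared after rounding at ``tol``; partition
        refinement to depth |S|), and relabels states ``S0, S1, ...`` in
        breadth-first order from the state with the lexicographically
        smallest behavioral signature.  Idempotent.
        """
        ndigits = max(1, int(round(-math.log10(tol))))
        rec = sorted(self.recurrent_states())
        trans = {
            (s, a): (t, p) for (s, a), (t, p) in self.transitions.items() if s in rec
        }
        # ---- partition refinement (Moore) on rounded probabilities
        block = {s: 0 for s in rec}
        for _ in range(max(1, len(rec))):
            sigs = {}
            for s in rec:
                sig = tuple(
                    sorted(
                        (a, block[t], round(p, ndigits))
                        for (s2, a), (t, p) in trans.items()
                        if s2 == s
                    )
                )
                sigs[s] = sig
            order: dict[tuple, int] = {}
            newblock = {}
            for s in rec:
                if sigs[s] not in order:
                    order[sigs[s]] = len(order)
                newblock[s] = order[sigs[s]]
            if newblock == block:
                break
            block = newblock
        rep: dict[int, State] = {}
        for s in rec:
            rep.setdefault(block[s], s)
        qstates = sorted(rep.values())
        qtrans: dict[Edge, tuple[State, float]] = {}
        for r in qstates:
            for a, t, p in self.out_edges(r):
                if (r, a) in trans:
                    qtrans[(r, a)] = (rep[block[t]], p)
        # ---- canonical relabeling: BFS from smallest depth-n signature
        def depth_sigs() -> dict[State, str]:
            sg = {s: "" for s in qstates}
            for _ in range(len(qstates)):
                sg = {
                    s: "("
                    + ";".join(
                        f"{a}:{round(p, ndigits)}:{sg[qtrans[(s, a)][0]]}"
                        for a, _t, p in [
                            (a, t, p)
                            for (s2, a), (t, p) in sorted(qtrans.items())
                            if s2 == s
                        ]
                    )
                    + ")"
                    for s in sg
                }
            return sg

    # (helper defined above to keep the relabeling readable)
        sg = depth_sigs()
        unplaced = set(qstates)
        naming: dict[State, str] = {}
        bfs_order: list[State] = []
        while unplaced:
            root = min(unplaced, key=lambda s: (sg[s], s))
            queue = [root]
            unplaced.discard(root)
            while queue:
                s = queue.pop(0)
                bfs_order.append(s)
                for a, t, _p in sorted(
                    (a, t, p) for (s2, a), (t, p) in qtrans.items() if s2 == s
                ):
                    if t in unplaced:
                        unplaced.discard(t)
                        queue.append(t)
        for i, s in enumerate(bfs_order):
            naming[s] = f"S{i}"
        ctrans = {
            (naming[s], a): (naming[t], p) for (s, a), (t, p) in qtrans.items()
        }
        return Machine(
            self.alphabet,
            ctrans,
            states=[naming[s] for s in bfs_order],
            notes=self.notes,
        )

    # -------------------------------------------------------------- serialization

    def to_json(self) -> str:
        """Canonical JSON serialization; round-trips exactly."""
        payload = {
            "alphabet": list(self.alphabet),
            "states": list(self.states),
            "transitions": [
                {"from": s, "symbol": a, "to": t, "p": p}
                for (s, a), (t, p) in sorted(self.transitions.items())
            ],
            "notes": self.notes,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Machine":
        payload = json.loads(text)
        trans = {
            (e["from"], e["symbol"]): (e["to"], e["p"])
            for e in payload["transitions"]
        }
        return cls(
            payload["alphabet"],
            trans,
            states=payload["states"],
            notes=payload.get("notes", ""),
        )

    def to_dot(self) -> str:
        """GraphViz DOT export; edges labeled ``symbol | p``."""
        lines = ["digraph machine {", "  rankdir=LR;"]
        for s in self.states:
            lines.append(f'  "{s}" [shape=circle];')
        for (s, a), (t, p) in sorted(self.transitions.items()):
            lines.append(f'  "{s}" -> "{t}" [label="{a} | {p:.6g}"];')
        lines.append("}")
        return "\n".join(lines)

    # ------------------------------------------------------------------- dunder

    def __eq__(self, other) -> bool:
        if not isinstance(other, Machine):
            return NotImplemented
        return (
            self.alphabet == other.alphabet
            and set(self.states) == set(other.states)
            and self.transitions == other.transitions
        )

    def __ne__(self, other) -> bool:
        eq = self.__eq__(other)
        return NotImplemented if eq is NotImplemented else not eq

    __hash__ = None  # mutable-ish container semantics

    def __repr__(self) -> str:
        return (
            f"Machine({len(self.states)} states, {len(self.transitions)} edges, "
            f"alphabet={''.join(self.alphabet)!r})"
        )


# ---------------------------------------------------------------------- library


def _check_branch_prob(p: float, name: str) -> float:
    p = float(p)
    if not (0.0 < p < 1.0):
        raise MachineError(f"{name} requires a branching probability in (0,1), got {p}")
    return p


def canonical_machine(name: str, **params) -> Machine:
    """Construct a canonical process by name.

    Supported names (binary alphabet ``{'0','1'}``; symbol ``'1'`` plays the
    role of Heads / the mutant allele):

    - ``alternating``: period-2 ``010101...``, two deterministic states.
    - ``fair_coin``: one state, self-loops at probability 1/2.
    - ``biased_coin``: one state, ``Pr['1'] = p``; ``p`` of 0 or 1 degenerates
      to the fixed coin.
    - ``fixed_coin``: one state, one self-loop emitting ``symbol`` (default '1').
    - ``golden_mean``: no two consecutive occurrences of the ``forbidden``
      symbol (default '1'); the branching state emits it with probability ``p``.
    - ``even``: blocks of '1's have even length; the branching state enters a
      block with probability ``p``.
    - ``period_n``: deterministic cycle emitting ``phase`` (a string).
    """
    alphabet = ("0", "1")
    if name == "alternating":
        trans = {("A", "0"): ("B", 1.0), ("B", "1"): ("A", 1.0)}
        return Machine(alphabet, trans, states=["A", "B"], notes="alternating")
    if name == "fair_coin":
        trans = {("A", "0"): ("A", 0.5), ("A", "1"): ("A", 0.5)}
        return Machine(alphabet, trans, states=["A"], notes="fair_coin")
    if name == "biased_coin":
        p = float(params["p"])
        if not (0.0 <= p <= 1.0):
            raise MachineError(f"biased_coin bias must lie in [0,1], got {p}")
        if p == 1.0:
            return canonical_machine("fixed_coin", symbol="1")
        if p == 0.0:
            return canonical_machine("fixed_coin", symbol="0")
        trans = {("A", "0"): ("A", 1.0 - p), ("A", "1"): ("A", p)}
        return Machine(alphabet, trans, states=["A"], notes=f"biased_coin(p={p})")
    if name == "fixed_coin":
        a = params.get("symbol", "1")
        if a not in alphabet:
            raise MachineError(f"fixed_coin symbol must be '0' or '1', got {a!r}")
        trans = {("A", a): ("A", 1.0)}
        return Machine(alphabet, trans, states=["A"], notes=f"fixed_coin({a})")
    if name == "golden_mean":
        p = _check_branch_prob(params["p"], "golden_mean")
        forbidden = params.get("forbidden", "1")
        if forbidden not in alphabet:
            raise MachineError("forbidden symbol must be '0' or '1'")
        other = "0" if forbidden == "1" else "1"
        trans = {
            ("A", other): ("A", 1.0 - p),
            ("A", forbidden): ("B", p),
            ("B", other): ("A", 1.0),
        }
        return Machine(
            alphabet, trans, states=["A", "B"], notes=f"golden_mean(p={p})"
        )
    if name == "even":
        p = _check_branch_prob(params["p"], "even")
        trans = {
            ("A", "0"): ("A", 1.0 - p),
            ("A", "1"): ("B", p),
            ("B", "1"): ("A", 1.0),
        }
        return Machine(alphabet, trans, states=["A", "B"], notes=f"even(p={p})")
    if name == "period_n":
        phase = params["phase"]
        n = int(params.get("n", len(phase)))
        if n != len(phase) or n < 1:
            raise MachineError("period_n needs a phase string of length n >= 1")
        if any(a not in alphabet for a in phase):
            raise MachineError("phase symbols must be '0'/'1'")
        trans = {
            (f"P{i}", phase[i]): (f"P{(i + 1) % n}", 1.0) for i in range(n)
        }
        return Machine(
            alphabet, trans, states=[f"P{i}" for i in range(n)], notes=f"period_{n}"
        )
    raise MachineError(f"unknown canonical process {name!r}")


def stationary_distribution(m: Machine) -> dict[State, float]:
    """Module-level convenience wrapper around :meth:`Machine.stationary_distribution`."""
    return m.stationary_distribution()


def generate(m: Machine, length: int, rng=None) -> PopulationSample:
    return m.generate(length, rng)


def parse(m: Machine, sample, start="best") -> ParseResult:
    return m.parse(sample, start)


def reestimate(m: Machine, sample) -> Machine:
    return m.reestimate(sample)


def canonicalize(m: Machine, tol: float = DEFAULT_PROB_TOL) -> Machine:
    return m.canonicalize(tol)
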