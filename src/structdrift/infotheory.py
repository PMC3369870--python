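"""Information measures of population-sampling machines.

All quantities are in bits (log base 2) and are computed on the recurrent
part of the machine only — transient states are excluded from the
stationary distribution and from every measure.

- ``population_diversity`` H(L): Shannon block entropy of length-L
  populations, the memory measure whose growth rate is the entropy rate.
- ``allelic_entropy`` h_mu: bits per allele, in closed form from the
  machine: h_mu = -sum_sigma pi(sigma) sum_edges p log2 p.  It vanishes
  exactly when no recurrent state branches.
- ``allelic_complexity`` C_mu: Shannon entropy of the stationary state
  distribution — the memory (in bits) needed to track the internal state.
- ``is_stasis``: structural stasis is the vanishing of the allelic entropy;
  it generalizes fixation/deletion to include periodic equilibria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .machines import Machine, MachineError, Symbol

STASIS_TOL = 1e-12
_WORD_GUARD = 10**6


@dataclass(frozen=True)
class InfoSummary:
    """Per-generation information summary of a machine."""

    h_mu: float
    C_mu: float
    is_stasis: bool


def word_distribution(m: Machine, L: int) -> dict[str, float]:
    """Exact distribution of length-L words emitted at stationarity.

    Pr(w) = sum_sigma pi(sigma) Pr(w | start sigma), via the unifilar path.
    Only words of positive probability appear in the result.
    """
    if L < 1:
        raise MachineError("L must be >= 1")
    if len(m.alphabet) ** L > _WORD_GUARD:
        raise MachineError(f"|A|^L = {len(m.alphabet)**L} exceeds enumeration guard")
    rec = m.recurrent_part()
    pi = rec.stationary_distribution()
    dist: dict[str, float] = {}
    # depth-first over the (state, prefix) tree; branching is tiny
    stack = [(s, "", w) for s, w in pi.items() if w > 0.0]
    outs = {s: rec.out_edges(s) for s in rec.states}
    while stack:
        state, prefix, prob = stack.pop()
        if len(prefix) == L:
            dist[prefix] = dist.get(prefix, 0.0) + prob
            continue
        for a, t, p in outs[state]:
            stack.append((t, prefix + a, prob * p))
    return dist


def population_diversity(m: Machine, L: int) -> float:
    """Block entropy H(L) of the length-L population distribution, in bits."""
    dist = word_distribution(m, L)
    return -sum(p * math.log2(p) for p in dist.values() if p > 0.0)


def allelic_entropy(m: Machine) -> float:
    """Entropy rate h_mu in bits per allele, closed form on the recurrent part."""
    pi = m.recurrent_part().stationary_distribution()
    h = 0.0
    for s, w in pi.items():
        if w <= 0.0:
            continue
        for _a, _t, p in m.out_edges(s):
            if 0.0 < p < 1.0:
                h -= w * p * math.log2(p)
    return h


def allelic_complexity(m: Machine) -> float:
    """Statistical complexity C_mu: entropy of the stationary state distribution."""
    pi = m.recurrent_part().stationary_distribution()
    return -sum(w * math.log2(w) for w in pi.values() if w > 0.0) + 0.0


def is_stasis(m: Machine, tol: float = STASIS_TOL) -> bool:
    """Structural stasis: the allelic entropy has vanished.

    With integer-count re-estimation all recurrent edges of a stasis machine
    have probability exactly 1, so h_mu is exactly 0.0 and the tolerance is
    only a safety margin.
    """
    return allelic_entropy(m) < tol


def summarize(m: Machine, tol: float = STASIS_TOL) -> InfoSummary:
    h = allelic_entropy(m)
    return InfoSummary(h_mu=h, C_mu=allelic_complexity(m), is_stasis=h < tol)


def symbol_probability(m: Machine, symbol: Symbol) -> float:
    """Stationary probability that one emitted allele equals ``symbol``."""
    pi = m.recurrent_part().stationary_distribution()
    total = 0.0
    for s, w in pi.items():
        for a, _t, p in m.out_edges(s):
            if a == symbol:
                total += w * p
    return total


def stasis_period(m: Machine) -> int:
    """Period of a stasis (h_mu = 0) machine: length of its canonical cycle.

    Canonicalization merges phase-equivalent states, so e.g. a 4-state cycle
    emitting ``0101`` reports period 2.
    """
    if not is_stasis(m):
        raise MachineError("machine is not at stasis; period undefined")
    return m.canonicalize().recurrent_part().n_states
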