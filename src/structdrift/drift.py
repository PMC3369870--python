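"""The sequential-learning loop and the PSV structural innovation/loss moves.

Each generation the current machine generates a finite population, a
successor machine is re-estimated from that sample, and the loop repeats
until structural stasis (vanishing allelic entropy).  Two explicit
topology-change proposals replace full machine reconstruction:

- *innovation*: clone a random state, reroute a random proper subset of its
  incoming transitions to the clone, perturb the clone's outgoing
  probabilities with Gaussian noise, and keep whichever of the incumbent
  and the candidate assigns the sample the higher likelihood (uniform model
  prior, so MAP reduces to maximum likelihood; ties keep the incumbent).
- *loss*: when some transition probability falls below ``merge_threshold``,
  score every pairwise state merging (plus the incumbent) with an
  AIC/AICc-penalized likelihood and keep the minimizer, breaking ties
  toward the smaller machine.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Literal

import numpy as np

from .infotheory import InfoSummary, summarize
from .machines import (
    Machine,
    PopulationSample,
    UnparseableSampleError,
    as_generator,
    as_sample,
)
from .subspaces import signature

_LN2 = math.log(2.0)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PSVConfig:
    """Configuration of the drift loop and the PSV proposals.

    noise_sigma: std. dev. of the Gaussian perturbation applied to a cloned
        state's outgoing probabilities (probability units).
    merge_threshold: edge probability below which the loss test runs;
        ``None`` means 3/M at run time (an edge supported by at most ~2
        observations).
    innovation_rate: cloning proposals attempted per generation.
    aic_correction: "AICc" (finite-sample corrected, default) or "AIC".
    prob_floor: clipping floor applied after noise, before renormalization,
        so the noise step alone never deletes an edge.
    history: how much of the trajectory to retain — "full" keeps machines
        and samples, "info" keeps per-generation summaries plus the machines
        at subspace entries, "minimal" keeps only the first and last record.
    """

    innovate: bool = False
    noise_sigma: float = 0.05
    merge_threshold: float | None = None
    innovation_rate: int = 1
    aic_correction: Literal["AIC", "AICc"] = "AICc"
    max_generations: int = 100_000
    prob_floor: float = 1e-6
    stasis_tol: float = 1e-12
    history: Literal["full", "info", "minimal"] = "full"

    def __post_init__(self):
        if not (self.noise_sigma > 0.0):
            raise ValueError("noise_sigma must be > 0")
        if self.merge_threshold is not None and not (0.0 < self.merge_threshold < 1.0):
            raise ValueError("merge_threshold must lie in (0,1)")


@dataclass(frozen=True)
class GenerationRecord:
    """One generation of a drift trajectory.

    ``event`` describes how this generation's machine arose from the
    previous one: "subspace_jump" when the topology signature changed,
    otherwise "loss_merge" / "innovation_accepted" / "none".
    """

    index: int
    machine: Machine | None
    sample: PopulationSample | None
    info: InfoSummary
    signature: str
    event: str = "none"


@dataclass(frozen=True)
class Trajectory:
    """A drift realization: generation records ending in stasis (or the cap)."""

    records: tuple[GenerationRecord, ...]
    terminal_status: Literal["stasis", "max_generations"]
    generations: int
    stasis_machine: Machine | None = None

    @property
    def stasis_time(self) -> int | None:
        return self.generations if self.terminal_status == "stasis" else None


# ------------------------------------------------------------------ innovation


def innovate(m: Machine, s, cfg: PSVConfig, rng) -> Machine:
    """One cloning proposal; returns the accepted machine (``m`` if rejected).

    A state is picked uniformly; each of its incoming transitions is
    rerouted to the clone independently with probability 1/2, resampled
    until at least one is rerouted and one kept.  States whose incoming
    edges cannot be split (fewer than two) reject immediately.
    """
    rng = as_generator(rng)
    s = as_sample(s)
    states = sorted(m.states)
    chosen = states[int(rng.integers(len(states)))]
    incoming = sorted(
        e for e, (t, _p) in m.transitions.items() if t == chosen
    )
    if len(incoming) < 2:
        return m
    mask = None
    for _ in range(64):
        trial = rng.random(len(incoming)) < 0.5
        if 0 < trial.sum() < len(incoming):
            mask = trial
            break
    if mask is None:  # pragma: no cover - vanishing probability
        return m
    clone = chosen + "'"
    existing = set(m.states)
    while clone in existing:
        clone += "'"
    newtrans = dict(m.transitions)
    for e, flag in zip(incoming, mask):
        if flag:
            t, p = newtrans[e]
            newtrans[e] = (clone, p)
    outs = m.out_edges(chosen)  # clone copies the outgoing transitions
    probs = np.array([p for _a, _t, p in outs])
    probs = probs + rng.normal(0.0, cfg.noise_sigma, size=len(probs))
    probs = np.clip(probs, cfg.prob_floor, 1.0)
    probs = probs / probs.sum()
    for (a, t, _p), pnew in zip(outs, probs):
        newtrans[(clone, a)] = (t, float(pnew))
    candidate = Machine(
        m.alphabet,
        newtrans,
        states=list(m.states) + [clone],
        notes=m.notes,
    )
    ll_old = m.parse(s, "best").log_likelihood
    ll_new = candidate.parse(s, "best").log_likelihood
    if ll_new > ll_old:
        logger.debug(
            "innovation accepted: cloned %s, log2-likelihood %.4f -> %.4f",
            chosen, ll_old, ll_new,
        )
        return candidate
    return m


# ------------------------------------------------------------------- scoring


def model_score(m: Machine, s, cfg: PSVConfig | None = None) -> float:
    """AIC- or AICc-penalized negative log-likelihood (lower is better).

    AIC = 2k - 2 ln L with k the number of transition probabilities (one
    parameter per edge); AICc adds the finite-sample correction
    2k(k+1)/(n-k-1) with n the sample length.  The likelihood is the
    best-start parse of the sample; an unparseable sample scores +inf.
    """
    cfg = cfg or PSVConfig()
    s = as_sample(s)
    ll_bits = m.parse(s, "best").log_likelihood
    if ll_bits == float("-inf"):
        return float("inf")
    k = m.n_edges
    n = len(s)
    lnL = ll_bits * _LN2
    score = 2.0 * k - 2.0 * lnL
    if cfg.aic_correction == "AICc":
        if n > k + 1:
            score += 2.0 * k * (k + 1) / (n - k - 1)
        else:
            warnings.warn(
                f"AICc undefined for n={n} <= k+1={k + 1}; falling back to AIC",
                RuntimeWarning,
                stacklevel=2,
            )
    return score


# ---------------------------------------------------------------------- loss


def _merge_states(m: Machine, a: str, b: str) -> Machine | None:
    """Merge states a and b; resolve unifilarity conflicts by recursively
    merging conflicting targets; per-symbol probabilities are summed over
    class members and rows renormalized (placeholder masses — callers
    re-fit from the sample)."""
    rep = {s: s for s in m.states}

    def find(s):
        while rep[s] != s:
            rep[s] = rep[rep[s]]
            s = rep[s]
        return s

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx == ry:
            return
        lo, hi = sorted((rx, ry))
        rep[hi] = lo

    union(a, b)
    # resolve unifilarity conflicts to a fixed point
    changed = True
    while changed:
        changed = False
        targets: dict[tuple[str, str], str] = {}
        for (s, sym), (t, _p) in m.transitions.items():
            key = (find(s), sym)
            ft = find(t)
            if key in targets and targets[key] != ft:
                union(targets[key], ft)
                changed = True
                break
            targets[key] = ft
    sums: dict[tuple[str, str], float] = {}
    tgt: dict[tuple[str, str], str] = {}
    for (s, sym), (t, p) in m.transitions.items():
        key = (find(s), sym)
        sums[key] = sums.get(key, 0.0) + p
        tgt[key] = find(t)
    row_tot: dict[str, float] = {}
    for (r, _sym), p in sums.items():
        row_tot[r] = row_tot.get(r, 0.0) + p
    trans = {
        (r, sym): (tgt[(r, sym)], p / row_tot[r]) for (r, sym), p in sums.items()
    }
    reps = sorted({find(s) for s in m.states})
    if len(reps) == len(m.states):
        return None
    return Machine(m.alphabet, trans, states=reps, notes=m.notes)


def try_loss(m: Machine, s, cfg: PSVConfig | None = None) -> Machine:
    """AICc-arbitrated structural simplification.

    If any transition probability lies below the merge threshold, every
    pairwise state merging is formed, re-fitted to the sample, canonicalized
    and scored against the incumbent; the minimizer wins, with ties broken
    toward fewer states, then fewer edges.  Returns ``m`` (the same object)
    when nothing wins or no edge is near zero.
    """
    cfg = cfg or PSVConfig()
    s = as_sample(s)
    thr = cfg.merge_threshold if cfg.merge_threshold is not None else 3.0 / len(s)
    if m.n_states < 2:
        return m
    if all(p >= thr for (_t, p) in m.transitions.values()):
        return m
    candidates: list[Machine] = []
    for si, sj in combinations(sorted(m.states), 2):
        merged = _merge_states(m, si, sj)
        if merged is None:
            continue
        try:
            fitted = merged.reestimate(s)
        except UnparseableSampleError:
            continue
        candidates.append(fitted.canonicalize())
    best = m
    incumbent_score = model_score(m, s, cfg)
    best_key = (incumbent_score, m.n_states, m.n_edges)
    for cand in candidates:
        key = (model_score(cand, s, cfg), cand.n_states, cand.n_edges)
        if key < best_key:
            best, best_key = cand, key
    if best is not m:
        logger.debug(
            "loss merge accepted: %d->%d states, penalized score %.4f -> %.4f",
            m.n_states, best.n_states, incumbent_score, best_key[0],
        )
    return best


# ----------------------------------------------------------------- main loop


def run_drift(
    m0: Machine, M: int, cfg: PSVConfig | None = None, rng=None
) -> Trajectory:
    """Run one sequential-learning chain from ``m0`` with samples of length M.

    Per generation: generate a sample, optionally propose innovations,
    re-estimate the winner's probabilities from the sample, then apply the
    loss test.  Terminates when the new machine is at stasis or the
    generation cap is hit.  Fully reproducible under (seed, cfg).
    """
    cfg = cfg or PSVConfig()
    rng = as_generator(rng)
    if M < 1:
        raise ValueError("sample length M must be >= 1")

    records: list[GenerationRecord] = []

    def keep_record(rec: GenerationRecord, final: bool) -> None:
        if cfg.history == "full":
            records.append(rec)
            return
        if cfg.history == "info":
            if final or rec.index == 0 or rec.event == "subspace_jump":
                records.append(replace(rec, sample=None))
            else:
                records.append(replace(rec, machine=None, sample=None))
            return
        # minimal: only first and last
        if final or rec.index == 0:
            records.append(replace(rec, machine=None if not final else rec.machine, sample=None))

    m = m0
    t = 0
    event = "none"
    info = summarize(m, cfg.stasis_tol)
    sig = signature(m)
    while True:
        if info.is_stasis:
            keep_record(
                GenerationRecord(t, m, None, info, sig, event), final=True
            )
            return Trajectory(
                tuple(records), "stasis", generations=t, stasis_machine=m
            )
        if t >= cfg.max_generations:
            keep_record(
                GenerationRecord(t, m, None, info, sig, event), final=True
            )
            return Trajectory(tuple(records), "max_generations", generations=t)
        sample = m.generate(M, rng)
        keep_record(
            GenerationRecord(t, m, sample, info, sig, event), final=False
        )
        cand = m
        innovated = False
        if cfg.innovate:
            for _ in range(cfg.innovation_rate):
                c2 = innovate(cand, sample, cfg, rng)
                if c2 is not cand:
                    innovated = True
                    cand = c2
        refit = cand.reestimate(sample)
        m_next = try_loss(refit, sample, cfg)
        merged = m_next is not refit
        new_sig = signature(m_next)
        new_info = summarize(m_next, cfg.stasis_tol)
        if new_sig != sig:
            event = "subspace_jump"
        elif merged:
            event = "loss_merge"
        elif innovated:
            event = "innovation_accepted"
        else:
            event = "none"
        m, info, sig = m_next, new_info, new_sig
        t += 1


def run_ensemble(
    m0: Machine,
    M: int,
    cfg: PSVConfig | None = None,
    n_realizations: int = 400,
    seed=None,
) -> list[Trajectory]:
    """Independent seeded realizations (seed-sequence spawning from ``seed``)."""
    cfg = cfg or PSVConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_realizations)
    return [run_drift(m0, M, cfg, np.random.default_rng(c)) for c in children]


def stasis_times(trajectories) -> np.ndarray:
    """Stasis times of the absorbed realizations, as a float array."""
    return np.array(
        [
            t.generations
            for t in trajectories
            if t.terminal_status == "stasis"
        ],
        dtype=float,
    )


def stasis_time_summary(trajectories) -> dict[str, float]:
    """Mean, standard error and counts of the ensemble's stasis times."""
    times = stasis_times(trajectories)
    n = times.size
    return {
        "mean": float(times.mean()) if n else float("nan"),
        "se": float(times.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
        "n_absorbed": int(n),
        "n_unabsorbed": int(len(trajectories) - n),
    }
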