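"""Isostructural-subspace bookkeeping.

An *isostructural subspace* is the set of machines sharing a topology — a
state count plus transition support — irrespective of the positive
transition probabilities.  Within a subspace, drift is pure parameter
diffusion; a *subspace jump* is a topology change (state or edge added or
removed).  This module computes relabeling-invariant topology signatures,
complexity-entropy (CE) diagram points, and the pathway decomposition of
stasis times: the grand mean stasis time is the pathway-probability-
weighted sum of per-pathway means, and each pathway mean is the sum of its
per-subspace mean dwell times — an exact accounting identity on any
ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .machines import Machine

_SIGNATURE_CACHE: dict[tuple, str] = {}


def _component_encoding(edges: dict, root: str, n: int) -> str | None:
    """BFS encoding of the reachable component from ``root``; None if it
    does not cover all ``n`` states."""
    order = {root: 0}
    queue = [root]
    while queue:
        s = queue.pop(0)
        for a, t in sorted(edges.get(s, [])):
            if t not in order:
                order[t] = len(order)
                queue.append(t)
    if len(order) != n:
        return None
    parts = []
    for s in sorted(order, key=order.get):
        parts.append(
            ",".join(f"{a}>{order[t]}" for a, t in sorted(edges.get(s, [])))
        )
    return f"{n}|" + ";".join(parts)


def signature(m: Machine) -> str:
    """Relabeling-invariant label of the machine's canonical topology.

    Computed on ``canonicalize(m)`` with probabilities discarded: machines
    differing only in their positive transition probabilities share a
    signature; machines with different edge support do not.
    """
    key = m.support_key()
    cached = _SIGNATURE_CACHE.get(key)
    if cached is not None:
        return cached
    c = m.canonicalize()
    edges: dict[str, list[tuple[str, str]]] = {}
    for (s, a), (t, _p) in c.transitions.items():
        edges.setdefault(s, []).append((a, t))
    n = c.n_states
    encodings = []
    for root in c.states:
        enc = _component_encoding(edges, root, n)
        if enc is not None:
            encodings.append(enc)
    if encodings:
        sig = min(encodings)
    else:  # multiple terminal components: encode each and join
        comps = c.terminal_components()
        sub = []
        for comp in comps:
            sub_edges = {s: edges.get(s, []) for s in comp}
            encs = [
                e
                for e in (
                    _component_encoding(sub_edges, r, len(comp)) for r in comp
                )
                if e is not None
            ]
            sub.append(min(encs))
        sig = "+".join(sorted(sub))
    _SIGNATURE_CACHE[key] = sig
    return sig


@dataclass(frozen=True)
class CEPoint:
    """One machine projected onto the complexity-entropy plane."""

    realization: int
    generation: int
    h_mu: float
    C_mu: float
    signature: str


def ce_diagram(trajectories) -> pd.DataFrame:
    """CE-diagram points: one row per generation per realization.

    Columns: realization, generation, h_mu, C_mu, signature.  Points in the
    same isostructural subspace share the signature label.
    """
    rows = []
    for r, traj in enumerate(trajectories):
        for rec in traj.records:
            rows.append(
                {
                    "realization": r,
                    "generation": rec.index,
                    "h_mu": rec.info.h_mu,
                    "C_mu": rec.info.C_mu,
                    "signature": rec.signature,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PathwayStats:
    """Per-pathway stasis-time statistics.

    ``pathway`` is the ordered sequence of subspace signatures a
    realization traverses (consecutive duplicates collapsed), ending in its
    stasis subspace.  ``dwells[i]`` holds each member realization's dwell
    time in pathway position i (generations from entry inclusive to exit
    exclusive; the final record is excluded, so dwells sum to the stasis
    time).  ``entry_params[i]`` holds, per realization, the outgoing
    probability vectors of the branching states at the first generation in
    that subspace (empty dict when the machine was not retained or has no
    branching state).
    """

    pathway: tuple[str, ...]
    n: int
    weight: float
    mean_stasis_time: float
    dwells: tuple[np.ndarray, ...]
    entry_params: tuple[tuple[dict, ...], ...]

    @property
    def dwell_means(self) -> tuple[float, ...]:
        return tuple(float(d.mean()) for d in self.dwells)


@dataclass(frozen=True)
class StasisTimeDecomposition:
    """Ensemble stasis-time decomposition over pathways and subspaces."""

    total_mean: float
    n: int
    n_excluded: int
    pathways: tuple[PathwayStats, ...]

    def reconstituted_mean(self) -> float:
        """Pathway-weighted sum of per-pathway means (the accounting identity)."""
        return sum(p.weight * p.mean_stasis_time for p in self.pathways)


def _branching_params(machine: Machine | None) -> dict:
    if machine is None:
        return {}
    out: dict = {}
    counts: dict[str, int] = {}
    for (s, _a) in machine.transitions:
        counts[s] = counts.get(s, 0) + 1
    for (s, a), (_t, p) in machine.transitions.items():
        if counts[s] > 1:
            out[(s, a)] = p
    return out


def decompose_stasis_times(trajectories) -> StasisTimeDecomposition:
    """Group absorbed realizations by pathway; compute weights and dwell times.

    Unabsorbed trajectories are excluded (their count is reported).
    Requires trajectories recorded with at least per-generation signatures
    (history "full" or "info").
    """
    import warnings

    groups: dict[tuple[str, ...], list] = {}
    n_excluded = 0
    totals = []
    for traj in trajectories:
        if traj.terminal_status != "stasis":
            n_excluded += 1
            continue
        if len(traj.records) != traj.generations + 1:
            raise ValueError(
                "trajectory lacks per-generation records; rerun with "
                "history='full' or 'info'"
            )
        sigs = [rec.signature for rec in traj.records]
        # runs of consecutive equal signatures
        runs: list[tuple[str, int, int]] = []  # (sig, start, end-exclusive)
        start = 0
        for i in range(1, len(sigs) + 1):
            if i == len(sigs) or sigs[i] != sigs[start]:
                runs.append((sigs[start], start, i))
                start = i
        pathway = tuple(r[0] for r in runs)
        # dwell: entry inclusive, exit exclusive; final record excluded
        T = traj.generations
        dwells = []
        entries = []
        for sig_, s0, e0 in runs:
            end = min(e0, T)
            dwells.append(max(0, end - s0))
            entries.append(_branching_params(traj.records[s0].machine))
        groups.setdefault(pathway, []).append((T, dwells, entries))
        totals.append(T)
    if not totals:
        raise ValueError("no absorbed trajectories to decompose")
    if n_excluded:
        warnings.warn(
            f"{n_excluded} unabsorbed trajectories excluded from decomposition",
            RuntimeWarning,
            stacklevel=2,
        )
    n_total = len(totals)
    stats = []
    for pathway, members in sorted(groups.items()):
        Ts = np.array([m[0] for m in members], dtype=float)
        k = len(pathway)
        dwell_arrays = tuple(
            np.array([m[1][i] for m in members], dtype=float) for i in range(k)
        )
        entry_tuple = tuple(
            tuple(m[2][i] for m in members) for i in range(k)
        )
        stats.append(
            PathwayStats(
                pathway=pathway,
                n=len(members),
                weight=len(members) / n_total,
                mean_stasis_time=float(Ts.mean()),
                dwells=dwell_arrays,
                entry_params=entry_tuple,
            )
        )
    return StasisTimeDecomposition(
        total_mean=float(np.mean(totals)),
        n=n_total,
        n_excluded=n_excluded,
        pathways=tuple(stats),
    )
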