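"""Classical memoryless neutral drift: Fisher-Wright sampling and
Kimura-Ohta absorption-time theory.

A population of M alleles with i copies of the tracked allele produces the
next generation by binomial sampling: j ~ Binomial(M, i/M).  Fixation
(p = 1) and deletion (p = 0) are the absorbing states.  The
fixation-conditioned and deletion-conditioned mean absorption times of the
diffusion limit are

    t1(p) = -(1/p) * 4*Ne * (1 - p) * ln(1 - p)        (fixation)
    t0(p) = -4*Ne * (p / (1 - p)) * ln(p)              (deletion)

in generations, with the boundary value t1(p -> 0) = 4*Ne.  ``Ne`` is the
effective number of *diploid individuals*; for a haploid sample of M
alleles use Ne = M/2 (the time scale depends only on the allele count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .machines import as_generator


@dataclass(frozen=True)
class KimuraParams:
    """Classical-drift parameters.

    N: population size in individuals; Ne: effective size (defaults to N);
    alleles_per_individual: 1 (haploid, M = N) or 2 (diploid, M = 2N);
    p0: initial frequency of the tracked allele.
    """

    N: int
    p0: float
    Ne: int | None = None
    alleles_per_individual: int = 1

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError("p0 must lie in [0,1]")
        if self.alleles_per_individual not in (1, 2):
            raise ValueError("alleles_per_individual must be 1 or 2")
        if self.Ne is not None and self.Ne > self.N:
            raise ValueError("Ne must not exceed N")

    @property
    def effective_size(self) -> int:
        return self.N if self.Ne is None else self.Ne

    @property
    def M(self) -> int:
        """Total number of alleles per generation (the sample length)."""
        return self.N * self.alleles_per_individual


@dataclass(frozen=True)
class DriftOutcome:
    """Result of one Monte Carlo drift realization."""

    generations: int
    absorbed_at: str | None  # "fixation" | "deletion" | None (unabsorbed)
    p_final: float
    trajectory: tuple[float, ...] | None = None

    @property
    def absorbed(self) -> bool:
        return self.absorbed_at is not None


def binomial_transition_pmf(i: int, M: int) -> np.ndarray:
    """One-generation transition law: Binomial(M, i/M) pmf over j = 0..M."""
    if not (0 <= i <= M):
        raise ValueError(f"allele count i={i} outside 0..{M}")
    j = np.arange(M + 1)
    return stats.binom.pmf(j, M, i / M)


def delta_p_moments(p: float, M: int) -> tuple[float, float]:
    """Mean (0) and variance p(1-p)/M of the per-generation frequency change."""
    return 0.0, p * (1.0 - p) / M


def mc_drift(
    params: KimuraParams,
    rng=None,
    max_generations: int = 10**6,
    record_trajectory: bool = False,
) -> DriftOutcome:
    """Monte Carlo drift: binomial sampling with MLE re-estimation each
    generation until fixation or deletion (or the safety cap)."""
    rng = as_generator(rng)
    M = params.M
    p = params.p0
    traj = [p] if record_trajectory else None
    if p == 0.0 or p == 1.0:
        return DriftOutcome(
            0, "fixation" if p == 1.0 else "deletion", p, tuple(traj) if traj else None
        )
    t = 0
    while t < max_generations:
        p = rng.binomial(M, p) / M
        t += 1
        if record_trajectory:
            traj.append(p)
        if p == 0.0 or p == 1.0:
            return DriftOutcome(
                t,
                "fixation" if p == 1.0 else "deletion",
                p,
                tuple(traj) if traj else None,
            )
    return DriftOutcome(t, None, p, tuple(traj) if traj else None)


def kimura_t1(p: float, Ne: float) -> float:
    """Mean generations to fixation, conditioned on fixation."""
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly in (0,1)")
    return -(1.0 / p) * 4.0 * Ne * (1.0 - p) * math.log(1.0 - p)


def kimura_t0(p: float, Ne: float) -> float:
    """Mean generations to deletion, conditioned on deletion."""
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly in (0,1)")
    return -4.0 * Ne * (p / (1.0 - p)) * math.log(p)


def conditional_absorption_times(M: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional mean absorption times of the binomial chain.

    Solves the absorbing Markov chain over allele counts 0..M by linear
    algebra.  Returns ``(t_fix, t_del)`` indexed by initial count i; entries
    are NaN where the conditioning event has probability zero (i = 0 for
    fixation, i = M for deletion).  Serves as a small-M oracle for the
    diffusion formulas.
    """
    P = np.vstack([binomial_transition_pmf(i, M) for i in range(M + 1)])
    idx = np.arange(1, M)  # transient states

    def conditioned(u: np.ndarray) -> np.ndarray:
        # Doob h-transform on the absorption probability u, then solve
        # (I - Q~) t = 1 over transient states.
        Q = P[np.ix_(idx, idx)] * u[idx][None, :] / u[idx][:, None]
        t = np.linalg.solve(np.eye(len(idx)) - Q, np.ones(len(idx)))
        return t

    u_fix = np.arange(M + 1) / M  # martingale: fixation prob = i/M
    u_del = 1.0 - u_fix
    t_fix = np.full(M + 1, np.nan)
    t_del = np.full(M + 1, np.nan)
    t_fix[idx] = conditioned(u_fix)
    t_del[idx] = conditioned(u_del)
    t_fix[M] = 0.0
    t_del[0] = 0.0
    return t_fix, t_del


def mc_fixation_summary(
    p0_values,
    N: int,
    n_realizations: int = 400,
    alleles_per_individual: int = 2,
    Ne: int | None = None,
    seed=None,
    max_generations: int = 10**6,
):
    """Fixation-conditioned Monte Carlo mean times across initial frequencies.

    Runs ``n_realizations`` per ``p0`` and averages only realizations whose
    tracked allele reaches fixation.  Returns a pandas DataFrame with
    columns p0, mean_t_fix, se, n_fixed, n_realizations, theory_t1,
    theory_t0.
    """
    import pandas as pd

    ss = np.random.SeedSequence(seed)
    ne = N if Ne is None else Ne
    rows = []
    for p0 in p0_values:
        params = KimuraParams(
            N=N, p0=float(p0), Ne=Ne, alleles_per_individual=alleles_per_individual
        )
        rng = np.random.default_rng(ss.spawn(1)[0])
        times = []
        for _ in range(n_realizations):
            out = mc_drift(params, rng, max_generations=max_generations)
            if out.absorbed_at == "fixation":
                times.append(out.generations)
        times = np.asarray(times, dtype=float)
        mean = float(times.mean()) if times.size else float("nan")
        se = float(times.std(ddof=1) / math.sqrt(times.size)) if times.size > 1 else float("nan")
        rows.append(
            {
                "p0": float(p0),
                "mean_t_fix": mean,
                "se": se,
                "n_fixed": int(times.size),
                "n_realizations": n_realizations,
                "theory_t1": kimura_t1(float(p0), ne),
                "theory_t0": kimura_t0(float(p0), ne),
            }
        )
    return pd.DataFrame(rows)
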