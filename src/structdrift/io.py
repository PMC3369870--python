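"""File I/O glue: machine JSON/DOT, trajectory and ensemble CSV writers,
YAML run configuration, and an optional FASTA-like population dump.

CSV column contracts are documented in ``docs/csv_schema.md``.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .infotheory import symbol_probability
from .machines import Machine
from .subspaces import StasisTimeDecomposition, ce_diagram


def save_machine(m: Machine, path) -> None:
    Path(path).write_text(m.to_json() + "\n")


def load_machine(path) -> Machine:
    return Machine.from_json(Path(path).read_text())


def save_dot(m: Machine, path) -> None:
    Path(path).write_text(m.to_dot() + "\n")


def trajectory_frame(traj, realization: int = 0, tracked_symbol: str = "1") -> pd.DataFrame:
    """Per-generation rows: generation, h_mu, C_mu, pr_symbol, signature, event.

    ``pr_symbol`` is the stationary probability of the tracked allele under
    that generation's machine (NaN when the machine was not retained).
    """
    rows = []
    for rec in traj.records:
        pr = (
            symbol_probability(rec.machine, tracked_symbol)
            if rec.machine is not None
            else math.nan
        )
        rows.append(
            {
                "realization": realization,
                "generation": rec.index,
                "h_mu": rec.info.h_mu,
                "C_mu": rec.info.C_mu,
                "pr_symbol": pr,
                "signature": rec.signature,
                "event": rec.event,
            }
        )
    return pd.DataFrame(rows)


def write_trajectory_csv(traj, path, realization: int = 0, tracked_symbol: str = "1") -> None:
    trajectory_frame(traj, realization, tracked_symbol).to_csv(path, index=False)


def ensemble_summary_frame(trajectories) -> pd.DataFrame:
    """One row per realization: stasis time, terminal status and signature."""
    rows = []
    for r, traj in enumerate(trajectories):
        rows.append(
            {
                "realization": r,
                "generations": traj.generations,
                "terminal_status": traj.terminal_status,
                "terminal_signature": traj.records[-1].signature,
                "terminal_h_mu": traj.records[-1].info.h_mu,
                "terminal_C_mu": traj.records[-1].info.C_mu,
            }
        )
    return pd.DataFrame(rows)


def write_ensemble_summary(trajectories, path) -> None:
    ensemble_summary_frame(trajectories).to_csv(path, index=False)


def write_ce_points(trajectories, path) -> None:
    ce_diagram(trajectories).to_csv(path, index=False)


def pathways_frame(decomp: StasisTimeDecomposition) -> pd.DataFrame:
    rows = []
    for p in decomp.pathways:
        se = math.nan
        if p.n > 1:
            totals = np.sum(np.vstack(p.dwells), axis=0)
            se = float(totals.std(ddof=1) / math.sqrt(p.n))
        rows.append(
            {
                "pathway": " -> ".join(p.pathway),
                "n": p.n,
                "weight": p.weight,
                "mean_time": p.mean_stasis_time,
                "se": se,
            }
        )
    return pd.DataFrame(rows)


def dwell_times_frame(decomp: StasisTimeDecomposition) -> pd.DataFrame:
    rows = []
    for p in decomp.pathways:
        for i, (sig, dwells) in enumerate(zip(p.pathway, p.dwells)):
            rows.append(
                {
                    "pathway": " -> ".join(p.pathway),
                    "position": i,
                    "signature": sig,
                    "n": p.n,
                    "mean_dwell": float(dwells.mean()),
                    "se": float(dwells.std(ddof=1) / math.sqrt(p.n))
                    if p.n > 1
                    else math.nan,
                }
            )
    return pd.DataFrame(rows)


def entry_params_frame(decomp: StasisTimeDecomposition) -> pd.DataFrame:
    rows = []
    for p in decomp.pathways:
        for i, sig in enumerate(p.pathway):
            for r, params in enumerate(p.entry_params[i]):
                for (state, symbol), prob in sorted(params.items()):
                    rows.append(
                        {
                            "pathway": " -> ".join(p.pathway),
                            "position": i,
                            "signature": sig,
                            "member": r,
                            "state": state,
                            "symbol": symbol,
                            "p": prob,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["pathway", "position", "signature", "member", "state", "symbol", "p"]
    )


def write_decomposition(decomp: StasisTimeDecomposition, out_dir) -> None:
    out = Path(out_dir)
    pathways_frame(decomp).to_csv(out / "pathways.csv", index=False)
    dwell_times_frame(decomp).to_csv(out / "dwell_times.csv", index=False)
    entry_params_frame(decomp).to_csv(out / "entry_params.csv", index=False)


def write_populations_fasta(traj, path, prefix: str = "gen") -> None:
    """FASTA-like plain-text dump: one generation string per record."""
    lines = []
    for rec in traj.records:
        if rec.sample is None:
            continue
        lines.append(f">{prefix}{rec.index}")
        lines.append(rec.sample.as_string())
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> dict:
    """Load a YAML run configuration (flat mapping mirroring the CLI flags)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg
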