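"""Phase-diagram experiments: repeated runs, classification frequencies.

For every environmental condition ``(d_c, d_m)`` the simulation is run
``n_trials`` times with distinct seeds, each final state is classified,
and the frequencies of the kinship structures and descent systems are
tabulated.  The modal structure per condition is what the phase diagram
plots.  Sensitivity sweeps repeat this while varying one of ``N_s``,
``N_f`` or ``mu``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import DESCENT_SYSTEMS, STRUCTURES, StructureClass, classify_world
from .engine import RunResult, run_simulation
from .params import ModelParams

__all__ = [
    "PhaseCell",
    "run_and_classify",
    "run_phase_sweep",
    "descent_frequency_table",
    "sensitivity_sweep",
    "cells_to_frame",
    "plot_modal_map",
]


@dataclass
class PhaseCell:
    """Classification tallies of repeated runs at one condition."""

    d_c: float
    d_m: float
    n_trials: int
    structure_counts: dict[str, int]
    descent_counts: dict[str, int]
    results: list[StructureClass] = field(default_factory=list, repr=False)
    seeds: list[int] = field(default_factory=list, repr=False)
    meta: dict = field(default_factory=dict)

    @property
    def extinct_fraction(self) -> float:
        return self.structure_counts.get("extinct", 0) / self.n_trials

    @property
    def modal_structure(self) -> str:
        """Most frequent structure; extinctions win only if they dominate
        every lived structure.  Ties break lexicographically (flagged in
        ``meta['modal_tie']``)."""
        counts = dict(self.structure_counts)
        extinct = counts.pop("extinct", 0)
        if not counts or extinct > max(counts.values(), default=0):
            return "extinct"
        best = max(counts.values())
        winners = sorted(k for k, v in counts.items() if v == best)
        self.meta["modal_tie"] = len(winners) > 1
        return winners[0]

    def modal_cycles(self) -> tuple[int, int]:
        """(C_m, C_d) of the modal structure class: the modal cycle pair
        among the runs classified into that structure."""
        modal = self.modal_structure
        pairs = [(r.C_m, r.C_d) for r in self.results if r.structure == modal]
        if not pairs:
            return (0, 0)
        vals, counts = np.unique(np.array(pairs), axis=0, return_counts=True)
        order = np.lexsort((vals[:, 0], vals[:, 1], -counts))
        return int(vals[order[0], 0]), int(vals[order[0], 1])


def run_and_classify(params: ModelParams, theta: float = 1.0,
                     k_max: int = 8) -> tuple[StructureClass, RunResult]:
    """One simulation plus classification of its largest final society."""
    result = run_simulation(params)
    cls = classify_world(result.world, params.tau, theta=theta, k_max=k_max,
                         seed=params.seed)
    return cls, result


def _tally(results: list[StructureClass], d_c: float, d_m: float,
           seeds: list[int], meta: dict | None = None) -> PhaseCell:
    sc = {s: 0 for s in STRUCTURES}
    dc_counts = {d: 0 for d in DESCENT_SYSTEMS}
    for r in results:
        sc[r.structure] += 1
        if r.structure != "extinct":
            dc_counts[r.descent_system] += 1
    return PhaseCell(d_c=d_c, d_m=d_m, n_trials=len(results),
                     structure_counts=sc, descent_counts=dc_counts,
                     results=results, seeds=seeds, meta=meta or {})


def run_phase_sweep(grid: list[tuple[float, float]], base_params: ModelParams,
                    n_trials: int = 20, base_seed: int = 0, theta: float = 1.0,
                    k_max: int = 8, progress: bool = False) -> list[PhaseCell]:
    """Repeated classified runs over a grid of (d_c, d_m) conditions.

    Trial seeds are ``base_seed + trial_index`` (recorded per cell), so
    a rerun with the same seed list is identical.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cells = []
    for d_c, d_m in grid:
        results, seeds = [], []
        for trial in range(n_trials):
            seed = base_seed + trial
            params = base_params.with_(d_c=d_c, d_m=d_m, seed=seed)
            cls, _ = run_and_classify(params, theta=theta, k_max=k_max)
            results.append(cls)
            seeds.append(seed)
            if progress:
                print(f"d_c={d_c} d_m={d_m} trial={trial}: {cls.structure}",
                      flush=True)
        cells.append(_tally(results, d_c, d_m, seeds))
    return cells


def descent_frequency_table(cells: list[PhaseCell]) -> pd.DataFrame:
    """Fractions of each descent system within each kinship structure.

    Aggregates all runs of the given cells.  Denominator per structure:
    its non-extinct run count; the patrilineal/matrilineal/double
    fractions sum to at most 1 (remainder: undivided/ambiguous).
    """
    runs = [r for c in cells for r in c.results if r.structure != "extinct"]
    if not runs:
        raise ValueError("no classified (non-extinct) runs to tabulate")
    rows = []
    for s in STRUCTURES[:-1]:  # skip "extinct"
        of_s = [r for r in runs if r.structure == s]
        if not of_s:
            continue
        n = len(of_s)
        row = {"structure": s, "n_runs": n}
        for d in DESCENT_SYSTEMS:
            row[d] = sum(r.descent_system == d for r in of_s) / n
        rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_sweep(vary: str, values: list, base_params: ModelParams,
                      grid: list[tuple[float, float]], n_trials: int = 20,
                      base_seed: int = 0, theta: float = 1.0,
                      k_max: int = 8) -> list[PhaseCell]:
    """Phase sweep repeated while varying one of N_s, N_f or mu."""
    if vary not in ("N_s", "N_f", "mu"):
        raise ValueError("vary must be one of 'N_s', 'N_f', 'mu'")
    cells = []
    for value in values:
        params = base_params.with_(**{vary: value})
        for cell in run_phase_sweep(grid, params, n_trials=n_trials,
                                    base_seed=base_seed, theta=theta,
                                    k_max=k_max):
            cell.meta[vary] = value
            cells.append(cell)
    return cells


def cells_to_frame(cells: list[PhaseCell]) -> pd.DataFrame:
    """Flat table of a sweep (one row per cell), ready for CSV export."""
    rows = []
    for c in cells:
        row = {"d_c": c.d_c, "d_m": c.d_m, "n_trials": c.n_trials}
        row.update({f"count_{s}": c.structure_counts.get(s, 0) for s in STRUCTURES})
        row["modal"] = c.modal_structure
        row["extinct_fraction"] = c.extinct_fraction
        row.update({f"count_{d}": c.descent_counts.get(d, 0) for d in DESCENT_SYSTEMS})
        row.update(c.meta)
        rows.append(row)
    return pd.DataFrame(rows)


_STRUCTURE_COLORS = {
    "clan_endogamy": "#e6c300",
    "dual_organization": "#2ca02c",
    "generalized_exchange": "#ff7f0e",
    "restricted_exchange": "#e377c2",
    "other": "#7f7f7f",
    "extinct": "#1f77b4",
}


def plot_modal_map(cells: list[PhaseCell], path=None, ax=None):
    """Scatter of the modal structure over the (d_c, d_m) plane."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    seen = set()
    for c in cells:
        m = c.modal_structure
        ax.scatter(c.d_c, c.d_m, s=120, marker="s",
                   color=_STRUCTURE_COLORS.get(m, "k"),
                   label=m if m not in seen else None)
        seen.add(m)
    ax.set_xlabel("$d_c$")
    ax.set_ylabel("$d_m$")
    ax.legend(fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
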