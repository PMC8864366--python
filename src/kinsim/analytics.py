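"""Analytic phase-boundary condition between kinship structures.

Clan endogamy keeps every family as kin-and-rival simultaneously, so its
per-family growth factor is ``p_C exp(-d_c*0 - d_m*1)``.  Dual
organization halves the rival density but pays a small cooperation cost
because the groom and bride clan centres deviate by order ``mu`` under
mutation fluctuations, reducing the mate's cooperation degree by the
factor ``exp(-alpha mu^2)`` (``alpha`` of order one):
``p_D exp(-d_c (1/2 - 1/2 exp(-alpha mu^2)) - d_m/2)``.  ``p_C`` and
``p_D`` are the sustenance probabilities of the two structures against
demographic fluctuation (supplied by the user or estimated by
simulation).  Dual organization is favoured when

    d_m / d_c  >  1 - exp(-alpha mu^2) + (2 / d_c) log(p_C / p_D)

so the boundary approaches a constant ratio ``d_m/d_c = C`` for large
``d_c`` and a constant ``d_m = C'`` for small ``d_c``.  Transitions to
generalized and restricted exchange reuse the same template with their
own sustenance probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnalyticParams",
    "dual_beats_endogamy",
    "threshold_ratio",
    "boundary_curve",
    "estimate_sustenance",
]


@dataclass(frozen=True)
class AnalyticParams:
    """Inputs of the boundary condition (all dimensionless)."""

    alpha: float = 1.0
    p_C: float = 1.0
    p_D: float = 1.0
    mu: float = 0.1
    d_c: float = 1.0
    d_m: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.p_C <= 1 and 0 < self.p_D <= 1):
            raise ValueError("sustenance probabilities must lie in (0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def dual_beats_endogamy(ap: AnalyticParams) -> tuple[bool, float, float]:
    """Compare the two growth expressions directly.

    Returns ``(dual_wins, endogamy_growth, dual_growth)`` where
    dual_wins means the dual-organization expression strictly exceeds
    the clan-endogamy expression.
    """
    lhs = ap.p_C * np.exp(-ap.d_m)
    rhs = ap.p_D * np.exp(
        -ap.d_c * (0.5 - 0.5 * np.exp(-ap.alpha * ap.mu ** 2)) - ap.d_m / 2.0
    )
    return bool(lhs < rhs), float(lhs), float(rhs)


def threshold_ratio(ap: AnalyticParams) -> float:
    """Critical ``d_m / d_c`` above which the transition occurs.

    ``1 - exp(-alpha mu^2) + (2 / d_c) log(p_C / p_D)``; requires
    ``d_c > 0`` (at ``d_c = 0`` compare the growth expressions
    directly).
    """
    if not ap.d_c > 0:
        raise ValueError("threshold_ratio requires d_c > 0")
    return float(
        1.0 - np.exp(-ap.alpha * ap.mu ** 2)
        + (2.0 / ap.d_c) * np.log(ap.p_C / ap.p_D)
    )


def boundary_curve(ap: AnalyticParams, d_c_grid: np.ndarray) -> pd.DataFrame:
    """Critical ``d_m`` along a grid of ``d_c`` values.

    ``d_m_crit = d_c * threshold_ratio``; for equal sustenance
    probabilities this is exactly linear with slope
    ``1 - exp(-alpha mu^2)``, and in general it is that line shifted by
    ``2 log(p_C / p_D)`` in ``d_m``.  Columns: d_c, d_m_crit, ratio.
    """
    d_c_grid = np.asarray(d_c_grid, dtype=float)
    if np.any(d_c_grid <= 0):
        raise ValueError("d_c grid must be positive")
    ratios = np.array(
        [threshold_ratio(AnalyticParams(ap.alpha, ap.p_C, ap.p_D, ap.mu, dc, ap.d_m))
         for dc in d_c_grid]
    )
    return pd.DataFrame({
        "d_c": d_c_grid,
        "d_m_crit": d_c_grid * ratios,
        "ratio": ratios,
    })


def estimate_sustenance(kind: str, params, n_steps: int = 50, n_trials: int = 20,
                        seed: int = 0, separation: float = 8.0) -> float:
    """Fraction of runs in which a seeded structure persists (utility hook).

    Initializes every society with the ideal point layout of the given
    structure kind (see :mod:`kinsim.fixtures`), runs ``n_steps``
    generations and counts the trials whose most populous society still
    classifies as that structure.
    """
    from .classify import classify_world
    from .engine import initialize_world, step
    from .fixtures import FixtureSpec, make_clan_cloud

    axis = {"endogamy": "t1", "dual": "t2", "generalized": "t1",
            "restricted": "both"}[kind]
    target = {"endogamy": "clan_endogamy", "dual": "dual_organization",
              "generalized": "generalized_exchange",
              "restricted": "restricted_exchange"}[kind]
    kept = 0
    for trial in range(n_trials):
        run_params = params.with_(seed=seed + trial, n_steps=n_steps)
        world = initialize_world(run_params)
        for si, soc in enumerate(world.societies):
            spec = FixtureSpec(
                kind=kind, n_families_per_clan=max(1, params.N_f // 4),
                separation=separation, noise_sd=params.mu / params.tau,
                descent_axis=axis, tau=params.tau, seed=seed + 1000 * trial + si,
            )
            pts, _ = make_clan_cloud(spec)
            idx = world.rng.integers(0, len(pts), size=soc.n)
            soc.t = pts[idx, :2].copy()
            soc.p = pts[idx, 2:].copy()
        for _ in range(run_params.n_steps):
            if world.all_extinct:
                break
            step(world, run_params)
        result = classify_world(world, params.tau, seed=seed + trial)
        if result.structure == target:
            kept += 1
    return kept / n_trials
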