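"""Synthetic data generators with known ground truth.

Two families of fixtures:

* :func:`make_clan_cloud` builds family point clouds in (t1, t2, p1, p2)
  space realizing each canonical kinship-structure geometry — a single
  endogamous clan, two clans exchanging brides directly (dual
  organization), k >= 3 clans exchanging cyclically (generalized
  exchange) and the four-clan double-descent grid (restricted exchange)
  — with configurable clan separation and within-clan noise, returning
  the implied ground-truth classification.

* :func:`make_sccs_table` emulates a cross-cultural ethnographic table:
  societies with latent cooperation/competition pressures (d_c, d_m),
  noisy observed indicator variables loading on one of them, missing
  cells, and structure labels assigned by thresholding d_m/d_c in the
  theoretical ordering (endogamy -> dual -> generalized -> restricted as
  the ratio grows).  It is the recovery test bed for the empirical
  estimation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClanPartition, StructureClass

__all__ = ["FixtureSpec", "make_clan_cloud", "make_sccs_table"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic clan point cloud.

    ``separation`` and ``noise_sd`` are in units of ``tau``;
    ``descent_axis`` selects which inherited trait dimension
    distinguishes the clans (t1: paternal, t2: maternal, both: double).
    """

    kind: str  # endogamy | dual | generalized | restricted
    n_families_per_clan: int = 30
    separation: float = 8.0
    noise_sd: float = 0.1
    descent_axis: str = "t1"  # t1 | t2 | both
    k: int = 3  # clans for generalized exchange
    tau: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise ValueError("separation must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.kind not in ("endogamy", "dual", "generalized", "restricted"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.descent_axis not in ("t1", "t2", "both"):
            raise ValueError(f"unknown descent_axis {self.descent_axis!r}")


def _centroid_layout(spec: FixtureSpec) -> tuple[np.ndarray, StructureClass]:
    """Clan centroids (k, 4) and the implied ground-truth classification."""
    s = spec.separation * spec.tau
    ax = spec.descent_axis
    if spec.kind == "endogamy":
        cents = np.zeros((1, 4))
        truth = ("clan_endogamy", 1, 1, "undivided")
    elif spec.kind == "dual":
        if ax == "both":
            raise ValueError("dual organization divides along one trait axis only")
        if ax == "t1":
            cents = np.array([[0, 0, s, 0], [s, 0, 0, 0]], dtype=float)
            descent = "patrilineal"
        else:
            cents = np.array([[0, 0, 0, s], [0, s, 0, 0]], dtype=float)
            descent = "matrilineal"
        truth = ("dual_organization", 2, 1, descent)
    elif spec.kind == "generalized":
        if spec.k < 3:
            raise ValueError("generalized exchange needs k >= 3 clans")
        if ax == "both":
            raise ValueError("generalized exchange divides along one trait axis only")
        k = spec.k
        cents = np.zeros((k, 4))
        pos = np.arange(k) * s
        nxt = np.roll(pos, -1)
        if ax == "t1":
            cents[:, 0], cents[:, 2] = pos, nxt
            descent = "patrilineal"
        else:
            cents[:, 1], cents[:, 3] = pos, nxt
            descent = "matrilineal"
        truth = ("generalized_exchange", k, 1, descent)
    else:  # restricted
        if ax != "both":
            raise ValueError("restricted exchange requires divergence on both axes")
        # A1, A2, B1, B2: pairwise marriage A1<=>B2, A2<=>B1; descent A1<->A2, B1<->B2
        cents = np.array(
            [[0, 0, s, s], [0, s, s, 0], [s, 0, 0, s], [s, s, 0, 0]], dtype=float
        )
        truth = ("restricted_exchange", 2, 2, "double")
    structure, C_m, C_d, descent_system = truth
    return cents, StructureClass(
        C_m=C_m, C_d=C_d, n_clans=len(cents), structure=structure,
        descent_system=descent_system,
    )


def make_clan_cloud(spec: FixtureSpec) -> tuple[np.ndarray, StructureClass]:
    """Point cloud realizing a known kinship structure, plus its ground truth.

    The returned StructureClass carries a ClanPartition with the true
    labels and centroids, so classifier recovery can be checked point by
    point.  ``noise_sd = 0`` reproduces the centroids exactly.
    """
    cents, truth = _centroid_layout(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_families_per_clan
    k = len(cents)
    labels = np.repeat(np.arange(k), n)
    points = cents[labels] + rng.normal(0.0, spec.noise_sd * spec.tau, size=(k * n, 4))
    truth.partition = ClanPartition(labels=labels, centroids=cents, k=k, bic=np.nan)
    return points, truth


#: default per-structure descent-system propensities for the table generator
_DESCENT_PROPENSITY = {
    "clan_endogamy": (("other", 1.0),),
    "dual_organization": (("patrilineal", 0.45), ("matrilineal", 0.40), ("double", 0.15)),
    "generalized_exchange": (("patrilineal", 0.75), ("matrilineal", 0.15), ("double", 0.10)),
    "restricted_exchange": (("double", 0.70), ("patrilineal", 0.20), ("matrilineal", 0.10)),
}


def default_phase_rule(dc: float, dm: float) -> str:
    """Theoretical ordering of structures in the pressure ratio d_m/d_c."""
    ratio = dm / dc if dc > 0 else np.inf
    if ratio < 0.15:
        return "clan_endogamy"
    if ratio < 0.5:
        return "dual_organization"
    if ratio < 1.5:
        return "generalized_exchange"
    return "restricted_exchange"


def make_sccs_table(
    n_societies: int,
    loadings: dict[str, float] | None = None,
    noise_sd: float = 0.5,
    phase_rule=default_phase_rule,
    seed: int = 0,
    missing_rate: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic ethnographic table with known latent pressures.

    Each society draws latent ``d_c ~ U(0.2, 5)`` and ``d_m ~ U(0.05, 3)``.
    Observed indicator variables are ``sign * loading * latent + noise``
    (noise sd in latent units), with cells missing independently at
    ``missing_rate``.  Structure labels follow ``phase_rule(d_c, d_m)``
    and descent labels are drawn with structure-dependent propensities.

    Returns ``(table, latent)``: the table in the empirical module's
    input layout (society_id, structure, descent, variable columns) and
    the latent per-society (d_c, d_m) values.
    """
    from .empirical import DEFAULT_MAPPING  # local import to avoid a cycle

    if n_societies < 10:
        raise ValueError("n_societies must be >= 10")
    rng = np.random.default_rng(seed)
    dc = rng.uniform(0.2, 5.0, n_societies)
    dm = rng.uniform(0.05, 3.0, n_societies)
    structures = [phase_rule(c, m) for c, m in zip(dc, dm)]
    descents = []
    for s in structures:
        opts = _DESCENT_PROPENSITY[s]
        names = [o[0] for o in opts]
        probs = np.array([o[1] for o in opts])
        descents.append(rng.choice(names, p=probs / probs.sum()))
    data = {
        "society_id": [f"S{i:03d}" for i in range(n_societies)],
        "structure": structures,
        "descent": descents,
    }
    latent = {"d_c": dc, "d_m": dm}
    for m in DEFAULT_MAPPING:
        load = 1.0 if loadings is None else loadings.get(m.variable, 1.0)
        base = latent["d_c"] if m.target == "d_c" else latent["d_m"]
        obs = m.sign * load * base + rng.normal(0.0, noise_sd, n_societies)
        if missing_rate > 0:
            obs = np.where(rng.random(n_societies) < missing_rate, np.nan, obs)
        data[m.variable] = obs
    table = pd.DataFrame(data)
    latent_df = pd.DataFrame(
        {"society_id": data["society_id"], "d_c": dc, "d_m": dm}
    )
    return table, latent_df
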