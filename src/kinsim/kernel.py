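"""Pure mathematical kernel of the family-interaction model.

Every family carries a two-dimensional cultural trait ``t = (t1, t2)`` and
mate preference ``p = (p1, p2)`` (t1/p1 transmitted through the paternal
line, t2/p2 through the maternal line).  Social relationships are Gaussian
kernels on distances in this four-dimensional space, with tolerance
``tau``:

* families *i* and *j* cooperate to degree
  ``exp(-min(|t_i - t_j|, |p_i - t_j|, |t_i - p_j|)^2 / tau^2)`` —
  cultural kin, and mates in either direction, are cooperators;
* they compete to degree ``exp(-|p_i - p_j|^2 / tau^2)`` — families that
  prefer the same grooms are mating rivals;
* the expected number of surviving children of each sex is
  ``r = b * exp(-d_c * (1 - friend) - d_m * rival)`` where ``friend`` and
  ``rival`` average the two degrees over all families of the society;
* women of family *j* accept a groom from family *i* with probability
  proportional to ``exp(-|t_i - p_j|^2 / tau^2)``;
* the child family of a groom from *i* and a bride from *j* inherits
  ``t = (t1_i, t2_j)`` and ``p = (p1_i, p2_j)``, each component perturbed
  by independent Normal(0, mu^2) noise.

The scalar functions here operate on :class:`FamilyState` objects and are
the readable reference; the batched array helpers (``friend_rival_arrays``
etc.) are the vectorized forms the simulation engine uses.  Both are
cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .params import ModelParams

__all__ = [
    "FamilyState",
    "InteractionProfile",
    "pair_distance",
    "cooperation_degree",
    "competition_degree",
    "growth_rate",
    "interaction_profile",
    "marriage_offer_distribution",
    "inherit",
    "min_sq_distance_matrix",
    "friend_rival_arrays",
    "marriage_weight_matrix",
]


@dataclass
class FamilyState:
    """A family: cultural identity plus its unmarried members by age.

    ``men_by_age[a]`` / ``women_by_age[a]`` count unmarried members who
    have been of marriageable age for ``a`` matching rounds
    (``a = 0 .. unmarried_lifespan - 1``).  ``pending`` marks a family
    formed by a marriage in the previous round, which has not yet borne
    its children.
    """

    family_id: int
    t: np.ndarray
    p: np.ndarray
    men_by_age: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))
    women_by_age: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))
    born_step: int = 0
    pending: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float).reshape(2)
        self.p = np.asarray(self.p, dtype=float).reshape(2)
        self.men_by_age = np.asarray(self.men_by_age, dtype=np.int64)
        self.women_by_age = np.asarray(self.women_by_age, dtype=np.int64)
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.p))):
            raise ValueError("family trait/preference vectors must be finite")
        if np.any(self.men_by_age < 0) or np.any(self.women_by_age < 0):
            raise ValueError("unmarried counts must be non-negative")


@dataclass(frozen=True)
class InteractionProfile:
    """Densities of cooperators and rivals, and the resulting growth rate."""

    friend: float
    rival: float
    r: float


def pair_distance(fam_i: FamilyState, fam_j: FamilyState) -> float:
    """Interaction distance between two families.

    ``d_ij = min(|t_i - t_j|, |p_i - t_j|, |t_i - p_j|)`` — the closest of
    the kin relation and the two directed mate relations.  Symmetric.
    """
    d_tt = np.linalg.norm(fam_i.t - fam_j.t)
    d_pt = np.linalg.norm(fam_i.p - fam_j.t)
    d_tp = np.linalg.norm(fam_i.t - fam_j.p)
    return float(min(d_tt, d_pt, d_tp))


def _check_tau(tau: float) -> None:
    if not tau > 0:
        raise ValueError("tau must be > 0")


def cooperation_degree(fam_i: FamilyState, fam_j: FamilyState, tau: float) -> float:
    """Gaussian kernel on the pair distance; 1 iff the families coincide as kin/mates."""
    _check_tau(tau)
    d = pair_distance(fam_i, fam_j)
    return float(np.exp(-(d * d) / (tau * tau)))


def competition_degree(fam_i: FamilyState, fam_j: FamilyState, tau: float) -> float:
    """Gaussian kernel on preference distance only (mating rivalry)."""
    _check_tau(tau)
    d2 = float(np.sum((fam_i.p - fam_j.p) ** 2))
    return float(np.exp(-d2 / (tau * tau)))


def growth_rate(friend: float, rival: float, params: ModelParams) -> float:
    """Expected surviving children per sex: ``b e^{-d_c(1-friend) - d_m rival}``."""
    return float(params.b * np.exp(-params.d_c * (1.0 - friend) - params.d_m * rival))


def interaction_profile(
    fam_i: FamilyState, society_families: list[FamilyState], params: ModelParams
) -> InteractionProfile:
    """Average cooperation and competition of ``fam_i`` over the society.

    The sums run over every family of the society including ``fam_i``
    itself (the self-term contributes 1 to both, so a singleton society
    has ``friend = rival = 1``).
    """
    if not society_families:
        raise ValueError("society has no families (extinct); caller must handle this")
    friend = float(
        np.mean([cooperation_degree(fam_i, fam_j, params.tau) for fam_j in society_families])
    )
    rival = float(
        np.mean([competition_degree(fam_i, fam_j, params.tau) for fam_j in society_families])
    )
    return InteractionProfile(friend=friend, rival=rival, r=growth_rate(friend, rival, params))


def marriage_offer_distribution(
    fam_i: FamilyState, society_families: list[FamilyState], tau: float
) -> np.ndarray:
    """Probability that a man of ``fam_i`` offers marriage to each family.

    Entries are proportional to ``exp(-|t_i - p_j|^2 / tau^2)`` and
    normalized over the society.  Marrying into one's own family is
    allowed (no built-in incest prohibition).  If every weight underflows
    to zero the distribution falls back to uniform.
    """
    _check_tau(tau)
    if not society_families:
        raise ValueError("society has no families")
    w = np.array(
        [np.exp(-np.sum((fam_i.t - fam_j.p) ** 2) / (tau * tau)) for fam_j in society_families]
    )
    total = w.sum()
    if total <= 0.0:
        return np.full(len(society_families), 1.0 / len(society_families))
    return w / total


def inherit(
    groom_family: FamilyState,
    bride_family: FamilyState,
    params: ModelParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Child-family ``(t, p)``: paternal first components, maternal second.

    ``t* = (t1_groom, t2_bride) + eta_t`` and ``p* = (p1_groom, p2_bride)
    + eta_p`` with all four noise components i.i.d. Normal(0, mu^2),
    drawn in the order (t1, t2, p1, p2).
    """
    eta = rng.normal(0.0, params.mu, size=4)
    t = np.array([groom_family.t[0], bride_family.t[1]]) + eta[:2]
    p = np.array([groom_family.p[0], bride_family.p[1]]) + eta[2:]
    return t, p


# ---------------------------------------------------------------------------
# vectorized forms used by the engine


def min_sq_distance_matrix(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Matrix of squared interaction distances ``d_ij^2`` for all pairs.

    ``d_ij = min(|t_i - t_j|, |p_i - t_j|, |t_i - p_j|)``; note
    ``|p_i - t_j| = |t_j - p_i|`` is the transpose of the t-vs-p matrix.
    """
    d_tt2 = cdist(t, t, "sqeuclidean")
    d_tp2 = cdist(t, p, "sqeuclidean")
    return np.minimum(d_tt2, np.minimum(d_tp2, d_tp2.T))


def friend_rival_arrays(
    t: np.ndarray, p: np.ndarray, tau: float
) -> tuple[np.ndarray, np.ndarray]:
    """``friend_i`` and ``rival_i`` for every family of one society."""
    tau2 = tau * tau
    friend = np.exp(-min_sq_distance_matrix(t, p) / tau2).mean(axis=1)
    rival = np.exp(-cdist(p, p, "sqeuclidean") / tau2).mean(axis=1)
    return friend, rival


def marriage_weight_matrix(t: np.ndarray, p: np.ndarray, tau: float) -> np.ndarray:
    """``W[i, j] = exp(-|t_i - p_j|^2 / tau^2)``: groom family i, bride family j."""
    return np.exp(-cdist(t, p, "sqeuclidean") / (tau * tau))
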