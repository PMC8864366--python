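"""Generational life cycle of families within competing societies.

One step (a generation) runs, for every society: draw offspring for the
families formed by last round's marriages (Poisson with the
interaction-dependent growth rate), match marriages (monogamous;
bride-side preference weights), form the child families, then age the
still-unmarried and drop those past the unmarried lifespan.  Finally any
society that has reached ``split_threshold_factor * N_f`` families splits
in half and a randomly chosen other society is removed, keeping the
number of societies fixed at ``N_s`` — this replacement is the
society-level selection.

Societies are stored column-wise (numpy arrays per society) for speed;
:class:`kinsim.kernel.FamilyState` views can be materialized on demand.

Randomness
----------
A single ``numpy.random.Generator`` seeded from ``ModelParams.seed``
drives the whole run.  Per step, draws occur in this order, for each
society in roster order:

1. if any family is pending reproduction: ``rng.poisson(lam)`` for the
   men then again for the women (``lam`` = growth rates of the pending
   families in roster order);
2. if any unmarried man exists: ``rng.permutation(n_men)`` (processing
   order), then ``rng.random(n_men)`` (one uniform per man);
3. if ``k`` marriages formed: ``rng.normal(0, mu, (k, 4))`` (transmission
   noise, columns t1, t2, p1, p2).

Then the split phase: while some society is at/over threshold,
``rng.integers`` picks which oversized society splits next,
``rng.permutation`` partitions its families into halves, and
``rng.integers`` picks the removed victim uniformly among all societies
except the two fresh halves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._match import consume_matches, match_loop
from .kernel import FamilyState, friend_rival_arrays
from .params import ModelParams

__all__ = [
    "Society",
    "World",
    "MarriageEvent",
    "EventBlock",
    "RunResult",
    "initialize_world",
    "reproduce",
    "match_marriages",
    "age_and_cull",
    "split_and_select",
    "step",
    "run_simulation",
]


@dataclass(frozen=True)
class MarriageEvent:
    """One logged marriage: ids resolve to families existing at that step."""

    step: int
    society_id: int
    groom_family_id: int
    bride_family_id: int
    child_family_id: int


@dataclass
class EventBlock:
    """All marriages of one society in one step, column-wise.

    ``*_vec`` rows are the (t1, t2, p1, p2) vectors of the participating
    families at the time of the marriage, so clan membership of families
    that later disappear from the roster can still be resolved.  The
    parent vectors are materialized lazily from the pre-marriage roster
    arrays (which the engine never mutates in place after the block is
    created).
    """

    step: int
    society_id: int
    lineage_id: int
    groom_id: np.ndarray
    bride_id: np.ndarray
    child_id: np.ndarray
    child_vec: np.ndarray
    _t: np.ndarray
    _p: np.ndarray
    _grooms: np.ndarray
    _brides: np.ndarray

    @property
    def groom_vec(self) -> np.ndarray:
        return np.hstack([self._t[self._grooms], self._p[self._grooms]])

    @property
    def bride_vec(self) -> np.ndarray:
        return np.hstack([self._t[self._brides], self._p[self._brides]])

    def __len__(self) -> int:
        return len(self.child_id)

    def to_events(self) -> list[MarriageEvent]:
        return [
            MarriageEvent(self.step, self.society_id, int(g), int(b), int(c))
            for g, b, c in zip(self.groom_id, self.bride_id, self.child_id)
        ]


class Society:
    """Roster of families of one society, stored column-wise.

    ``lineage_id`` persists through splits (both halves inherit it) so a
    society can be followed through the split-and-replace process.
    """

    __slots__ = ("society_id", "lineage_id", "t", "p", "men", "women",
                 "family_id", "born_step", "pending")

    def __init__(self, society_id, lineage_id, t, p, men, women, family_id,
                 born_step, pending):
        self.society_id = int(society_id)
        self.lineage_id = int(lineage_id)
        self.t = t
        self.p = p
        self.men = men
        self.women = women
        self.family_id = family_id
        self.born_step = born_step
        self.pending = pending

    @property
    def n(self) -> int:
        return self.t.shape[0]

    @property
    def extinct(self) -> bool:
        return self.n == 0

    def points(self) -> np.ndarray:
        """(n, 4) array of family (t1, t2, p1, p2) vectors."""
        return np.hstack([self.t, self.p])

    def families(self) -> list[FamilyState]:
        """Materialize the roster as FamilyState objects (for the scalar API)."""
        return [
            FamilyState(
                family_id=int(self.family_id[i]),
                t=self.t[i].copy(),
                p=self.p[i].copy(),
                men_by_age=self.men[i].copy(),
                women_by_age=self.women[i].copy(),
                born_step=int(self.born_step[i]),
                pending=bool(self.pending[i]),
            )
            for i in range(self.n)
        ]

    def take(self, idx: np.ndarray, society_id: int | None = None) -> "Society":
        """New Society holding the selected rows."""
        return Society(
            self.society_id if society_id is None else society_id,
            self.lineage_id,
            self.t[idx], self.p[idx],
            self.men[idx], self.women[idx],
            self.family_id[idx], self.born_step[idx],
            self.pending[idx],
        )

    @staticmethod
    def empty(society_id: int, lineage_id: int, lifespan: int) -> "Society":
        return Society(
            society_id, lineage_id,
            np.zeros((0, 2)), np.zeros((0, 2)),
            np.zeros((0, lifespan), np.int64), np.zeros((0, lifespan), np.int64),
            np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0, bool),
        )


@dataclass
class World:
    """The full system: exactly ``N_s`` societies plus run bookkeeping."""

    societies: list[Society]
    step: int
    rng: np.random.Generator
    next_family_id: int
    next_society_id: int
    events: list[EventBlock] = field(default_factory=list)

    @property
    def all_extinct(self) -> bool:
        return all(s.extinct for s in self.societies)

    def total_families(self) -> int:
        return sum(s.n for s in self.societies)

    def largest_society(self) -> Society | None:
        """Most populous surviving society (None if all extinct)."""
        alive = [s for s in self.societies if not s.extinct]
        if not alive:
            return None
        return max(alive, key=lambda s: (s.n, -s.society_id))


def initialize_world(params: ModelParams) -> World:
    """``N_s`` societies of ``N_f`` families each, all at t = p = (0, 0).

    Founding families are treated as just-married couples: they are
    pending reproduction, so their first offspring are drawn at step 1.
    """
    L = params.unmarried_lifespan
    societies = []
    fid = 0
    for sid in range(params.N_s):
        n = params.N_f
        societies.append(
            Society(
                sid, sid,
                np.zeros((n, 2)), np.zeros((n, 2)),
                np.zeros((n, L), np.int64), np.zeros((n, L), np.int64),
                np.arange(fid, fid + n, dtype=np.int64),
                np.zeros(n, np.int64),
                np.ones(n, bool),
            )
        )
        fid += n
    return World(
        societies=societies,
        step=0,
        rng=np.random.default_rng(params.seed),
        next_family_id=fid,
        next_society_id=params.N_s,
    )


def reproduce(
    society: Society,
    params: ModelParams,
    rng: np.random.Generator,
    _d_tp2: np.ndarray | None = None,
) -> Society:
    """Draw Poisson offspring for families pending reproduction.

    Growth rates come from the interaction profile over the whole roster
    (including families that merely hold lingering unmarried members).
    Men and women are independent draws appended as age-0 unmarried.
    """
    if society.extinct:
        raise ValueError("cannot reproduce in an extinct society")
    pend = society.pending
    if not pend.any():
        return society
    tau2 = params.tau * params.tau
    t, p = society.t, society.p
    if _d_tp2 is None:
        _d_tp2 = cdist(t, p, "sqeuclidean")
    m2 = np.minimum(cdist(t, t, "sqeuclidean"), np.minimum(_d_tp2, _d_tp2.T))
    friend = np.exp(-m2 / tau2).mean(axis=1)
    rival = np.exp(-cdist(p, p, "sqeuclidean") / tau2).mean(axis=1)
    r = params.b * np.exp(-params.d_c * (1.0 - friend) - params.d_m * rival)
    lam = r[pend]
    men0 = rng.poisson(lam)
    women0 = rng.poisson(lam)
    society.men[pend, 0] += men0
    society.women[pend, 0] += women0
    society.pending[:] = False
    return society


def match_marriages(
    society: Society,
    params: ModelParams,
    rng: np.random.Generator,
    id_start: int = 0,
    _W: np.ndarray | None = None,
) -> EventBlock | None:
    """Match unmarried men to bride families and found the child families.

    Monogamy: each marriage consumes exactly one unmarried man and one
    unmarried woman.  Men are processed in a uniformly random order; each
    offers to one family sampled from the full-society distribution with
    weights ``exp(-|t_groom - p_bride|^2/tau^2)``.  The offer succeeds
    only if the sampled family currently holds an unmarried woman;
    otherwise the man stays unmarried this round.  Every couple
    immediately founds a child family (placed in the same society,
    pending reproduction next step) whose (t, p) follow the
    paternal/maternal transmission rule plus noise.  Returns the block of
    logged marriages, or None if none occurred; new family ids are
    ``id_start .. id_start + k - 1``.
    """
    n = society.n
    if n == 0:
        return None
    men_total = society.men.sum(axis=1)
    n_men = int(men_total.sum())
    if n_men == 0:
        return None
    man_fams = np.repeat(np.arange(n), men_total)
    man_fams = man_fams[rng.permutation(n_men)]
    u = rng.random(n_men)
    if _W is None:
        _W = np.exp(
            -cdist(society.t, society.p, "sqeuclidean") / (params.tau * params.tau)
        )
    women_total = society.women.sum(axis=1)
    grooms, brides = match_loop(man_fams, u, _W, women_total)
    k = len(grooms)
    if k == 0:
        return None
    noise = rng.normal(0.0, params.mu, size=(k, 4))
    t_child = np.column_stack([society.t[grooms, 0], society.t[brides, 1]]) + noise[:, :2]
    p_child = np.column_stack([society.p[grooms, 0], society.p[brides, 1]]) + noise[:, 2:]
    block = EventBlock(
        step=-1,  # caller stamps the step; standalone use keeps -1
        society_id=society.society_id,
        lineage_id=society.lineage_id,
        groom_id=society.family_id[grooms].copy(),
        bride_id=society.family_id[brides].copy(),
        child_id=np.arange(id_start, id_start + k, dtype=np.int64),
        child_vec=np.hstack([t_child, p_child]),
        _t=society.t, _p=society.p, _grooms=grooms, _brides=brides,
    )
    consume_matches(society.men, society.women, grooms, brides)
    L = params.unmarried_lifespan
    society.t = np.concatenate([society.t, t_child])
    society.p = np.concatenate([society.p, p_child])
    society.men = np.concatenate([society.men, np.zeros((k, L), np.int64)])
    society.women = np.concatenate([society.women, np.zeros((k, L), np.int64)])
    society.family_id = np.concatenate([society.family_id, block.child_id])
    society.born_step = np.concatenate(
        [society.born_step, np.full(k, -1, np.int64)]
    )
    society.pending = np.concatenate([society.pending, np.ones(k, bool)])
    return block


def age_and_cull(society: Society, params: ModelParams) -> Society:
    """Age unmarried members; those past the lifespan die childless.

    Families left with no unmarried members and no pending reproduction
    are dropped from the roster.  An emptied roster marks the society
    extinct.
    """
    men, women = society.men, society.women
    for a in range(men.shape[1] - 1, 0, -1):  # shift ages up in place
        men[:, a] = men[:, a - 1]
        women[:, a] = women[:, a - 1]
    men[:, 0] = 0
    women[:, 0] = 0
    keep = society.pending | ((men.sum(axis=1) + women.sum(axis=1)) > 0)
    if not keep.all():
        idx = np.flatnonzero(keep)
        society.t = society.t[idx]
        society.p = society.p[idx]
        society.men = society.men[idx]
        society.women = society.women[idx]
        society.family_id = society.family_id[idx]
        society.born_step = society.born_step[idx]
        society.pending = society.pending[idx]
    return society


def split_and_select(world: World, params: ModelParams, rng: np.random.Generator) -> World:
    """Split societies at the family-count threshold; replace a random other.

    While any society holds at least ``split_threshold_factor * N_f``
    families, one such society (chosen uniformly at random) is partitioned
    uniformly into two halves (odd counts differ by one); one victim,
    chosen uniformly among all societies except the two fresh halves
    (extinct ones included), is removed, restoring the society count.
    """
    thr = params.split_threshold
    while True:
        oversized = [i for i, s in enumerate(world.societies) if s.n >= thr]
        if not oversized:
            return world
        idx = oversized[int(rng.integers(len(oversized)))]
        soc = world.societies[idx]
        perm = rng.permutation(soc.n)
        h1 = np.sort(perm[: soc.n // 2])
        h2 = np.sort(perm[soc.n // 2:])
        first = soc.take(h1)
        second = soc.take(h2, society_id=world.next_society_id)
        world.next_society_id += 1
        world.societies[idx] = first
        world.societies.append(second)
        candidates = [
            i for i in range(len(world.societies))
            if i != idx and i != len(world.societies) - 1
        ]
        victim = candidates[int(rng.integers(len(candidates)))]
        del world.societies[victim]


def step(world: World, params: ModelParams) -> World:
    """Advance one generation: reproduce, marry, cull, split-and-replace."""
    if world.all_extinct:
        raise RuntimeError("all societies are extinct; the run has ended")
    rng = world.rng
    tau2 = params.tau * params.tau
    for soc in world.societies:
        if soc.extinct:
            continue
        d_tp2 = cdist(soc.t, soc.p, "sqeuclidean")
        reproduce(soc, params, rng, _d_tp2=d_tp2)
        block = match_marriages(
            soc, params, rng, id_start=world.next_family_id, _W=np.exp(-d_tp2 / tau2)
        )
        if block is not None:
            block.step = world.step
            soc.born_step[soc.pending] = world.step
            world.next_family_id += len(block)
            world.events.append(block)
        age_and_cull(soc, params)
    split_and_select(world, params, rng)
    world.step += 1
    if params.event_log_window >= 0:
        cutoff = world.step - params.event_log_window
        world.events = [b for b in world.events if b.step >= cutoff]
    return world


@dataclass
class RunResult:
    """Final state of a run plus light per-step trajectory summaries."""

    params: ModelParams
    world: World
    outcome: str  # "completed" or "extinct"
    #: per executed step: total families, number of surviving societies
    total_families: np.ndarray
    alive_societies: np.ndarray
    #: per executed step: pooled variance of (t1, t2, p1, p2) over all families
    trait_variance: np.ndarray
    #: per executed step and society slot: family count
    families_per_society: np.ndarray

    @property
    def events(self) -> list[EventBlock]:
        return self.world.events

    def final_points(self) -> np.ndarray:
        """(n, 4) point cloud of the most populous surviving society."""
        soc = self.world.largest_society()
        if soc is None:
            return np.zeros((0, 4))
        return soc.points()


def run_simulation(params: ModelParams) -> RunResult:
    """Run ``n_steps`` generations (or until global extinction)."""
    world = initialize_world(params)
    n = params.n_steps
    total = np.zeros(n, np.int64)
    alive = np.zeros(n, np.int64)
    tvar = np.zeros((n, 4))
    fps = np.zeros((n, params.N_s), np.int64)
    executed = 0
    outcome = "completed"
    for i in range(n):
        if world.all_extinct:
            outcome = "extinct"
            break
        step(world, params)
        executed += 1
        sizes = np.array([s.n for s in world.societies])
        total[i] = sizes.sum()
        alive[i] = int((sizes > 0).sum())
        fps[i] = sizes
        if total[i] > 0:
            pts = np.concatenate([s.points() for s in world.societies if s.n])
            tvar[i] = pts.var(axis=0)
    if world.all_extinct:
        outcome = "extinct"
    return RunResult(
        params=params,
        world=world,
        outcome=outcome,
        total_families=total[:executed],
        alive_societies=alive[:executed],
        trait_variance=tvar[:executed],
        families_per_society=fps[:executed],
    )


def interaction_profiles_of(society: Society, params: ModelParams):
    """friend, rival and r arrays of a society's current roster (diagnostics)."""
    friend, rival = friend_rival_arrays(society.t, society.p, params.tau)
    r = params.b * np.exp(-params.d_c * (1.0 - friend) - params.d_m * rival)
    return friend, rival, r
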