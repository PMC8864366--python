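"""Clan detection and kinship-structure classification.

A converged society is a point cloud in the four-dimensional
``(t1, t2, p1, p2)`` space.  Clans are the clusters of that cloud: the
number of clusters is selected by sweeping k-means over ``k = 1..k_max``
and scoring each partition with the Bayesian information criterion under
a spherical-Gaussian model (the model-selection step of X-means).
Clustering is done in raw trait units: the kernel tolerance ``tau`` sets
the natural scale, diverged dimensions separate by several ``tau`` while
non-diverged dimensions carry only mutation noise, and rescaling the
noise dimensions to unit variance would drown the signal.

Marriage and descent relations between clans are read off the cluster
centres.  Women of clan X marry men of the clan whose trait centroid is
nearest to X's preference centroid (written X => Y).  Children of a
couple (groom clan A, bride clan W) carry the paternal first components
and maternal second components; assembling that child vector from the
centroids and assigning it to its nearest centroid gives the
father-line descent map A -> child-clan and the mother-line map
W -> child-clan.  Clan membership is preserved along the father line in
a patrilineal system and along the mother line in a matrilineal one, so
the descent cycle C_d is the shorter of the two line cycles; the
marriage cycle C_m is the cycle of the marriage map.  The (C_m, C_d)
pair then names the structure:

========================  =====  =====
structure                  C_m    C_d
========================  =====  =====
clan endogamy (1 clan)      1      1
dual organization           2      1
generalized exchange       >=3     1
restricted exchange         2      2
========================  =====  =====

anything else (several endogamous clans, inconsistent multi-cycle
graphs, ...) is reported as ``other``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .engine import EventBlock, World

__all__ = [
    "ClanPartition",
    "ClanGraphs",
    "StructureClass",
    "cluster_families",
    "merge_close_clans",
    "build_clan_graphs",
    "trace_event_graphs",
    "cycle_length",
    "cycle_detail",
    "cycles_from_events",
    "classify_descent",
    "classify_structure",
    "classify_world",
]

STRUCTURES = (
    "clan_endogamy",
    "dual_organization",
    "generalized_exchange",
    "restricted_exchange",
    "other",
    "extinct",
)
DESCENT_SYSTEMS = ("patrilineal", "matrilineal", "double", "undivided", "ambiguous")


@dataclass
class ClanPartition:
    """Clustering of one society's families into clans."""

    labels: np.ndarray  # clan index per family
    centroids: np.ndarray  # (k, 4) over (t1, t2, p1, p2)
    k: int
    bic: float

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class ClanGraphs:
    """Functional graphs on clans.

    ``marriage[X] = Y`` means women of X marry men of Y (X => Y).
    ``descent_father[A]`` / ``descent_mother[W]`` give the clan of the
    children of a father from A / a mother from W.
    """

    marriage: dict[int, int]
    descent_father: dict[int, int]
    descent_mother: dict[int, int]


@dataclass
class StructureClass:
    """Cycle lengths, structure class and descent system of one society."""

    C_m: int
    C_d: int
    n_clans: int
    structure: str
    descent_system: str
    inconsistent: bool = False
    partition: ClanPartition | None = field(default=None, repr=False)
    graphs: ClanGraphs | None = field(default=None, repr=False)


def _bic_score(points: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Pelleg–Moore BIC of a k-means partition (larger is better).

    Spherical Gaussians with one shared variance; parameter count
    ``(k - 1) + k d + 1`` (mixture weights, centroids, variance).
    """
    n, d = points.shape
    k = centroids.shape[0]
    rss = float(np.sum((points - centroids[labels]) ** 2))
    if n <= k:
        sigma2 = 0.0
    else:
        sigma2 = rss / (d * (n - k))
    sigma2 = max(sigma2, 1e-12)  # degenerate exact-duplicate clouds
    sizes = np.bincount(labels, minlength=k).astype(float)
    sizes = sizes[sizes > 0]
    ll = (
        float(np.sum(sizes * np.log(sizes))) - n * np.log(n)
        - 0.5 * n * d * np.log(2.0 * np.pi * sigma2)
        - 0.5 * d * (n - k)
    )
    n_params = (k - 1) + k * d + 1
    return ll - 0.5 * n_params * np.log(n)


def cluster_families(points: np.ndarray, k_max: int = 8, seed: int = 0,
                     n_init: int = 10) -> ClanPartition:
    """Cluster family (t1, t2, p1, p2) vectors into clans, selecting k by BIC.

    Runs seeded k-means for each ``k = 1..min(k_max, n)`` with ``n_init``
    restarts and keeps the partition with the best spherical-Gaussian
    BIC.  Deterministic for a given seed.  Raises on an empty cloud
    (extinct society — callers classify that directly).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be an (n, 4) array")
    n = points.shape[0]
    if n == 0:
        raise ValueError("empty point cloud (extinct society)")
    best: ClanPartition | None = None
    for k in range(1, min(k_max, n) + 1):
        if k == 1:
            centroids = points.mean(axis=0, keepdims=True)
            labels = np.zeros(n, dtype=int)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(points)
            labels = km.labels_.astype(int)
            centroids = km.cluster_centers_
            if len(np.unique(labels)) < k:  # fewer distinct clusters than asked
                continue
        bic = _bic_score(points, labels, centroids)
        if best is None or bic > best.bic:
            best = ClanPartition(labels=labels, centroids=centroids, k=k, bic=bic)
    assert best is not None
    return best


def merge_close_clans(partition: ClanPartition, tol: float) -> ClanPartition:
    """Merge clusters whose centroids lie within ``tol`` of each other.

    Families at sub-``tau`` distance cooperate, compete and intermarry
    essentially as one group (the Gaussian kernels cannot tell them
    apart), so k-means clusters separated by less than the tolerance are
    one clan behaviourally.  Single-linkage merging with
    size-weighted centroid recomputation; labels are renumbered in order
    of the lowest original cluster index.
    """
    k = partition.k
    if k == 1 or tol <= 0:
        return partition
    c = partition.centroids
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(k):
        for j in range(i + 1, k):
            if np.sqrt(np.sum((c[i] - c[j]) ** 2)) < tol:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    roots = [find(i) for i in range(k)]
    order = sorted(set(roots))
    remap = {r: new for new, r in enumerate(order)}
    labels = np.array([remap[roots[l]] for l in partition.labels])
    sizes = np.bincount(partition.labels, minlength=k).astype(float)
    new_k = len(order)
    new_c = np.zeros((new_k, c.shape[1]))
    for old in range(k):
        new_c[remap[roots[old]]] += sizes[old] * c[old]
    group_sizes = np.bincount(labels, minlength=new_k).astype(float)
    new_c /= group_sizes[:, None]
    return ClanPartition(labels=labels, centroids=new_c, k=new_k, bic=partition.bic)


def _nearest(vec: np.ndarray, centroids: np.ndarray) -> int:
    """Index of the nearest centroid; ties break to the lowest index."""
    d = np.sum((centroids - vec) ** 2, axis=1)
    return int(np.argmin(d))  # argmin takes the first (lowest) index on ties


def build_clan_graphs(partition: ClanPartition) -> ClanGraphs:
    """Marriage and descent maps read off the cluster centres."""
    c = partition.centroids
    k = partition.k
    t_cent, p_cent = c[:, :2], c[:, 2:]
    marriage: dict[int, int] = {}
    bride_of: dict[int, int] = {}
    for x in range(k):
        # women of X marry men of the clan whose traits match X's preference
        marriage[x] = _nearest(p_cent[x], t_cent)
    for a in range(k):
        # the clan whose women most prefer A's men supplies A's brides
        bride_of[a] = _nearest(t_cent[a], p_cent)
    descent_father: dict[int, int] = {}
    descent_mother: dict[int, int] = {}
    for a in range(k):
        w = bride_of[a]
        child = _child_vec(c[a], c[w])
        descent_father[a] = _nearest(child, c)
    for w in range(k):
        h = marriage[w]
        child = _child_vec(c[h], c[w])
        descent_mother[w] = _nearest(child, c)
    return ClanGraphs(marriage=marriage, descent_father=descent_father,
                      descent_mother=descent_mother)


def _child_vec(groom: np.ndarray, bride: np.ndarray) -> np.ndarray:
    """Child-family centroid vector: paternal first, maternal second components."""
    return np.array([groom[0], bride[1], groom[2], bride[3]])


def trace_event_graphs(
    events: list[EventBlock],
    partition: ClanPartition,
    family_table: dict[int, np.ndarray] | None = None,
) -> ClanGraphs:
    """Clan graphs traced from logged marriages instead of centroids.

    Each participating family is assigned to its nearest clan centroid
    (using the vectors stored in the event blocks, or looked up in
    ``family_table`` by family id).  For every clan the modal
    bride-clan -> groom-clan relation defines the marriage edge, and the
    modal father-clan -> child-clan / mother-clan -> child-clan relations
    define the two descent edges.  Clans with no logged events are
    absent from the maps (callers fall back to the centroid method).
    """
    if not events:
        raise ValueError("no events to trace")
    cents = partition.centroids
    k = partition.k
    mar = np.zeros((k, k), dtype=np.int64)
    des_f = np.zeros((k, k), dtype=np.int64)
    des_m = np.zeros((k, k), dtype=np.int64)
    for block in events:
        if isinstance(block, EventBlock):
            gv, bv, cv = block.groom_vec, block.bride_vec, block.child_vec
        else:  # bare MarriageEvents plus a family table
            if family_table is None:
                raise ValueError("family_table required for bare MarriageEvents")
            gv = np.array([family_table[e.groom_family_id] for e in block])
            bv = np.array([family_table[e.bride_family_id] for e in block])
            cv = np.array([family_table[e.child_family_id] for e in block])
        g = np.argmin(((cents[None, :, :] - gv[:, None, :]) ** 2).sum(-1), axis=1)
        b = np.argmin(((cents[None, :, :] - bv[:, None, :]) ** 2).sum(-1), axis=1)
        ch = np.argmin(((cents[None, :, :] - cv[:, None, :]) ** 2).sum(-1), axis=1)
        np.add.at(mar, (b, g), 1)  # women of clan b married men of clan g
        np.add.at(des_f, (g, ch), 1)
        np.add.at(des_m, (b, ch), 1)
    def modal(counts: np.ndarray) -> dict[int, int]:
        out = {}
        for x in range(k):
            if counts[x].sum() > 0:
                out[x] = int(np.argmax(counts[x]))
        return out
    return ClanGraphs(marriage=modal(mar), descent_father=modal(des_f),
                      descent_mother=modal(des_m))


def cycles_from_events(events, partition: ClanPartition,
                       weights: dict[int, float] | None = None,
                       family_table: dict[int, np.ndarray] | None = None):
    """(C_m, C_d) from logged marriages, or None if any clan lacks events.

    The event-based counterpart of the centroid route: marriage and
    descent cycles measured on the modal edges of
    :func:`trace_event_graphs`.  Partial maps (a clan with no logged
    event) return None — callers fall back to the centroid graphs.
    """
    graphs = trace_event_graphs(events, partition, family_table)
    k = partition.k
    if any(len(g) < k for g in (graphs.marriage, graphs.descent_father,
                                graphs.descent_mother)):
        return None
    C_m, _ = cycle_detail(graphs.marriage, weights)
    lf, _ = cycle_detail(graphs.descent_father, weights)
    lm, _ = cycle_detail(graphs.descent_mother, weights)
    return C_m, min(lf, lm)


def cycle_detail(edge_map: dict[int, int],
                 weights: dict[int, float] | None = None) -> tuple[int, bool]:
    """(cycle length, inconsistency flag) of a functional graph.

    Every node of a functional graph reaches exactly one cycle.  If all
    nodes reach cycles of one common length that length is returned
    un-flagged; otherwise the length of the cycle carrying the most
    weight (families in the clans on the cycle; ties to the shorter
    cycle) is returned and the graph is flagged inconsistent.
    """
    if not edge_map:
        raise ValueError("empty edge map")
    cycles: dict[frozenset, int] = {}
    node_cycle: dict[int, frozenset] = {}
    for start in edge_map:
        seen: dict[int, int] = {}
        node = start
        order = 0
        while node not in seen:
            if node in node_cycle:  # memoized tail
                node_cycle[start] = node_cycle[node]
                break
            seen[node] = order
            order += 1
            node = edge_map[node]
        else:
            cyc = frozenset(n for n, i in seen.items() if i >= seen[node])
            cycles[cyc] = len(cyc)
            node_cycle[start] = cyc
    lengths = set(cycles.values())
    if len(lengths) == 1:
        return lengths.pop(), False
    w = weights or {}
    def cycle_weight(cyc: frozenset) -> float:
        return sum(w.get(n, 1.0) for n in cyc)
    best = max(cycles, key=lambda c: (cycle_weight(c), -cycles[c]))
    return cycles[best], True


def cycle_length(edge_map: dict[int, int],
                 weights: dict[int, float] | None = None) -> int:
    """Cycle length of a total functional graph (see :func:`cycle_detail`)."""
    return cycle_detail(edge_map, weights)[0]


def classify_descent(partition: ClanPartition, C_d: int, tau: float,
                     theta: float = 1.0) -> str:
    """Descent system from the spread of clan centroids along t1 and t2.

    A trait dimension is significant when the centroid spread along it
    exceeds ``theta * tau``.  Paternal (t1) only -> patrilineal; maternal
    (t2) only -> matrilineal; both -> double; a single undifferentiated
    clan -> undivided; several clans with no significant trait dimension
    -> ambiguous.
    """
    if partition.k == 1:
        return "undivided"
    spread_t1 = float(np.ptp(partition.centroids[:, 0]))
    spread_t2 = float(np.ptp(partition.centroids[:, 1]))
    sig1 = spread_t1 > theta * tau
    sig2 = spread_t2 > theta * tau
    if sig1 and sig2:
        return "double"
    if sig1:
        return "patrilineal"
    if sig2:
        return "matrilineal"
    return "ambiguous"


def _cycles_from_graphs(graphs: ClanGraphs, weights: dict[int, float]):
    C_m, flag_m = cycle_detail(graphs.marriage, weights)
    lf, ff = cycle_detail(graphs.descent_father, weights)
    lm, fm = cycle_detail(graphs.descent_mother, weights)
    # membership survives along whichever parent line cycles shortest
    C_d = min(lf, lm)
    achieving = [f for l, f in ((lf, ff), (lm, fm)) if l == C_d]
    flag_d = all(achieving)
    return C_m, flag_m, C_d, flag_d


def _structure_from_cycles(C_m: int, C_d: int, k: int, inconsistent: bool) -> str:
    if inconsistent:
        return "other"
    if C_m == 1 and C_d == 1 and k == 1:
        return "clan_endogamy"
    if C_m == 2 and C_d == 1:
        return "dual_organization"
    if C_m >= 3 and C_d == 1:
        return "generalized_exchange"
    if C_m == 2 and C_d == 2:
        return "restricted_exchange"
    return "other"


def classify_structure(points: np.ndarray, tau: float, theta: float = 1.0,
                       k_max: int = 8, seed: int = 0,
                       merge_tol: float = 1.0) -> StructureClass:
    """Full classification of one society's family point cloud.

    Cluster into clans (k selected by BIC, then clusters closer than
    ``merge_tol * tau`` merged — see :func:`merge_close_clans`), build
    the clan graphs from the centroids, measure the marriage and descent
    cycles and name the structure and descent system.  An empty cloud
    classifies as extinct.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] == 0:
        return StructureClass(C_m=0, C_d=0, n_clans=0, structure="extinct",
                              descent_system="undivided")
    partition = cluster_families(points, k_max=k_max, seed=seed)
    partition = merge_close_clans(partition, merge_tol * tau)
    graphs = build_clan_graphs(partition)
    weights = {i: float(s) for i, s in enumerate(partition.sizes)}
    C_m, flag_m, C_d, flag_d = _cycles_from_graphs(graphs, weights)
    inconsistent = flag_m or flag_d
    structure = _structure_from_cycles(C_m, C_d, partition.k, inconsistent)
    descent = classify_descent(partition, C_d, tau, theta)
    return StructureClass(C_m=C_m, C_d=C_d, n_clans=partition.k,
                          structure=structure, descent_system=descent,
                          inconsistent=inconsistent,
                          partition=partition, graphs=graphs)


def classify_world(world: World, tau: float, theta: float = 1.0, k_max: int = 8,
                   seed: int = 0, merge_tol: float = 1.0,
                   per_society: bool = False):
    """Classify the most populous surviving society of a world.

    With ``per_society=True`` returns a dict of society_id ->
    StructureClass for every surviving society instead.
    """
    if per_society:
        return {
            s.society_id: classify_structure(s.points(), tau, theta, k_max,
                                             seed, merge_tol)
            for s in world.societies if not s.extinct
        }
    soc = world.largest_society()
    if soc is None:
        return StructureClass(C_m=0, C_d=0, n_clans=0, structure="extinct",
                              descent_system="undivided")
    return classify_structure(soc.points(), tau, theta, k_max, seed, merge_tol)
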