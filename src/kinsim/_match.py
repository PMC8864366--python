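"""Sequential marriage-matching inner loop.

Men are processed one at a time in a pre-shuffled order.  Each man from
groom family ``g`` samples one bride family ``j`` from the full-society
offer distribution ``P(j) = W[g, j] / sum_j' W[g, j']`` (the
distribution is over every family of the society, whether or not it
currently holds an unmarried woman).  If the sampled family still holds
an unmarried woman the marriage happens and consumes her; otherwise the
offer fails and the man stays unmarried this round.  This keeps the
bride side selective: families whose preferences match nobody's traits
draw no offers, so their daughters go unmarried even when men are
plentiful.  If a groom row's total weight has underflowed to zero the
offer falls back to a uniform choice over families.

All randomness is pre-drawn by the caller (one uniform per man), so the
compiled loop is a pure function.  ``match_loop_py`` is the plain-Python
twin kept as the readable reference; the numba version must agree with
it exactly and the test suite asserts that it does.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["match_loop", "match_loop_py", "consume_matches"]

_TINY = 1e-300


def _match_loop_impl(man_fams, u, W, women_avail):  # pragma: no cover - jit template
    n = W.shape[0]
    avail = women_avail.copy()
    totals = np.zeros(n)
    for g in range(n):
        s = 0.0
        for j in range(n):
            s += W[g, j]
        totals[g] = s
    n_women = 0
    for j in range(n):
        n_women += avail[j]
    m_max = man_fams.shape[0]
    grooms = np.empty(m_max, np.int64)
    brides = np.empty(m_max, np.int64)
    count = 0
    for m in range(m_max):
        if n_women == 0:
            break
        g = man_fams[m]
        tot = totals[g]
        if tot > _TINY:
            target = u[m] * tot
            acc = 0.0
            chosen = n - 1  # float round-off: the last family
            for j in range(n):
                acc += W[g, j]
                if acc >= target:
                    chosen = j
                    break
        else:
            chosen = int(u[m] * n)
            if chosen >= n:
                chosen = n - 1
        if avail[chosen] == 0:
            continue  # offer declined: no unmarried woman there
        avail[chosen] -= 1
        n_women -= 1
        grooms[count] = g
        brides[count] = chosen
        count += 1
    return grooms[:count], brides[:count]


match_loop = njit(cache=True)(_match_loop_impl)


@njit(cache=True)
def consume_matches(men: np.ndarray, women: np.ndarray,
                    grooms: np.ndarray, brides: np.ndarray) -> None:
    """Remove one man per groom and one woman per bride from the age
    cohorts, oldest first (marrying individuals leave their natal family)."""
    for m in range(grooms.shape[0]):
        i = grooms[m]
        for a in range(men.shape[1] - 1, -1, -1):
            if men[i, a] > 0:
                men[i, a] -= 1
                break
    for m in range(brides.shape[0]):
        i = brides[m]
        for a in range(women.shape[1] - 1, -1, -1):
            if women[i, a] > 0:
                women[i, a] -= 1
                break


def match_loop_py(
    man_fams: np.ndarray, u: np.ndarray, W: np.ndarray, women_avail: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pure-Python reference implementation of :func:`match_loop`."""
    return _match_loop_impl(
        np.asarray(man_fams, dtype=np.int64),
        np.asarray(u, dtype=float),
        np.asarray(W, dtype=float),
        np.asarray(women_avail, dtype=np.int64),
    )
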