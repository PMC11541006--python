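"""Numba-accelerated Gillespie kernel for the birth-death population model.

The kernel advances a population of cells, each carrying integer copy
numbers of two ecDNA species, through exact continuous-time birth-death
dynamics: every cell divides at rate ``lambda_base * (1 + s)`` (``s``
selected by which species are present) and dies at rate ``mu``.  Divisions
apply one of the three segregation rules from :mod:`ecdna.segregation`
(re-implemented here in nopython form; the pure-Python functions remain the
reference implementation and the two are cross-checked in the test suite).

The kernel is an implementation detail — use :func:`ecdna.simulate.simulate_population`.

Status codes: 0 reached target cell count, 1 reached target time,
2 extinct, 3 event-buffer overflow (caller retries with a larger buffer),
4 population exceeded the cell capacity before any stop condition.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# record levels
REC_NONE = 0
REC_TRAJ = 1
REC_FULL = 2

STATUS_TARGET_CELLS = 0
STATUS_TARGET_TIME = 1
STATUS_EXTINCT = 2
STATUS_EVENT_OVERFLOW = 3
STATUS_CAPACITY = 4


@njit(cache=True)
def _class_of(k1, k2):
    # 0: (-,-)  1: (-,+)  2: (+,-)  3: (+,+)
    c = 0
    if k1 > 0:
        c += 2
    if k2 > 0:
        c += 1
    return c


@njit(cache=True)
def _divide(N1, N2, gamma, phi, model):
    """Split doubled copies of a parent (N1, N2); returns daughter 1's share.

    Species 1 is the anchor throughout the kernel; callers wanting the other
    anchoring swap the species before and after.
    """
    if model == 0:  # element_level
        if N1 > 0:
            n11 = np.random.binomial(2 * N1, 0.5)
            scale = gamma * 2.0 * N2 / (2.0 * N1)
            c1 = int(np.floor(scale * n11 + 1e-9))
            c2 = int(np.floor(scale * (2 * N1 - n11) + 1e-9))
        else:
            n11 = 0
            c1 = 0
            c2 = 0
        rem = 2 * N2 - c1 - c2
        r1 = np.random.binomial(rem, 0.5) if rem > 0 else 0
        return n11, c1 + r1
    elif model == 1:  # cell_level
        b1 = np.random.binomial(2 * N1, 0.5) if N1 > 0 else 0
        b2 = np.random.binomial(2 * N2, 0.5) if N2 > 0 else 0
        hi1 = max(b1, 2 * N1 - b1)
        lo1 = 2 * N1 - hi1
        hi2 = max(b2, 2 * N2 - b2)
        lo2 = 2 * N2 - hi2
        if np.random.random() < gamma:
            dA1, dA2 = hi1, hi2
            dB1, dB2 = lo1, lo2
        else:
            dA1, dA2 = hi1, lo2
            dB1, dB2 = lo1, hi2
        if np.random.random() < 0.5:
            return dB1, dB2
        return dA1, dA2
    else:  # fraction_coupled
        c1 = int(np.rint(phi * 2 * N1))
        c2 = int(np.rint(phi * 2 * N2))
        if c1 > 0:
            x1 = np.random.binomial(c1, 0.5)
            ratio = x1 / c1
        else:
            x1 = 0
            ratio = np.random.random()
        x2 = int(np.rint(ratio * c2))
        rem1 = 2 * N1 - c1
        rem2 = 2 * N2 - c2
        d1 = x1 + (np.random.binomial(rem1, 0.5) if rem1 > 0 else 0)
        d2 = x2 + (np.random.binomial(rem2, 0.5) if rem2 > 0 else 0)
        if np.random.random() < 0.5:
            return 2 * N1 - d1, 2 * N2 - d2
        return d1, d2


@njit(cache=True)
def population_kernel(seed,
                      k1_0, k2_0, t0,
                      s_mm, s_mp, s_pm, s_pp, lam_base, mu,
                      gamma, phi, model,
                      target_cells, target_time,
                      max_cells, record, max_events):
    """Run the birth-death process; see module docstring for status codes."""
    np.random.seed(seed)

    n0 = k1_0.shape[0]
    k1 = np.zeros(max_cells, dtype=np.int64)
    k2 = np.zeros(max_cells, dtype=np.int64)
    ids = np.zeros(max_cells, dtype=np.int64)
    k1[:n0] = k1_0
    k2[:n0] = k2_0
    for i in range(n0):
        ids[i] = i
    next_id = n0
    n = n0

    lams = np.empty(4, dtype=np.float64)
    lams[0] = lam_base * (1.0 + s_mm)
    lams[1] = lam_base * (1.0 + s_mp)
    lams[2] = lam_base * (1.0 + s_pm)
    lams[3] = lam_base * (1.0 + s_pp)
    lam_max = lams.max()

    cls_counts = np.zeros(4, dtype=np.int64)
    sum1 = np.int64(0)
    sum2 = np.int64(0)
    for i in range(n):
        cls_counts[_class_of(k1[i], k2[i])] += 1
        sum1 += k1[i]
        sum2 += k2[i]

    # event log
    nrec = max_events if record > 0 else 1
    ev_time = np.empty(nrec, dtype=np.float64)
    ev_type = np.empty(nrec, dtype=np.int8)
    ev_n = np.empty(nrec, dtype=np.int64)
    ev_sum1 = np.empty(nrec, dtype=np.int64)
    ev_sum2 = np.empty(nrec, dtype=np.int64)
    nfull = max_events if record == REC_FULL else 1
    ev_parent = np.empty(nfull, dtype=np.int64)
    ev_d1 = np.empty(nfull, dtype=np.int64)
    ev_d2 = np.empty(nfull, dtype=np.int64)
    ev_d1k1 = np.empty(nfull, dtype=np.int64)
    ev_d1k2 = np.empty(nfull, dtype=np.int64)
    ev_d2k1 = np.empty(nfull, dtype=np.int64)
    ev_d2k2 = np.empty(nfull, dtype=np.int64)
    n_ev = 0

    t = t0
    status = STATUS_TARGET_TIME
    if target_cells > 0 and n >= target_cells:
        status = STATUS_TARGET_CELLS
        return (status, t, k1[:n].copy(), k2[:n].copy(), ids[:n].copy(), n_ev,
                ev_time, ev_type, ev_n, ev_sum1, ev_sum2,
                ev_parent, ev_d1, ev_d2, ev_d1k1, ev_d1k2, ev_d2k1, ev_d2k2)

    while True:
        if n == 0:
            status = STATUS_EXTINCT
            break
        B = (cls_counts[0] * lams[0] + cls_counts[1] * lams[1]
             + cls_counts[2] * lams[2] + cls_counts[3] * lams[3])
        total = B + mu * n
        t_next = t + np.random.exponential(1.0 / total)
        if t_next >= target_time:
            t = target_time
            status = STATUS_TARGET_TIME
            break
        t = t_next

        if record > 0 and n_ev >= max_events:
            status = STATUS_EVENT_OVERFLOW
            break

        if np.random.random() * total < mu * n:
            # death of a uniformly chosen cell
            i = np.random.randint(0, n)
            cls_counts[_class_of(k1[i], k2[i])] -= 1
            sum1 -= k1[i]
            sum2 -= k2[i]
            dying = ids[i]
            n -= 1
            k1[i] = k1[n]
            k2[i] = k2[n]
            ids[i] = ids[n]
            if record > 0:
                ev_time[n_ev] = t
                ev_type[n_ev] = 1
                ev_n[n_ev] = n
                ev_sum1[n_ev] = sum1
                ev_sum2[n_ev] = sum2
                if record == REC_FULL:
                    ev_parent[n_ev] = dying
                    ev_d1[n_ev] = -1
                    ev_d2[n_ev] = -1
                    ev_d1k1[n_ev] = 0
                    ev_d1k2[n_ev] = 0
                    ev_d2k1[n_ev] = 0
                    ev_d2k2[n_ev] = 0
                n_ev += 1
            continue

        # division: choose the dividing cell with probability proportional
        # to its birth rate (rejection against the maximal rate)
        while True:
            i = np.random.randint(0, n)
            if np.random.random() * lam_max < lams[_class_of(k1[i], k2[i])]:
                break
        if n >= max_cells:
            status = STATUS_CAPACITY
            break
        N1 = k1[i]
        N2 = k2[i]
        d1k1, d1k2 = _divide(N1, N2, gamma, phi, model)
        d2k1 = 2 * N1 - d1k1
        d2k2 = 2 * N2 - d1k2

        cls_counts[_class_of(N1, N2)] -= 1
        parent = ids[i]
        k1[i] = d1k1
        k2[i] = d1k2
        ids[i] = next_id
        k1[n] = d2k1
        k2[n] = d2k2
        ids[n] = next_id + 1
        cls_counts[_class_of(d1k1, d1k2)] += 1
        cls_counts[_class_of(d2k1, d2k2)] += 1
        sum1 += N1
        sum2 += N2
        n += 1
        if record > 0:
            ev_time[n_ev] = t
            ev_type[n_ev] = 0
            ev_n[n_ev] = n
            ev_sum1[n_ev] = sum1
            ev_sum2[n_ev] = sum2
            if record == REC_FULL:
                ev_parent[n_ev] = parent
                ev_d1[n_ev] = next_id
                ev_d2[n_ev] = next_id + 1
                ev_d1k1[n_ev] = d1k1
                ev_d1k2[n_ev] = d1k2
                ev_d2k1[n_ev] = d2k1
                ev_d2k2[n_ev] = d2k2
            n_ev += 1
        next_id += 2
        if target_cells > 0 and n >= target_cells:
            status = STATUS_TARGET_CELLS
            break

    return (status, t, k1[:n].copy(), k2[:n].copy(), ids[:n].copy(), n_ev,
            ev_time, ev_type, ev_n, ev_sum1, ev_sum2,
            ev_parent, ev_d1, ev_d2, ev_d1k1, ev_d1k2, ev_d2k1, ev_d2k2)
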