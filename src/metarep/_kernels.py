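"""Numba kernels for the lattice engine.

The lattice state lives in four parallel ``L x L`` arrays: the two enzyme
activities ``e1``, ``e2``, the replication rate ``k``, and ``conf``, an
``int8`` code per site (-1 empty, 0 non-enzymatic, 1 expressing e1,
2 expressing e2).  Every stochastic draw consumes the single per-run
``numpy.random.Generator``, in schedule order, so a run is bit-reproducible
given the seed and parameters.

These functions are the only implementation of the elementary events; the
Python-level per-site API in :mod:`metarep.lattice` calls the same jitted
helpers that the fused per-generation kernel uses.
"""

import numpy as np
from numba import njit

EMPTY = np.int8(-1)
CONF_NONE = np.int8(0)
CONF_E1 = np.int8(1)
CONF_E2 = np.int8(2)

@njit(cache=True)
def metabolic_supply(e1, e2, conf, i, j):
    """M = sqrt(A1 * A2): geometric mean of the two summed expressed
    activities over the 3x3 (n = 9) Moore neighbourhood of (i, j).

    A1 and A2 sum only the *expressed* activity of each occupant (the one
    matching its current conformation); either sum being zero starves the
    focal replicator (M = 0).
    """
    L = e1.shape[0]
    a1 = 0.0
    a2 = 0.0
    for di in range(-1, 2):
        ni = (i + di) % L
        for dj in range(-1, 2):
            nj = (j + dj) % L
            c = conf[ni, nj]
            if c == CONF_E1:
                a1 += e1[ni, nj]
            elif c == CONF_E2:
                a2 += e2[ni, nj]
    return np.sqrt(a1 * a2)


@njit(cache=True)
def draw_mutant(b, g, E_max, k_min, k_max, rng):
    """Uniform draw of (e1, e2, k) from below the trade-off surface by
    rejection from the bounding box [0, E_max]^2 x [k_min, k_max]."""
    while True:
        x = rng.random() * E_max
        y = rng.random() * E_max
        u = (x ** b + y ** b) ** (1.0 / b) / E_max
        if u > 1.0:
            continue
        if k_max == k_min:
            return x, y, k_min
        cap = k_min + (k_max - k_min) * (1.0 - u) ** (1.0 / g)
        kk = k_min + rng.random() * (k_max - k_min)
        if kk <= cap:
            return x, y, kk


@njit(cache=True)
def assign_conformation(x, y, rng):
    """Fold of a newly created sequence: uniform among nonzero activities."""
    if x > 0.0 and y > 0.0:
        if rng.random() < 0.5:
            return CONF_E1
        return CONF_E2
    if x > 0.0:
        return CONF_E1
    if y > 0.0:
        return CONF_E2
    return CONF_NONE


@njit(cache=True)
def lottery(e1, e2, k, conf, i, j, offsets, W_e, rng):
    """Replication lottery at empty site (i, j).

    Claimants are the occupants of the replication neighbourhood; claimant
    t wins with probability W_t / (W_e + sum_j W_j), where W_t = k_t * M_t
    with M_t computed in the claimant's own metabolic neighbourhood.
    Returns the winner's coordinates, or (-1, -1) if the site stays empty.
    """
    L = e1.shape[0]
    nofs = offsets.shape[0]
    w = np.empty(nofs)
    total = W_e
    for t in range(nofs):
        ni = (i + offsets[t, 0]) % L
        nj = (j + offsets[t, 1]) % L
        wt = 0.0
        if conf[ni, nj] >= 0:
            wt = k[ni, nj] * metabolic_supply(e1, e2, conf, ni, nj)
        w[t] = wt
        total += wt
    r = rng.random() * total
    acc = 0.0
    for t in range(nofs):
        acc += w[t]
        if r < acc:
            return (i + offsets[t, 0]) % L, (j + offsets[t, 1]) % L
    return -1, -1


@njit(cache=True)
def place_offspring(e1, e2, k, conf, wi, wj, i, j, p_m, b, g, E_max, k_min, k_max, rng):
    """Copy the winner's phenotype into the empty site; with probability
    p_m the copy is a fresh mutant draw.  Faithful copies inherit the
    parent's conformation; mutants fold anew."""
    if rng.random() < p_m:
        x, y, kk = draw_mutant(b, g, E_max, k_min, k_max, rng)
        e1[i, j] = x
        e2[i, j] = y
        k[i, j] = kk
        conf[i, j] = assign_conformation(x, y, rng)
    else:
        e1[i, j] = e1[wi, wj]
        e2[i, j] = e2[wi, wj]
        k[i, j] = k[wi, wj]
        conf[i, j] = conf[wi, wj]


@njit(cache=True)
def diffusion_event(e1, e2, k, conf, offsets, occupied_only, rng):
    """One site-swap: a uniform site, a uniform neighbour, contents
    exchanged.  With ``occupied_only`` the swap is skipped unless both
    sites hold replicators."""
    L = e1.shape[0]
    i = rng.integers(0, L)
    j = rng.integers(0, L)
    t = rng.integers(0, offsets.shape[0])
    ni = (i + offsets[t, 0]) % L
    nj = (j + offsets[t, 1]) % L
    if occupied_only and (conf[i, j] < 0 or conf[ni, nj] < 0):
        return
    tmp = e1[i, j]
    e1[i, j] = e1[ni, nj]
    e1[ni, nj] = tmp
    tmp = e2[i, j]
    e2[i, j] = e2[ni, nj]
    e2[ni, nj] = tmp
    tmp = k[i, j]
    k[i, j] = k[ni, nj]
    k[ni, nj] = tmp
    tmpc = conf[i, j]
    conf[i, j] = conf[ni, nj]
    conf[ni, nj] = tmpc


@njit(cache=True)
def conformation_sweep(e1, e2, conf, rng):
    """Between-generation conformation update of every occupant: toggle
    with probability 1 - s, only towards a state with positive activity."""
    L = conf.shape[0]
    for i in range(L):
        for j in range(L):
            c = conf[i, j]
            if c == CONF_E1 or c == CONF_E2:
                tot = e1[i, j] + e2[i, j]
                s = abs(e1[i, j] - e2[i, j]) / tot
                if rng.random() < 1.0 - s:
                    if c == CONF_E1 and e2[i, j] > 0.0:
                        conf[i, j] = CONF_E2
                    elif c == CONF_E2 and e1[i, j] > 0.0:
                        conf[i, j] = CONF_E1


@njit(cache=True)
def generation(
    e1, e2, k, conf,
    rep_offsets, diff_offsets,
    p_d, p_m, n_diff,
    b, g, E_max, k_min, k_max, W_e,
    occupied_only, rng,
):
    """One generation: L^2 elementary site updates and ``n_diff`` diffusion
    events, randomly interleaved (exact counts, uniform order), followed by
    the conformation sweep."""
    L = e1.shape[0]
    rem_s = L * L
    rem_d = n_diff
    while rem_s + rem_d > 0:
        if rem_d == 0:
            site_update = True
        elif rem_s == 0:
            site_update = False
        else:
            site_update = rng.random() * (rem_s + rem_d) < rem_s
        if site_update:
            rem_s -= 1
            i = rng.integers(0, L)
            j = rng.integers(0, L)
            if conf[i, j] >= 0:
                if rng.random() < p_d:
                    conf[i, j] = EMPTY
            else:
                wi, wj = lottery(e1, e2, k, conf, i, j, rep_offsets, W_e, rng)
                if wi >= 0:
                    place_offspring(
                        e1, e2, k, conf, wi, wj, i, j,
                        p_m, b, g, E_max, k_min, k_max, rng,
                    )
        else:
            rem_d -= 1
            diffusion_event(e1, e2, k, conf, diff_offsets, occupied_only, rng)
    conformation_sweep(e1, e2, conf, rng)


@njit(cache=True)
def fill_random_phenotypes(e1, e2, k, conf, rows, cols, b, g, E_max, k_min, k_max, rng):
    """Populate the listed sites with independent uniform feasible draws."""
    for t in range(rows.size):
        x, y, kk = draw_mutant(b, g, E_max, k_min, k_max, rng)
        i = rows[t]
        j = cols[t]
        e1[i, j] = x
        e2[i, j] = y
        k[i, j] = kk
        conf[i, j] = assign_conformation(x, y, rng)
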