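"""Numba-compiled batch assembly kernel.

The kernel mirrors the reference implementation in :mod:`polyevo.assembly`
(single categorical draw per binding step, weight ``multiplicity * S**T``)
on flat arrays, so that population-scale evolutionary runs and large
Monte Carlo oracles stay cheap.  Canonical polyomino forms computed here are
cross-checked against the pure-Python canonicalizer in the test suite.

Cell encoding: a canonical cell is packed as ``((x * stride) + y) * 8 + t``
with ``t`` the (canonically permuted) tile type, so lexicographic order of
encoded values equals lexicographic order of ``(x, y, t)`` triples.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_DX = np.array([0, 1, 0, -1], dtype=np.int64)
_DY = np.array([1, 0, -1, 0], dtype=np.int64)

FNV_OFFSET = np.uint64(0xCBF29CE484222325)
FNV_PRIME = np.uint64(0x100000001B3)


@njit(cache=True)
def _canonical_encode(xs, ys, ts, n, stride, perms, wv, best):
    """Canonical colored-polyomino encoding into best[:n].

    Minimises the sorted encoded cell list lexicographically over the 8
    rotations/reflections and all tile-type permutations in ``perms``.
    """
    have_best = False
    n_perms = perms.shape[0]
    for refl in range(2):
        for rot in range(4):
            for pi in range(n_perms):
                minx = np.int64(1 << 40)
                miny = np.int64(1 << 40)
                for i in range(n):
                    x = xs[i]
                    y = ys[i]
                    if refl == 1:
                        x = -x
                    for _ in range(rot):
                        x, y = y, -x
                    if x < minx:
                        minx = x
                    if y < miny:
                        miny = y
                for i in range(n):
                    x = xs[i]
                    y = ys[i]
                    if refl == 1:
                        x = -x
                    for _ in range(rot):
                        x, y = y, -x
                    wv[i] = ((x - minx) * stride + (y - miny)) * 8 + perms[pi, ts[i]]
                # insertion sort (n is small)
                for i in range(1, n):
                    key = wv[i]
                    j = i - 1
                    while j >= 0 and wv[j] > key:
                        wv[j + 1] = wv[j]
                        j -= 1
                    wv[j + 1] = key
                if not have_best:
                    for i in range(n):
                        best[i] = wv[i]
                    have_best = True
                else:
                    for i in range(n):
                        if wv[i] < best[i]:
                            for m in range(n):
                                best[m] = wv[m]
                            break
                        elif wv[i] > best[i]:
                            break


@njit(cache=True)
def _hash_cells(best, n):
    h = FNV_OFFSET
    h = (h ^ np.uint64(n)) * FNV_PRIME
    for i in range(n):
        h = (h ^ np.uint64(best[i])) * FNV_PRIME
    return np.int64(h >> np.uint64(1))


@njit(cache=True)
def assemble_batch_kernel(
    site_off,       # (n_types*4 + 1,) int64 CSR offsets into partner arrays
    p_type,         # partner tile type per directed partner entry
    p_face,         # partner face per entry
    p_weight,       # binding weight S**T per entry (0 entries must be pruned)
    seeds,          # (k,) int64 seed tile type per repeat
    perms,          # (n_perms, n_types) int64 tile-relabeling group
    size_cap,       # int64
    rng_seed,       # int64
    sizes_out,      # (k,) int64; -1 marks unbound growth
    hashes_out,     # (k,) int64 canonical-phenotype hash
    cells_out,      # (k, size_cap + 1) int64 canonical encoded cells
):
    np.random.seed(rng_seed)
    side = 2 * size_cap + 3
    stride = np.int64(side)
    grid = np.full((side, side), -1, dtype=np.int64)
    cap = size_cap
    tx = np.empty(cap + 1, dtype=np.int64)
    ty = np.empty(cap + 1, dtype=np.int64)
    ttype = np.empty(cap + 1, dtype=np.int64)
    trot = np.empty(cap + 1, dtype=np.int64)
    max_p = 0
    n_sites = site_off.shape[0] - 1
    for s in range(n_sites):
        c = site_off[s + 1] - site_off[s]
        if c > max_p:
            max_p = c
    amax = (cap + 1) * 4 * max_p + 1
    ax = np.empty(amax, dtype=np.int64)
    ay = np.empty(amax, dtype=np.int64)
    at = np.empty(amax, dtype=np.int64)
    ar = np.empty(amax, dtype=np.int64)
    aw = np.empty(amax, dtype=np.float64)
    wv = np.empty(cap + 1, dtype=np.int64)
    best = np.empty(cap + 1, dtype=np.int64)

    for rep in range(seeds.shape[0]):
        c0 = np.int64(size_cap + 1)
        tx[0] = c0
        ty[0] = c0
        ttype[0] = seeds[rep]
        trot[0] = 0
        grid[c0, c0] = 0
        n = 1
        unbound = False
        while True:
            na = 0
            for i in range(n):
                for d in range(4):
                    nx = tx[i] + _DX[d]
                    ny = ty[i] + _DY[d]
                    if grid[nx, ny] != -1:
                        continue
                    f = (d - trot[i]) % 4
                    site = ttype[i] * 4 + f
                    for j in range(site_off[site], site_off[site + 1]):
                        ax[na] = nx
                        ay[na] = ny
                        at[na] = p_type[j]
                        ar[na] = (d + 2 - p_face[j]) % 4
                        aw[na] = p_weight[j]
                        na += 1
            if na == 0:
                break
            if n >= cap:
                unbound = True
                break
            tot = 0.0
            for j in range(na):
                tot += aw[j]
            r = np.random.random() * tot
            pick = na - 1
            acc = 0.0
            for j in range(na):
                acc += aw[j]
                if r < acc:
                    pick = j
                    break
            tx[n] = ax[pick]
            ty[n] = ay[pick]
            ttype[n] = at[pick]
            trot[n] = ar[pick]
            grid[ax[pick], ay[pick]] = n
            n += 1
        if unbound:
            sizes_out[rep] = -1
            hashes_out[rep] = -1
        else:
            # translate to the seed cell to keep coordinates small
            for i in range(n):
                tx[i] -= c0
                ty[i] -= c0
            _canonical_encode(tx, ty, ttype, n, stride, perms, wv, best)
            sizes_out[rep] = n
            hashes_out[rep] = _hash_cells(best, n)
            for i in range(n):
                cells_out[rep, i] = best[i]
            for i in range(n):
                tx[i] += c0
                ty[i] += c0
        # reset touched grid cells
        for i in range(n):
            grid[tx[i], ty[i]] = -1


def graph_to_kernel_arrays(graph, params):
    """CSR directed-partner arrays for the kernel from an AssemblyGraph.

    Edges below the critical strength (possible after ``with_strengths``)
    carry zero binding probability and are dropped.
    """
    n_sites = graph.n_tiles * 4
    partners: list[list[tuple[int, int, float]]] = [[] for _ in range(n_sites)]
    for u, v, s in graph.edges:
        if s < params.S_c - 1e-9:
            continue
        w = float(s) ** params.T
        partners[u.flat].append((v.tile, int(v.face), w))
        if v.flat != u.flat:
            partners[v.flat].append((u.tile, int(u.face), w))
    site_off = np.zeros(n_sites + 1, dtype=np.int64)
    for i, p in enumerate(partners):
        site_off[i + 1] = site_off[i] + len(p)
    total = int(site_off[-1])
    p_type = np.empty(total, dtype=np.int64)
    p_face = np.empty(total, dtype=np.int64)
    p_weight = np.empty(total, dtype=np.float64)
    k = 0
    for p in partners:
        for t, f, w in p:
            p_type[k] = t
            p_face[k] = f
            p_weight[k] = w
            k += 1
    return site_off, p_type, p_face, p_weight


def _perm_array(n_types: int) -> np.ndarray:
    import itertools

    return np.array(list(itertools.permutations(range(n_types))), dtype=np.int64)


def assemble_batch(graph, params, seeds, size_cap, rng_seed):
    """Run ``len(seeds)`` assemblies; returns (sizes, hashes, encoded cells, stride).

    sizes of -1 mark unbound growth.  Encoded cells pack canonical coloured
    cells as ``((x * stride) + y) * 8 + t``.
    """
    site_off, p_type, p_face, p_weight = graph_to_kernel_arrays(graph, params)
    seeds = np.asarray(seeds, dtype=np.int64)
    perms = _perm_array(graph.n_tiles)
    k = seeds.shape[0]
    sizes = np.empty(k, dtype=np.int64)
    hashes = np.empty(k, dtype=np.int64)
    cells = np.zeros((k, size_cap + 1), dtype=np.int64)
    assemble_batch_kernel(site_off, p_type, p_face, p_weight, seeds, perms,
                          np.int64(size_cap), np.int64(rng_seed),
                          sizes, hashes, cells)
    return sizes, hashes, cells, 2 * size_cap + 3
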