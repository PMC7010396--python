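"""Numba kernels for the anisotropic eikonal solver.

The discrete operator is a semi-Lagrangian (Tsitsiklis-type) update on a
radius-1 stencil: the 26 cube neighbors of a node are triangulated into 48
tetrahedra (6 spherical triangles per octant), and the arrival value at the
node is the minimum over tetrahedra of

    min_{lambda in simplex}  sum_k lambda_k W_k + || sum_k lambda_k v_k ||_M

with linear interpolation of W on the triangle and the local Riemannian
metric M = C^2 M0.  The interior minimizer has the closed form
``W = c`` with ``a c^2 - 2 b c + (d - 1) = 0``,
``a = 1^T G^-1 1, b = 1^T G^-1 u, d = u^T G^-1 u``, ``G_kl = v_k^T M v_l``;
faces/edges of the simplex are handled by the same formula in lower
dimension.  Because the stencil's tetrahedra cover every direction, the
scheme is monotone and consistent for arbitrary (anisotropic) metrics; a
causal fast-marching pass gives a near-fixed-point solution and
Gauss-Seidel sweeps polish it to the fixed point.
"""

import numpy as np
from numba import njit

BIG = 1e30


def build_stencil():
    """Offsets (26, 3), tetrahedra (48, 3) as offset indices, and for each
    offset the list of tetrahedra that contain it (padded with -1)."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dt in (-1, 0, 1):
                if (dx, dy, dt) != (0, 0, 0):
                    offsets.append((dx, dy, dt))
    offsets = np.array(offsets, dtype=np.int64)
    index = {tuple(o): i for i, o in enumerate(offsets)}
    tets = []
    for sx in (-1, 1):
        for sy in (-1, 1):
            for st in (-1, 1):
                a1, a2, a3 = (sx, 0, 0), (0, sy, 0), (0, 0, st)
                e12, e13, e23 = (sx, sy, 0), (sx, 0, st), (0, sy, st)
                c = (sx, sy, st)
                for tri in [(a1, e12, c), (e12, a2, c), (a2, e23, c),
                            (e23, a3, c), (a3, e13, c), (e13, a1, c)]:
                    tets.append([index[v] for v in tri])
    tets = np.array(tets, dtype=np.int64)
    tets_of_offset = np.full((len(offsets), 8), -1, dtype=np.int64)
    for oi in range(len(offsets)):
        hits = [ti for ti in range(len(tets)) if oi in tets[ti]]
        tets_of_offset[oi, : len(hits)] = hits
    neg_index = np.array(
        [index[tuple(-o)] for o in offsets], dtype=np.int64
    )
    return offsets, tets, tets_of_offset, neg_index


@njit(cache=True, inline="always")
def _flat(ix, iy, it, nx, ny, nt):
    return (ix * ny + iy) * nt + it


@njit(cache=True, inline="always")
def _neighbor(ix, iy, it, dx, dy, dt, nx, ny, nt):
    jx = ix + dx
    if jx < 0 or jx >= nx:
        return -1
    jy = iy + dy
    if jy < 0:
        jy += ny
    elif jy >= ny:
        jy -= ny
    jt = it + dt
    if jt < 0:
        jt += nt
    elif jt >= nt:
        jt -= nt
    return (jx * ny + jy) * nt + jt


@njit(cache=True)
def _tet_solve(g11, g12, g13, g22, g23, g33, u1, u2, u3):
    """Min over the 2-simplex of lambda.u + sqrt(lambda^T G lambda)."""
    best = BIG
    # vertices
    if u1 < BIG and g11 > 0.0:
        v = u1 + np.sqrt(g11)
        if v < best:
            best = v
    if u2 < BIG and g22 > 0.0:
        v = u2 + np.sqrt(g22)
        if v < best:
            best = v
    if u3 < BIG and g33 > 0.0:
        v = u3 + np.sqrt(g33)
        if v < best:
            best = v
    # edges
    best = _edge_solve(g11, g12, g22, u1, u2, best)
    best = _edge_solve(g11, g13, g33, u1, u3, best)
    best = _edge_solve(g22, g23, g33, u2, u3, best)
    # interior
    if u1 < BIG and u2 < BIG and u3 < BIG:
        det = (
            g11 * (g22 * g33 - g23 * g23)
            - g12 * (g12 * g33 - g23 * g13)
            + g13 * (g12 * g23 - g22 * g13)
        )
        if det > 1e-300:
            i11 = (g22 * g33 - g23 * g23) / det
            i12 = (g13 * g23 - g12 * g33) / det
            i13 = (g12 * g23 - g13 * g22) / det
            i22 = (g11 * g33 - g13 * g13) / det
            i23 = (g12 * g13 - g11 * g23) / det
            i33 = (g11 * g22 - g12 * g12) / det
            r1 = i11 + i12 + i13
            r2 = i12 + i22 + i23
            r3 = i13 + i23 + i33
            a = r1 + r2 + r3
            b = r1 * u1 + r2 * u2 + r3 * u3
            d = (
                u1 * (i11 * u1 + i12 * u2 + i13 * u3)
                + u2 * (i12 * u1 + i22 * u2 + i23 * u3)
                + u3 * (i13 * u1 + i23 * u2 + i33 * u3)
            )
            if a > 0.0:
                disc = b * b - a * (d - 1.0)
                if disc >= 0.0:
                    c = (b + np.sqrt(disc)) / a
                    if c < best:
                        # lambda = L * Ginv (c 1 - u), L > 0
                        l1 = i11 * (c - u1) + i12 * (c - u2) + i13 * (c - u3)
                        l2 = i12 * (c - u1) + i22 * (c - u2) + i23 * (c - u3)
                        l3 = i13 * (c - u1) + i23 * (c - u2) + i33 * (c - u3)
                        if l1 >= -1e-12 and l2 >= -1e-12 and l3 >= -1e-12:
                            best = c
    return best


@njit(cache=True, inline="always")
def _edge_solve(gaa, gab, gbb, ua, ub, best):
    if ua >= BIG or ub >= BIG:
        return best
    det = gaa * gbb - gab * gab
    if det <= 1e-300:
        return best
    i11 = gbb / det
    i12 = -gab / det
    i22 = gaa / det
    r1 = i11 + i12
    r2 = i12 + i22
    a = r1 + r2
    b = r1 * ua + r2 * ub
    d = ua * (i11 * ua + i12 * ub) + ub * (i12 * ua + i22 * ub)
    if a <= 0.0:
        return best
    disc = b * b - a * (d - 1.0)
    if disc < 0.0:
        return best
    c = (b + np.sqrt(disc)) / a
    if c < best:
        l1 = i11 * (c - ua) + i12 * (c - ub)
        l2 = i12 * (c - ua) + i22 * (c - ub)
        if l1 >= -1e-12 and l2 >= -1e-12:
            return c
    return best


@njit(cache=True)
def _node_update_tets(W, node, tet_list, n_tets, offsets, tets, G0, C2,
                      nx, ny, nt):
    """Best candidate value for `node` over the given tetrahedron ids."""
    it = node % nt
    iy = (node // nt) % ny
    ix = node // (nt * ny)
    c2 = C2[node]
    cost = np.sqrt(c2)
    best = BIG
    for k in range(n_tets):
        ti = tet_list[k]
        if ti < 0:
            break
        o1 = tets[ti, 0]
        o2 = tets[ti, 1]
        o3 = tets[ti, 2]
        n1 = _neighbor(ix, iy, it, offsets[o1, 0], offsets[o1, 1], offsets[o1, 2], nx, ny, nt)
        n2 = _neighbor(ix, iy, it, offsets[o2, 0], offsets[o2, 1], offsets[o2, 2], nx, ny, nt)
        n3 = _neighbor(ix, iy, it, offsets[o3, 0], offsets[o3, 1], offsets[o3, 2], nx, ny, nt)
        u1 = W[n1] if n1 >= 0 else BIG
        u2 = W[n2] if n2 >= 0 else BIG
        u3 = W[n3] if n3 >= 0 else BIG
        if u1 >= BIG and u2 >= BIG and u3 >= BIG:
            continue
        base = (ix * nt + it) * tets.shape[0] + ti
        g11 = G0[base, 0] * c2
        g12 = G0[base, 1] * c2
        g13 = G0[base, 2] * c2
        g22 = G0[base, 3] * c2
        g23 = G0[base, 4] * c2
        g33 = G0[base, 5] * c2
        v = _tet_solve(g11, g12, g13, g22, g23, g33, u1, u2, u3)
        if v < best:
            best = v
    return best


# ---------------------------------------------------------------------------
# binary heap (min-heap with lazy deletion)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _heap_push(hv, hi, size, val, idx):
    i = size
    hv[i] = val
    hi[i] = idx
    while i > 0:
        p = (i - 1) // 2
        if hv[p] <= hv[i]:
            break
        hv[p], hv[i] = hv[i], hv[p]
        hi[p], hi[i] = hi[i], hi[p]
        i = p
    return size + 1


@njit(cache=True, inline="always")
def _heap_pop(hv, hi, size):
    val = hv[0]
    idx = hi[0]
    size -= 1
    hv[0] = hv[size]
    hi[0] = hi[size]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        m = i
        if l < size and hv[l] < hv[m]:
            m = l
        if r < size and hv[r] < hv[m]:
            m = r
        if m == i:
            break
        hv[m], hv[i] = hv[i], hv[m]
        hi[m], hi[i] = hi[i], hi[m]
        i = m
    return val, idx, size


@njit(cache=True)
def fast_march(W, C2, G0, offsets, tets, tets_of_offset, neg_index,
               seed_flat, nx, ny, nt, target_flat=-1):
    """Single-pass causal fast marching from the seed node (W preset to BIG,
    seed shell preinitialized by the caller with finite values).  If
    ``target_flat`` >= 0, stops once that node freezes."""
    n = nx * ny * nt
    state = np.zeros(n, dtype=np.uint8)  # 0 far, 2 frozen
    cap = 4 * n + 64
    hv = np.empty(cap, dtype=np.float64)
    hi = np.empty(cap, dtype=np.int64)
    size = 0
    state[seed_flat] = 2
    for i in range(n):
        if W[i] < BIG and i != seed_flat:
            size = _heap_push(hv, hi, size, W[i], i)
    n_tets_per_offset = tets_of_offset.shape[1]
    while size > 0:
        val, node, size = _heap_pop(hv, hi, size)
        if state[node] == 2 or val > W[node] + 1e-12:
            continue
        state[node] = 2
        if node == target_flat:
            break
        it = node % nt
        iy = (node // nt) % ny
        ix = node // (nt * ny)
        for oi in range(offsets.shape[0]):
            nb = _neighbor(ix, iy, it, offsets[oi, 0], offsets[oi, 1],
                           offsets[oi, 2], nx, ny, nt)
            if nb < 0 or state[nb] == 2:
                continue
            rel = neg_index[oi]  # offset of `node` as seen from `nb`
            cand = _node_update_tets(W, nb, tets_of_offset[rel],
                                     n_tets_per_offset, offsets, tets,
                                     G0, C2, nx, ny, nt)
            if cand < W[nb] - 1e-13:
                W[nb] = cand
                if size >= cap - 1:
                    # heap full: compact by dropping stale entries
                    newsize = 0
                    for k in range(size):
                        if state[hi[k]] != 2 and hv[k] <= W[hi[k]] + 1e-12:
                            hv[newsize] = hv[k]
                            hi[newsize] = hi[k]
                            newsize += 1
                    # re-heapify
                    for k in range(1, newsize):
                        v2 = hv[k]
                        i2 = hi[k]
                        j = k
                        while j > 0:
                            p = (j - 1) // 2
                            if hv[p] <= v2:
                                break
                            hv[j] = hv[p]
                            hi[j] = hi[p]
                            j = p
                        hv[j] = v2
                        hi[j] = i2
                    size = newsize
                size = _heap_push(hv, hi, size, cand, nb)


@njit(cache=True)
def label_correct(W, C2, G0, offsets, tets, seed_flat, order, nx, ny, nt, tol):
    """FIFO label-correcting relaxation to the fixed point of the scheme.

    ``order`` is the initial processing order (ideally W-ascending, so the
    first pass is nearly causal).  Returns the number of node relaxations."""
    n = nx * ny * nt
    all_tets = np.arange(tets.shape[0]).astype(np.int64)
    cap = n + 64  # the in_queue flags bound occupancy by n
    queue = np.empty(cap, dtype=np.int64)
    in_queue = np.zeros(n, dtype=np.uint8)
    head = 0
    tail = 0
    for k in range(len(order)):
        node = order[k]
        if node != seed_flat:
            queue[tail] = node
            tail += 1
            in_queue[node] = 1
    count = 0
    while head != tail:
        node = queue[head]
        head += 1
        if head == cap:
            head = 0
        in_queue[node] = 0
        cand = _node_update_tets(W, node, all_tets, tets.shape[0], offsets,
                                 tets, G0, C2, nx, ny, nt)
        count += 1
        if cand < W[node] - tol:
            W[node] = cand
            it = node % nt
            iy = (node // nt) % ny
            ix = node // (nt * ny)
            for oi in range(offsets.shape[0]):
                nb = _neighbor(ix, iy, it, offsets[oi, 0], offsets[oi, 1],
                               offsets[oi, 2], nx, ny, nt)
                if nb < 0 or nb == seed_flat or in_queue[nb] == 1:
                    continue
                queue[tail] = nb
                tail += 1
                if tail == cap:
                    tail = 0
                in_queue[nb] = 1
    return count


@njit(cache=True)
def gauss_seidel_sweeps(W, C2, G0, offsets, tets, seed_flat, nx, ny, nt,
                        max_sweeps, tol):
    """Alternating-ordering Gauss-Seidel iteration of the same operator.

    Returns the number of full sweeps performed (8 orderings each)."""
    all_tets = np.arange(tets.shape[0]).astype(np.int64)
    sweeps = 0
    for sweep in range(max_sweeps):
        maxchange = 0.0
        for order in range(8):
            sx = 1 if order & 1 else -1
            sy = 1 if order & 2 else -1
            st = 1 if order & 4 else -1
            for ix0 in range(nx):
                ix = ix0 if sx > 0 else nx - 1 - ix0
                for iy0 in range(ny):
                    iy = iy0 if sy > 0 else ny - 1 - iy0
                    for it0 in range(nt):
                        it = it0 if st > 0 else nt - 1 - it0
                        node = (ix * ny + iy) * nt + it
                        if node == seed_flat:
                            continue
                        cand = _node_update_tets(
                            W, node, all_tets, tets.shape[0], offsets, tets,
                            G0, C2, nx, ny, nt,
                        )
                        if cand < W[node]:
                            ch = W[node] - cand
                            if ch < BIG / 2 and ch > maxchange:
                                maxchange = ch
                            elif ch >= BIG / 2:
                                maxchange = max(maxchange, 1.0)
                            W[node] = cand
        sweeps += 1
        if maxchange < tol:
            break
    return sweeps
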