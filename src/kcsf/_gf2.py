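"""Sparse XOR-system solver: hypergraph peeling + packed Gauss-Jordan.

The system is given in CSR form: equation e owns the (distinct)
variables ``vars_flat[eq_ptr[e]:eq_ptr[e+1]]`` and right-hand bit
``rhs[e]``.  Degree-1 variables are peeled with the classic
degree/XOR-accumulator trick in O(total arity); the unpeelable 2-core is
renumbered and solved by dense Gauss-Jordan on a bit-packed matrix.
Compiled with numba: chunk sizes upstream are chosen so the dense step
stays a few hundred thousand word operations.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def solve_xor_csr(vars_flat, eq_ptr, rhs, n_vars):  # pragma: no cover - jitted
    """Return (ok, x): ok=False when inconsistent, else x satisfies all."""
    one = np.uint64(1)
    n_eq = rhs.shape[0]
    x = np.zeros(n_vars, np.uint8)
    if n_eq == 0:
        return True, x

    deg = np.zeros(n_vars, np.int64)
    xeq = np.zeros(n_vars, np.int64)
    for e in range(n_eq):
        for i in range(eq_ptr[e], eq_ptr[e + 1]):
            v = vars_flat[i]
            deg[v] += 1
            xeq[v] ^= e

    alive = np.ones(n_eq, np.uint8)
    stack = np.empty(n_vars, np.int64)
    top = 0
    for v in range(n_vars):
        if deg[v] == 1:
            stack[top] = v
            top += 1
    peel_eq = np.empty(n_eq, np.int64)
    peel_var = np.empty(n_eq, np.int64)
    npeel = 0
    while top > 0:
        top -= 1
        v = stack[top]
        if deg[v] != 1:
            continue
        e = xeq[v]  # the single alive equation containing v
        alive[e] = 0
        peel_eq[npeel] = e
        peel_var[npeel] = v
        npeel += 1
        for i in range(eq_ptr[e], eq_ptr[e + 1]):
            u = vars_flat[i]
            deg[u] -= 1
            xeq[u] ^= e
            if deg[u] == 1:
                stack[top] = u
                top += 1

    nce = 0
    for e in range(n_eq):
        if alive[e]:
            nce += 1
    if nce > 0:
        # renumber core variables densely
        var_map = np.full(n_vars, -1, np.int64)
        core_rows = np.empty(nce, np.int64)
        ncv = 0
        r = 0
        for e in range(n_eq):
            if alive[e]:
                core_rows[r] = e
                r += 1
                for i in range(eq_ptr[e], eq_ptr[e + 1]):
                    v = vars_flat[i]
                    if var_map[v] < 0:
                        var_map[v] = ncv
                        ncv += 1
        words = (ncv + 1 + 63) // 64  # +1 column for the RHS
        M = np.zeros((nce, words), np.uint64)
        for r in range(nce):
            e = core_rows[r]
            for i in range(eq_ptr[e], eq_ptr[e + 1]):
                c = var_map[vars_flat[i]]
                M[r, c >> 6] ^= one << np.uint64(c & 63)
            if rhs[e] == 1:
                M[r, ncv >> 6] ^= one << np.uint64(ncv & 63)

        pivot_col = np.full(nce, -1, np.int64)
        rr = 0
        for col in range(ncv):
            w = col >> 6
            b = np.uint64(col & 63)
            piv = -1
            for row in range(rr, nce):
                if (M[row, w] >> b) & one:
                    piv = row
                    break
            if piv < 0:
                continue
            if piv != rr:
                for t in range(words):
                    tmp = M[rr, t]
                    M[rr, t] = M[piv, t]
                    M[piv, t] = tmp
            for row in range(nce):
                if row != rr and ((M[row, w] >> b) & one):
                    for t in range(words):
                        M[row, t] ^= M[rr, t]
            pivot_col[rr] = col
            rr += 1
            if rr == nce:
                break
        rw = ncv >> 6
        rb = np.uint64(ncv & 63)
        for row in range(rr, nce):
            if (M[row, rw] >> rb) & one:
                return False, x  # 0 = 1 row: inconsistent core
        inv_map = np.empty(ncv, np.int64)
        for v in range(n_vars):
            if var_map[v] >= 0:
                inv_map[var_map[v]] = v
        for row in range(rr):
            if (M[row, rw] >> rb) & one:
                x[inv_map[pivot_col[row]]] = 1

    # back-substitute peeled equations, most recent first; each pivot
    # variable occurs in no equation peeled after it, so values are final
    for t in range(npeel - 1, -1, -1):
        e = peel_eq[t]
        v = peel_var[t]
        acc = rhs[e]
        for i in range(eq_ptr[e], eq_ptr[e + 1]):
            u = vars_flat[i]
            if u != v:
                acc ^= x[u]
        x[v] = acc
    return True, x
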