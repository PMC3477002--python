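"""Numba kernels: all-pairs dissimilarities over a CSR-encoded sequence pool.

Rows are sparse frequency vectors sharing an implicit dimension ``dim``;
``zerov[i]`` is row ``i``'s value at every coordinate outside its stored
support (0 unsmoothed, ``1/(total_i + dim)`` smoothed).  Each pair is a
single merge over the two sorted supports plus a closed-form term for the
coordinates stored in neither row, so cost is O(nnz_i + nnz_j) per pair
regardless of ``dim``.

Measure codes: 0 = 1-norm, 1 = 2-norm, 2 = ∞-norm, 3 = KL divergence
(asymmetric; row index i of the output is the query).
"""

from __future__ import annotations

import numpy as np
from numba import njit

KIND_L1 = 0
KIND_L2 = 1
KIND_LINF = 2
KIND_KL = 3


@njit(cache=True)
def _pair(indices, data, a, aend, b, bend, zx, zy, dim, kind):
    acc = 0.0
    mx = 0.0
    u = 0
    while a < aend or b < bend:
        if b >= bend or (a < aend and indices[a] < indices[b]):
            xv, yv = data[a], zy
            a += 1
        elif a >= aend or indices[b] < indices[a]:
            xv, yv = zx, data[b]
            b += 1
        else:
            xv, yv = data[a], data[b]
            a += 1
            b += 1
        u += 1
        if kind == 0:
            acc += abs(xv - yv)
        elif kind == 1:
            acc += (xv - yv) * (xv - yv)
        elif kind == 2:
            d = abs(xv - yv)
            if d > mx:
                mx = d
        else:
            if xv > 0.0:
                acc += xv * np.log(xv / yv)
    rest = dim - u
    if rest > 0:
        if kind == 0:
            acc += rest * abs(zx - zy)
        elif kind == 1:
            acc += rest * (zx - zy) * (zx - zy)
        elif kind == 2:
            d = abs(zx - zy)
            if d > mx:
                mx = d
        else:
            if zx > 0.0:
                acc += rest * zx * np.log(zx / zy)
    if kind == 1:
        return np.sqrt(acc)
    if kind == 2:
        return mx
    return acc


@njit(cache=True)
def pairwise_matrix(indptr, indices, data, zerov, dim, kind):
    """Dense m×m dissimilarity matrix; diagonal is 0 by construction."""
    m = indptr.shape[0] - 1
    out = np.zeros((m, m))
    symmetric = kind != KIND_KL
    for i in range(m):
        start = i + 1 if symmetric else 0
        for j in range(start, m):
            if i == j:
                continue
            d = _pair(
                indices, data,
                indptr[i], indptr[i + 1],
                indptr[j], indptr[j + 1],
                zerov[i], zerov[j], dim, kind,
            )
            out[i, j] = d
            if symmetric:
                out[j, i] = d
    return out
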