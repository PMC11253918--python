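"""Numba kernel for the factored forward-backward E-step.

The state spaces of single peptides are small (tens of states) but the
E-step applies ~40 sparse factor matrices per read per EM iteration,
which in pure numpy is dominated by many tiny matrix products.  This
kernel runs the scaled forward pass, the backward pass and the
per-parameter statistic accumulation in one serial sweep per read over
padded sparse factor structures.  It is numerically equivalent to the
numpy implementation in :mod:`fluorfit.fit_bw` (asserted in the test
suite); only the summation order differs at float rounding level.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["estep_kernel", "pack_factors"]


def pack_factors(mats_list, xmats_list, nvecs_list):
    """Pad per-slot sparse structures into rectangular arrays.

    ``mats_list`` are the dense row-stochastic factor matrices in slot
    order; ``xmats_list`` the per-slot transition-statistic matrices
    (same sparsity or subset); ``nvecs_list`` per-slot state weights for
    the trial-count statistic (``None`` where unused).
    """
    n_slots = len(mats_list)
    S = mats_list[0].shape[0]

    def pad_rows(matrices):
        nnz = np.zeros((n_slots, S), dtype=np.int64)
        entries = [[[] for _ in range(S)] for _ in range(n_slots)]
        K = 1
        for f, M in enumerate(matrices):
            if M is None:
                continue
            for i in range(S):
                cols = np.flatnonzero(M[i])
                nnz[f, i] = cols.size
                entries[f][i] = [(int(j), float(M[i, j])) for j in cols]
                K = max(K, cols.size)
        col = np.zeros((n_slots, S, K), dtype=np.int64)
        val = np.zeros((n_slots, S, K), dtype=np.float64)
        for f in range(n_slots):
            for i in range(S):
                for k, (j, v) in enumerate(entries[f][i]):
                    col[f, i, k] = j
                    val[f, i, k] = v
        return nnz, col, val

    rnnz, rcol, rval = pad_rows(mats_list)
    xnnz, xcol, xval = pad_rows(xmats_list)
    cnnz, ccol, cval = pad_rows([M.T.copy() for M in mats_list])

    has_n = np.zeros(n_slots, dtype=np.bool_)
    nvec = np.zeros((n_slots, S), dtype=np.float64)
    for f, v in enumerate(nvecs_list):
        if v is not None:
            has_n[f] = True
            nvec[f] = v
    return (rnnz, rcol, rval, cnnz, ccol, cval, xnnz, xcol, xval, has_n, nvec)


@njit(cache=True, fastmath=True)
def estep_kernel(
    rnnz, rcol, rval,      # row structure of each factor (for F @ b)
    cnnz, ccol, cval,      # column structure (for a @ F)
    xnnz, xcol, xval,      # transition-statistic structure (F elementwise* weight)
    has_n, nvec,           # occupancy-weight vectors for trial counts
    emit_idx,              # observation emitted after each slot, -1 if none
    E,                     # [n_obs, n_reads, S] shifted linear emission densities
    shifts,                # [n_reads, n_obs] log-density shifts
    init_idx,              # starting state index
    weights,               # per-read multiplicity (bootstrap resampling)
):
    n_slots, S = rnnz.shape
    n_obs, n_reads = E.shape[0], E.shape[1]
    xsum = np.zeros(n_slots)
    nsum = np.zeros(n_slots)
    total_ll = 0.0
    alpha_pre = np.empty((n_slots, S))
    a = np.empty(S)
    b = np.empty(S)
    bnew = np.empty(S)
    anew = np.empty(S)
    norms = np.empty(n_obs)

    for r in range(n_reads):
        for s in range(S):
            a[s] = 0.0
        a[init_idx] = 1.0
        ll = 0.0
        bad = False
        for f in range(n_slots):
            for s in range(S):
                alpha_pre[f, s] = a[s]
            for j in range(S):
                acc = 0.0
                for k in range(cnnz[f, j]):
                    acc += a[ccol[f, j, k]] * cval[f, j, k]
                anew[j] = acc
            for s in range(S):
                a[s] = anew[s]
            t = emit_idx[f]
            if t >= 0:
                norm = 0.0
                for s in range(S):
                    a[s] *= E[t, r, s]
                    norm += a[s]
                if not (norm > 0.0) or not np.isfinite(norm):
                    bad = True
                    break
                inv = 1.0 / norm
                for s in range(S):
                    a[s] *= inv
                norms[t] = norm
                ll += np.log(norm) + shifts[r, t]
        if bad:
            return total_ll, xsum, nsum, r
        w = weights[r]
        total_ll += w * ll

        for s in range(S):
            b[s] = 1.0
        for f in range(n_slots - 1, -1, -1):
            t = emit_idx[f]
            if t >= 0:
                inv = 1.0 / norms[t]
                for s in range(S):
                    b[s] *= E[t, r, s] * inv
            xv = 0.0
            for i in range(S):
                ai = alpha_pre[f, i]
                if ai != 0.0:
                    acc = 0.0
                    for k in range(xnnz[f, i]):
                        acc += xval[f, i, k] * b[xcol[f, i, k]]
                    xv += ai * acc
            xsum[f] += w * xv
            for i in range(S):
                acc = 0.0
                for k in range(rnnz[f, i]):
                    acc += rval[f, i, k] * b[rcol[f, i, k]]
                bnew[i] = acc
            if has_n[f]:
                nv = 0.0
                for i in range(S):
                    nv += alpha_pre[f, i] * bnew[i] * nvec[f, i]
                nsum[f] += w * nv
            for s in range(S):
                b[s] = bnew[s]
    return total_ll, xsum, nsum, -1
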