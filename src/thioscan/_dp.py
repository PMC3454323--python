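"""Numba kernels for local profile-HMM alignment.

The model is a match/insert/delete profile aligned locally: a path enters at
any match state (free entry), moves through M/I/D with the profile's
transition probabilities, and exits from any match state (free exit). Scores
are log-odds against the background in natural log units; callers convert
to bits. Delete states consume no residue, so each row first fills M and I
from the previous row and then sweeps D left-to-right within the row.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def _lae(a: float, b: float) -> float:
    if a < b:
        a, b = b, a
    if b <= -1.0e29:
        return a
    return a + np.log1p(np.exp(b - a))


@njit(cache=True)
def viterbi_kernel(seq, mlo, ilo, tr):
    """Best local path score (nats) plus the residue envelope [start, end)."""
    L = seq.shape[0]
    m = mlo.shape[0]
    VM = np.full(m, NEG)
    VI = np.full(m, NEG)
    VD = np.full(m, NEG)
    SM = np.zeros(m, np.int64)
    SI = np.zeros(m, np.int64)
    SD = np.zeros(m, np.int64)
    nVM = np.empty(m)
    nVI = np.empty(m)
    nVD = np.empty(m)
    nSM = np.zeros(m, np.int64)
    nSI = np.zeros(m, np.int64)
    nSD = np.zeros(m, np.int64)
    best = NEG
    best_s = 0
    best_e = 0
    for i in range(L):
        a = seq[i]
        for k in range(m):
            b = 0.0  # fresh local entry at this match state
            sidx = i
            if k > 0:
                c = VM[k - 1] + tr[k - 1, 0]
                if c > b:
                    b = c
                    sidx = SM[k - 1]
                c = VI[k - 1] + tr[k - 1, 3]
                if c > b:
                    b = c
                    sidx = SI[k - 1]
                c = VD[k - 1] + tr[k - 1, 5]
                if c > b:
                    b = c
                    sidx = SD[k - 1]
            nVM[k] = b + mlo[k, a]
            nSM[k] = sidx
            c1 = VM[k] + tr[k, 1]
            c2 = VI[k] + tr[k, 4]
            if c1 >= c2:
                nVI[k] = c1 + ilo[k, a]
                nSI[k] = SM[k]
            else:
                nVI[k] = c2 + ilo[k, a]
                nSI[k] = SI[k]
            if nVM[k] > best:
                best = nVM[k]
                best_s = nSM[k]
                best_e = i + 1
        nVD[0] = NEG
        nSD[0] = 0
        for k in range(1, m):
            c1 = nVM[k - 1] + tr[k - 1, 2]
            c2 = nVD[k - 1] + tr[k - 1, 6]
            if c1 >= c2:
                nVD[k] = c1
                nSD[k] = nSM[k - 1]
            else:
                nVD[k] = c2
                nSD[k] = nSD[k - 1]
        VM, nVM = nVM, VM
        VI, nVI = nVI, VI
        VD, nVD = nVD, VD
        SM, nSM = nSM, SM
        SI, nSI = nSI, SI
        SD, nSD = nSD, SD
    return best, best_s, best_e


@njit(cache=True)
def forward_kernel(seq, mlo, ilo, tr):
    """Log-sum (nats) over all local paths ending at any match state."""
    L = seq.shape[0]
    m = mlo.shape[0]
    FM = np.full(m, NEG)
    FI = np.full(m, NEG)
    FD = np.full(m, NEG)
    nFM = np.empty(m)
    nFI = np.empty(m)
    nFD = np.empty(m)
    total = NEG
    for i in range(L):
        a = seq[i]
        for k in range(m):
            b = 0.0  # fresh local entry
            if k > 0:
                b = _lae(b, FM[k - 1] + tr[k - 1, 0])
                b = _lae(b, FI[k - 1] + tr[k - 1, 3])
                b = _lae(b, FD[k - 1] + tr[k - 1, 5])
            nFM[k] = b + mlo[k, a]
            nFI[k] = _lae(FM[k] + tr[k, 1], FI[k] + tr[k, 4]) + ilo[k, a]
            total = _lae(total, nFM[k])
        nFD[0] = NEG
        for k in range(1, m):
            nFD[k] = _lae(nFM[k - 1] + tr[k - 1, 2], nFD[k - 1] + tr[k - 1, 6])
        FM, nFM = nFM, FM
        FI, nFI = nFI, FI
        FD, nFD = nFD, FD
    return total
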