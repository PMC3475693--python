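"""Minimum-free-energy folding by Zuker-style dynamic programming.

The recursion minimises the same additive energy function that
:func:`pcevol.rna.structure.energy_of_structure` evaluates: stacking terms,
size-indexed hairpin/bulge/internal-loop penalties (interior loops capped
at ``max_interior`` unpaired nt), a linear multibranch penalty and AU/GU
helix-end penalties.  Among co-optimal structures the one with the most
base pairs is returned (an epsilon bonus per pair, far below the 0.1
kcal/mol parameter granularity, implements this inside the DP); remaining
ties are resolved by a fixed, deterministic traceback preference order
(hairpin, then stack, then smallest interior loop, then leftmost
multibranch split).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import PAIR_TABLE, EnergyModel, default_model, encode
from .structure import SecondaryStructure, energy_of_structure

_EPS = 1e-6  # per-pair bonus used only for tie-breaking
_INF = 1e9
_TOL = 1e-9


@dataclass(frozen=True)
class FoldResult:
    structure: SecondaryStructure
    energy: float  # kcal/mol, evaluated by energy_of_structure


@njit(cache=True)
def _fill(seq, pt, stack, hp, bulge, internal, term, ml_a, ml_b, min_hp, max_il):
    n = seq.shape[0]
    V = np.full((n, n), _INF)
    WM = np.full((n, n), _INF)
    M1 = np.full((n, n), _INF)
    for span in range(min_hp + 1, n):
        for i in range(0, n - span):
            j = i + span
            p = pt[seq[i], seq[j]]
            if p >= 0:
                best = hp[j - i - 1] + term[p] - _EPS  # hairpin
                # stack
                q = pt[seq[i + 1], seq[j - 1]]
                if q >= 0 and V[i + 1, j - 1] < _INF:
                    cand = stack[p, q] + V[i + 1, j - 1] - _EPS
                    if cand < best:
                        best = cand
                # bulge / internal loop
                for size in range(1, max_il + 1):
                    for l1 in range(0, size + 1):
                        l2 = size - l1
                        k = i + 1 + l1
                        l = j - 1 - l2
                        if k >= l:
                            continue
                        r = pt[seq[k], seq[l]]
                        if r < 0 or V[k, l] >= _INF:
                            continue
                        pen = bulge[size] if (l1 == 0 or l2 == 0) else internal[size]
                        cand = pen + term[p] + term[r] + V[k, l] - _EPS
                        if cand < best:
                            best = cand
                # multibranch: >= 2 branches inside (i+1 .. j-1)
                for k in range(i + 2, j - 1):
                    if WM[i + 1, k - 1] < _INF and M1[k, j - 1] < _INF:
                        cand = (
                            ml_a + ml_b + term[p] - _EPS
                            + WM[i + 1, k - 1] + M1[k, j - 1]
                        )
                        if cand < best:
                            best = cand
                V[i, j] = best
            # M1: a single branch starting exactly at i, trailing unpaired free
            m = M1[i, j - 1] if j - 1 >= i else _INF
            if p >= 0 and V[i, j] < _INF:
                cand = V[i, j] + ml_b + term[p]
                if cand < m:
                    m = cand
            M1[i, j] = m
            # WM: >= 1 branch within [i, j]
            w = WM[i + 1, j] if i + 1 <= j else _INF
            if M1[i, j] < w:
                w = M1[i, j]
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < _INF and M1[k, j] < _INF:
                    cand = WM[i, k - 1] + M1[k, j]
                    if cand < w:
                        w = cand
            WM[i, j] = w
    # exterior
    W = np.zeros(n + 1)
    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(0, j - 1):
            p = pt[seq[i], seq[j - 1]]
            if p >= 0 and V[i, j - 1] < _INF:
                cand = W[i] + V[i, j - 1] + term[p]
                if cand < best:
                    best = cand
        W[j] = best
    return V, WM, M1, W


@njit(cache=True)
def _traceback(seq, pt, stack, hp, bulge, internal, term, ml_a, ml_b,
               min_hp, max_il, V, WM, M1, W):
    n = seq.shape[0]
    partner = np.full(n, -1, dtype=np.int64)
    # task stack: (kind, i, j) with kind 0=V, 1=WM, 2=M1
    ti = np.empty(4 * n + 4, dtype=np.int64)
    tj = np.empty(4 * n + 4, dtype=np.int64)
    tk = np.empty(4 * n + 4, dtype=np.int64)
    top = 0
    j = n
    while j > 0:
        if W[j] <= W[j - 1] + _TOL and W[j] >= W[j - 1] - _TOL:
            j -= 1
            continue
        found = False
        for i in range(0, j - 1):
            p = pt[seq[i], seq[j - 1]]
            if p >= 0 and V[i, j - 1] < _INF:
                if abs(W[i] + V[i, j - 1] + term[p] - W[j]) < _TOL:
                    tk[top] = 0
                    ti[top] = i
                    tj[top] = j - 1
                    top += 1
                    j = i
                    found = True
                    break
        if not found:  # numerical safety: treat as unpaired
            j -= 1
    while top > 0:
        top -= 1
        kind, i, j = tk[top], ti[top], tj[top]
        if kind == 0:  # V[i, j] — (i, j) is paired
            partner[i] = j
            partner[j] = i
            p = pt[seq[i], seq[j]]
            e = V[i, j]
            if abs(hp[j - i - 1] + term[p] - _EPS - e) < _TOL:
                continue  # hairpin
            q = pt[seq[i + 1], seq[j - 1]]
            if q >= 0 and V[i + 1, j - 1] < _INF and abs(
                stack[p, q] + V[i + 1, j - 1] - _EPS - e
            ) < _TOL:
                tk[top] = 0
                ti[top] = i + 1
                tj[top] = j - 1
                top += 1
                continue
            done = False
            for size in range(1, max_il + 1):
                for l1 in range(0, size + 1):
                    l2 = size - l1
                    k = i + 1 + l1
                    l = j - 1 - l2
                    if k >= l:
                        continue
                    r = pt[seq[k], seq[l]]
                    if r < 0 or V[k, l] >= _INF:
                        continue
                    pen = bulge[size] if (l1 == 0 or l2 == 0) else internal[size]
                    if abs(pen + term[p] + term[r] + V[k, l] - _EPS - e) < _TOL:
                        tk[top] = 0
                        ti[top] = k
                        tj[top] = l
                        top += 1
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            for k in range(i + 2, j - 1):
                if WM[i + 1, k - 1] < _INF and M1[k, j - 1] < _INF:
                    cand = (
                        ml_a + ml_b + term[p] - _EPS
                        + WM[i + 1, k - 1] + M1[k, j - 1]
                    )
                    if abs(cand - e) < _TOL:
                        tk[top] = 1
                        ti[top] = i + 1
                        tj[top] = k - 1
                        top += 1
                        tk[top] = 2
                        ti[top] = k
                        tj[top] = j - 1
                        top += 1
                        break
        elif kind == 1:  # WM[i, j]
            e = WM[i, j]
            if i + 1 <= j and abs(WM[i + 1, j] - e) < _TOL:
                tk[top] = 1
                ti[top] = i + 1
                tj[top] = j
                top += 1
                continue
            if abs(M1[i, j] - e) < _TOL:
                tk[top] = 2
                ti[top] = i
                tj[top] = j
                top += 1
                continue
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < _INF and M1[k, j] < _INF and abs(
                    WM[i, k - 1] + M1[k, j] - e
                ) < _TOL:
                    tk[top] = 1
                    ti[top] = i
                    tj[top] = k - 1
                    top += 1
                    tk[top] = 2
                    ti[top] = k
                    tj[top] = j
                    top += 1
                    break
        else:  # M1[i, j]: branch starts at i
            jj = j
            e = M1[i, jj]
            while jj - 1 >= i and M1[i, jj - 1] < _INF and abs(M1[i, jj - 1] - e) < _TOL:
                jj -= 1
            tk[top] = 0
            ti[top] = i
            tj[top] = jj
            top += 1
    return partner


def fold(
    sequence: str,
    model: EnergyModel | None = None,
    min_length: int = 8,
) -> FoldResult:
    """Predict the minimum-free-energy pseudoknot-free structure.

    ``N`` is treated as unpairable (with a warning); T is accepted and
    read as U, so folding is invariant under DNA/RNA representation.
    """
    model = model or default_model()
    rna = sequence.upper().replace("T", "U")
    if len(rna) < min_length:
        raise ValueError(f"sequence shorter than {min_length} nt")
    if "N" in rna:
        warnings.warn("sequence contains N; treated as unpairable", stacklevel=2)
    seq = encode(rna)
    n = len(seq)
    hp, bulge, internal = model.arrays_for(n)
    args = (
        seq, PAIR_TABLE, model.stack, hp, bulge, internal, model.terminal,
        model.ml_init, model.ml_branch, np.int64(model.min_hairpin),
        np.int64(min(model.max_interior, n)),
    )
    V, WM, M1, W = _fill(*args)
    partner = _traceback(*args, V, WM, M1, W)
    pairs = [(i, int(j)) for i, j in enumerate(partner) if j > i]
    structure = SecondaryStructure.from_pairs(n, pairs)
    energy = energy_of_structure(rna, structure, model)
    return FoldResult(structure=structure, energy=energy)
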