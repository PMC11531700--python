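"""Brute-force Smith-Waterman oracle (score-only, affine gaps).

This module is the ground truth that every lane-group engine in the package
is tested against.  It implements the textbook affine-gap local-alignment
recurrences directly:

    H(i,j) = max( H(i-1,j-1) + sigma(q[i-1], s[j-1]),  E(i,j),  F(i,j),  0 )
    E(i,j) = max( E(i-1,j) - beta,  H(i-1,j) - alpha )
    F(i,j) = max( F(i,j-1) - beta,  H(i,j-1) - alpha )

with boundaries H(i,0) = H(0,j) = 0, E(i,0) = -alpha-(i-1)*beta,
F(0,j) = -alpha-(j-1)*beta, and the remaining E/F boundary cells at
minus infinity, modelled by a large negative integer sentinel.  The optimal
local score is the maximum over H; no traceback is computed.

DP indices are 1-based as in the recurrences; sequence storage is 0-based,
so cell (i, j) scores the residue pair (q[i-1], s[j-1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .alphabet import EncodedSequence
from .scoring import ScoringScheme

__all__ = ["DPResult", "sw_score_full", "sw_score_linear", "SENTINEL"]

# -inf stand-in: far below any reachable score, yet safe under repeated
# subtraction of alpha/beta in 64-bit arithmetic.
SENTINEL = -(2**40)


@dataclass(frozen=True)
class DPResult:
    """Score-only DP outcome; matrices retained only when requested."""

    score: int
    H: np.ndarray | None = None
    E: np.ndarray | None = None
    F: np.ndarray | None = None


@njit(cache=True)
def _sw_full(q, s, sigma, alpha, beta, sentinel):  # pragma: no cover - jitted
    m, n = q.shape[0], s.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.empty((m + 1, n + 1), dtype=np.int64)
    F = np.empty((m + 1, n + 1), dtype=np.int64)
    E[0, 0] = sentinel
    F[0, 0] = sentinel
    for i in range(1, m + 1):
        E[i, 0] = -alpha - (i - 1) * beta
        F[i, 0] = sentinel
    for j in range(1, n + 1):
        F[0, j] = -alpha - (j - 1) * beta
        E[0, j] = sentinel
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = max(E[i - 1, j] - beta, H[i - 1, j] - alpha)
            f = max(F[i, j - 1] - beta, H[i, j - 1] - alpha)
            h = H[i - 1, j - 1] + sigma[qi, s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
    return H, E, F


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, EncodedSequence):
        codes = seq.codes
    else:
        codes = np.asarray(seq, dtype=np.int64)
    if codes.size == 0:
        raise ValueError("cannot align an empty sequence")
    return codes


def sw_score_full(Q, S, scheme: ScoringScheme, *, keep_matrices: bool = False) -> DPResult:
    """Full-matrix Smith-Waterman score between ``Q`` and ``S``.

    Accepts :class:`~lanesw.alphabet.EncodedSequence` or raw code arrays.
    With ``keep_matrices=True`` the H/E/F matrices (including boundary row
    and column) are returned for debugging and boundary-store checks.
    """
    q, s = _as_codes(Q), _as_codes(S)
    sigma = scheme.engine_matrix()
    H, E, F = _sw_full(q, s, sigma, scheme.alpha, scheme.beta, SENTINEL)
    score = int(H.max())
    if keep_matrices:
        return DPResult(score=score, H=H, E=E, F=F)
    return DPResult(score=score)


def sw_score_linear(Q, S, scheme: ScoringScheme) -> int:
    """Smith-Waterman score in memory proportional to ``min(m, n)``."""
    q, s = _as_codes(Q), _as_codes(S)
    if s.shape[0] > q.shape[0]:
        q, s = s, q  # sigma symmetric: score invariant under swap
    sigma = scheme.engine_matrix()
    return int(_sw_linear_impl(q, s, sigma, scheme.alpha, scheme.beta, SENTINEL))


@njit(cache=True)
def _sw_linear_impl(q, s, sigma, alpha, beta, sentinel):  # pragma: no cover
    # rows run over q (the longer sequence); state is kept per column of s
    m, n = q.shape[0], s.shape[0]
    h_prev = np.zeros(n + 1, dtype=np.int64)
    e_prev = np.full(n + 1, sentinel, dtype=np.int64)
    h_cur = np.zeros(n + 1, dtype=np.int64)
    e_cur = np.empty(n + 1, dtype=np.int64)
    best = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        h_cur[0] = 0
        e_cur[0] = -alpha - (i - 1) * beta
        f = sentinel
        for j in range(1, n + 1):
            e = max(e_prev[j] - beta, h_prev[j] - alpha)
            f = max(f - beta, h_cur[j - 1] - alpha)
            h = h_prev[j - 1] + sigma[qi, s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            e_cur[j] = e
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, h_cur = h_cur, h_prev
        e_prev, e_cur = e_cur, e_prev
    return best
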