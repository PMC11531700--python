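"""Column-chunk tiling for subjects longer than one lane-group width.

A subject of length ``n > p*k`` is processed in ``l = ceil(n / (k*p))``
stages, each a full wavefront pass over one ``m x (k*p)`` column chunk,
left to right.  The rightmost lane's boundary column values — the pair
(H, F) for every query row — accumulate in a p-slot buffer that is flushed
in blocks of ``p`` rows (emulating coalesced write-out) into a boundary
store; the next stage's leftmost lane reads that store in place of the DP
initialization.  Only (H, F) cross a stage boundary: E is vertical and
never leaves its column.  The running maximum and overflow flags carry
across stages, so precision semantics are identical to the untiled engine.

The final, possibly narrower, stage pads its missing columns with the pad
residue rather than shrinking the group, keeping a single code path.
"""

from __future__ import annotations

import math

import numpy as np

from .engine import (
    GroupResult,
    KernelConfig,
    OverflowFlag,
    _as_codes,
    _max_reduce,
    _run_stage,
    _subject_columns,
    saturating_ops,
)
from .engine import flush_boundary  # re-exported: part of the tiling surface
from .scoring import ScoringScheme

__all__ = ["align_tiled", "n_stages", "flush_boundary"]


def n_stages(n: int, config: KernelConfig) -> int:
    """Number of column-chunk stages, ``ceil(n / (k*p))``."""
    return max(1, math.ceil(n / (config.k * config.p)))


def align_tiled(
    Q,
    S,
    config: KernelConfig,
    scheme: ScoringScheme,
    *,
    subject_index: int = -1,
    debug: bool = False,
    capture_boundaries: list | None = None,
) -> GroupResult:
    """Score a query/subject pair of any subject length via staged tiling.

    ``capture_boundaries``, if given, receives the boundary store written
    after each non-final stage as ``(column_index, h_array, f_array)`` — H
    and F at that column for rows ``0..m`` — for verification against a
    full-matrix oracle.
    """
    q, s = _as_codes(Q), _as_codes(S)
    p, k = config.p, config.k
    width = p * k
    n = int(s.shape[0])
    m = int(q.shape[0])
    l = n_stages(n, config)
    arith = saturating_ops(config.precision)
    pad = scheme.alphabet.pad_code

    coverage = np.zeros((m + 1, n + 1), dtype=np.int64) if debug else None
    running_max = None
    boundary = None  # stage 0 reads the DP initialization
    flagged_any = False
    total_iter = 0
    for stage in range(l):
        chunk = s[stage * width : (stage + 1) * width]
        s_cols = _subject_columns(chunk, p, k, pad)[None, :, :]
        running_max, flagged, boundary_out, n_iter = _run_stage(
            q,
            s_cols,
            p,
            k,
            scheme,
            arith,
            boundary_in=boundary,
            collect_boundary=(stage < l - 1),
            running_max=running_max,
            col_offset=stage * width,
            n_real=int(chunk.shape[0]),
            coverage=coverage,
        )
        flagged_any = flagged_any or bool(flagged[0])
        total_iter += n_iter
        boundary = boundary_out
        if boundary_out is not None and capture_boundaries is not None:
            capture_boundaries.append(
                ((stage + 1) * width, boundary_out.h.copy(), boundary_out.f.copy())
            )

    score = _max_reduce(running_max[0])
    flag = (
        OverflowFlag(subject_index, arith.flag_reason) if flagged_any else None
    )
    return GroupResult(
        score=score, overflow=flag, iterations=total_iter, coverage=coverage
    )
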