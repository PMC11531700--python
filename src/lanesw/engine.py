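"""Lane-group wavefront engine for score-only Smith-Waterman.

The engine emulates, deterministically and in software, the execution model
of a warp-parallel alignment kernel: a group of ``p`` lanes advances in
lockstep over the DP matrix along an anti-diagonal wavefront.  Lane ``t``
owns ``k`` adjacent columns and, at iteration ``i``, computes the ``k``
cells of row ``i - t + 1``; the whole ``m x n`` matrix (``n <= p*k``, the
subject padded up to ``p*k``) is covered in exactly ``m + p`` iterations.

Lanes exchange data only through shuffle-style register moves
(:func:`shift_up_exchange` / :func:`shift_down_exchange`): after each
iteration a lane passes the rightmost H and F of its freshly computed row to
its right-hand neighbour, which consumes H both as the same-row left value
(next iteration) and as the diagonal value (the iteration after that).
Query characters travel through the group by the two-register rotation
scheme (:class:`QueryRotator`): a fresh block of ``p`` characters is loaded
only once every ``p`` iterations and then circulated by shuffles.

Three arithmetic modes are supported (:func:`saturating_ops`):

``wide32``
    exact integer arithmetic, never flags; scores equal the brute-force
    oracle by construction.
``int16sat``
    saturating signed 16-bit arithmetic; a subject whose H values reach
    32,767 is flagged for recomputation in wide arithmetic.
``fp16emu``
    half-precision emulation: arithmetic is exact but any H value reaching
    2,048 — the region where half floats start losing integer precision —
    flags the subject.  Scores below the cutoff are bit-exact, which is the
    only observable behaviour because flagged subjects are rescored anyway.

The packed variant (:func:`align_group_packed`) carries two independent
subjects through one lane group, fetching both substitution scores per cell
from the packed ``|S| x |S|^2`` table, mirroring two-alignments-per-register
16-bit arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import EncodedSequence
from .scoring import PackedSubstitutionTable, ScoringScheme, build_packed_table

__all__ = [
    "ALLOWED_P",
    "K_MAX",
    "KernelConfig",
    "OverflowFlag",
    "GroupResult",
    "Arithmetic",
    "saturating_ops",
    "shift_up_exchange",
    "shift_down_exchange",
    "QueryRotator",
    "align_group",
    "align_group_packed",
]

ALLOWED_P = (2, 4, 8, 16, 32)

#: Largest per-lane column count; mirrors the register-pressure ceiling of
#: the kernel menu this engine emulates (32 lanes * 40 columns = 1280).
K_MAX = 40

INT16_MAX = 32767
INT16_MIN = -32768
FP16_EXACT_LIMIT = 2048

# -inf stand-in for unbounded modes; engine state never leaves int64.
_WIDE_FLOOR = -(2**40)


@dataclass(frozen=True)
class KernelConfig:
    """Lane-group shape and arithmetic mode of one alignment kernel."""

    p: int
    k: int
    precision: str = "wide32"
    packed: bool = False
    tiled: bool = False

    def __post_init__(self) -> None:
        if self.p not in ALLOWED_P:
            raise ValueError(f"p must be one of {ALLOWED_P}, got {self.p}")
        if not 1 <= self.k <= K_MAX:
            raise ValueError(f"k must be in 1..{K_MAX}, got {self.k}")
        if self.precision not in ("wide32", "int16sat", "fp16emu"):
            raise ValueError(f"unknown precision {self.precision!r}")
        if self.packed and self.precision == "wide32":
            raise ValueError("packed mode requires a 16-bit precision")

    @property
    def width(self) -> int:
        """Subject capacity of one untiled pass."""
        return self.p * self.k


@dataclass(frozen=True)
class OverflowFlag:
    """Raised when a subject left the representable/accurate score range."""

    subject_index: int
    reason: str  # "saturated16" | "fp16range"


@dataclass(frozen=True)
class GroupResult:
    score: int
    overflow: OverflowFlag | None = None
    iterations: int = 0
    coverage: np.ndarray | None = None

    @property
    def valid(self) -> bool:
        return self.overflow is None


@dataclass(frozen=True)
class Arithmetic:
    """Arithmetic contract of one precision mode."""

    name: str
    floor: int  # representable minimum (plays the role of -inf)
    lo: int | None  # saturation bounds, None = unbounded
    hi: int | None
    flag_threshold: int | None  # H reaching this flags the subject
    flag_reason: str | None

    def add(self, a, b):
        out = np.asarray(a) + np.asarray(b)
        if self.lo is not None:
            out = np.clip(out, self.lo, self.hi)
        return out

    def sub(self, a, b):
        out = np.asarray(a) - np.asarray(b)
        if self.lo is not None:
            out = np.clip(out, self.lo, self.hi)
        return out

    def max(self, a, b):
        return np.maximum(a, b)

    def flags(self, h) -> bool:
        """Whether these H values trip the overflow/accuracy threshold."""
        if self.flag_threshold is None:
            return False
        return bool(np.any(np.asarray(h) >= self.flag_threshold))


_MODES = {
    "wide32": Arithmetic("wide32", _WIDE_FLOOR, None, None, None, None),
    "int16sat": Arithmetic(
        "int16sat", INT16_MIN, INT16_MIN, INT16_MAX, INT16_MAX, "saturated16"
    ),
    "fp16emu": Arithmetic(
        "fp16emu", _WIDE_FLOOR, None, None, FP16_EXACT_LIMIT, "fp16range"
    ),
}


def saturating_ops(precision: str) -> Arithmetic:
    """Arithmetic contract (add/sub/max semantics and flag rule) of a mode."""
    try:
        return _MODES[precision]
    except KeyError:
        raise ValueError(f"unknown precision {precision!r}") from None


def shift_up_exchange(values: np.ndarray, offset: int) -> np.ndarray:
    """Shuffle-up: lane ``t`` receives lane ``t - offset``'s value.

    Lanes ``t < offset`` keep their own value, mirroring the hardware
    contract for out-of-range source lanes.  Operates on the last axis.
    """
    values = np.asarray(values)
    p = values.shape[-1]
    if not 0 <= offset < p:
        raise ValueError(f"offset must be in 0..{p - 1}")
    if offset == 0:
        return values.copy()
    return np.concatenate(
        [values[..., :offset], values[..., : p - offset]], axis=-1
    )


def shift_down_exchange(values: np.ndarray, offset: int) -> np.ndarray:
    """Shuffle-down: lane ``t`` receives lane ``t + offset``'s value.

    Lanes ``t >= p - offset`` keep their own value.
    """
    values = np.asarray(values)
    p = values.shape[-1]
    if not 0 <= offset < p:
        raise ValueError(f"offset must be in 0..{p - 1}")
    if offset == 0:
        return values.copy()
    return np.concatenate(
        [values[..., offset:], values[..., p - offset :]], axis=-1
    )


def _max_reduce(values: np.ndarray) -> int:
    """Lane max-reduction via log2(p) shuffle-down steps; result in lane 0."""
    vals = np.asarray(values).copy()
    off = vals.shape[-1] // 2
    while off >= 1:
        vals = np.maximum(vals, shift_down_exchange(vals, off))
        off //= 2
    return int(vals[..., 0].max()) if vals.ndim > 1 else int(vals[0])


class QueryRotator:
    """Two-register query-character rotation across a lane group.

    Lane ``t`` needs query character ``q[i - t]`` at iteration ``i``.  A
    block of ``p`` characters is loaded from the query only every ``p``
    iterations (in chunks of four codes, emulating ``char4`` block reads);
    in between, characters circulate through the group: each iteration lane
    0 copies ``cq_next`` into ``cq_current``, a shuffle-up moves
    ``cq_current`` one lane to the right, and a shuffle-down moves
    ``cq_next`` one lane to the left.  The schedule is independent of the
    subject.
    """

    def __init__(self, q_codes: np.ndarray, p: int, pad_code: int):
        self.p = p
        self.pad_code = pad_code
        self.m = int(q_codes.shape[0])
        # query extended with pads so block loads never run off the end
        self.q_ext = np.concatenate(
            [
                np.asarray(q_codes, dtype=np.int64),
                np.full(2 * p + 4, pad_code, dtype=np.int64),
            ]
        )
        self.cur = np.full(p, pad_code, dtype=np.int64)
        self.nxt = np.full(p, pad_code, dtype=np.int64)
        self._block: dict[int, np.ndarray] = {}  # lane -> cached char4 block
        self._block_base: dict[int, int] = {}
        self.fetches = 0

    def _load(self, lane: int, idx: int) -> int:
        base = self._block_base.get(lane)
        if base is None or not base <= idx < base + 4:
            self._block[lane] = self.q_ext[idx : idx + 4]
            self._block_base[lane] = idx
            self.fetches += 1
        return int(self._block[lane][idx - self._block_base[lane]])

    def step(self, iteration: int) -> np.ndarray:
        """Advance one iteration; returns cq_current (one code per lane)."""
        p = self.p
        if iteration % p == 0:
            for t in range(p):
                self.nxt[t] = self._load(t, iteration + t)
        shifted = shift_up_exchange(self.cur, 1)
        new_cur = shifted.copy()
        new_cur[0] = self.nxt[0]
        self.cur = new_cur
        self.nxt = shift_down_exchange(self.nxt, 1)
        return self.cur


@dataclass
class _StageIO:
    """Left/right boundary columns of one tiling stage.

    ``h[r]`` / ``f[r]`` hold H and F at the boundary column for query row
    ``r`` (index 0 is the all-zero initialization row).
    """

    h: np.ndarray
    f: np.ndarray


def _init_boundary(m: int, floor: int) -> _StageIO:
    return _StageIO(
        h=np.zeros(m + 1, dtype=np.int64),
        f=np.full(m + 1, floor, dtype=np.int64),
    )


def _run_stage(
    q: np.ndarray,
    s_cols: np.ndarray,  # (slots, p, k) subject codes, padded
    p: int,
    k: int,
    scheme: ScoringScheme,
    arith: Arithmetic,
    *,
    packed_table: PackedSubstitutionTable | None = None,
    boundary_in: _StageIO | None = None,
    collect_boundary: bool = False,
    running_max: np.ndarray | None = None,  # (slots, p) carried across stages
    col_offset: int = 0,
    n_real: int | None = None,
    coverage: np.ndarray | None = None,
):
    """Run one wavefront pass over ``p*k`` subject columns.

    Returns ``(running_max, flagged_per_slot, out_boundary, iterations)``.
    ``boundary_in`` supplies the left boundary read by lane 0 (``None``
    means the DP initialization); ``collect_boundary`` gathers the
    rightmost-lane column through the p-slot flush buffer.
    """
    slots = s_cols.shape[0]
    m = int(q.shape[0])
    floor = arith.floor
    pad = scheme.alphabet.pad_code

    if boundary_in is None:
        boundary_in = _init_boundary(m, floor)
    bh, bf = boundary_in.h, boundary_in.f

    if packed_table is not None:
        if slots != 2:
            raise ValueError("packed stage needs exactly two subject slots")
        packed_idx = packed_table.pack(s_cols[0], s_cols[1])  # (p, k)
    else:
        ext = scheme.engine_matrix()

    h_up = np.zeros((slots, p, k), dtype=np.int64)
    e_up = np.full((slots, p, k), floor, dtype=np.int64)
    new_h = np.empty((slots, p, k), dtype=np.int64)
    h_left = np.zeros((slots, p), dtype=np.int64)
    f_left = np.full((slots, p), floor, dtype=np.int64)
    h_diag = np.zeros((slots, p), dtype=np.int64)
    # lane 0 boundary for its first row (row 1)
    h_left[:, 0] = bh[1] if m >= 1 else 0
    f_left[:, 0] = bf[1] if m >= 1 else floor
    h_diag[:, 0] = bh[0]

    if running_max is None:
        running_max = np.zeros((slots, p), dtype=np.int64)
    flagged = np.zeros(slots, dtype=bool)

    rotator = QueryRotator(q, p, pad)
    lanes = np.arange(p)

    out = _init_boundary(m, floor) if collect_boundary else None
    flush_buf: list[tuple[int, np.ndarray, np.ndarray]] = []

    n_iter = m + p
    for i in range(n_iter):
        cur = rotator.step(i)  # (p,)
        rows = i - lanes + 1  # row computed by each lane
        active = (rows >= 1) & (rows <= m)

        # substitution scores for this wavefront, one row-select per lane
        if packed_table is not None:
            subst = np.moveaxis(
                packed_table.lookup(cur[:, None], packed_idx), -1, 0
            )  # (2, p, k)
        else:
            subst = ext[cur[:, None], s_cols[0]][None, :, :]  # (1, p, k)

        new_e = np.maximum(arith.sub(e_up, scheme.beta), arith.sub(h_up, scheme.alpha))
        f_carry = f_left
        h_row_prev = h_left
        for c in range(k):
            diag = h_diag if c == 0 else h_up[:, :, c - 1]
            f_carry = np.maximum(
                arith.sub(f_carry, scheme.beta), arith.sub(h_row_prev, scheme.alpha)
            )
            h = arith.add(diag, subst[:, :, c])
            h = np.maximum(h, new_e[:, :, c])
            h = np.maximum(h, f_carry)
            h = np.maximum(h, 0)
            new_h[:, :, c] = h
            h_row_prev = h

        for sl in range(slots):
            if not flagged[sl] and arith.flags(new_h[sl]):
                flagged[sl] = True

        np.maximum(running_max, new_h.max(axis=2), out=running_max)

        if coverage is not None:
            limit = n_real if n_real is not None else p * k
            for t in np.flatnonzero(active):
                j0 = col_offset + t * k
                width = min(k, limit - t * k)
                if width > 0:
                    coverage[rows[t], j0 + 1 : j0 + 1 + width] += 1

        # shuffle the rightmost (H, F) of each lane to its right neighbour;
        # the value exchanged one iteration earlier becomes the diagonal
        send_h = new_h[:, :, k - 1]
        send_f = f_carry
        recv_h = shift_up_exchange(send_h, 1)
        recv_f = shift_up_exchange(send_f, 1)
        h_diag = h_left
        h_left = recv_h
        f_left = recv_f
        next_row0 = i + 2  # row lane 0 computes in the next iteration
        if next_row0 <= m:
            h_left[:, 0] = bh[next_row0]
            f_left[:, 0] = bf[next_row0]
        else:
            h_left[:, 0] = 0
            f_left[:, 0] = floor

        if collect_boundary:
            r_last = i - (p - 1) + 1
            if 1 <= r_last <= m:
                flush_buf.append((r_last, send_h[:, p - 1].copy(), send_f[:, p - 1].copy()))
                if len(flush_buf) == p:
                    flush_boundary(flush_buf, out)

        h_up, new_h = new_h, h_up
        e_up = new_e

    if collect_boundary and flush_buf:
        flush_boundary(flush_buf, out)  # final wavefront drain

    return running_max, flagged, out, n_iter


def flush_boundary(buffer: list, stage_store: _StageIO) -> _StageIO:
    """Flush the p-slot boundary buffer into the stage store, in row order.

    A partial buffer is only legal at the final wavefront drain; the engine
    enforces that by flushing eagerly whenever the buffer is full.
    """
    for r, h, f in buffer:
        stage_store.h[r] = h if np.ndim(h) == 0 else h[0]
        stage_store.f[r] = f if np.ndim(f) == 0 else f[0]
    buffer.clear()
    return stage_store


def _subject_columns(s_codes: np.ndarray, p: int, k: int, pad: int) -> np.ndarray:
    """Pad a subject to ``p*k`` and split it into per-lane column blocks."""
    n = s_codes.shape[0]
    padded = np.full(p * k, pad, dtype=np.int64)
    padded[:n] = s_codes
    return padded.reshape(p, k)


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, EncodedSequence):
        codes = seq.codes
    else:
        codes = np.asarray(seq, dtype=np.int64)
    if codes.size == 0:
        raise ValueError("cannot align an empty sequence")
    return codes


def align_group(
    Q,
    S,
    config: KernelConfig,
    scheme: ScoringScheme,
    *,
    subject_index: int = -1,
    debug: bool = False,
) -> GroupResult:
    """Score one query/subject pair with a single lane-group pass.

    The subject must fit the group (``len(S) <= p*k``); longer subjects
    belong to the tiled engine (:func:`lanesw.tiling.align_tiled`).
    """
    q, s = _as_codes(Q), _as_codes(S)
    p, k = config.p, config.k
    if s.shape[0] > p * k:
        raise ValueError(
            f"subject length {s.shape[0]} exceeds group capacity {p * k}; "
            "use the tiled engine (align_tiled) for long subjects"
        )
    arith = saturating_ops(config.precision)
    s_cols = _subject_columns(s, p, k, scheme.alphabet.pad_code)[None, :, :]
    m, n = q.shape[0], s.shape[0]
    coverage = np.zeros((m + 1, n + 1), dtype=np.int64) if debug else None
    running_max, flagged, _, n_iter = _run_stage(
        q, s_cols, p, k, scheme, arith, n_real=n, coverage=coverage
    )
    score = _max_reduce(running_max[0])
    flag = (
        OverflowFlag(subject_index, arith.flag_reason) if flagged[0] else None
    )
    return GroupResult(score=score, overflow=flag, iterations=n_iter, coverage=coverage)


def align_group_packed(
    Q,
    S_a,
    S_b,
    config: KernelConfig,
    scheme: ScoringScheme,
    *,
    packed_table: PackedSubstitutionTable | None = None,
    subject_indices: tuple[int, int] = (-1, -1),
) -> tuple[GroupResult, GroupResult]:
    """Score two independent subjects in one lane-group pass.

    Emulates two-alignments-per-register 16-bit arithmetic: both halves of
    every substitution lookup come from the packed ``|S| x |S|^2`` table and
    the two DP computations share the iteration schedule.  Overflow flags
    are independent per subject.
    """
    if not config.packed:
        raise ValueError("align_group_packed requires a packed KernelConfig")
    q = _as_codes(Q)
    sa, sb = _as_codes(S_a), _as_codes(S_b)
    p, k = config.p, config.k
    if max(sa.shape[0], sb.shape[0]) > p * k:
        raise ValueError(
            "subject exceeds group capacity; use the tiled engine"
        )
    pad = scheme.alphabet.pad_code
    s_cols = np.stack(
        [_subject_columns(sa, p, k, pad), _subject_columns(sb, p, k, pad)]
    )
    arith = saturating_ops(config.precision)
    if packed_table is None:
        packed_table = build_packed_table(scheme)
    running_max, flagged, _, n_iter = _run_stage(
        q, s_cols, p, k, scheme, arith, packed_table=packed_table
    )
    results = []
    for sl in range(2):
        flag = (
            OverflowFlag(subject_indices[sl], arith.flag_reason)
            if flagged[sl]
            else None
        )
        results.append(
            GroupResult(
                score=_max_reduce(running_max[sl]),
                overflow=flag,
                iterations=n_iter,
            )
        )
    return results[0], results[1]
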