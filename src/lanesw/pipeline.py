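"""Database scan workflow: batching, per-bin dispatch, overflow recompute,
ranking, and multi-worker partitioning.

A scan walks the length-sorted database in residue-budget batches, splits
every batch into the fixed length bins, and runs each bin through its
dedicated lane-group kernel (the long bin through the tiled engine).  Under
the ``auto16`` precision policy the first pass uses saturating 16-bit
arithmetic; subjects whose scores leave the representable range come back
flagged and are rescored with 32-bit arithmetic, so the final hit list is
always exact.  With several workers the database is partitioned so that
every worker receives about the same number of residues per length bin;
per-worker hit lists are merged at the end and are guaranteed to equal a
single-worker scan.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import db as dbmod
from .alphabet import EncodedSequence, encode_sequence
from .db import LocalDB, bin_of, partition_by_length, select_kernel_config
from .engine import KernelConfig, OverflowFlag, align_group
from .scoring import ScoringScheme, load_builtin_scheme
from .tiling import align_tiled

__all__ = [
    "ScanParams",
    "Hit",
    "HitList",
    "scan",
    "recompute_overflows",
    "merge_worker_results",
    "Session",
]


@dataclass(frozen=True)
class ScanParams:
    """Knobs of one database scan."""

    scheme: ScoringScheme
    top_k: int = 10
    precision: str = "auto16"  # "auto16" (16-bit + recompute) or "wide32"
    residue_budget: int = dbmod.DEFAULT_RESIDUE_BUDGET
    n_workers: int = 1

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.precision not in ("auto16", "wide32"):
            raise ValueError(f"unknown precision policy {self.precision!r}")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")


@dataclass(frozen=True)
class Hit:
    index: int  # database index (ascending-length storage order)
    subject_id: str
    score: int


@dataclass(frozen=True)
class HitList:
    """Ranked hits for one query: descending score, ties by database index."""

    query_id: str
    hits: tuple[Hit, ...]

    def __iter__(self):
        return iter(self.hits)

    def __len__(self):
        return len(self.hits)

    def as_mapping(self) -> dict[str, int]:
        return {h.subject_id: h.score for h in self.hits}


def _score_subject(
    query: EncodedSequence,
    db: LocalDB,
    idx: int,
    config: KernelConfig,
    scheme: ScoringScheme,
):
    subject = db.sequence(idx)
    if config.tiled:
        return align_tiled(query, subject, config, scheme, subject_index=idx)
    return align_group(query, subject, config, scheme, subject_index=idx)


def _scan_indices(
    query: EncodedSequence,
    db: LocalDB,
    indices: np.ndarray,
    params: ScanParams,
) -> tuple[dict[int, int], list[OverflowFlag]]:
    """Score the given database indices; returns scores and overflow flags."""
    first_pass = "int16sat" if params.precision == "auto16" else "wide32"
    scores: dict[int, int] = {}
    flags: list[OverflowFlag] = []
    plan = dbmod.iterate_batches(db, params.residue_budget)
    index_set = np.asarray(indices, dtype=np.int64)
    for start, stop in plan:
        batch = index_set[(index_set >= start) & (index_set < stop)]
        if batch.size == 0:
            continue
        bins = partition_by_length(db.lengths[batch])
        for b in np.unique(bins):
            config = select_kernel_config(bin_of(int(b)), precision=first_pass)
            for idx in batch[bins == b]:
                result = _score_subject(query, db, int(idx), config, params.scheme)
                scores[int(idx)] = result.score
                if result.overflow is not None:
                    flags.append(result.overflow)
    return scores, flags


def recompute_overflows(
    db: LocalDB,
    query: EncodedSequence,
    flags: list[OverflowFlag],
    scheme: ScoringScheme,
) -> dict[int, int]:
    """Rescore flagged subjects with exact 32-bit arithmetic."""
    corrected: dict[int, int] = {}
    for flag in flags:
        idx = flag.subject_index
        b = int(partition_by_length([int(db.lengths[idx])])[0])
        config = select_kernel_config(bin_of(b), precision="wide32")
        corrected[idx] = _score_subject(query, db, idx, config, scheme).score
    return corrected


def _rank(query_id: str, scores: dict[int, int], db: LocalDB, top_k: int) -> HitList:
    order = sorted(scores, key=lambda i: (-scores[i], i))[:top_k]
    ids = db.ids
    return HitList(
        query_id=query_id,
        hits=tuple(Hit(index=i, subject_id=ids[i], score=scores[i]) for i in order),
    )


def merge_worker_results(per_worker: list[HitList], top_k: int) -> HitList:
    """Merge per-worker hit lists into the global top-k.

    Workers hold disjoint database slices, so merging is a re-rank of the
    union under the same (score desc, index asc) order.
    """
    if not per_worker:
        raise ValueError("no worker results to merge")
    all_hits = [h for hl in per_worker for h in hl.hits]
    all_hits.sort(key=lambda h: (-h.score, h.index))
    return HitList(query_id=per_worker[0].query_id, hits=tuple(all_hits[:top_k]))


def scan(db: LocalDB, queries, params: ScanParams) -> list[HitList]:
    """Scan the database with one or more queries.

    ``queries`` is an iterable of :class:`EncodedSequence` (or raw residue
    strings, which are encoded — and validated — before any alignment runs).
    Every database sequence is scored exactly once per query through its
    bin's kernel; with ``auto16`` the flagged subjects are rescored in wide
    arithmetic before ranking.  Results are independent of ``n_workers``.
    """
    prepared: list[EncodedSequence] = []
    for q in queries if isinstance(queries, (list, tuple)) else [queries]:
        if isinstance(q, EncodedSequence):
            prepared.append(q)
        else:
            prepared.append(encode_sequence(str(q), db.alphabet))
    if not prepared:
        raise ValueError("no queries given")

    if params.n_workers == 1:
        worker_sets = [np.arange(db.n_sequences, dtype=np.int64)]
    else:
        worker_sets = dbmod.assign_to_workers(db, params.n_workers).workers

    results = []
    for query in prepared:
        per_worker = []
        for indices in worker_sets:
            scores, flags = _scan_indices(query, db, indices, params)
            if flags:
                scores.update(recompute_overflows(db, query, flags, params.scheme))
            per_worker.append(_rank(query.id, scores, db, params.top_k))
        results.append(merge_worker_results(per_worker, params.top_k))
    return results


class Session:
    """A loaded database ready for repeated scanning (interactive use).

    The database is read from disk once at construction; every subsequent
    :meth:`scan` call reuses the in-memory copy, mirroring a workflow where
    the database transfer happens a single time for many queries.
    """

    def __init__(self, db_dir, scheme: ScoringScheme | None = None):
        self.db = dbmod.load_db(db_dir)
        self.scheme = scheme or load_builtin_scheme("blosum62", 11, 1)

    def scan(self, queries, **overrides) -> list[HitList]:
        params = ScanParams(scheme=self.scheme)
        if overrides:
            params = replace(params, **overrides)
        return scan(self.db, queries, params)
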