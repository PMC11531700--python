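"""Local database preprocessing and on-disk storage (the makeDB step).

Protein databases are scanned many times but need parsing only once, so
FASTA input (plain or gzip-compressed) is converted up front into a compact
binary store: sequences are integer-encoded, sorted by ascending length
(ties broken by original file order), and concatenated, with offset/length
tables for random access.  Length sorting is what later enables partitioning
the scan into per-length-range kernel launches.

On-disk layout (directory with ``db.bin`` + ``db.meta``), all little-endian:

``db.bin``
    magic ``LSWDB\\0`` + u32 format version, u64 sequence count, u64 total
    residues, u64 offset table (count entries), u32 length table, one
    residue code per byte, then a UTF-8 header blob with its own u64 offset
    table.
``db.meta``
    small JSON summary (version tag, alphabet identifier, counts).

The module also owns the scan-side partitioning logic: fixed 64-wide length
bins with their lane-group kernel configurations, residue-budget batching,
and the balanced multi-worker split.
"""

from __future__ import annotations

import gzip
import json
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .alphabet import PROTEIN, Alphabet, EncodedSequence, encode_sequence
from .engine import K_MAX, KernelConfig

__all__ = [
    "LocalDB",
    "LengthBin",
    "BatchPlan",
    "WorkerAssignment",
    "makedb",
    "load_db",
    "iterate_batches",
    "partition_by_length",
    "select_kernel_config",
    "assign_to_workers",
    "BIN_WIDTH",
    "N_BINS",
    "LONG_BIN",
    "MAX_UNTILED_LENGTH",
    "DEFAULT_RESIDUE_BUDGET",
]

_MAGIC = b"LSWDB\x00"
_VERSION = 1

#: Fixed-width length bins: bin i covers [64*i + 1, 64*(i + 1)].
BIN_WIDTH = 64
N_BINS = 20
LONG_BIN = N_BINS  # index of the catch-all bin handled by the tiled engine
#: Longest subject a single untiled lane group can hold (32 lanes * 40 cols).
MAX_UNTILED_LENGTH = 32 * K_MAX

#: Default per-batch residue budget (residues, not bytes).
DEFAULT_RESIDUE_BUDGET = 64_000_000


@dataclass
class LocalDB:
    """Length-sorted encoded database held in memory."""

    residues: np.ndarray  # concatenated int8 codes
    offsets: np.ndarray  # u64, start of each sequence
    lengths: np.ndarray  # u32, ascending
    headers: list[str]  # full FASTA headers, same order
    alphabet: Alphabet = PROTEIN
    version: int = _VERSION

    @property
    def n_sequences(self) -> int:
        return int(self.lengths.shape[0])

    @property
    def total_residues(self) -> int:
        return int(self.lengths.sum())

    def sequence(self, idx: int) -> EncodedSequence:
        off, ln = int(self.offsets[idx]), int(self.lengths[idx])
        return EncodedSequence(
            id=self.ids[idx], codes=self.residues[off : off + ln].astype(np.int64)
        )

    @property
    def ids(self) -> list[str]:
        """Headers truncated at the first whitespace (FASTA id convention)."""
        return [h.split()[0] if h.split() else h for h in self.headers]


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_fasta(paths, alphabet: Alphabet):
    records = []
    record_no = 0
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        with _open_maybe_gzip(path) as fh:
            first = fh.readline()
            while first and not first.strip():
                first = fh.readline()
            if first and not first.startswith(">"):
                raise ValueError(
                    f"malformed FASTA in {path}: expected '>' at the first record"
                )
            fh.seek(0)
            try:
                for header, seq in SimpleFastaParser(fh):
                    record_no += 1
                    seq = "".join(seq.split())
                    if not seq:
                        raise ValueError(
                            f"record {record_no} ({header!r}) in {path} is empty"
                        )
                    try:
                        enc = encode_sequence(seq, alphabet, id=header)
                    except ValueError as exc:
                        raise ValueError(
                            f"record {record_no} ({header!r}) in {path}: {exc}"
                        ) from exc
                    records.append((header, enc.codes))
            except ValueError as exc:
                if "start with '>'" in str(exc):
                    raise ValueError(
                        f"malformed FASTA near record {record_no + 1} in {path}: {exc}"
                    ) from exc
                raise
    if not records:
        raise ValueError("no sequences found in input")
    return records


def makedb(fasta_paths, out_dir, alphabet: Alphabet = PROTEIN) -> Path:
    """Build a local database directory from FASTA / FASTA.gz files.

    Sequences are encoded, sorted by ascending length (stable in input
    order), and written in the documented binary layout.  gzip and plain
    input with identical content produce byte-identical databases.
    """
    if isinstance(fasta_paths, (str, Path)):
        fasta_paths = [fasta_paths]
    records = _parse_fasta(fasta_paths, alphabet)
    order = sorted(range(len(records)), key=lambda i: (records[i][1].shape[0], i))
    headers = [records[i][0] for i in order]
    codes = [records[i][1] for i in order]
    lengths = np.array([c.shape[0] for c in codes], dtype=np.uint64)
    offsets = np.zeros(len(codes), dtype=np.uint64)
    np.cumsum(lengths[:-1], out=offsets[1:])
    residues = np.concatenate(codes).astype(np.int8)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header_blob = b"".join(h.encode("utf-8") + b"\x00" for h in headers)
    header_offsets = np.zeros(len(headers), dtype=np.uint64)
    hlens = np.array([len(h.encode("utf-8")) + 1 for h in headers], dtype=np.uint64)
    np.cumsum(hlens[:-1], out=header_offsets[1:])

    with open(out_dir / "db.bin", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", _VERSION))
        fh.write(struct.pack("<QQ", len(codes), int(lengths.sum())))
        fh.write(offsets.astype("<u8").tobytes())
        fh.write(lengths.astype("<u4").tobytes())
        fh.write(residues.tobytes())
        fh.write(header_offsets.astype("<u8").tobytes())
        fh.write(header_blob)

    meta = {
        "format": "lanesw-db",
        "version": _VERSION,
        "alphabet": alphabet.symbols,
        "n_sequences": len(codes),
        "total_residues": int(lengths.sum()),
    }
    (out_dir / "db.meta").write_text(json.dumps(meta, indent=2) + "\n")
    return out_dir


def load_db(db_dir, alphabet: Alphabet = PROTEIN) -> LocalDB:
    """Load a database directory written by :func:`makedb`."""
    db_dir = Path(db_dir)
    meta = json.loads((db_dir / "db.meta").read_text())
    if meta.get("alphabet") != alphabet.symbols:
        raise ValueError("database was built with a different alphabet")
    raw = (db_dir / "db.bin").read_bytes()
    if raw[: len(_MAGIC)] != _MAGIC:
        raise ValueError(f"{db_dir / 'db.bin'} is not a lanesw database")
    pos = len(_MAGIC)
    (version,) = struct.unpack_from("<I", raw, pos)
    pos += 4
    if version != _VERSION:
        raise ValueError(f"unsupported database version {version}")
    count, total = struct.unpack_from("<QQ", raw, pos)
    pos += 16
    offsets = np.frombuffer(raw, dtype="<u8", count=count, offset=pos).copy()
    pos += 8 * count
    lengths = np.frombuffer(raw, dtype="<u4", count=count, offset=pos).copy()
    pos += 4 * count
    residues = np.frombuffer(raw, dtype=np.int8, count=total, offset=pos).copy()
    pos += total
    header_offsets = np.frombuffer(raw, dtype="<u8", count=count, offset=pos)
    pos += 8 * count
    blob = raw[pos:]
    headers = []
    for i in range(count):
        start = int(header_offsets[i])
        end = int(header_offsets[i + 1]) - 1 if i + 1 < count else len(blob) - 1
        headers.append(blob[start:end].decode("utf-8"))
    return LocalDB(
        residues=residues,
        offsets=offsets.astype(np.int64),
        lengths=lengths.astype(np.int64),
        headers=headers,
        alphabet=alphabet,
        version=version,
    )


@dataclass(frozen=True)
class LengthBin:
    """Inclusive length range served by one kernel configuration."""

    index: int
    lo: int
    hi: int | None  # None = unbounded (long bin)

    @property
    def is_long(self) -> bool:
        return self.hi is None


def partition_by_length(seq_lengths) -> np.ndarray:
    """Bin index for each length: bin i covers ``[64i+1, 64(i+1)]`` for
    i = 0..19; anything longer than 1280 lands in the long (tiled) bin."""
    lengths = np.asarray(seq_lengths, dtype=np.int64)
    if lengths.size and lengths.min() < 1:
        raise ValueError("sequence lengths must be >= 1")
    bins = (lengths - 1) // BIN_WIDTH
    return np.minimum(bins, LONG_BIN)


def bin_of(index: int) -> LengthBin:
    if index == LONG_BIN:
        return LengthBin(index=LONG_BIN, lo=MAX_UNTILED_LENGTH + 1, hi=None)
    if not 0 <= index < N_BINS:
        raise ValueError(f"bin index must be 0..{N_BINS}")
    return LengthBin(index=index, lo=BIN_WIDTH * index + 1, hi=BIN_WIDTH * (index + 1))


def select_kernel_config(bin: LengthBin, precision: str = "wide32") -> KernelConfig:
    """Lane-group shape for a length bin.

    Short bins use ``k = 32`` with the smallest sub-warp that fits
    (p = 4/8/16/32 up to lengths 128/256/512/1024); lengths 1025-1280 use
    the full-register ``p = 32, k = 40`` kernel; the long bin falls back to
    ``p = 32, k = 32`` with matrix tiling.
    """
    if bin.is_long:
        return KernelConfig(p=32, k=32, precision=precision, tiled=True)
    hi = bin.hi
    if hi <= 128:
        return KernelConfig(p=4, k=32, precision=precision)
    if hi <= 256:
        return KernelConfig(p=8, k=32, precision=precision)
    if hi <= 512:
        return KernelConfig(p=16, k=32, precision=precision)
    if hi <= 1024:
        return KernelConfig(p=32, k=32, precision=precision)
    return KernelConfig(p=32, k=K_MAX, precision=precision)  # 1025..1280


@dataclass(frozen=True)
class BatchPlan:
    """Contiguous batches of database indices under a residue budget."""

    boundaries: list[tuple[int, int]]  # [start, stop) index ranges

    def __iter__(self):
        return iter(self.boundaries)

    def __len__(self):
        return len(self.boundaries)


def iterate_batches(db: LocalDB, residue_budget: int = DEFAULT_RESIDUE_BUDGET) -> BatchPlan:
    """Split the database into contiguous batches of at most ``residue_budget``
    residues; a single sequence larger than the budget forms its own batch."""
    if residue_budget < 1:
        raise ValueError("residue budget must be positive")
    boundaries = []
    start = 0
    acc = 0
    for i, ln in enumerate(db.lengths):
        ln = int(ln)
        if acc and acc + ln > residue_budget:
            boundaries.append((start, i))
            start, acc = i, 0
        acc += ln
    if acc or not boundaries:
        boundaries.append((start, db.n_sequences))
    return BatchPlan(boundaries=boundaries)


@dataclass(frozen=True)
class WorkerAssignment:
    """Partition of database indices across workers."""

    workers: list[np.ndarray]  # sorted index arrays, one per worker

    @property
    def n_workers(self) -> int:
        return len(self.workers)


def assign_to_workers(db: LocalDB, n_workers: int) -> WorkerAssignment:
    """Split the database so every worker gets about the same residue total.

    Balancing is done independently inside each length bin (each bin maps to
    its own kernel, so per-bin balance is what avoids stragglers): sequences
    are taken in descending length and greedily given to the least-loaded
    worker, which bounds the per-bin worker spread by that bin's longest
    sequence.
    """
    if n_workers < 1:
        raise ValueError("need at least one worker")
    bins = partition_by_length(db.lengths)
    loads = [dict.fromkeys(range(n_workers), 0) for _ in range(LONG_BIN + 1)]
    assignment: list[list[int]] = [[] for _ in range(n_workers)]
    for b in range(LONG_BIN + 1):
        idx = np.flatnonzero(bins == b)
        if idx.size == 0:
            continue
        order = idx[np.argsort(-db.lengths[idx], kind="stable")]
        bin_load = loads[b]
        for i in order:
            w = min(range(n_workers), key=lambda wk: (bin_load[wk], wk))
            bin_load[w] += int(db.lengths[i])
            assignment[w].append(int(i))
    return WorkerAssignment(
        workers=[np.array(sorted(ix), dtype=np.int64) for ix in assignment]
    )
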