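"""Analytic peak-performance model for wavefront alignment kernels.

The model counts the arithmetic operations a kernel must issue per DP cell
and converts them, given a device description, into a theoretical peak
throughput in TCUPS (tera cell updates per second):

    TPP = #SMs * Throughput_per_Instruction * Clock / Cycles_per_cell

The base operation count per cell is 10: the main recurrence contributes
1 addition and 3 max operations, the gap recurrences in their
one-subtraction-saved optimized form contribute 3 subtractions and 2 max
operations, and tracking the running maximum adds 1 more max.  Lookup and
register-movement instructions are excluded — they can issue concurrently
with arithmetic on the modelled devices.

Device capabilities rewrite the per-cell cycle count in order:

``packing2``   two cells per 32-bit operation (16-bit pairs): 10 -> 5
``dual_port``  add/sub issue on a second port, leaving only the serialized
               max chain: 5 -> 3 (with packing)
``dpx_fused``  fused add+max instructions shrink the serialized packed-pair
               schedule to 4 operations: 3 -> 2

The three bundled device fixtures (A100, L40S, H100) carry the printed SM
counts, clocks, and a per-instruction throughput of 64 results/cycle/SM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources

__all__ = [
    "ArchSpec",
    "InstructionSchedule",
    "base_op_count",
    "cycles_per_cell",
    "tpp",
    "efficiency",
    "builtin_arch",
    "BUILTIN_ARCHS",
]

# per-cell operation counts of the wavefront inner loop
BASE_MAX_OPS = 6  # 3 (main recurrence) + 2 (gap recurrences) + 1 (running max)
BASE_ADDSUB_OPS = 4  # 1 addition + 3 subtractions

BUILTIN_ARCHS = ("a100", "l40s", "h100")


@dataclass(frozen=True)
class ArchSpec:
    """Device description feeding the peak-performance model."""

    name: str
    sm_count: int
    clock_max_ghz: float
    clock_sustained_ghz: float
    throughput_per_instruction: int  # results / cycle / SM
    packing2: bool = False
    dual_port: bool = False
    dpx_fused: bool = False

    def __post_init__(self) -> None:
        if min(self.sm_count, self.throughput_per_instruction) <= 0:
            raise ValueError("SM count and instruction throughput must be positive")
        if min(self.clock_max_ghz, self.clock_sustained_ghz) <= 0:
            raise ValueError("clocks must be positive")
        _validate_caps(self.caps)

    @property
    def caps(self) -> frozenset[str]:
        return frozenset(
            c for c in ("packing2", "dual_port", "dpx_fused") if getattr(self, c)
        )

    def clock(self, which: str = "max") -> float:
        if which == "max":
            return self.clock_max_ghz
        if which == "sustained":
            return self.clock_sustained_ghz
        raise ValueError("clock must be 'max' or 'sustained'")


@dataclass(frozen=True)
class InstructionSchedule:
    """Serialized inner-loop schedule after capability rewrites."""

    caps: frozenset[str]
    n_max_ops: int
    n_addsub_ops: int
    cells_per_op: int  # 1, or 2 with 16-bit packing
    serialized_ops: int  # ops on the critical issue port, per packed unit
    cycles_per_cell: Fraction


def _validate_caps(caps) -> frozenset[str]:
    caps = frozenset(caps)
    unknown = caps - {"packing2", "dual_port", "dpx_fused"}
    if unknown:
        raise ValueError(f"unknown capabilities: {sorted(unknown)}")
    if "dpx_fused" in caps and not {"packing2", "dual_port"} <= caps:
        raise ValueError(
            "dpx_fused presumes 16-bit packing and dual-port issue; "
            "inconsistent capability set"
        )
    return caps


def base_op_count() -> dict[str, int]:
    """Arithmetic operations per DP cell before any capability rewrite."""
    return {
        "max": BASE_MAX_OPS,
        "addsub": BASE_ADDSUB_OPS,
        "total": BASE_MAX_OPS + BASE_ADDSUB_OPS,
    }


def build_schedule(caps=()) -> InstructionSchedule:
    """Apply capability rewrites to the base schedule, in order."""
    caps = _validate_caps(caps)
    cells_per_op = 2 if "packing2" in caps else 1
    serialized = BASE_MAX_OPS + BASE_ADDSUB_OPS
    if "dual_port" in caps:
        # add/sub retire on the second port; only the max chain serializes
        serialized = BASE_MAX_OPS
    if "dpx_fused" in caps:
        # fused add+max collapses the packed-pair schedule to 4 issued ops
        serialized = 4
    return InstructionSchedule(
        caps=caps,
        n_max_ops=BASE_MAX_OPS,
        n_addsub_ops=BASE_ADDSUB_OPS,
        cells_per_op=cells_per_op,
        serialized_ops=serialized,
        cycles_per_cell=Fraction(serialized, cells_per_op),
    )


def cycles_per_cell(caps=()) -> Fraction:
    """Clock cycles per DP cell update under the given capability set."""
    return build_schedule(caps).cycles_per_cell


def tpp(arch: ArchSpec, cycles: Fraction | float | None = None, clock: str = "max") -> float:
    """Theoretical peak performance in TCUPS.

    ``cycles`` defaults to the schedule implied by the device's own
    capability flags.
    """
    if cycles is None:
        cycles = cycles_per_cell(arch.caps)
    cycles = Fraction(cycles) if not isinstance(cycles, Fraction) else cycles
    if cycles <= 0:
        raise ValueError("cycles per cell must be positive")
    gcups = arch.sm_count * arch.throughput_per_instruction * arch.clock(clock) / float(cycles)
    return gcups / 1000.0  # GHz-based GCUPS -> TCUPS


def efficiency(achieved_tcups: float, tpp_tcups: float) -> int:
    """Achieved share of theoretical peak, as a rounded integer percent."""
    if achieved_tcups <= 0 or tpp_tcups <= 0:
        raise ValueError("throughputs must be positive")
    return round(100.0 * achieved_tcups / tpp_tcups)


def builtin_arch(name: str) -> ArchSpec:
    """Load one of the bundled device fixtures (a100, l40s, h100)."""
    key = name.lower()
    if key not in BUILTIN_ARCHS:
        raise ValueError(
            f"unknown architecture {name!r}; built-ins: {', '.join(BUILTIN_ARCHS)}"
        )
    path = resources.files("lanesw.data") / f"arch_{key}.json"
    return load_arch(json.loads(path.read_text()))


def load_arch(spec: dict) -> ArchSpec:
    """Build an :class:`ArchSpec` from a plain JSON-style mapping."""
    caps = spec.get("caps", [])
    return ArchSpec(
        name=spec["name"],
        sm_count=int(spec["sm_count"]),
        clock_max_ghz=float(spec["clock_max_ghz"]),
        clock_sustained_ghz=float(spec["clock_sustained_ghz"]),
        throughput_per_instruction=int(spec["throughput_per_instruction"]),
        packing2="packing2" in caps,
        dual_port="dual_port" in caps,
        dpx_fused="dpx_fused" in caps,
    )
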