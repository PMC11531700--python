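# Methods

## Model and contract

`lanesw` computes score-only local alignments under the affine-gap
Smith–Waterman recurrences (H/E/F formulation, zero-clamped H, no
traceback). DP indices are 1-based; cell (i, j) scores the residue pair
(q[i−1], s[j−1]). The E/F "minus infinity" boundary is a fixed large
negative integer sentinel (−2^40), chosen so that subtracting α and n·β
repeatedly can never underflow 64-bit arithmetic; the E(i,0) and F(0,j)
boundary values −α−(i−1)β exist in the full-matrix oracle for completeness
but are never consumed by interior cells in this orientation.

Two independent routes produce scores:

* **Reference oracle** (`reference.py`): the recurrences written as plain
  scalar loops (full-matrix and linear-space variants), compiled with
  numba for speed. This is ground truth for everything else.
* **Lane-group engine** (`engine.py`, `tiling.py`): a deterministic
  lockstep emulation of a warp-style wavefront kernel, built on the
  shuffle primitives it models. In `wide32` mode its scores are asserted
  equal to the oracle across the whole configuration space.

## Lane-group wavefront schedule

A group of `p ∈ {2,4,8,16,32}` lanes processes one alignment; lane `t`
owns columns `t·k+1 .. (t+1)·k`. At iteration `i` (0-based), lane `t`
computes row `i − t + 1`; the full matrix takes exactly `m + p`
iterations. Data crossing lane boundaries:

* after each iteration a lane sends the rightmost (H, F) of the row it
  just computed to lane `t+1` via a shuffle-up; the receiver uses H as the
  same-row left neighbour in the next iteration and retains the previous
  exchange as the diagonal value (the "second antecedent row");
* E never crosses a lane boundary — it is a vertical recurrence and stays
  within its column;
* query characters circulate by the two-register rotation: one block load
  of `p` characters every `p` iterations (fetched in 4-code blocks,
  emulating `char4` reads), then per-iteration shuffle-up of
  `cq_current` and shuffle-down of `cq_next`, with lane 0 refilling
  `cq_current` from `cq_next`.

Lanes outside the active wavefront (rows < 1 or > m) compute on pad rows:
the pad residue scores −(α + max|σ| + 1) against everything, so those
cells clamp to H = 0 and are harmless; this keeps the emulation
branch-free, matching the lockstep design intent. Subjects are padded to
`p·k` columns with the same residue. A debug mode records a per-cell
coverage bitmap; tests assert the wavefront touches exactly
{1..m}×{1..n}, once each.

The per-cell substitution lookup is two-stage: the current query character
selects a matrix row, which is then indexed by the lane's `k` stored
subject characters. The packed variant keeps a `|Σ|×|Σ|²` table whose
entry for (q, pack(s₁, s₂)) yields both σ(q,s₁) and σ(q,s₂) in one
access; `align_group_packed` carries two independent subjects through one
group this way, and tests pin it to two unpacked runs, flags included.

## Precision modes and overflow fallback

* `wide32`: exact 64-bit integer arithmetic standing in for 32-bit kernels
  (protein scores never approach either limit); never flags.
* `int16sat`: all adds/subtracts saturate to [−32768, 32767]; a subject
  whose H reaches 32,767 is flagged `saturated16`. Scores below the
  ceiling are exact.
* `fp16emu`: models half-precision kernels by their accuracy region, not
  bit-level rounding: arithmetic is exact but any H reaching 2,048 flags
  the subject (`fp16range`). Rationale: a real half-float kernel rescores
  such subjects in wide arithmetic anyway, so bit-accurate rounding below
  the cutoff would add no observable behaviour.

Flag soundness is the tested invariant: whenever the oracle score is at or
above a mode's threshold the flag must be raised; false positives are
possible only if some intermediate H crossed the threshold. The scan
pipeline's `auto16` policy runs the 16-bit pass first and rescores flagged
subjects in `wide32`, and is asserted to produce hit lists identical to a
pure `wide32` scan.

## Tiling

Subjects longer than `p·k` run in `l = ⌈n/(k·p)⌉` stages over column
chunks. The rightmost lane's boundary column (H, F per query row) is
buffered p rows at a time (emulating coalesced write-out, including the
final partial flush when `m mod p ≠ 0`) into a boundary store; stage
`s+1` may read nothing of stage `s` except that store, which replaces the
DP initialization for its leftmost lane. The final narrower stage pads its
columns rather than reshaping the group. Tests compare each intermediate
store against the corresponding column of the oracle's full H and F
matrices, exactly. The untiled ceiling is 32·40 = 1280 columns: `k` is
capped at 40 to mirror the register-pressure ceiling of the kernel menu
being emulated, even though the emulation itself has no such limit.

## Database store and scan

`makedb` parses FASTA or gzipped FASTA (Biopython parser), encodes
residues (unknown letters → X), sorts by ascending length with ties in
file order, and writes a documented little-endian binary layout (magic +
version, u64 counts, u64 offsets, u32 lengths, one code per byte, header
blob with its own offset table) plus a JSON side-car. The layout is an
independent design — documented here precisely so round-trips can be
tested bit-exactly; gzip and plain input produce identical bytes.

Scans walk the store in residue-budget batches (default 64 M residues, a
knob, since no canonical batch size exists), bin each batch into twenty
64-wide length ranges plus a long bin, and dispatch per bin: k = 32 with
p = 4/8/16/32 for lengths up to 128/256/512/1024, the p = 32, k = 40
kernel for 1025–1280, and the tiled engine above that. Ranking is by
descending score with ties broken by ascending database index (a choice;
no canonical rule exists), top-10 by default. Multi-worker execution
balances residues per worker *within each bin* (greedy
longest-first-to-least-loaded, which bounds the per-bin spread by that
bin's longest sequence); per-worker hit lists merge into a global top-k
that is provably identical to a single-worker scan, and tests assert
invariance for 1, 2, 4, 8 workers. The interactive mode of the original
workflow is realised as a `Session` object that loads the database once
and serves repeated scans; there is no REPL.

## Performance model

The per-cell operation count is derived from the recurrences: the main
recurrence contributes 1 add and 3 max; the gap recurrences, in the
optimized form that reuses H−α, contribute 3 subtracts and 2 max; the
running maximum adds 1 max — 10 operations, 6 max + 4 add/sub. Capability
rewrites are applied in a fixed order: `packing2` processes two cells per
operation (10 → 5 cycles/cell); `dual_port` retires add/sub on a second
issue port, leaving the 6-max chain (→ 3); `dpx_fused` collapses the
packed-pair schedule to 4 issued operations (→ 2). The fused endpoint is
calibrated to the known 2-cycles-per-cell figure rather than derived
op-by-op, because the published inner-loop description ("5 max/add
instructions plus 2 data movements per 64 cells") does not pin down the
normalisation unit; the three-operand max available on Ada is likewise
treated as a throughput remark, not a cycle-count change, to stay
consistent with the 3-cycle figure. Data-movement and table-lookup
instructions are excluded throughout (they can issue concurrently).
`dpx_fused` is only accepted together with `packing2` and `dual_port`,
since its calibration point presumes both. TPP = #SMs × throughput ×
clock / cycles-per-cell; bundled device fixtures (A100: 108 SM, 1.41 GHz,
packing2; L40S: 142 SM, 2.56/2.11 GHz, +dual_port; H100: 132 SM,
1.98 GHz, +dpx_fused; throughput 64 results/cycle/SM each) reproduce
1.95, 7.75, and 8.36 TCUPS and the 68% efficiency of a measured
5.71 TCUPS on the Hopper fixture. Efficiency is reported as a rounded
integer percent.

## Synthetic data

The fixture generators define the test conditions. Equal-length databases
mirror the D128…D2048 peak-throughput pattern (scaled down in sequence
count). Length-distributed databases model a curated-database profile:
log-normal lengths with fixed shape 0.7 and location solved so the mean is
361 (the Swiss-Prot mean), hard-capped at 4,000 for desk-scale runs
(standing in for the real 35,213 maximum) — at n = 1000 this populates
the long (tiled) bin with ~1–2% of sequences. Residues draw from BLOSUM62
background frequencies by default (uniform retained for worst cases).
Overflow pairs are runs of the highest self-scoring residue (W, +11 under
BLOSUM62), giving a known diagonal score per unit length. What this does
*not* emulate: real homology structure (scores between random synthetic
sequences are low and tie-heavy), real header conventions, and real
length/composition correlations — so passing tests demonstrate
algorithmic correctness and determinism, not retrieval quality on real
databases.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale inputs chosen to exercise every
code path: ≥ 2,000 random pairs across all (p, k) configurations for the
oracle-equivalence suite (m ≤ 48, subjects up to 3·p·k), a
1,000-sequence mixed-length database for the determinism scan, and
~3,000-residue engineered pairs for 16-bit saturation. Randomized tests
use fixed seeds; hypothesis suites are derandomized. The engine is pure
numpy over lane-shaped arrays (a deliberate trade: transparency of the
lockstep emulation over raw speed); the oracle is numba-jitted and also
serves as the fast path for large engineered inputs.

## Known limitations

* No traceback, E-values, or bit scores — scores only, by design.
* The emulation models the algorithmic contract (schedule, exchanges,
  precision, flags), not timing, occupancy, or memory coalescing; the
  analytic model lives separately and is not a simulator.
* `fp16emu` is a accuracy-region model, not IEEE half arithmetic.
* Worker execution is sequential; the multi-worker contract is about
  result invariance of the partition, not wall-clock parallelism.
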