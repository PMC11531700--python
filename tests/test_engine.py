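"""Lane-group wavefront engine: shuffles, rotation, oracle equivalence,
precision modes, and packed execution."""

import numpy as np
import pytest

from lanesw.alphabet import PROTEIN
from lanesw.engine import (
    ALLOWED_P,
    KernelConfig,
    QueryRotator,
    align_group,
    align_group_packed,
    saturating_ops,
    shift_up_exchange,
    shift_down_exchange,
)
from lanesw.fixtures import gen_overflow_pair
from lanesw.reference import sw_score_full

from conftest import random_codes


class TestShuffles:
    def test_shift_up_by_one(self):
        assert shift_up_exchange(np.array([10, 20, 30, 40]), 1).tolist() == [10, 10, 20, 30]

    def test_offset_zero_is_identity(self):
        v = np.array([5, 6, 7, 8])
        assert shift_up_exchange(v, 0).tolist() == v.tolist()

    @pytest.mark.parametrize("p", [2, 4, 8])
    def test_matches_index_arithmetic(self, p, rng):
        """Both shuffles agree with the per-lane index rule for all offsets."""
        v = rng.integers(0, 1000, p)
        for off in range(p):
            up = shift_up_exchange(v, off)
            down = shift_down_exchange(v, off)
            for t in range(p):
                assert up[t] == (v[t - off] if t >= off else v[t])
                assert down[t] == (v[t + off] if t + off < p else v[t])

    def test_out_of_range_offset(self):
        with pytest.raises(ValueError):
            shift_up_exchange(np.array([1, 2]), 2)


class TestQueryRotation:
    @pytest.mark.parametrize("p", [2, 4, 8])
    @pytest.mark.parametrize("m", [1, 3, 7, 20])
    def test_delivers_wavefront_schedule(self, p, m):
        """After iteration i, lane t holds query code q[i - t] (pad outside)."""
        q = np.arange(100, 100 + m)
        rot = QueryRotator(q, p, PROTEIN.pad_code)
        for i in range(m + p):
            cur = rot.step(i)
            for t in range(p):
                want = q[i - t] if 0 <= i - t < m else PROTEIN.pad_code
                if i - t < 0:
                    # lanes ahead of the wavefront still hold pad
                    assert cur[t] == PROTEIN.pad_code
                else:
                    assert cur[t] == want

    def test_schedule_independent_of_subject(self):
        # the rotator never sees the subject at all: its input is (Q, p)
        q = np.arange(10)
        a = [QueryRotator(q, 4, PROTEIN.pad_code).step(i).tolist() for i in range(6)]
        b = [QueryRotator(q, 4, PROTEIN.pad_code).step(i).tolist() for i in range(6)]
        assert a == b

    def test_block_loads_reduce_fetches(self):
        # one load event per p iterations, served from char4-style blocks
        q = np.arange(64)
        rot = QueryRotator(q, 2, PROTEIN.pad_code)
        for i in range(64 + 2):
            rot.step(i)
        naive_loads = (64 + 2 + 1) // 2 * 2  # one code per lane per event
        assert rot.fetches < naive_loads


class TestAlignGroup:
    @pytest.mark.parametrize("p", ALLOWED_P)
    @pytest.mark.parametrize("k", [1, 8, 32, 40])
    def test_oracle_equivalence_wide32(self, p, k, bl62, rng):
        for _ in range(3):
            m = int(rng.integers(1, 40))
            n = int(rng.integers(1, p * k + 1))
            q = random_codes(rng, m)
            s = random_codes(rng, n)
            res = align_group(q, s, KernelConfig(p, k), bl62)
            assert res.score == sw_score_full(q, s, bl62).score
            assert res.overflow is None

    def test_iteration_count_is_m_plus_p(self, bl62, rng):
        q = random_codes(rng, 23)
        s = random_codes(rng, 50)
        res = align_group(q, s, KernelConfig(8, 8), bl62)
        assert res.iterations == 23 + 8

    def test_all_pad_subject_scores_zero(self, bl62):
        q = random_codes(np.random.default_rng(0), 10)
        s = np.full(16, PROTEIN.pad_code)
        res = align_group(q, s, KernelConfig(4, 4), bl62)
        assert res.score == 0

    def test_lockstep_covers_every_cell_once(self, bl62, rng):
        """The wavefront computes exactly {1..m} x {1..n}, each cell once."""
        q = random_codes(rng, 17)
        s = random_codes(rng, 41)
        res = align_group(q, s, KernelConfig(4, 16), bl62, debug=True)
        assert (res.coverage[1:, 1:] == 1).all()
        assert res.coverage[0].sum() == 0 and res.coverage[:, 0].sum() == 0

    def test_subject_too_long_points_to_tiling(self, bl62):
        with pytest.raises(ValueError, match="tiled"):
            align_group(np.array([0]), np.zeros(33, dtype=int), KernelConfig(4, 8), bl62)

    def test_query_shorter_than_lane_count(self, bl62, rng):
        # m < p: trailing lanes only ever see pad rows
        q = random_codes(rng, 3)
        s = random_codes(rng, 100)
        res = align_group(q, s, KernelConfig(32, 4), bl62)
        assert res.score == sw_score_full(q, s, bl62).score


class TestPrecisionModes:
    def test_int16_saturating_add(self):
        arith = saturating_ops("int16sat")
        assert arith.add(32000, 1000) == 32767
        assert arith.flags(32767)
        assert not arith.flags(32766)

    def test_fp16_flags_at_2048(self):
        arith = saturating_ops("fp16emu")
        assert arith.flags(2048)
        assert not arith.flags(2047)
        # arithmetic itself is exact below the cutoff
        assert arith.add(2000, 40) == 2040

    def test_wide32_never_flags(self):
        arith = saturating_ops("wide32")
        assert not arith.flags(10**9)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            saturating_ops("int8")

    def test_fp16_exact_below_cutoff(self, bl62, rng):
        for _ in range(10):
            q = random_codes(rng, int(rng.integers(1, 30)))
            s = random_codes(rng, int(rng.integers(1, 60)))
            res = align_group(q, s, KernelConfig(4, 16, precision="fp16emu"), bl62)
            assert res.overflow is None
            assert res.score == sw_score_full(q, s, bl62).score

    def test_fp16_flags_above_cutoff(self, bl62):
        q, s = gen_overflow_pair(bl62, 2100)
        res = align_group(q, s, KernelConfig(8, 32, precision="fp16emu"), bl62)
        assert res.overflow is not None
        assert res.overflow.reason == "fp16range"

    def test_overflow_soundness_near_threshold(self, bl62, rng):
        """Whenever the oracle score crosses the fp16 cutoff the flag is up."""
        for target in (1900, 2000, 2047, 2048, 2200):
            q, s = gen_overflow_pair(bl62, target)
            oracle = sw_score_full(q, s, bl62).score
            res = align_group(q, s, KernelConfig(8, 32, precision="fp16emu"), bl62)
            if oracle >= 2048:
                assert res.overflow is not None
            if res.overflow is None:
                assert res.score == oracle


class TestPackedMode:
    CFG = KernelConfig(8, 16, precision="int16sat", packed=True)

    def test_requires_16bit(self):
        with pytest.raises(ValueError, match="packed"):
            KernelConfig(8, 16, precision="wide32", packed=True)

    def test_identical_subjects_identical_results(self, bl62, rng):
        q = random_codes(rng, 20)
        s = random_codes(rng, 64)
        ra, rb = align_group_packed(q, s, s, self.CFG, bl62)
        assert ra.score == rb.score
        assert (ra.overflow is None) == (rb.overflow is None)

    def test_equals_two_unpacked_runs(self, bl62, rng):
        unpacked = KernelConfig(8, 16, precision="int16sat")
        for _ in range(8):
            q = random_codes(rng, int(rng.integers(1, 40)))
            sa = random_codes(rng, int(rng.integers(1, 129)))
            sb = random_codes(rng, int(rng.integers(1, 129)))
            ra, rb = align_group_packed(q, sa, sb, self.CFG, bl62)
            ua = align_group(q, sa, unpacked, bl62)
            ub = align_group(q, sb, unpacked, bl62)
            assert (ra.score, ra.overflow) == (ua.score, ua.overflow)
            assert (rb.score, rb.overflow) == (ub.score, ub.overflow)

    def test_matches_oracle_below_threshold(self, bl62, rng):
        q = random_codes(rng, 30)
        sa = random_codes(rng, 100)
        sb = random_codes(rng, 50)
        ra, rb = align_group_packed(q, sa, sb, self.CFG, bl62)
        assert ra.score == sw_score_full(q, sa, bl62).score
        assert rb.score == sw_score_full(q, sb, bl62).score
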