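"""Seeded synthetic protein data generators for tests and benchmarks.

Two database shapes are produced: equal-length databases (the D128..D2048
pattern used for peak-throughput kernel studies, scaled down here) and
length-distributed databases emulating curated real-database statistics —
Swiss-Prot-like mean length 361 with a long upper tail (observed maximum
35,213, capped lower for desk-scale runs).  Lengths follow a log-normal
with fixed shape 0.7 (a reasonable fit for curated protein databases) whose
location parameter is solved so the distribution mean matches the target;
the hard cap truncates a negligible mass at desk-scale caps.

Residues are drawn from the BLOSUM62 background frequencies by default
(realistic composition and bin occupancy); a uniform mode is kept for
worst-case tests.  All generators are pure functions of their arguments and
the seed.
"""

from __future__ import annotations

import math

import numpy as np

from .reference import sw_score_linear
from .scoring import ScoringScheme

__all__ = [
    "gen_equal_length_db",
    "gen_distributed_db",
    "gen_overflow_pair",
    "BACKGROUND_FREQS",
]

# BLOSUM62 amino-acid background frequencies (Robinson & Robinson style),
# in the canonical residue order A R N D C Q E G H I L K M F P S T W Y V.
BACKGROUND_FREQS = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

_RESIDUES = "".join(BACKGROUND_FREQS)
_LOGNORMAL_SHAPE = 0.7


def _residue_sampler(rng: np.random.Generator, distribution: str):
    if distribution == "background":
        p = np.array(list(BACKGROUND_FREQS.values()))
        p = p / p.sum()
    elif distribution == "uniform":
        p = np.full(len(_RESIDUES), 1.0 / len(_RESIDUES))
    else:
        raise ValueError(f"unknown residue distribution {distribution!r}")
    letters = np.array(list(_RESIDUES))

    def draw(n: int) -> str:
        return "".join(letters[rng.choice(len(letters), size=n, p=p)])

    return draw


def _fasta(records) -> str:
    lines = []
    for name, seq in records:
        lines.append(f">{name}")
        for i in range(0, len(seq), 60):
            lines.append(seq[i : i + 60])
    return "\n".join(lines) + "\n"


def gen_equal_length_db(
    n: int, L: int, seed: int, *, distribution: str = "background"
) -> str:
    """FASTA text with ``n`` sequences, all of length ``L``."""
    if n < 1 or L < 1:
        raise ValueError("need n >= 1 and L >= 1")
    rng = np.random.default_rng(seed)
    draw = _residue_sampler(rng, distribution)
    return _fasta((f"synth{L}_{i}", draw(L)) for i in range(n))


def gen_distributed_db(
    n: int,
    mean_len: int = 361,
    max_len: int = 4000,
    seed: int = 0,
    *,
    distribution: str = "background",
) -> str:
    """FASTA text with log-normally distributed lengths.

    The empirical mean lands within 10% of ``mean_len`` for n >= 1000 (the
    shape parameter is fixed; the location is solved from the mean), and
    every length is clamped to ``[1, max_len]``.
    """
    if not 1 <= mean_len <= max_len:
        raise ValueError("need 1 <= mean_len <= max_len")
    rng = np.random.default_rng(seed)
    draw = _residue_sampler(rng, distribution)
    mu = math.log(mean_len) - _LOGNORMAL_SHAPE**2 / 2
    lengths = np.exp(rng.normal(mu, _LOGNORMAL_SHAPE, size=n))
    lengths = np.clip(np.round(lengths), 1, max_len).astype(int)
    return _fasta(
        (f"synthdist_{i} len={ln}", draw(int(ln))) for i, ln in enumerate(lengths)
    )


def gen_overflow_pair(scheme: ScoringScheme, target_score: int, *, max_len: int = 50000):
    """An identical pair of sequences whose alignment score >= target.

    Built from repeats of the residue with the highest self-score (W under
    BLOSUM62), so the optimal local alignment is the full diagonal with
    score ``length * sigma_max``.  Used to provoke 16-bit saturation and
    half-precision range flags deterministically.
    """
    if target_score < 1:
        raise ValueError("target score must be >= 1")
    n = scheme.alphabet.size
    std = [scheme.alphabet.index_of[c] for c in _RESIDUES]
    diag = np.diag(scheme.sigma)[std]
    best_code = std[int(np.argmax(diag))]
    per_residue = int(diag.max())
    length = math.ceil(target_score / per_residue)
    if length > max_len:
        raise ValueError(
            f"target {target_score} needs length {length} > max_len {max_len}"
        )
    codes = np.full(length, best_code, dtype=np.int64)
    assert sw_score_linear(codes, codes, scheme) >= target_score
    return codes, codes.copy()
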