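"""Substitution matrices, affine gap schemes, and the packed score table.

A :class:`ScoringScheme` bundles a symmetric substitution matrix sigma with
affine gap parameters: a gap of length L is penalised ``alpha + (L-1)*beta``
(``alpha`` opens, ``beta`` extends).  Built-in BLOSUM62 / BLOSUM50 matrices
ship as plain-text NCBI-format files and are parsed with Biopython.

The engines additionally need scores against the pad residue used to fill
subject sequences to a lane-group width; :meth:`ScoringScheme.engine_matrix`
extends sigma with a pad row/column scoring ``-(alpha + max|sigma| + 1)``
against everything, so a padded column can never start or extend a local
alignment (H clamps at zero before pad scores could matter).

For two-alignments-per-register arithmetic the substitution table is
reshaped to ``|S| x |S|^2`` so that one lookup keyed by a query code and a
*pair* of subject codes yields both scores at once
(:class:`PackedSubstitutionTable`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import PROTEIN, Alphabet

__all__ = [
    "ScoringScheme",
    "PackedSubstitutionTable",
    "load_builtin_scheme",
    "build_packed_table",
    "BUILTIN_MATRICES",
]

BUILTIN_MATRICES = {"blosum62": "BLOSUM62.txt", "blosum50": "BLOSUM50.txt"}


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix sigma plus affine gap penalties (alpha, beta)."""

    name: str
    sigma: np.ndarray  # |Sigma| x |Sigma| signed integers
    alpha: int  # gap-open penalty, positive
    beta: int  # gap-extend penalty, positive
    alphabet: Alphabet = PROTEIN

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma, dtype=np.int64)
        object.__setattr__(self, "sigma", sigma)
        n = self.alphabet.size
        if sigma.shape != (n, n):
            raise ValueError(f"sigma must be {n}x{n}, got {sigma.shape}")
        if not np.array_equal(sigma, sigma.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (self.alpha >= self.beta >= 1):
            raise ValueError("gap penalties must satisfy alpha >= beta >= 1")
        if np.abs(sigma).max() > 127:
            raise ValueError("substitution scores must fit in 8 bits")

    @property
    def pad_score(self) -> int:
        """Score of the pad residue against anything (strongly negative)."""
        return -(self.alpha + int(np.abs(self.sigma).max()) + 1)

    def engine_matrix(self) -> np.ndarray:
        """Sigma extended with the pad row/column (shape ``(n+1, n+1)``)."""
        n = self.alphabet.size
        ext = np.full((n + 1, n + 1), self.pad_score, dtype=np.int64)
        ext[:n, :n] = self.sigma
        return ext


def load_builtin_scheme(name: str, alpha: int, beta: int) -> ScoringScheme:
    """Load a built-in NCBI matrix with the given gap parameters.

    The common database-search schemes are ``("blosum62", 11, 1)`` and
    ``("blosum50", 13, 2)``.
    """
    key = name.lower()
    if key not in BUILTIN_MATRICES:
        raise ValueError(
            f"unknown matrix {name!r}; built-ins are: "
            + ", ".join(sorted(BUILTIN_MATRICES))
        )
    path = resources.files("lanesw.data") / BUILTIN_MATRICES[key]
    with resources.as_file(path) as fp:
        mat = substitution_matrices.read(str(fp))
    if str(mat.alphabet) != PROTEIN.symbols:
        raise ValueError(
            f"matrix file order {mat.alphabet!r} does not match the canonical "
            f"alphabet {PROTEIN.symbols!r}"
        )
    sigma = np.array(mat, dtype=np.int64)
    return ScoringScheme(name=key, sigma=sigma, alpha=int(alpha), beta=int(beta))


@dataclass(frozen=True)
class PackedSubstitutionTable:
    """Two-subjects-per-lookup layout of a substitution matrix.

    ``table[q, pack(s1, s2)]`` holds ``(sigma[q, s1], sigma[q, s2])``; the
    layout covers the pad code so packed engines can look up padded columns
    like any other.
    """

    table: np.ndarray  # (n, n*n, 2)
    n_codes: int

    def pack(self, s1, s2):
        """Column index of the subject-code pair ``(s1, s2)``."""
        return np.asarray(s1) * self.n_codes + np.asarray(s2)

    def lookup(self, q, packed):
        """Both scores for query code(s) ``q`` against a packed pair."""
        return self.table[q, packed]


def build_packed_table(scheme: ScoringScheme) -> PackedSubstitutionTable:
    """Build the ``|S| x |S|^2`` packed table from a scoring scheme."""
    ext = scheme.engine_matrix()
    n = ext.shape[0]
    table = np.empty((n, n * n, 2), dtype=np.int64)
    s1, s2 = np.divmod(np.arange(n * n), n)
    table[:, :, 0] = ext[:, s1]
    table[:, :, 1] = ext[:, s2]
    return PackedSubstitutionTable(table=table, n_codes=n)
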