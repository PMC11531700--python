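"""Amino-acid alphabet and integer sequence encoding.

Protein residues are mapped to small integer codes in the canonical NCBI
BLAST column order ``ARNDCQEGHILKMFPSTWYVBZX*``.  The ambiguity codes B
(Asx), Z (Glx) and X share the alphabet with the 20 standard residues and
the stop symbol ``*``; any other letter (J, U, O, ...) is folded onto X,
which is the usual database-search convention.  A dedicated pad code sits
outside the alphabet proper and is used by the alignment engines to fill
subject sequences up to a lane-group width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CANONICAL_ORDER",
    "Alphabet",
    "EncodedSequence",
    "PROTEIN",
    "encode_sequence",
]

#: NCBI BLAST residue column order used for all built-in matrices.
CANONICAL_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet with a reserved padding code.

    Codes ``0 .. size-1`` are bijective with :attr:`symbols`; :attr:`pad_code`
    equals ``size`` and never appears in encoded user input.
    """

    symbols: str = CANONICAL_ORDER
    index_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        object.__setattr__(
            self, "index_of", {c: i for i, c in enumerate(self.symbols)}
        )

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def pad_code(self) -> int:
        return len(self.symbols)

    @property
    def unknown_code(self) -> int:
        """Code of the ambiguity residue X."""
        return self.index_of["X"]

    def decode(self, codes) -> str:
        out = []
        for c in codes:
            c = int(c)
            if not 0 <= c < self.size:
                raise ValueError(f"code {c} outside alphabet")
            out.append(self.symbols[c])
        return "".join(out)


#: The default protein alphabet shared across the package.
PROTEIN = Alphabet()


@dataclass(frozen=True)
class EncodedSequence:
    """Integer-coded protein sequence with an identifier."""

    id: str
    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)

    def __len__(self) -> int:
        return int(self.codes.shape[0])


def encode_sequence(
    text: str, alphabet: Alphabet = PROTEIN, *, id: str = ""
) -> EncodedSequence:
    """Encode a residue string into integer codes.

    Characters are case-insensitive.  Letters outside the alphabet map to
    the ambiguity code X; non-letter characters are rejected with the
    offending position.
    """
    if not text:
        raise ValueError("cannot encode an empty sequence")
    codes = np.empty(len(text), dtype=np.int64)
    unknown = alphabet.unknown_code
    for i, ch in enumerate(text):
        up = ch.upper()
        if up in alphabet.index_of:
            codes[i] = alphabet.index_of[up]
        elif up.isalpha():
            codes[i] = unknown
        else:
            raise ValueError(
                f"non-letter character {ch!r} at position {i} cannot be encoded"
            )
    return EncodedSequence(id=id, codes=codes)
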