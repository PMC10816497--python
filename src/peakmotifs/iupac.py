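"""IUPAC degenerate-nucleotide alphabet, nibble encoding and bitwise matching.

Motifs are written in the 15-letter IUPAC code (A, C, G, T plus the eleven
ambiguity letters R, Y, M, K, W, S, B, D, H, V, N).  Each letter is encoded as
a 4-bit nibble with one bit per admitted base, ordered (C, G, T, A) from most
to least significant, so A -> 0001, T -> 0010, G -> 0100, C -> 1000 and
N -> 1111.  A motif of length k packs its k nibbles into a single integer
(first position in the most significant nibble), and every length-k window of
an A/C/G/T sequence is packed the same way.  A window matches a motif iff

    (window & motif) == window

i.e. every window nibble is a subset of the motif nibble at that position.
This reduces the per-window comparison to one AND and one equality test and
is exactly equivalent to per-position IUPAC set membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "IUPAC_LETTERS",
    "LETTER_TO_CODE",
    "CODE_TO_LETTER",
    "AlphabetError",
    "IupacMotif",
    "EncodedSequenceSet",
    "encode_letter",
    "hash_window",
    "matches",
    "reverse_complement_motif",
    "scan_sequence",
]

# bit per base, order (C, G, T, A) from MSB to LSB within the nibble
_BASE_BIT = {"A": 0b0001, "T": 0b0010, "G": 0b0100, "C": 0b1000}

LETTER_TO_CODE: dict[str, int] = {
    "A": 0b0001,
    "T": 0b0010,
    "G": 0b0100,
    "C": 0b1000,
    "R": 0b0101,  # G/A
    "Y": 0b1010,  # T/C
    "M": 0b1001,  # A/C
    "K": 0b0110,  # G/T
    "W": 0b0011,  # A/T
    "S": 0b1100,  # C/G
    "B": 0b1110,  # not A
    "H": 0b1011,  # not G
    "V": 0b1101,  # not T
    "D": 0b0111,  # not C
    "N": 0b1111,
}

CODE_TO_LETTER: dict[int, str] = {v: k for k, v in LETTER_TO_CODE.items()}
IUPAC_LETTERS = "".join(sorted(LETTER_TO_CODE))

# complement swaps A<->T (bits 0,1) and G<->C (bits 2,3)
_COMPLEMENT_CODE = tuple(
    ((c & 0b0001) << 1) | ((c & 0b0010) >> 1) | ((c & 0b0100) << 1) | ((c & 0b1000) >> 1)
    for c in range(16)
)

# base index convention shared with the background model: A=0, C=1, G=2, T=3
BASE_ORDER = "ACGT"
_CODE_TO_BASES = tuple(
    tuple(i for i, b in enumerate(BASE_ORDER) if LETTER_TO_CODE[b] & c) for c in range(16)
)

# uint8 lookup tables for vectorised encoding (indexed by ASCII byte)
_ASCII_CODE = np.zeros(256, dtype=np.uint8)
for _ch, _code in LETTER_TO_CODE.items():
    _ASCII_CODE[ord(_ch)] = _code
    _ASCII_CODE[ord(_ch.lower())] = _code
_ASCII_ACGT = np.zeros(256, dtype=bool)
for _ch in "ACGTacgt":
    _ASCII_ACGT[ord(_ch)] = True


class AlphabetError(ValueError):
    """A character outside the accepted alphabet was encountered."""


def encode_letter(letter: str, position: int | None = None) -> int:
    """Return the 4-bit nibble code of one IUPAC letter (case-insensitive)."""
    code = LETTER_TO_CODE.get(letter.upper())
    if code is None:
        where = "" if position is None else f" at position {position}"
        raise AlphabetError(f"unknown IUPAC character {letter!r}{where}")
    return code


def degeneracy(code: int) -> int:
    """Number of bases admitted by a nibble code (its popcount)."""
    return bin(code).count("1")


def _pack(codes: Sequence[int]) -> int:
    packed = 0
    for c in codes:
        packed = (packed << 4) | c
    return packed


def hash_window(kmer: str) -> int:
    """Pack an A/C/G/T k-mer into its nibble hash (first base most significant)."""
    codes = []
    for i, ch in enumerate(kmer):
        up = ch.upper()
        if up not in "ACGT":
            raise AlphabetError(f"non-ACGT character {ch!r} at position {i}")
        codes.append(LETTER_TO_CODE[up])
    return _pack(codes)


@dataclass(frozen=True)
class IupacMotif:
    """A degenerate consensus of fixed length k over the 15-letter IUPAC code."""

    letters: str
    code: tuple[int, ...] = field(init=False, repr=False, compare=False)
    packed: int = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        up = self.letters.upper()
        codes = tuple(encode_letter(ch, i) for i, ch in enumerate(up))
        object.__setattr__(self, "letters", up)
        object.__setattr__(self, "code", codes)
        object.__setattr__(self, "packed", _pack(codes))

    @property
    def k(self) -> int:
        return len(self.letters)

    @property
    def per_position_degeneracy(self) -> tuple[int, ...]:
        return tuple(degeneracy(c) for c in self.code)

    def reverse_complement(self) -> "IupacMotif":
        codes = tuple(_COMPLEMENT_CODE[c] for c in reversed(self.code))
        return IupacMotif("".join(CODE_TO_LETTER[c] for c in codes))

    def is_palindromic(self) -> bool:
        return self.reverse_complement().letters == self.letters

    def expansion(self) -> Iterator[str]:
        """Yield every exact A/C/G/T word matching the motif (lexicographic)."""
        per_pos = [[BASE_ORDER[i] for i in _CODE_TO_BASES[c]] for c in self.code]
        for word in product(*per_pos):
            yield "".join(word)

    def n_words(self) -> int:
        out = 1
        for d in self.per_position_degeneracy:
            out *= d
        return out

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.letters


def reverse_complement_motif(motif: IupacMotif | str) -> IupacMotif:
    if isinstance(motif, str):
        motif = IupacMotif(motif)
    return motif.reverse_complement()


def matches(motif: IupacMotif | int, window: int, k: int | None = None) -> bool:
    """True iff the packed window hash matches the packed motif code.

    When both arguments are packed integers the caller is responsible for
    ensuring equal k (``IupacMotif`` arguments are checked against ``k``).
    """
    if isinstance(motif, IupacMotif):
        if k is not None and motif.k != k:
            raise ValueError(f"length mismatch: motif k={motif.k}, window k={k}")
        motif = motif.packed
    return (window & motif) == window


def _encode_bytes(seq: str) -> np.ndarray:
    """Per-character nibble codes of an A/C/G/T string as uint8."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    bad = ~_ASCII_ACGT[raw]
    if bad.any():
        i = int(np.argmax(bad))
        raise AlphabetError(f"non-ACGT character {seq[i]!r} at position {i}")
    return _ASCII_CODE[raw]


def window_hashes(seq: str, k: int) -> np.ndarray:
    """All L-k+1 packed window hashes of a sequence, as uint64."""
    codes = _encode_bytes(seq)
    L = codes.size
    if L < k:
        raise ValueError(f"sequence length {L} < k={k}")
    shifts = (4 * np.arange(k - 1, -1, -1)).astype(np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.uint64)
    return (win << shifts).sum(axis=1, dtype=np.uint64)


class EncodedSequenceSet:
    """A set of A/C/G/T sequences with per-window packed hashes and masks.

    Masks start all-active; greedy discovery only ever deactivates windows
    (masking is monotone within a run).
    """

    def __init__(self, sequences: Sequence[str], k: int, ids: Sequence[str] | None = None):
        if not sequences:
            raise ValueError("empty sequence set")
        if not 1 <= k:
            raise ValueError("k must be positive")
        self.k = int(k)
        self.sequences = [s.upper() for s in sequences]
        for s in self.sequences:
            if len(s) < k:
                raise ValueError(f"sequence of length {len(s)} shorter than k={k}")
        self.ids = list(ids) if ids is not None else [f"seq{i}" for i in range(len(sequences))]
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        self.windows: list[np.ndarray] = [window_hashes(s, k) for s in self.sequences]
        self.masks: list[np.ndarray] = [np.ones(w.size, dtype=bool) for w in self.windows]

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def lengths(self) -> list[int]:
        return [len(s) for s in self.sequences]

    def uniform_length(self) -> int | None:
        ls = set(self.lengths)
        return ls.pop() if len(ls) == 1 else None

    def scan(
        self,
        motif: IupacMotif,
        index: int,
        both_strands: bool = True,
        respect_mask: bool = True,
    ) -> tuple[bool, int]:
        """(present, count) of a motif in one sequence.

        Reverse-strand hits are evaluated by matching the reverse-complement
        motif against the forward windows, which is exactly equivalent to
        scanning the other strand.  A palindromic motif counts each matching
        window on both strands, so its count is doubled; presence (the
        quantity used downstream) is unaffected.
        """
        if motif.k != self.k:
            raise ValueError(f"motif k={motif.k} does not match set k={self.k}")
        w = self.windows[index]
        active = self.masks[index] if respect_mask else np.ones(w.size, dtype=bool)
        m = np.uint64(motif.packed)
        hit = ((w & m) == w) & active
        count = int(hit.sum())
        if both_strands:
            rc = np.uint64(motif.reverse_complement().packed)
            hit_rc = ((w & rc) == w) & active
            count += int(hit_rc.sum())
        return count >= 1, count

    def mask_motif(self, motif: IupacMotif, both_strands: bool = True) -> int:
        """Deactivate every active window matching the motif (and, with
        ``both_strands``, its reverse complement) in every sequence.
        Returns the number of windows newly masked."""
        m = np.uint64(motif.packed)
        rc = np.uint64(motif.reverse_complement().packed) if both_strands else None
        removed = 0
        for w, mask in zip(self.windows, self.masks):
            hit = (w & m) == w
            if rc is not None:
                hit |= (w & rc) == w
            hit &= mask
            removed += int(hit.sum())
            mask[hit] = False
        return removed

    def copy(self) -> "EncodedSequenceSet":
        out = object.__new__(EncodedSequenceSet)
        out.k = self.k
        out.sequences = list(self.sequences)
        out.ids = list(self.ids)
        out.windows = [w.copy() for w in self.windows]
        out.masks = [m.copy() for m in self.masks]
        return out


def scan_sequence(motif: IupacMotif, sequence: str, both_strands: bool = True) -> tuple[bool, int]:
    """Convenience scan of a bare string (no masking)."""
    w = window_hashes(sequence.upper(), motif.k)
    m = np.uint64(motif.packed)
    count = int(((w & m) == w).sum())
    if both_strands:
        rc = np.uint64(motif.reverse_complement().packed)
        count += int(((w & rc) == w).sum())
    return count >= 1, count


@lru_cache(maxsize=None)
def all_motifs(k: int) -> tuple[str, ...]:
    """All 15^k IUPAC motifs of length k in lexicographic letter order."""
    return tuple("".join(t) for t in product(sorted(LETTER_TO_CODE), repeat=k))
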