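"""Markov background models and expected motif abundance Q.

The background is an order-m Markov chain over A/C/G/T (m in 0..3) fitted by
pooling transition counts over the forward strands of the input sequences,
with an additive pseudocount.  Conditional tables for every context length
0..m are kept so that the first positions of a window, which have fewer than
m preceding bases, fall back to the lower-order conditionals.

For a motif of length k, ``motif_window_probability`` is the probability that
a single chain-generated window matches the motif: the sum of chain
probabilities over all exact words in the motif's expansion, computed by
dynamic programming over positions with the last min(m, i) bases as state
(never by expanding the up-to-4^k word list).

The expected abundance Q of a motif — the probability that a random length-L
sequence contains at least one occurrence — treats the L-k+1 windows as
independent:

    single strand:  Q = 1 - (1 - p_w)^(L-k+1)
    both strands:   Q = 1 - [(1 - p_w)(1 - p_rc)]^(L-k+1)

where p_rc is the window probability of the reverse-complement motif.  The
independence approximation ignores window overlap (it slightly overestimates
Q for self-overlapping motifs) and, on both strands, counts a palindromic
motif's two strands as separate events.
"""

from __future__ import annotations

import json
import warnings
from typing import Sequence

import numpy as np

from .iupac import BASE_ORDER, IupacMotif

__all__ = ["MarkovBackground", "motif_window_probability", "expected_abundance"]

_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASE_ORDER):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i

# nibble code -> boolean (4,) of admitted bases in A,C,G,T order
_CODE_ALLOWED = np.zeros((16, 4), dtype=float)
for _c in range(16):
    from .iupac import LETTER_TO_CODE as _L2C

    for _j, _b in enumerate(BASE_ORDER):
        if _c & _L2C[_b]:
            _CODE_ALLOWED[_c, _j] = 1.0


def _to_indices(seq: str) -> np.ndarray:
    idx = _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (idx < 0).any():
        bad = int(np.argmax(idx < 0))
        raise ValueError(f"non-ACGT character {seq[bad]!r} at position {bad}")
    return idx


class MarkovBackground:
    """Order-m nucleotide Markov chain with per-context-length tables.

    Parameters
    ----------
    order : int
        Markov order, 0..3.
    counts : list of ndarray
        ``counts[c]`` has shape (4**c, 4): occurrence counts of base b after
        each length-c context.  Probabilities add ``pseudocount`` to every
        cell before normalising, so they are strictly positive whenever
        ``pseudocount > 0``.
    """

    MAX_ORDER = 3

    def __init__(self, order: int, counts: Sequence[np.ndarray], pseudocount: float = 1.0):
        if not 0 <= order <= self.MAX_ORDER:
            raise ValueError(f"order must be in 0..{self.MAX_ORDER}, got {order}")
        if pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        self.order = int(order)
        self.pseudocount = float(pseudocount)
        self.counts = [np.asarray(c, dtype=float) for c in counts]
        if len(self.counts) != order + 1:
            raise ValueError("need one count table per context length 0..order")
        self.probs: list[np.ndarray] = []
        for c, table in enumerate(self.counts):
            if table.shape != (4**c, 4):
                raise ValueError(f"table {c} has shape {table.shape}, expected {(4**c, 4)}")
            sm = table + self.pseudocount
            tot = sm.sum(axis=1, keepdims=True)
            # unseen contexts (possible only with pseudocount 0) fall back to
            # a uniform conditional rather than leaving an undefined row
            empty = (tot == 0).ravel()
            sm[empty] = 0.25
            tot[empty] = 1.0
            self.probs.append(sm / tot)

    # ------------------------------------------------------------------ #
    @classmethod
    def uniform(cls) -> "MarkovBackground":
        """Bernoulli model with P(A)=P(C)=P(G)=P(T)=0.25."""
        return cls(0, [np.ones((1, 4))], pseudocount=0.0)

    @classmethod
    def fit(
        cls, sequences: Sequence[str], order: int = 3, pseudocount: float = 1.0
    ) -> "MarkovBackground":
        """Fit conditional frequencies from forward-strand counts.

        Counts are pooled over all sequences; a sequence shorter than
        order+1 contributes only to the context lengths it can support
        (a warning is emitted if any sequence is that short).
        """
        if not sequences:
            raise ValueError("cannot fit a background on an empty sequence set")
        counts = [np.zeros((4**c, 4)) for c in range(order + 1)]
        short = 0
        pow4 = 4 ** np.arange(order, -1, -1, dtype=np.int64) if order else None
        for seq in sequences:
            idx = _to_indices(seq)
            if idx.size < order + 1:
                short += 1
            for c in range(order + 1):
                if idx.size < c + 1:
                    continue
                if c == 0:
                    np.add.at(counts[0], (0, idx), 1)
                else:
                    win = np.lib.stride_tricks.sliding_window_view(idx, c + 1)
                    ctx = win[:, :-1] @ (4 ** np.arange(c - 1, -1, -1, dtype=np.int64))
                    np.add.at(counts[c], (ctx, win[:, -1]), 1)
        if short:
            warnings.warn(
                f"{short} sequence(s) shorter than order+1 contribute nothing at the top order"
            )
        return cls(order, counts, pseudocount)

    # ------------------------------------------------------------------ #
    def window_probability_many(self, nibbles: np.ndarray) -> np.ndarray:
        """Vectorised window probability for an (n, k) array of nibble codes."""
        nibbles = np.asarray(nibbles)
        if nibbles.ndim == 1:
            nibbles = nibbles[None, :]
        n, k = nibbles.shape
        out = np.empty(n)
        # chunk to bound the (chunk, 4^order, 4) intermediate
        chunk = max(1, int(4e6 // max(1, 4 ** self.order * 4)))
        for lo in range(0, n, chunk):
            sub = nibbles[lo : lo + chunk]
            mass = np.ones((sub.shape[0], 1))
            c = 0
            for i in range(k):
                allowed = _CODE_ALLOWED[sub[:, i]]  # (m, 4)
                cond = self.probs[c]  # (4^c, 4)
                contrib = mass[:, :, None] * cond[None, :, :] * allowed[:, None, :]
                c_new = min(self.order, i + 1)
                if c_new == c + 1:
                    mass = contrib.reshape(sub.shape[0], -1)
                elif c_new == 0:  # order-0 chain keeps no state
                    mass = contrib.reshape(sub.shape[0], -1).sum(axis=1, keepdims=True)
                else:  # drop the oldest context base
                    mass = (
                        contrib.reshape(sub.shape[0], 4, 4 ** (c_new - 1), 4)
                        .sum(axis=1)
                        .reshape(sub.shape[0], -1)
                    )
                c = c_new
            out[lo : lo + chunk] = mass.sum(axis=1)
        return np.clip(out, 0.0, 1.0)

    def window_probability(self, motif: IupacMotif) -> float:
        return float(self.window_probability_many(np.array(motif.code, dtype=np.uint8))[0])

    # ------------------------------------------------------------------ #
    def sample(self, n: int, L: int, rng: np.random.Generator) -> list[str]:
        """Draw n random length-L sequences from the chain."""
        letters = np.frombuffer(BASE_ORDER.encode(), dtype=np.uint8)
        out = np.empty((n, L), dtype=np.uint8)
        state = np.zeros(n, dtype=np.int64)
        for i in range(L):
            c = min(self.order, i)
            p = self.probs[c][state % (4**c)]
            cum = np.cumsum(p, axis=1)
            u = rng.random(n)[:, None]
            b = (u > cum[:, :-1]).sum(axis=1)
            out[:, i] = letters[b]
            state = (state * 4 + b) % (4 ** max(self.order, 1))
        return [bytes(row).decode() for row in out]

    # ------------------------------------------------------------------ #
    def to_json(self) -> str:
        return json.dumps(
            {
                "order": self.order,
                "pseudocount": self.pseudocount,
                "counts": [c.tolist() for c in self.counts],
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "MarkovBackground":
        d = json.loads(doc)
        return cls(d["order"], [np.asarray(c) for c in d["counts"]], d["pseudocount"])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MarkovBackground(order={self.order}, pseudocount={self.pseudocount})"


def motif_window_probability(motif: IupacMotif | str, background: MarkovBackground) -> float:
    """Probability that one background-generated window matches the motif."""
    if isinstance(motif, str):
        motif = IupacMotif(motif)
    return background.window_probability(motif)


def expected_abundance(
    motif: IupacMotif | str,
    background: MarkovBackground,
    L: int,
    strands: str = "both",
) -> float:
    """Expected abundance Q: probability of >=1 occurrence in a length-L sequence."""
    if isinstance(motif, str):
        motif = IupacMotif(motif)
    if L < motif.k:
        raise ValueError(f"L={L} < motif length k={motif.k}")
    W = L - motif.k + 1
    p = background.window_probability(motif)
    if strands == "single":
        return float(1.0 - (1.0 - p) ** W)
    if strands == "both":
        p_rc = background.window_probability(motif.reverse_complement())
        return float(1.0 - ((1.0 - p) * (1.0 - p_rc)) ** W)
    raise ValueError(f"strands must be 'single' or 'both', got {strands!r}")
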