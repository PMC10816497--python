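"""Independent reference implementations used as test oracles.

Everything here works on plain strings with explicit IUPAC letter sets —
no nibble hashing, no shared code paths with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps

# The standard 15-letter nucleotide ambiguity code, written out by hand.
IUPAC_SETS = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "R": {"A", "G"},
    "Y": {"C", "T"},
    "M": {"A", "C"},
    "K": {"G", "T"},
    "W": {"A", "T"},
    "S": {"C", "G"},
    "B": {"C", "G", "T"},
    "D": {"A", "G", "T"},
    "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def naive_match(motif: str, word: str) -> bool:
    """Per-position IUPAC set membership."""
    assert len(motif) == len(word)
    return all(b in IUPAC_SETS[m] for m, b in zip(motif, word))


def naive_reverse_complement(motif: str) -> str:
    out = []
    for ch in reversed(motif):
        bases = {_COMPLEMENT[b] for b in IUPAC_SETS[ch]}
        (letter,) = [l for l, s in IUPAC_SETS.items() if s == bases]
        out.append(letter)
    return "".join(out)


def naive_expansion(motif: str) -> list[str]:
    return ["".join(t) for t in itertools.product(*(sorted(IUPAC_SETS[c]) for c in motif))]


def naive_count(motif: str, seq: str, both_strands: bool = True) -> int:
    k = len(motif)
    count = sum(naive_match(motif, seq[i : i + k]) for i in range(len(seq) - k + 1))
    if both_strands:
        rc = naive_reverse_complement(motif)
        count += sum(naive_match(rc, seq[i : i + k]) for i in range(len(seq) - k + 1))
    return count


class BruteForceDiscovery:
    """From-scratch greedy discovery over all 15^k motifs.

    Re-scans every motif against the (string-level) window mask state at
    each iteration.  Uniform background only; Q from the explicit word
    expansion; binomial tail via scipy in log space.  Deliberately naive —
    the only shared convention with the package is the selection criterion
    itself.
    """

    def __init__(self, k, f0, q0, p0, q_strands="both", max_iterations=None):
        self.k, self.f0, self.q0, self.p0 = k, f0, q0, p0
        self.q_strands = q_strands
        self.max_iterations = max_iterations

    def run(self, sequences: list[str]) -> list[dict]:
        k = self.k
        N = len(sequences)
        L = len(sequences[0])
        W = L - k + 1
        motifs = ["".join(t) for t in itertools.product(sorted(IUPAC_SETS), repeat=k)]
        # Q filter under the uniform background
        candidates = []
        for m in motifs:
            p = len(naive_expansion(m)) / 4.0**k
            if self.q_strands == "both":
                p_rc = len(naive_expansion(naive_reverse_complement(m))) / 4.0**k
                Q = 1.0 - ((1.0 - p) * (1.0 - p_rc)) ** W
            else:
                Q = 1.0 - (1.0 - p) ** W
            if Q < self.q0:
                candidates.append((m, Q))
        M = len(candidates)
        if M == 0:
            return []
        # window matches do not depend on the mask state, so compute each
        # candidate's matching (sequence, window) pairs once by naive
        # membership, then replay only the mask bookkeeping per iteration
        matched: dict[str, list[tuple[int, int]]] = {}
        for m, _ in candidates:
            rc = naive_reverse_complement(m)
            hits = []
            for i, seq in enumerate(sequences):
                for j in range(W):
                    w = seq[j : j + k]
                    if naive_match(m, w) or naive_match(rc, w):
                        hits.append((i, j))
            matched[m] = hits
        active = [[True] * W for _ in range(N)]
        out = []
        it = 0
        while self.max_iterations is None or it < self.max_iterations:
            best = None
            for m, Q in candidates:
                n = len({i for i, j in matched[m] if active[i][j]})
                if n / N <= self.f0:
                    continue
                logp = sps.binom.logsf(n - 1, N, Q) / math.log(10)
                logpb = min(0.0, logp + math.log10(M))
                if logpb >= math.log10(self.p0):
                    continue
                key = (logpb, -n, m)
                if best is None or key < best[0]:
                    best = (key, m, n, Q, logp, logpb)
            if best is None:
                break
            _, m, n, Q, logp, logpb = best
            for i, j in matched[m]:
                active[i][j] = False
            out.append({"motif": m, "n": n, "Q": Q, "minus_log10_P_Bonf": -logpb, "iteration": it})
            it += 1
        return out


def monte_carlo_abundance(
    motif: str, sampler, n_samples: int, both_strands: bool = True
) -> tuple[float, float]:
    """(fraction of sampled sequences containing the motif, its standard error)."""
    hits = 0
    seqs = sampler(n_samples)
    for s in seqs:
        hits += naive_count(motif, s, both_strands) >= 1
    f = hits / n_samples
    se = math.sqrt(max(f * (1 - f), 1e-12) / n_samples)
    return f, se
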