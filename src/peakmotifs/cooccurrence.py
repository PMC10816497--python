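"""Motif and TF co-occurrence via the phi coefficient, with a shuffling null.

The phi coefficient of a 2x2 contingency table

        |  B=1  B=0
    A=1 |   a    b
    A=0 |   c    d

is phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)), identical to the Pearson
correlation of the two binary indicator vectors.

Significance against the sequence composition is assessed by a permutation
null: each replicate shuffles the letters *within* every sequence
independently (mononucleotide shuffling, preserving each sequence's length
and base composition exactly), recomputes motif abundances and TF-level phi
coefficients, and the empirical p-value of a partner TF is the proportion of
replicates whose |phi| exceeds the |phi| observed on the real sequences.
Motifs whose real abundance F does not strictly exceed the shuffled
abundance in at least 95% of replicates are discarded before the TF-level
analysis, removing motifs that merely track the nucleotide context.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .iupac import IupacMotif, window_hashes

__all__ = [
    "phi",
    "phi_from_vectors",
    "presence_vectors",
    "pairwise_phi_matrix",
    "tf_presence",
    "shuffle_significance",
    "ShuffleResult",
]


def phi(a: int, b: int, c: int, d: int) -> float:
    """Phi coefficient of a 2x2 table with cells (a, b, c, d)."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("cell counts must be nonnegative")
    m1, m0 = a + b, c + d
    n1, n0 = a + c, b + d
    if min(m1, m0, n1, n0) == 0:
        raise ValueError("phi undefined: a marginal of the 2x2 table is zero")
    return (a * d - b * c) / np.sqrt(float(m1) * m0 * n1 * n0)


def phi_from_vectors(x: Sequence[int], y: Sequence[int]) -> float:
    """Phi of two binary vectors (equals their Pearson correlation)."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    a = int((x & y).sum())
    b = int((x & ~y).sum())
    c = int((~x & y).sum())
    d = int((~x & ~y).sum())
    return phi(a, b, c, d)


def presence_vectors(
    sequences: Sequence[str],
    motifs: Sequence[str | IupacMotif],
    both_strands: bool = True,
) -> pd.DataFrame:
    """Binary presence matrix: entry (j, i) = 1 iff motif i occurs in sequence j.

    A motif counts as present if found at least once on either strand; no
    masking is applied.
    """
    motifs = [m if isinstance(m, IupacMotif) else IupacMotif(m) for m in motifs]
    out = np.zeros((len(sequences), len(motifs)), dtype=int)
    by_k = {k: [window_hashes(s.upper(), k) for s in sequences] for k in {m.k for m in motifs}}
    for i, motif in enumerate(motifs):
        m = np.uint64(motif.packed)
        rc = np.uint64(motif.reverse_complement().packed)
        for j, w in enumerate(by_k[motif.k]):
            hit = ((w & m) == w).any()
            if both_strands and not hit:
                hit = ((w & rc) == w).any()
            out[j, i] = int(bool(hit))
    return pd.DataFrame(out, columns=[m.letters for m in motifs])


def pairwise_phi_matrix(
    presence: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Phi for every motif pair with a chi-square significance mask.

    Returns (phi_matrix, p_matrix, significant_mask).  p-values use the
    chi-square approximation phi^2 * N on 1 df.  Pairs with a zero marginal
    are flagged as NaN (undefined), not zero; the diagonal is 1.
    """
    X = presence.to_numpy(dtype=float)
    N, m = X.shape
    if m < 2:
        raise ValueError("need at least two motifs")
    means = X.mean(axis=0)
    sd = X.std(axis=0)
    cov = (X - means).T @ (X - means) / N
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = cov / np.outer(sd, sd)
    undefined = (sd == 0)[:, None] | (sd == 0)[None, :]
    mat[undefined] = np.nan
    np.fill_diagonal(mat, 1.0)
    chi2 = np.square(mat) * N
    p = sps.chi2.sf(chi2, df=1)
    sig = (p < alpha) & ~np.isnan(mat)
    cols = presence.columns
    return (
        pd.DataFrame(mat, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
        pd.DataFrame(sig, index=cols, columns=cols),
    )


def tf_presence(presence: pd.DataFrame, motif_to_tf: Mapping[str, str]) -> pd.DataFrame:
    """Collapse motif presence to TF presence: a TF's site is present in a
    sequence iff at least one of its motifs is present there."""
    if not motif_to_tf:
        raise ValueError("motif_to_tf map is empty")
    tfs: dict[str, list[str]] = {}
    for motif, tf in motif_to_tf.items():
        tfs.setdefault(tf, []).append(motif)
    out = {}
    for tf, motifs in tfs.items():
        missing = [m for m in motifs if m not in presence.columns]
        if missing:
            raise ValueError(f"TF {tf}: motifs {missing} absent from the presence matrix")
        out[tf] = presence[motifs].to_numpy().any(axis=1).astype(int)
    return pd.DataFrame(out, index=presence.index)


def _shuffle_within(seq_array: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute letters independently within each row (composition preserved)."""
    keys = rng.random(seq_array.shape)
    order = np.argsort(keys, axis=1)
    return np.take_along_axis(seq_array, order, axis=1)


@dataclass
class ShuffleResult:
    """Outcome of the shuffling-based co-occurrence significance test."""

    retained_motifs: list[str]
    phi_real: dict[str, float]
    p_values: dict[str, float]
    n_replicates: int
    seed: int | None
    motif_filter: pd.DataFrame = field(repr=False)

    def table(self) -> pd.DataFrame:
        rows = []
        for tf, r in self.phi_real.items():
            p = self.p_values[tf]
            rows.append(
                {
                    "partner_tf": tf,
                    "phi": r,
                    "empirical_p": p,
                    "p_floor": 1.0 / self.n_replicates,
                    "replicates": self.n_replicates,
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(rows)


def shuffle_significance(
    sequences: Sequence[str],
    motifs: Sequence[str | IupacMotif],
    motif_to_tf: Mapping[str, str],
    target_tf: str,
    partner_tfs: Sequence[str] | None = None,
    reps: int = 10_000,
    seed: int | None = None,
    both_strands: bool = True,
    filter_motifs: bool = True,
) -> ShuffleResult:
    """Shuffling null for motif abundance and TF-pair co-occurrence.

    Each of ``reps`` replicates shuffles the letters within every sequence,
    then motif presence, the abundance F of every motif and the TF-level phi
    coefficients are recomputed.  A motif is retained when its real F
    strictly exceeds its shuffled F in at least 95% of replicates.  The
    empirical p-value per partner TF is the proportion of replicates with
    |phi_null| > |phi_real| (an observed 0 is reported as 0; it means
    p < 1/reps).  Replicates where phi is undefined (a zero marginal) never
    count as exceeding.

    ``filter_motifs=False`` skips the abundance filter and keeps every motif;
    this is the exchangeable configuration for calibration diagnostics
    (under pure-composition data, real and shuffled statistics are then
    drawn from the same distribution).
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    motifs = [m if isinstance(m, IupacMotif) else IupacMotif(m) for m in motifs]
    motif_names = [m.letters for m in motifs]
    unknown = [m for m in motif_names if m not in motif_to_tf]
    if unknown:
        raise ValueError(f"motifs without a TF annotation: {unknown}")
    tf_of = {m.letters: motif_to_tf[m.letters] for m in motifs}
    all_tfs = sorted(set(tf_of.values()))
    if target_tf not in all_tfs:
        raise ValueError(f"target TF {target_tf!r} has no motifs in the input")
    if partner_tfs is None:
        partner_tfs = [t for t in all_tfs if t != target_tf]

    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("shuffling analysis requires equal-length sequences")
    arr = np.frombuffer("".join(s.upper() for s in sequences).encode(), dtype=np.uint8)
    arr = arr.reshape(len(sequences), lengths.pop()).copy()

    real = _presence_from_array(arr, motifs, both_strands)
    F_real = real.mean(axis=0)
    # pass 1: abundance null for the motif filter
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(motifs), dtype=np.int64)
    if filter_motifs:
        for _ in range(reps):
            shuf = _shuffle_within(arr, rng)
            pres = _presence_from_array(shuf, motifs, both_strands)
            exceed += F_real > pres.mean(axis=0)
        retained = exceed >= 0.95 * reps
    else:
        retained = np.ones(len(motifs), dtype=bool)
    filt = pd.DataFrame(
        {
            "motif": motif_names,
            "F_real": F_real,
            "frac_replicates_exceeded": exceed / reps,
            "retained": retained,
        }
    )
    if not retained.any():
        warnings.warn("all motifs were filtered out by the abundance null")
        return ShuffleResult([], {}, {}, reps, seed, filt)

    kept = [i for i in range(len(motifs)) if retained[i]]
    kept_motifs = [motifs[i] for i in kept]
    kept_tf = [tf_of[motif_names[i]] for i in kept]
    tf_cols = {tf: [j for j, t in enumerate(kept_tf) if t == tf] for tf in set(kept_tf)}

    def tf_vec(presence_kept: np.ndarray, tf: str) -> np.ndarray:
        cols = tf_cols.get(tf, [])
        if not cols:
            return np.zeros(presence_kept.shape[0], dtype=bool)
        return presence_kept[:, cols].any(axis=1)

    phi_real: dict[str, float] = {}
    real_kept = real[:, kept]
    target_real = tf_vec(real_kept, target_tf)
    live_partners = []
    for tf in partner_tfs:
        try:
            phi_real[tf] = phi_from_vectors(target_real, tf_vec(real_kept, tf))
            live_partners.append(tf)
        except ValueError:
            warnings.warn(f"phi undefined for partner {tf} on the real data; skipped")
    # pass 2: replay the identical shuffles (same seed) for the phi null on
    # the retained motifs only
    rng = np.random.default_rng(seed)
    n_exceed = {tf: 0 for tf in live_partners}
    for _ in range(reps):
        shuf = _shuffle_within(arr, rng)
        pres = _presence_from_array(shuf, kept_motifs, both_strands)
        t = tf_vec(pres, target_tf)
        for tf in live_partners:
            try:
                r_null = phi_from_vectors(t, tf_vec(pres, tf))
            except ValueError:
                continue
            if abs(r_null) > abs(phi_real[tf]):
                n_exceed[tf] += 1
    p_values = {tf: n_exceed[tf] / reps for tf in live_partners}
    return ShuffleResult([motif_names[i] for i in kept], phi_real, p_values, reps, seed, filt)


def _presence_from_array(
    arr: np.ndarray, motifs: Sequence[IupacMotif], both_strands: bool
) -> np.ndarray:
    """(n_seq, n_motifs) boolean presence from a (n_seq, L) byte array."""
    from .iupac import _ASCII_CODE  # uint8 nibble codes indexed by ASCII

    codes = _ASCII_CODE[arr]
    out = np.zeros((codes.shape[0], len(motifs)), dtype=bool)
    hashes_by_k: dict[int, np.ndarray] = {}
    for k in {m.k for m in motifs}:
        shifts = (4 * np.arange(k - 1, -1, -1)).astype(np.uint64)
        win = np.lib.stride_tricks.sliding_window_view(codes, k, axis=1).astype(np.uint64)
        hashes_by_k[k] = (win << shifts).sum(axis=2, dtype=np.uint64)
    for j, motif in enumerate(motifs):
        hashes = hashes_by_k[motif.k]
        m = np.uint64(motif.packed)
        hit = ((hashes & m) == hashes).any(axis=1)
        if both_strands:
            rc = np.uint64(motif.reverse_complement().packed)
            hit |= ((hashes & rc) == hashes).any(axis=1)
        out[:, j] = hit
    return out
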