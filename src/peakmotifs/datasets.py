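"""Bundled reference data: published summary characteristics of ten mouse
ChIP-seq experiments analysed with exhaustive IUPAC motif discovery.

Each training set held the N = 5000 highest-scoring peaks of one
experiment; motifs of length 8 were called significant at a Bonferroni-
corrected binomial probability below 1e-2 ("all motifs") or 1e-30 ("most
significant").  ``training_r`` / ``control_r`` are the Pearson correlations
between observed and regression-predicted ln(peak score) on the training
and held-out control sets.  These numbers serve as benchmark inputs for the
summary statistics the package recomputes; they are not produced by this
package.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["chipseq_summary", "significance_worked_example"]

_ROWS = [
    # tf, max -log10 P_Bonf, motifs at p0=1e-2, motifs at p0=1e-30,
    # training r, training max lnPS, control N, control r, control max lnPS
    ("CEBPA", 1585, 151, 36, 0.38, 5.29, 28559, 0.11, 3.60),
    ("CEBPB", 1028, 164, 39, 0.37, 5.53, 8374, 0.13, 2.74),
    ("NFE2L2", 880, 239, 71, 0.33, 5.54, 22065, 0.01, 3.17),
    ("SP1", 520, 243, 80, 0.57, 5.69, 19404, 0.06, 3.50),
    ("GATA1", 932, 168, 31, 0.30, 5.45, 2534, -0.03, 2.42),
    ("FOXA2", 1462, 202, 50, 0.33, 5.40, 20191, 0.09, 3.49),
    ("FOXO1", 447, 220, 51, 0.32, 5.68, 6433, 0.08, 2.45),
    ("NFYA", 1134, 270, 81, 0.53, 5.46, 975, 0.07, 1.88),
    ("MEF2D", 749, 219, 57, 0.36, 5.41, 29789, 0.07, 2.93),
    ("STAT5B", 744, 181, 44, 0.32, 5.20, 13510, 0.09, 3.10),
]


def chipseq_summary() -> pd.DataFrame:
    """Per-experiment motif counts, maximum significance and regression r."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "tf",
            "max_minus_log10_p_bonf",
            "n_motifs",
            "n_motifs_strict",
            "training_r",
            "training_max_lnps",
            "control_n",
            "control_r",
            "control_max_lnps",
        ],
    )


def significance_worked_example() -> dict:
    """The published worked example for the top forkhead-box motif TRTWKACH:
    present in n of N training sequences with an expectation of
    ``expected_n`` sequences under the background, tested against
    ``n_candidates`` motifs that survived the expected-abundance filter."""
    return {
        "motif": "TRTWKACH",
        "n": 3345,
        "N": 5000,
        "expected_n": 764,
        "n_candidates": 8.6e8,
        "minus_log10_p_bonf": 1462.3,
    }
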