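"""Multiple linear regression of ln(peak score) on motif presence.

The model is  Y = B0 + B1 X1 + ... + Bn Xn + e  fitted by ordinary least
squares, where Y is the natural logarithm of the peak score and Xi indicates
the i-th motif (presence/absence by default; per-sequence occurrence counts
optionally).  Peak scores are treated as opaque positive numbers — no
assumption is made about the peak caller that produced them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .iupac import IupacMotif, window_hashes

__all__ = [
    "MotifPresenceTransformer",
    "PeakScoreRegression",
    "CorrelationResult",
    "build_design",
    "evaluate_correlation",
    "fit_peak_score_model",
]


class MotifPresenceTransformer(BaseEstimator, TransformerMixin):
    """Turn sequences into a motif design matrix.

    Parameters
    ----------
    motifs : sequence of str or IupacMotif
        Column motifs, in order.
    mode : {"presence", "count"}, default "presence"
        Presence yields 0/1 indicators (>= 1 hit on either strand); count
        yields the number of matching windows (both strands, palindromic
        windows counted twice).
    both_strands : bool, default True
    """

    def __init__(self, motifs: Sequence[str | IupacMotif], mode: str = "presence", both_strands: bool = True):
        self.motifs = motifs
        self.mode = mode
        self.both_strands = both_strands

    def fit(self, X=None, y=None) -> "MotifPresenceTransformer":
        if not self.motifs:
            raise ValueError("motifs must be nonempty")
        if self.mode not in ("presence", "count"):
            raise ValueError(f"mode must be 'presence' or 'count', got {self.mode!r}")
        self.motif_objects_ = [m if isinstance(m, IupacMotif) else IupacMotif(m) for m in self.motifs]
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        if not hasattr(self, "motif_objects_"):
            self.fit()
        out = np.zeros((len(X), len(self.motif_objects_)), dtype=float)
        # hash windows once per distinct motif length, not once per motif
        by_k: dict[int, list[np.ndarray]] = {}
        for k in {m.k for m in self.motif_objects_}:
            by_k[k] = [window_hashes(seq.upper(), k) for seq in X]
        for j, motif in enumerate(self.motif_objects_):
            m = np.uint64(motif.packed)
            rc = np.uint64(motif.reverse_complement().packed)
            for i, w in enumerate(by_k[motif.k]):
                count = int(((w & m) == w).sum())
                if self.both_strands:
                    count += int(((w & rc) == w).sum())
                out[i, j] = count if self.mode == "count" else float(count >= 1)
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array([m if isinstance(m, str) else m.letters for m in self.motifs], dtype=object)


def build_design(
    sequences: Sequence[str],
    motifs: Sequence[str | IupacMotif],
    mode: str = "presence",
    both_strands: bool = True,
) -> pd.DataFrame:
    """Design matrix as a DataFrame with motif-string column labels."""
    tr = MotifPresenceTransformer(motifs, mode=mode, both_strands=both_strands).fit()
    X = tr.transform(sequences)
    return pd.DataFrame(X, columns=tr.get_feature_names_out())


class PeakScoreRegression(BaseEstimator, RegressorMixin):
    """OLS regression of y = ln(peak score) on a motif design matrix.

    Exact-duplicate and constant predictor columns are detected and dropped
    with a warning before fitting (their coefficients are not identifiable);
    remaining collinearity is handled by the pseudoinverse solver.
    Coefficient p-values come from the t distribution on N - p - 1 degrees
    of freedom.

    Attributes (after fit)
    ----------------------
    intercept_, coef_ : B0 and B1..Bn for the retained columns
    bse_, tvalues_, pvalues_ : inference per retained column (incl. intercept)
    rsquared_, df_resid_, resid_var_ : goodness-of-fit summaries
    dropped_ : list of dropped column labels
    feature_names_ : retained column labels in design order
    """

    def __init__(self, drop_collinear: bool = True):
        self.drop_collinear = drop_collinear

    def fit(self, X, y) -> "PeakScoreRegression":
        X = pd.DataFrame(X).copy()
        X.columns = [str(c) for c in X.columns]
        y = np.asarray(y, dtype=float)
        if len(X) != y.size:
            raise ValueError("X and y differ in length")
        dropped: list[str] = []
        if self.drop_collinear:
            constant = [c for c in X.columns if X[c].nunique() <= 1]
            dropped += constant
            X = X.drop(columns=constant)
            seen: dict[bytes, str] = {}
            dup = []
            for c in X.columns:
                key = X[c].to_numpy().tobytes()
                if key in seen:
                    dup.append(c)
                else:
                    seen[key] = c
            dropped += dup
            X = X.drop(columns=dup)
        if dropped:
            warnings.warn(f"dropped constant/duplicate columns: {dropped}")
        if len(X) <= X.shape[1] + 1:
            raise ValueError(
                f"need N > p + 1 for inference (N={len(X)}, p={X.shape[1]})"
            )
        design = sm.add_constant(X, has_constant="add")
        res = sm.OLS(y, design).fit()
        self.result_ = res
        self.dropped_ = dropped
        self.feature_names_ = list(X.columns)
        self.intercept_ = float(res.params.iloc[0])
        self.coef_ = res.params.iloc[1:].to_numpy()
        self.bse_ = res.bse.to_numpy()
        self.tvalues_ = res.tvalues.to_numpy()
        self.pvalues_ = res.pvalues.to_numpy()
        self.rsquared_ = float(res.rsquared)
        self.df_resid_ = float(res.df_resid)
        self.resid_var_ = float(res.mse_resid) if res.df_resid > 0 else 0.0
        return self

    def predict(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
        missing = [c for c in self.feature_names_ if c not in X.columns]
        if missing:
            raise ValueError(f"design is missing fitted columns: {missing}")
        X = X[self.feature_names_]
        return self.intercept_ + X.to_numpy(dtype=float) @ self.coef_

    def significant_coefficients(self, alpha: float = 0.05) -> pd.DataFrame:
        """Motif coefficients with p < alpha, in design-matrix order."""
        df = pd.DataFrame(
            {
                "motif": self.feature_names_,
                "coefficient": self.coef_,
                "p_value": self.pvalues_[1:],
            }
        )
        return df[df["p_value"] < alpha].reset_index(drop=True)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": ["intercept"] + self.feature_names_,
                "coefficient": np.concatenate([[self.intercept_], self.coef_]),
                "std_error": self.bse_,
                "t": self.tvalues_,
                "p_value": self.pvalues_,
            }
        )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    significant: bool
    n_tests: int


def evaluate_correlation(
    observed: Sequence[float], expected: Sequence[float], n_tests: int = 1
) -> CorrelationResult:
    """Pearson r between observed and predicted ln(PS), Bonferroni-adjusted.

    Significance is declared when p * n_tests < 0.05, n_tests being the
    number of evaluation sets considered together.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.size != exp.size or obs.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.std(obs) == 0 or np.std(exp) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = sps.pearsonr(obs, exp)
    return CorrelationResult(float(r), float(p), bool(p * n_tests < 0.05), n_tests)


def fit_peak_score_model(
    sequences: Sequence[str],
    scores: Sequence[float],
    motifs: Sequence[str | IupacMotif],
    mode: str = "presence",
    both_strands: bool = True,
) -> tuple[PeakScoreRegression, pd.DataFrame, np.ndarray]:
    """Convenience: design + ln transform + OLS.  Returns (fit, X, y)."""
    scores = np.asarray(scores, dtype=float)
    if (scores <= 0).any():
        bad = int(np.argmax(scores <= 0))
        raise ValueError(f"nonpositive peak score at sequence index {bad}")
    y = np.log(scores)
    X = build_design(sequences, motifs, mode=mode, both_strands=both_strands)
    fit = PeakScoreRegression().fit(X, y)
    return fit, X, y
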