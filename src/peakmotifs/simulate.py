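"""Synthetic ChIP-seq-peak data: planted IUPAC motifs and model-driven scores.

The generator emulates fixed-width windows around peak summits (default
L = 201, the inclusive [-100, +100] region).  Background sequence comes from
a Markov chain (uniform by default); for each plant, a sequence carries the
motif with the given per-sequence probability, realised by sampling one
exact word uniformly from the motif's expansion, reverse-complementing it
with the strand probability, and writing it at a uniform valid position.
Plants overwrite the background (and possibly each other — overwrites are
recorded), which keeps L fixed.

Peak scores follow the same linear model the regression stage fits:

    PS = exp(B0 + sum_i Bi * X_i + eps),  eps ~ Normal(0, sigma^2)

with X_i the intended presence indicator of plant i, so scores are positive
by construction and ln(PS) is exactly linear in presence up to the noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import json
import numpy as np
import pandas as pd

from .background import MarkovBackground
from .iupac import IupacMotif

__all__ = ["PlantSpec", "SyntheticSpec", "generate_sequences", "generate_scores", "make_fixture", "Fixture"]


@dataclass(frozen=True)
class PlantSpec:
    """One planted motif.

    ``prob`` is the per-sequence plant probability.  When ``co_with`` names
    another plant (by index), ``prob`` applies to sequences where that plant
    is present and ``prob_alone`` to the rest, producing co-occurring sites.
    """

    motif: str
    prob: float
    strand_prob: float = 0.5
    co_with: int | None = None
    prob_alone: float | None = None

    def __post_init__(self) -> None:
        IupacMotif(self.motif)  # validate letters
        for p in (self.prob, self.strand_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if (self.co_with is None) != (self.prob_alone is None):
            raise ValueError("co_with and prob_alone must be given together")


@dataclass
class SyntheticSpec:
    """Study conditions of one synthetic peak set."""

    n_sequences: int = 500
    length: int = 201
    plants: Sequence[PlantSpec] = field(default_factory=tuple)
    betas: Sequence[float] = field(default_factory=lambda: (3.5,))
    noise_sd: float = 0.5
    seed: int | None = None
    background: MarkovBackground | None = None

    def __post_init__(self) -> None:
        if len(self.betas) != len(self.plants) + 1:
            raise ValueError("betas must have one entry per plant plus the intercept")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for p in self.plants:
            if len(p.motif) > self.length:
                raise ValueError(f"motif {p.motif} longer than L={self.length}")

    def to_json(self) -> str:
        d = {
            "n_sequences": self.n_sequences,
            "length": self.length,
            "plants": [asdict(p) for p in self.plants],
            "betas": list(self.betas),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "background": None if self.background is None else json.loads(self.background.to_json()),
        }
        return json.dumps(d, indent=2)


def generate_sequences(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[list[str], list[str], pd.DataFrame, int]:
    """Generate (ids, sequences, intended-presence matrix, n_overwrites).

    The presence matrix records *intended* presence: a later plant may
    overwrite an earlier one, in which case the earlier motif can be absent
    from the realised sequence although its ground-truth entry is 1.  The
    number of such overlap events is returned (rare at default densities).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    bg = spec.background or MarkovBackground.uniform()
    seqs = bg.sample(spec.n_sequences, spec.length, rng)
    arrs = [bytearray(s.encode()) for s in seqs]
    truth = np.zeros((spec.n_sequences, len(spec.plants)), dtype=int)
    occupied = [np.zeros(spec.length, dtype=bool) for _ in range(spec.n_sequences)]
    overwrites = 0
    for pi, plant in enumerate(spec.plants):
        motif = IupacMotif(plant.motif)
        words = list(motif.expansion())
        for si in range(spec.n_sequences):
            if plant.co_with is not None:
                p = plant.prob if truth[si, plant.co_with] else plant.prob_alone
            else:
                p = plant.prob
            if rng.random() >= p:
                continue
            truth[si, pi] = 1
            word = words[rng.integers(len(words))]
            if rng.random() < plant.strand_prob:
                word = str(IupacMotif(word).reverse_complement())
            pos = int(rng.integers(0, spec.length - motif.k + 1))
            span = slice(pos, pos + motif.k)
            if occupied[si][span].any():
                overwrites += 1
            occupied[si][span] = True
            arrs[si][span] = word.encode()
    ids = [f"peak{i:05d}" for i in range(spec.n_sequences)]
    out = [a.decode() for a in arrs]
    cols = [p.motif for p in spec.plants]
    return ids, out, pd.DataFrame(truth, columns=cols, index=ids), overwrites


def generate_scores(
    presence: pd.DataFrame | np.ndarray,
    betas: Sequence[float],
    noise_sd: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Peak scores PS = exp(B0 + sum Bi Xi + eps); always positive."""
    X = presence.to_numpy() if isinstance(presence, pd.DataFrame) else np.asarray(presence)
    betas = np.asarray(betas, dtype=float)
    if betas.size != X.shape[1] + 1:
        raise ValueError("betas must have one entry per motif plus the intercept")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    eps = rng.normal(0.0, noise_sd, size=X.shape[0]) if noise_sd > 0 else 0.0
    return np.exp(betas[0] + X @ betas[1:] + eps)


@dataclass
class Fixture:
    name: str
    spec: SyntheticSpec
    ids: list[str]
    sequences: list[str]
    truth: pd.DataFrame
    scores: np.ndarray
    overwrites: int


# Named study conditions used throughout the test-suite and examples.
#  - "mini":       small enough for brute-force k=3 oracles
#  - "foxa2_like": one strong forkhead-style plant at the abundance a
#                  pioneer-factor peak set shows (F ~ 0.67) plus two weaker
#                  co-occurring partner plants (nuclear-receptor-like and
#                  GC-box-like), with scores from the linear ln(PS) model
#  - "null":       background only, no planted signal
_FIXTURES = {
    "mini": lambda seed: SyntheticSpec(
        n_sequences=60,
        length=30,
        plants=(PlantSpec("TGW", 0.6),),
        betas=(3.0, 0.4),
        noise_sd=0.3,
        seed=seed,
    ),
    "foxa2_like": lambda seed: SyntheticSpec(
        n_sequences=500,
        length=201,
        plants=(
            PlantSpec("TRTWKACH", 0.67),
            PlantSpec("RGGTCAAR", 0.45, co_with=0, prob_alone=0.10),
            PlantSpec("GGGCGGRR", 0.35, co_with=0, prob_alone=0.10),
        ),
        betas=(3.2, 0.5, 0.25, 0.20),
        noise_sd=0.5,
        seed=seed,
    ),
    "null": lambda seed: SyntheticSpec(
        n_sequences=200,
        length=50,
        plants=(),
        betas=(3.0,),
        noise_sd=0.5,
        seed=seed,
    ),
}


def make_fixture(name: str, seed: int = 0) -> Fixture:
    """Build one of the named synthetic peak sets ("mini", "foxa2_like", "null")."""
    try:
        spec = _FIXTURES[name](seed)
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}") from None
    rng = np.random.default_rng(seed)
    ids, seqs, truth, overwrites = generate_sequences(spec, rng)
    scores = generate_scores(truth, spec.betas, spec.noise_sd, rng)
    return Fixture(name, spec, ids, seqs, truth, scores, overwrites)
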