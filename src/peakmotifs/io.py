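"""File formats: FASTA sequences, peak-score tables, reports and run configs."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("peakmotifs")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_scores",
    "rank_and_split",
    "write_motif_report",
    "write_run_config",
]

_ACGT = set("ACGT")


def read_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Load (ids, sequences) from FASTA, case-folded to uppercase.

    Records containing characters outside A/C/G/T (including ambiguity
    letters such as N) are excluded with a warning naming the record —
    ambiguity codes are allowed only in motifs, never in sequences.  Mixed
    record lengths are allowed with a warning; fixed-length analyses check
    again downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids, seqs, skipped = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if not s or set(s) - _ACGT:
            skipped.append(rec.id)
            continue
        ids.append(rec.id)
        seqs.append(s)
    if skipped:
        warnings.warn(
            f"excluded {len(skipped)} record(s) with non-ACGT characters: "
            + ", ".join(skipped[:5])
            + ("..." if len(skipped) > 5 else "")
        )
    if not seqs:
        raise ValueError(f"no valid A/C/G/T records in {path}")
    if len({len(s) for s in seqs}) > 1:
        warnings.warn(f"{path} contains sequences of mixed lengths")
    return ids, seqs


def write_fasta(path: str | Path, ids: Sequence[str], sequences: Sequence[str]) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in zip(ids, sequences)]
    SeqIO.write(records, str(path), "fasta")


def read_scores(path: str | Path, fmt: str = "auto") -> dict[str, float]:
    """Peak scores as an id -> score mapping from TSV (id, score) or BED.

    BED is interpreted as standard 0-based half-open intervals; only the
    name (column 4) and score (column 5) fields are consumed.  Scores must
    be positive; duplicates and non-numeric entries raise with the line
    named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "bed" if path.suffix.lower() == ".bed" else "tsv"
    scores: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if fmt == "tsv":
                if lineno == 1 and not _is_number(parts[-1]):
                    continue  # header
                name, raw = parts[0], parts[1]
            else:
                if len(parts) < 5:
                    raise ValueError(f"{path}:{lineno}: BED needs >= 5 columns for a score")
                name, raw = parts[3], parts[4]
            try:
                val = float(raw)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric score {raw!r}") from None
            if val <= 0:
                raise ValueError(f"{path}:{lineno}: nonpositive score for {name!r}")
            if name in scores:
                raise ValueError(f"{path}:{lineno}: duplicate id {name!r}")
            scores[name] = val
    if not scores:
        raise ValueError(f"no scores found in {path}")
    return scores


def _is_number(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False


def rank_and_split(
    ids: Sequence[str],
    sequences: Sequence[str],
    scores: dict[str, float],
    n_train: int,
) -> tuple[tuple[list[str], list[str]], tuple[list[str], list[str]]]:
    """Split into a training set of the n_train highest-scoring sequences
    and a control set of the rest.  Ties at the boundary keep input order."""
    if n_train <= 0:
        raise ValueError("n_train must be positive")
    if n_train > len(ids):
        raise ValueError(f"n_train={n_train} exceeds the {len(ids)} scored sequences")
    missing = [i for i in ids if i not in scores]
    if missing:
        raise ValueError(f"ids without scores: {missing[:5]}")
    vals = np.array([scores[i] for i in ids])
    order = np.argsort(-vals, kind="stable")
    tr = order[:n_train]
    ct = order[n_train:]
    pick = lambda idx: ([ids[i] for i in idx], [sequences[i] for i in idx])
    return pick(tr), pick(ct)


def write_motif_report(path: str | Path, report: pd.DataFrame) -> None:
    """Motif report TSV (motif, n, N, F, Q, minus_log10_P_Bonf, iteration),
    sorted by descending significance within iteration order."""
    df = report.sort_values(["iteration", "minus_log10_P_Bonf"], ascending=[True, False])
    df.to_csv(path, sep="\t", index=False)


def write_run_config(path: str | Path, params: dict, inputs: Sequence[str | Path] = ()) -> None:
    """Serialise the resolved run parameters with input checksums."""
    from . import __version__

    prov = {"version": __version__, "inputs": {}}
    for p in inputs:
        p = Path(p)
        if p.exists():
            prov["inputs"][str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    doc = {"params": params, "provenance": prov}
    Path(path).write_text(json.dumps(doc, indent=2, default=str))
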