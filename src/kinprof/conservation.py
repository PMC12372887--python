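"""Per-column residue conservation from a multiple sequence alignment.

Implements a deterministic, tree-free conservation scorer for kinase-domain
MSAs: Henikoff position-based sequence weighting, a weighted Jensen-Shannon
divergence of each column's residue distribution against a background
amino-acid distribution (scaled by the column's non-gap weight so gappy
columns cannot outrank full ones), a rank-based 1-9 grading (9 = most
conserved), a bootstrap low-confidence flag, pairwise identities to a
reference sequence, and mapping of alignment columns onto the reference's
author residue numbering.

The method tag ``jsd-henikoff-v1`` is recorded in every profile so that
grades produced by other scorers are never silently mixed with these.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

METHOD_TAG = "jsd-henikoff-v1"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

__all__ = [
    "MsaColumn",
    "ConservationProfile",
    "PairwiseIdentity",
    "MsaFormatError",
    "read_msa",
    "write_msa",
    "load_background",
    "sequence_weights",
    "column_scores",
    "grade_scores",
    "flag_confidence",
    "pairwise_identity",
    "map_to_reference",
    "compute_profile",
]


class MsaFormatError(ValueError):
    """Raised for ragged alignments, duplicate ids or too few sequences."""


@dataclass
class MsaColumn:
    column_index: int
    residue_counts: dict[str, float]
    n_nongap: int
    score: float
    grade: int
    low_confidence: bool = False


@dataclass
class PairwiseIdentity:
    query_id: str
    reference_id: str
    identity: float
    n_aligned: int


@dataclass
class ConservationProfile:
    """Scored, graded and reference-mapped conservation of one MSA."""

    msa_id: str
    columns: list[MsaColumn]
    reference_id: str = ""
    column_to_residue: dict[int, int] = field(default_factory=dict)
    method_tag: str = METHOD_TAG

    def by_residue(self) -> dict[int, MsaColumn]:
        """Mapping author residue number -> column, for mapped columns only."""
        return {
            resnum: self.columns[col]
            for col, resnum in self.column_to_residue.items()
        }

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for col in self.columns:
            rows.append(
                {
                    "column": col.column_index,
                    "residue_number": self.column_to_residue.get(col.column_index, ""),
                    "score": col.score,
                    "grade": col.grade,
                    "n_nongap": col.n_nongap,
                    "low_confidence": int(col.low_confidence),
                }
            )
        df = pd.DataFrame(rows)
        with open(path, "w") as fh:
            fh.write(f"# msa_id={self.msa_id} reference={self.reference_id} method={self.method_tag}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConservationProfile":
        meta = {"msa_id": "", "reference": "", "method": METHOD_TAG}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        columns = []
        mapping: dict[int, int] = {}
        for _, row in df.iterrows():
            ci = int(row["column"])
            columns.append(
                MsaColumn(
                    column_index=ci,
                    residue_counts={},
                    n_nongap=int(row["n_nongap"]),
                    score=float(row["score"]),
                    grade=int(row["grade"]),
                    low_confidence=bool(int(row["low_confidence"])),
                )
            )
            if str(row["residue_number"]).strip() not in ("", "nan"):
                mapping[ci] = int(float(row["residue_number"]))
        return cls(
            msa_id=meta["msa_id"],
            columns=columns,
            reference_id=meta["reference"],
            column_to_residue=mapping,
            method_tag=meta["method"],
        )


# ---------------------------------------------------------------------------
# MSA I/O
# ---------------------------------------------------------------------------

def read_msa(source: str | Path) -> MultipleSeqAlignment:
    """Read an aligned FASTA; '.' and '-' gaps both accepted, normalized to '-'.

    Requires >= 2 sequences of equal gapped length with unique ids.
    """
    records = list(SeqIO.parse(str(source), "fasta"))
    if len(records) < 2:
        raise MsaFormatError(f"{source}: alignment needs >= 2 sequences, found {len(records)}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise MsaFormatError(f"{source}: duplicate sequence ids {dupes}")
    length = len(records[0].seq)
    cleaned = []
    for rec in records:
        seq = str(rec.seq).upper().replace(".", GAP)
        if len(seq) != length:
            raise MsaFormatError(
                f"{source}: ragged alignment; sequence {rec.id!r} has length "
                f"{len(seq)}, expected {length}"
            )
        cleaned.append(SeqRecord(Seq(seq), id=rec.id, description=""))
    return MultipleSeqAlignment(cleaned)


def write_msa(alignment: MultipleSeqAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in alignment:
            fh.write(f">{rec.id}\n{str(rec.seq)}\n")


def _matrix(alignment: MultipleSeqAlignment) -> np.ndarray:
    """(n_seqs, n_cols) array of single characters."""
    return np.array([list(str(rec.seq)) for rec in alignment])


def load_background(source: str | Path | Mapping[str, float] | None = None) -> dict[str, float]:
    """Background amino-acid frequencies, normalized to sum 1.

    Defaults to the packaged Robinson-Robinson table.  Raises if any of the
    20 standard residues is missing.
    """
    if source is None:
        text = resources.files("kinprof.data").joinpath("background_frequencies.json").read_text()
        freqs = json.loads(text)["frequencies"]
    elif isinstance(source, Mapping):
        freqs = dict(source)
    else:
        freqs = json.loads(Path(source).read_text())["frequencies"]
    missing = [aa for aa in AMINO_ACIDS if aa not in freqs]
    if missing:
        raise ValueError(f"background frequencies missing amino acid(s) {missing}")
    total = float(sum(freqs[aa] for aa in AMINO_ACIDS))
    return {aa: float(freqs[aa]) / total for aa in AMINO_ACIDS}


# ---------------------------------------------------------------------------
# weighting and scoring
# ---------------------------------------------------------------------------

def _weight_vector(mat: np.ndarray) -> np.ndarray:
    """Henikoff-Henikoff position-based weights, normalized to sum 1.

    Each column contributes 1/(r * s) to a sequence holding one of s copies
    of a residue type, where r is the number of distinct (non-gap) types in
    the column; gap positions contribute nothing.
    """
    n_seqs, n_cols = mat.shape
    w = np.zeros(n_seqs)
    for j in range(n_cols):
        col = mat[:, j]
        nongap = col != GAP
        if not nongap.any():
            continue
        types, inverse, counts = np.unique(col[nongap], return_inverse=True, return_counts=True)
        r = len(types)
        contrib = 1.0 / (r * counts[inverse])
        w[nongap] += contrib
    if (w <= 0).any():
        bad = [int(i) for i in np.nonzero(w <= 0)[0]]
        raise ValueError(f"sequence(s) at index {bad} are fully gapped; cannot weight")
    return w / w.sum()


def sequence_weights(alignment: MultipleSeqAlignment) -> dict[str, float]:
    """Per-sequence Henikoff weights keyed by id; weights sum to 1."""
    w = _weight_vector(_matrix(alignment))
    return {rec.id: float(wi) for rec, wi in zip(alignment, w)}


def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in bits between two distributions."""
    m = 0.5 * (p + q)
    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))
    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def _score_vector(
    mat: np.ndarray, weights: np.ndarray, background: Mapping[str, float]
) -> np.ndarray:
    """Per-column conservation scores.

    score = JSD(column residue distribution, background) * (weighted non-gap
    fraction).  Non-standard residue codes are treated as gaps.  A fully
    gapped column scores exactly 0.
    """
    q = np.array([background[aa] for aa in AMINO_ACIDS])
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    n_seqs, n_cols = mat.shape
    scores = np.zeros(n_cols)
    for j in range(n_cols):
        col = mat[:, j]
        counts = np.zeros(len(AMINO_ACIDS))
        wsum = 0.0
        for ch, wi in zip(col, weights):
            idx = aa_index.get(ch)
            if idx is not None:
                counts[idx] += wi
                wsum += wi
        if wsum <= 0:
            continue
        p = counts / wsum
        scores[j] = _jsd(p, q) * wsum  # weights sum to 1 -> wsum is the non-gap fraction
    return scores


def column_scores(
    alignment: MultipleSeqAlignment,
    weights: Mapping[str, float] | None = None,
    background: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Conservation score per alignment column (higher = more conserved)."""
    mat = _matrix(alignment)
    if weights is None:
        wvec = _weight_vector(mat)
    else:
        wvec = np.array([weights[rec.id] for rec in alignment], dtype=float)
    bg = load_background(background)
    return _score_vector(mat, wvec, bg)


def grade_scores(scores: Sequence[float]) -> np.ndarray:
    """Map scores to 1-9 grades by splitting ranks into 9 equal-count bins.

    Grade 9 is the top-scoring bin, grade 1 the lowest.  Tied scores all
    share the grade of their first occurrence in rank order; if every score
    is identical, the neutral midpoint grade 5 is assigned throughout.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n == 0:
        return np.array([], dtype=int)
    if np.max(scores) - np.min(scores) <= 1e-300:
        return np.full(n, 5, dtype=int)
    order = np.argsort(scores, kind="stable")
    grades_sorted = 1 + (9 * np.arange(n)) // n
    # ties share the grade of their first occurrence in sorted order
    sorted_scores = scores[order]
    for i in range(1, n):
        if sorted_scores[i] == sorted_scores[i - 1]:
            grades_sorted[i] = grades_sorted[i - 1]
    grades = np.empty(n, dtype=int)
    grades[order] = grades_sorted
    return grades


def flag_confidence(
    alignment: MultipleSeqAlignment,
    grades: Sequence[int],
    n_bootstrap: int = 200,
    seed: int | None = None,
    background: Mapping[str, float] | None = None,
    min_nongap: int = 6,
    max_interval_width: float = 3.0,
) -> np.ndarray:
    """Low-confidence flags per column.

    A column is flagged iff fewer than ``min_nongap`` sequences carry a
    residue there, or the central 95% interval of its grade across
    ``n_bootstrap`` resamplings of the sequences (with replacement, seeded)
    is wider than ``max_interval_width`` grades.
    """
    if seed is None:
        raise ValueError("flag_confidence requires an explicit seed")
    if n_bootstrap < 50:
        raise ValueError("n_bootstrap must be >= 50")
    mat = _matrix(alignment)
    n_seqs, n_cols = mat.shape
    grades = np.asarray(grades, dtype=int)
    if len(grades) != n_cols:
        raise ValueError("grades length does not match alignment width")
    bg = load_background(background)
    rng = np.random.default_rng(seed)

    boot = np.empty((n_bootstrap, n_cols), dtype=int)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n_seqs, size=n_seqs)
        sub = mat[idx]
        try:
            w = _weight_vector(sub)
        except ValueError:  # a resample can strand a fully gapped pseudo-sequence
            w = np.full(n_seqs, 1.0 / n_seqs)
        boot[b] = grade_scores(_score_vector(sub, w, bg))

    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    n_nongap = (mat != GAP).sum(axis=0)
    return (n_nongap < min_nongap) | ((hi - lo) > max_interval_width)


# ---------------------------------------------------------------------------
# identities and reference mapping
# ---------------------------------------------------------------------------

def pairwise_identity(
    alignment: MultipleSeqAlignment, reference_id: str
) -> list[PairwiseIdentity]:
    """Percent identity of every other sequence to the reference.

    Identity counts only columns where both sequences are non-gap.
    """
    seqs = {rec.id: np.array(list(str(rec.seq))) for rec in alignment}
    if reference_id not in seqs:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    ref = seqs[reference_id]
    out = []
    for qid, q in seqs.items():
        if qid == reference_id:
            continue
        both = (ref != GAP) & (q != GAP)
        n_aligned = int(both.sum())
        if n_aligned == 0:
            warnings.warn(f"{qid!r} shares no non-gap columns with {reference_id!r}; skipped")
            continue
        matches = int((ref[both] == q[both]).sum())
        out.append(
            PairwiseIdentity(
                query_id=qid,
                reference_id=reference_id,
                identity=100.0 * matches / n_aligned,
                n_aligned=n_aligned,
            )
        )
    return out


def map_to_reference(
    alignment: MultipleSeqAlignment, reference_id: str, first_residue_number: int
) -> dict[int, int]:
    """Alignment column -> author residue number along the reference row.

    The k-th non-gap reference position maps to ``first_residue_number + k - 1``;
    columns where the reference is gapped are unmapped.
    """
    ref = None
    for rec in alignment:
        if rec.id == reference_id:
            ref = str(rec.seq)
            break
    if ref is None:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    mapping: dict[int, int] = {}
    resnum = first_residue_number
    for col, ch in enumerate(ref):
        if ch != GAP:
            mapping[col] = resnum
            resnum += 1
    return mapping


def compute_profile(
    alignment: MultipleSeqAlignment,
    reference_id: str,
    first_residue_number: int,
    seed: int,
    msa_id: str = "",
    background: Mapping[str, float] | None = None,
    n_bootstrap: int = 200,
) -> ConservationProfile:
    """Full conservation pipeline: weights -> scores -> grades -> flags -> mapping."""
    mat = _matrix(alignment)
    bg = load_background(background)
    wvec = _weight_vector(mat)
    scores = _score_vector(mat, wvec, bg)
    grades = grade_scores(scores)
    flags = flag_confidence(
        alignment, grades, n_bootstrap=n_bootstrap, seed=seed, background=bg
    )
    n_nongap = (mat != GAP).sum(axis=0)
    columns = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        counts: dict[str, float] = {}
        for ch, wi in zip(col, wvec):
            if ch in AMINO_ACIDS:
                counts[ch] = counts.get(ch, 0.0) + float(wi)
        columns.append(
            MsaColumn(
                column_index=j,
                residue_counts=counts,
                n_nongap=int(n_nongap[j]),
                score=float(scores[j]),
                grade=int(grades[j]),
                low_confidence=bool(flags[j]),
            )
        )
    mapping = map_to_reference(alignment, reference_id, first_residue_number)
    return ConservationProfile(
        msa_id=msa_id,
        columns=columns,
        reference_id=reference_id,
        column_to_residue=mapping,
        method_tag=METHOD_TAG,
    )
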