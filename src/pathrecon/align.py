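"""Deterministic pairwise protein alignment backend.

Reciprocal-best-hit annotation needs local alignment statistics
(identity, query coverage, bit score, E-value) for protein pairs.  The
built-in backend is Smith-Waterman via Biopython's ``PairwiseAligner``
with BLOSUM62, gap open 11 / extend 1, so results are reproducible
without an external aligner.  E-values use the standard Karlin-Altschul
approximation E = m * n * K * exp(-lambda * S) with the BLAST gapped
BLOSUM62(11,1) constants lambda = 0.267, K = 0.041; search-space sizes
are the plain sequence lengths (no edge-effect correction).  An adapter
for BLAST tabular (outfmt 6) files is provided for hits produced by an
external BLASTp run on real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignParams",
    "AlignmentHit",
    "PairwiseBackend",
    "align_pair",
    "raw_score",
    "self_bitscore",
    "read_blast_tabular",
]

#: 20 standard residues plus X (unknown).
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for the built-in Smith-Waterman backend."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    # Karlin-Altschul constants for gapped BLOSUM62(11,1).
    lambda_: float = 0.267
    k: float = 0.041


@dataclass(frozen=True)
class AlignmentHit:
    """Local alignment statistics for one (query, subject) pair."""

    query_id: str
    subject_id: str
    evalue: float
    identity_pct: float
    coverage_pct: float
    bitscore: float
    raw_score: float = 0.0
    length: int = 0  # aligned columns, gaps included

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0 and 0.0 <= self.coverage_pct <= 100.0):
            raise ValueError("identity/coverage percentages must lie in [0, 100]")
        if self.evalue < 0 or not math.isfinite(self.bitscore):
            raise ValueError("evalue must be >= 0 and bitscore finite")


def _check_sequence(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq.upper()) - VALID_RESIDUES
    if bad:
        raise ValueError(f"{label}: invalid residue characters {sorted(bad)}")


class PairwiseBackend:
    """Smith-Waterman alignment with Karlin-Altschul statistics.

    The backend is deterministic: when several optimal local alignments
    exist, the aligner's first traceback is used.
    """

    def __init__(self, params: AlignParams | None = None) -> None:
        self.params = params or AlignParams()
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = substitution_matrices.load(self.params.matrix)
        self._aligner.open_gap_score = -self.params.gap_open
        self._aligner.extend_gap_score = -self.params.gap_extend

    def bitscore(self, raw: float) -> float:
        p = self.params
        return (p.lambda_ * raw - math.log(p.k)) / math.log(2.0)

    def evalue(self, raw: float, m: int, n: int) -> float:
        p = self.params
        return m * n * p.k * math.exp(-p.lambda_ * raw)

    def score(self, a: str, b: str) -> float:
        """Raw optimal local alignment score (fast, no traceback)."""
        return float(self._aligner.score(a.upper(), b.upper()))

    def align(
        self, a: str, b: str, query_id: str = "query", subject_id: str = "subject"
    ) -> AlignmentHit | None:
        """Full alignment statistics, or None when no local alignment
        scores above zero."""
        _check_sequence(a, query_id)
        _check_sequence(b, subject_id)
        a, b = a.upper(), b.upper()
        raw = self.score(a, b)
        if raw <= 0:
            return None
        aln = self._aligner.align(a, b)[0]
        counts = aln.counts()
        ncols = counts.identities + counts.mismatches + counts.gaps
        q_start, q_end = aln.aligned[0][0][0], aln.aligned[0][-1][1]
        return AlignmentHit(
            query_id=query_id,
            subject_id=subject_id,
            evalue=self.evalue(raw, len(a), len(b)),
            identity_pct=100.0 * counts.identities / ncols,
            coverage_pct=100.0 * (q_end - q_start) / len(a),
            bitscore=self.bitscore(raw),
            raw_score=raw,
            length=int(ncols),
        )


@lru_cache(maxsize=4)
def _default_backend(params: AlignParams = AlignParams()) -> PairwiseBackend:
    return PairwiseBackend(params)


def align_pair(
    a: str,
    b: str,
    params: AlignParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit | None:
    """Align two protein sequences and return local alignment statistics
    (None when nothing scores above zero)."""
    return _default_backend(params or AlignParams()).align(a, b, query_id, subject_id)


def raw_score(a: str, b: str, params: AlignParams | None = None) -> float:
    return _default_backend(params or AlignParams()).score(a, b)


def self_bitscore(seq: str, params: AlignParams | None = None) -> float:
    """Bit score of a sequence aligned against itself (the match-score
    normaliser)."""
    backend = _default_backend(params or AlignParams())
    return backend.bitscore(backend.score(seq, seq))


_BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tabular(path, query_lengths: dict[str, int] | None = None) -> list[AlignmentHit]:
    """Read BLAST tabular (outfmt 6) hits.

    Accepts the standard 12 columns, optionally followed by a 13th
    ``qcovs`` column.  Without ``qcovs``, query coverage is computed as
    (qend - qstart + 1) / query length, which requires *query_lengths*.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == len(_BLAST6_COLUMNS) + 1:
        df.columns = _BLAST6_COLUMNS + ["qcovs"]
    elif df.shape[1] == len(_BLAST6_COLUMNS):
        df.columns = _BLAST6_COLUMNS
        if query_lengths is None:
            raise ValueError(
                "12-column BLAST tabular input requires query_lengths to compute coverage"
            )
        df["qcovs"] = [
            100.0 * (row.qend - row.qstart + 1) / query_lengths[row.qseqid]
            for row in df.itertuples()
        ]
    else:
        raise ValueError(f"expected 12 or 13 tab-separated columns, got {df.shape[1]}")
    return [
        AlignmentHit(
            query_id=str(row.qseqid),
            subject_id=str(row.sseqid),
            evalue=float(row.evalue),
            identity_pct=float(row.pident),
            coverage_pct=float(row.qcovs),
            bitscore=float(row.bitscore),
            length=int(row.length),
        )
        for row in df.itertuples()
    ]
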