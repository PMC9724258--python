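"""Pairwise and group sequence similarity on a 0-1000 scale.

Similarity between two DNA sequences is the identity fraction over the
columns of one optimal global alignment, scaled so that identical sequences
score 1000.  The scale follows the convention of consistency-based multiple
aligners: 700-1000 high similarity, 400-699 moderate, below 400 low.  Group
statistics (intra-group mean, representative species) and the family-merge
decision used during re-grouping live here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

HIGH_SIMILARITY_FLOOR = 700
MODERATE_SIMILARITY_FLOOR = 400


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment scoring parameters (standard DNA defaults)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


DEFAULT_ALIGNMENT = AlignmentParams()


def classify_score(value: int) -> str:
    """Bucket a 0-1000 similarity score as high / moderate / low."""
    if not 0 <= value <= 1000:
        raise ValueError(f"score out of range: {value}")
    if value >= HIGH_SIMILARITY_FLOOR:
        return "high"
    if value >= MODERATE_SIMILARITY_FLOOR:
        return "moderate"
    return "low"


@lru_cache(maxsize=8)
def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def pairwise_similarity(
    seq_a: str,
    seq_b: str,
    params: AlignmentParams = DEFAULT_ALIGNMENT,
    *,
    gap_free: bool = False,
) -> int:
    """Identity-fraction similarity of two sequences, scaled to 0-1000.

    One optimal global alignment is computed (first co-optimal alignment,
    which is deterministic for fixed inputs and parameters) and the score is
    ``round(1000 * identities / alignment_columns)``.

    With ``gap_free=True`` the sequences must have equal length and identity
    is counted position-by-position (Hamming), which makes the score exactly
    monotone in the number of substitutions.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_similarity requires non-empty sequences")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if seq_a == seq_b:
        return 1000
    if gap_free:
        if len(seq_a) != len(seq_b):
            raise ValueError("gap_free similarity requires equal-length sequences")
        matches = sum(a == b for a, b in zip(seq_a, seq_b))
        return round(1000 * matches / len(seq_a))
    # Canonical argument order: co-optimal alignments of (a, b) and (b, a)
    # can differ in column count, so the score is defined on the sorted pair
    # to make it exactly symmetric.
    if seq_a > seq_b:
        seq_a, seq_b = seq_b, seq_a
    alignment = _aligner(params).align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return round(1000 * counts.identities / alignment.length)


@dataclass
class GroupSimilarityStats:
    """Pairwise-score matrix and summary for one group of sequences."""

    group_id: str
    segment_kind: str  # L-tRNA | COI | R-tRNA | F-primer | R-primer
    accessions: list[str]
    pair_matrix: np.ndarray
    intra_mean: int
    representative: str


def group_similarity(
    sequences: Mapping[str, str] | Sequence[str],
    group_id: str = "",
    segment_kind: str = "COI",
    params: AlignmentParams = DEFAULT_ALIGNMENT,
) -> GroupSimilarityStats:
    """Average pairwise similarity of a group plus its representative member.

    ``intra_mean`` is the mean over all unordered distinct pairs (1000 by
    convention for singletons).  The representative is the member with the
    highest row-mean of the pair matrix; ties break on the smallest
    accession so the choice is reproducible.
    """
    if isinstance(sequences, Mapping):
        items = sorted(sequences.items())
    else:
        items = [(f"seq{i:04d}", s) for i, s in enumerate(sequences)]
    if not items:
        raise ValueError("group_similarity requires a non-empty group")
    accs = [a for a, _ in items]
    seqs = [s for _, s in items]
    m = len(items)
    matrix = np.full((m, m), 1000, dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            s = pairwise_similarity(seqs[i], seqs[j], params)
            matrix[i, j] = matrix[j, i] = s
    if m == 1:
        intra = 1000
    else:
        iu = np.triu_indices(m, k=1)
        intra = round(float(matrix[iu].mean()))
    row_means = matrix.mean(axis=1)
    best = min(range(m), key=lambda i: (-row_means[i], accs[i]))
    return GroupSimilarityStats(
        group_id=group_id,
        segment_kind=segment_kind,
        accessions=accs,
        pair_matrix=matrix,
        intra_mean=intra,
        representative=accs[best],
    )


@dataclass(frozen=True)
class MergeDecision:
    """Outcome of testing whether two groups should be combined.

    Two groups merge when pooling the candidate group barely moves the
    intra-group COI similarity (drop of at most ``delta`` points) and the
    pooled group still sits in the high-similarity band (``theta`` floor).
    """

    group_a: str
    group_b: str
    score_before: int
    score_after: int
    merged: bool

    @property
    def delta(self) -> int:
        return self.score_before - self.score_after


DEFAULT_MERGE_DELTA = 30
DEFAULT_MERGE_THETA = HIGH_SIMILARITY_FLOOR


def evaluate_merge(
    group_a: Mapping[str, str],
    group_b: Mapping[str, str],
    group_a_id: str = "a",
    group_b_id: str = "b",
    delta: int = DEFAULT_MERGE_DELTA,
    theta: int = DEFAULT_MERGE_THETA,
    params: AlignmentParams = DEFAULT_ALIGNMENT,
) -> MergeDecision:
    """Decide whether group_b (the closest related group) joins group_a.

    Both arguments map accession to COI sequence.  ``score_before`` is the
    intra-group mean of group_a alone, ``score_after`` that of the union.
    """
    if not group_a or not group_b:
        raise ValueError("evaluate_merge requires non-empty groups")
    before = group_similarity(group_a, group_a_id, "COI", params).intra_mean
    union = dict(group_a)
    union.update(group_b)
    after = group_similarity(union, f"{group_a_id}+{group_b_id}", "COI", params).intra_mean
    merged = (before - after) <= delta and after >= theta
    return MergeDecision(group_a_id, group_b_id, before, after, merged)


def matrix_to_tsv(stats: GroupSimilarityStats, path) -> None:
    """Write the pairwise score matrix as accession x accession TSV."""
    import pandas as pd

    pd.DataFrame(stats.pair_matrix, index=stats.accessions, columns=stats.accessions).to_csv(
        path, sep="\t"
    )
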