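"""Primer candidate enumeration, scoring and pair assembly.

Candidates are every substring window of a flanking tRNA segment between the
minimum and maximum primer length that survives the hard filters (no N, no
long homopolymer, GC within bounds, no long self-complementary run).  Each
survivor gets a non-negative penalty combining distance from the optimum
length, melting temperature, GC content and the absence of a 3' G/C clamp;
ranking is by ascending penalty with deterministic tie-breaks.

Forward primers are windows of the upstream (left) segment read 5'->3' on
the reference strand; reverse primers are windows of the reverse complement
of the downstream (right) segment, so an assembled pair brackets the COI
locus in amplifiable orientation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from functools import lru_cache

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerConstraints:
    """Hard filters and optima for single-primer selection.

    Length bounds follow the standard barcode-primer setting of 18-26 nt
    with a 21 nt optimum.  Set ``gc_range=(0, 1)``, ``max_homopolymer=None``
    and ``max_self_complement_run=None`` to disable the respective filters.
    """

    min_len: int = 18
    max_len: int = 26
    opt_len: int = 21
    tm_range: tuple[float, float] = (50.0, 65.0)
    tm_opt: float = 57.5
    gc_range: tuple[float, float] = (0.30, 0.70)
    max_homopolymer: int | None = 4
    max_self_complement_run: int | None = 8
    require_no_n: bool = True
    # penalty weights
    w_len: float = 1.0
    w_tm: float = 1.0
    w_gc: float = 2.0
    w_clamp: float = 3.0
    w_pair_tm: float = 1.0

    def __post_init__(self) -> None:
        if not self.min_len <= self.opt_len <= self.max_len:
            raise ValueError(
                f"need min_len <= opt_len <= max_len, got {self.min_len}/{self.opt_len}/{self.max_len}"
            )

    def relaxed(self) -> "PrimerConstraints":
        """Copy with every hard filter disabled (length bounds kept)."""
        return replace(
            self,
            gc_range=(0.0, 1.0),
            max_homopolymer=None,
            max_self_complement_run=None,
            require_no_n=False,
        )


DEFAULT_CONSTRAINTS = PrimerConstraints()


@dataclass(frozen=True)
class PrimerCandidate:
    sequence: str  # 5'->3' as synthesised
    source_side: str  # L | R
    source_rank: int  # 1-based rank of the flank segment the window came from
    offset: int  # 0-based start within the enumerated strand of the segment
    orientation: str  # forward | reverse_complement
    penalty: float
    tm: float
    gc: float

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    f_primer: PrimerCandidate
    r_primer: PrimerCandidate
    pair_penalty: float
    rank: int = 0

    @property
    def key(self) -> tuple[str, str]:
        return (self.f_primer.sequence, self.r_primer.sequence)


@dataclass
class PairDesign:
    """Result of designing pairs for one species' flank set."""

    accession: str
    pairs: list[PrimerPair]
    missing_left: bool = False
    missing_right: bool = False

    @property
    def missing_flank(self) -> bool:
        return self.missing_left or self.missing_right


# ---------------------------------------------------------------------------
# Primer physics (simple closed-form models, exact for testing)


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str) -> float:
    """Wallace rule below 14 nt, marmur-like long-oligo formula otherwise."""
    gc = seq.count("G") + seq.count("C")
    if len(seq) < 14:
        at = seq.count("A") + seq.count("T")
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def longest_homopolymer(seq: str) -> int:
    return max(len(list(g)) for _, g in itertools.groupby(seq)) if seq else 0


@lru_cache(maxsize=65536)
def longest_self_complementary_run(seq: str) -> int:
    """Length of the longest substring whose reverse complement also occurs.

    A cheap, deterministic stand-in for dimer/hairpin screening: a primer
    that contains a long inverted repeat can fold or dimerise.  Classic
    longest-common-substring DP between the primer and its reverse
    complement; primers are short so the quadratic sweep is cheap, and
    overlapping windows repeat across related species so results are memoised.
    """
    n = len(seq)
    rc = reverse_complement(seq)
    best = 0
    prev = [0] * (n + 1)
    for a in seq:
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            if a == rc[j - 1]:
                v = prev[j - 1] + 1
                cur[j] = v
                if v > best:
                    best = v
        prev = cur
    return best


def passes_filters(seq: str, constraints: PrimerConstraints) -> bool:
    if constraints.require_no_n and "N" in seq:
        return False
    lo, hi = constraints.gc_range
    if not lo <= gc_fraction(seq) <= hi:
        return False
    if constraints.max_homopolymer is not None and longest_homopolymer(seq) > constraints.max_homopolymer:
        return False
    if (
        constraints.max_self_complement_run is not None
        and longest_self_complementary_run(seq) > constraints.max_self_complement_run
    ):
        return False
    return True


def score_candidate(seq: str, constraints: PrimerConstraints) -> float:
    """Penalty of one primer: weighted distance from the optima.

    penalty = w_len*|len - opt_len| + w_tm*|tm - tm_opt|
            + w_gc*(distance of GC fraction to the GC band)
            + w_clamp*(1 if the 3' base is not G/C)
    """
    tm = melting_temperature(seq)
    gc = gc_fraction(seq)
    lo, hi = constraints.gc_range
    gc_dist = max(0.0, lo - gc, gc - hi)
    clamp = 0.0 if seq[-1] in "GC" else 1.0
    return (
        constraints.w_len * abs(len(seq) - constraints.opt_len)
        + constraints.w_tm * abs(tm - constraints.tm_opt)
        + constraints.w_gc * gc_dist
        + constraints.w_clamp * clamp
    )


def enumerate_candidates(
    segment: str,
    constraints: PrimerConstraints = DEFAULT_CONSTRAINTS,
    orientation: str = "forward",
    source_side: str = "L",
    source_rank: int = 1,
) -> list[PrimerCandidate]:
    """All window candidates of one segment, filtered, scored and ranked.

    For ``orientation="reverse_complement"`` the windows are taken from the
    reverse complement of the segment (offsets refer to that strand).  Sort
    order: ascending penalty, then (offset, length).
    """
    if orientation not in ("forward", "reverse_complement"):
        raise ValueError(f"unknown orientation {orientation!r}")
    strand = segment.upper() if orientation == "forward" else reverse_complement(segment.upper())
    out = []
    for length in range(constraints.min_len, constraints.max_len + 1):
        for offset in range(0, len(strand) - length + 1):
            window = strand[offset : offset + length]
            if not passes_filters(window, constraints):
                continue
            out.append(
                PrimerCandidate(
                    sequence=window,
                    source_side=source_side,
                    source_rank=source_rank,
                    offset=offset,
                    orientation=orientation,
                    penalty=score_candidate(window, constraints),
                    tm=melting_temperature(window),
                    gc=gc_fraction(window),
                )
            )
    out.sort(key=lambda c: (c.penalty, c.offset, len(c)))
    return out


def pair_penalty(f: PrimerCandidate, r: PrimerCandidate, constraints: PrimerConstraints) -> float:
    return f.penalty + r.penalty + constraints.w_pair_tm * abs(f.tm - r.tm)


def design_pairs(
    flanks,
    constraints: PrimerConstraints = DEFAULT_CONSTRAINTS,
    top_n: int = 5,
    per_side: int | None = None,
) -> PairDesign:
    """Assemble ranked primer pairs for one species.

    Uses the outermost available segment on each side (the segment at the
    requested extension depth): designing at depth k means designing inside
    the k-th nearest tRNA, not across all of them.  Up to ``per_side``
    (default ``top_n``) best candidates per side form a Cartesian product
    ranked by pair penalty; the top ``top_n`` pairs are returned with
    1-based ranks.  A side with no usable segment yields a missing-flank
    result rather than an error, so the pipeline can escalate.
    """
    per_side = per_side or top_n
    missing_left = not flanks.left_segments
    missing_right = not flanks.right_segments
    if missing_left or missing_right:
        return PairDesign(flanks.accession, [], missing_left, missing_right)
    left = flanks.left_segments[-1]
    right = flanks.right_segments[-1]
    rank_used = len(flanks.left_segments)
    fwd = enumerate_candidates(left, constraints, "forward", "L", rank_used)[:per_side]
    rev = enumerate_candidates(
        right, constraints, "reverse_complement", "R", len(flanks.right_segments)
    )[:per_side]
    if not fwd or not rev:
        return PairDesign(flanks.accession, [], not fwd, not rev)
    pairs = [
        PrimerPair(f, r, pair_penalty(f, r, constraints))
        for f, r in itertools.product(fwd, rev)
    ]
    pairs.sort(
        key=lambda p: (
            p.pair_penalty,
            p.f_primer.offset,
            len(p.f_primer),
            p.r_primer.offset,
            len(p.r_primer),
        )
    )
    ranked = [replace(p, rank=i) for i, p in enumerate(pairs[:top_n], start=1)]
    return PairDesign(flanks.accession, ranked)
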