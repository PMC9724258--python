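"""In-silico PCR: primer mapping, amplicon prediction, exclusivity, cover.

A primer matches a genome site when it aligns end-to-end (no indels) with at
most ``max_mm`` mismatches and its three 3'-terminal bases match exactly --
polymerase extension is far more sensitive to 3' mismatches than to internal
ones, which is also why short-read mappers tolerate internal mismatches.
Both strands are scanned and circular genomes are scanned across the origin.

An amplicon is a plus-strand forward-primer site paired with a minus-strand
reverse-primer site downstream of it (modulo the origin on circles) whose
product length falls inside configured bounds.  A primer pair is *exclusive*
for a group when it amplifies at least one group member and no genome
outside the group.  Minimal multi-pair coverage of a multispecies group is
the classic greedy set cover with deterministic tie-breaks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .primers import PrimerPair, reverse_complement
from .records import MitogenomeRecord

THREE_PRIME_EXACT = 3  # 3'-terminal bases that must match exactly

_BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class MatchSite:
    accession: str
    position: int  # 0-based start of the matched window on the reference strand
    strand: int  # +1: primer equals the window; -1: primer equals its reverse complement
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    accession: str
    f_site: MatchSite
    r_site: MatchSite
    product_length: int


@dataclass
class ExclusivityReport:
    group_id: str
    pair: PrimerPair
    matched_in_group: set[str]
    matched_out_group: set[str]

    @property
    def exclusive(self) -> bool:
        return bool(self.matched_in_group) and not self.matched_out_group


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _window_mismatches(genome: np.ndarray, primer: np.ndarray) -> np.ndarray:
    """Mismatch count of the primer against every window (vectorised)."""
    m = len(primer)
    windows = np.lib.stride_tricks.sliding_window_view(genome, m)
    return (windows != primer).sum(axis=1)


def _scan_one_strand(
    seq: str, primer: str, max_mm: int, three_prime_at_end: bool, circular: bool
) -> list[tuple[int, int]]:
    """(position, mismatches) of end-to-end matches of primer on seq.

    ``three_prime_at_end`` says whether the primer's 3' terminus maps to the
    rightmost (plus-strand primer) or leftmost (minus-strand primer) bases of
    the window.
    """
    n, m = len(seq), len(primer)
    if m == 0:
        raise ValueError("empty primer")
    if m > n:
        return []
    scan = seq + seq[: m - 1] if circular and n > m else seq
    g = _encode(scan)
    p = _encode(primer)
    diff = np.lib.stride_tricks.sliding_window_view(g, m) != p
    mm = diff.sum(axis=1)
    k = min(THREE_PRIME_EXACT, m)
    # 3'-exact anchor: zero mismatches allowed over the k anchor positions.
    anchor_ok = ~diff[:, m - k :].any(axis=1) if three_prime_at_end else ~diff[:, :k].any(axis=1)
    hits = np.flatnonzero((mm <= max_mm) & anchor_ok)
    out = []
    for pos in hits.tolist():
        if pos < n:  # positions >= n are duplicates of the wrapped prefix
            out.append((pos, int(mm[pos])))
    return out


def find_matches(primer: str, genome: MitogenomeRecord, max_mm: int = 0) -> list[MatchSite]:
    """All sites where the primer anneals on either strand of a genome.

    Plus-strand sites are windows equal to the primer (up to ``max_mm``
    internal mismatches, 3'-terminal bases exact); minus-strand sites are
    windows equal to the primer's reverse complement, with the exact-match
    anchor therefore at the window's left end.  Positions are 0-based window
    starts on the reference strand; circular genomes are scanned across the
    origin and positions reported modulo the genome length.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    primer = primer.upper()
    # Per-record memo: the same primer is rescanned many times during cover
    # eligibility screening (top pairs share forward/reverse candidates).
    cache = genome.__dict__.setdefault("_match_cache", {})
    key = (primer, max_mm)
    hit = cache.get(key)
    if hit is not None:
        return hit
    circular = genome.topology == "circular"
    sites = [
        MatchSite(genome.accession, pos, 1, mm)
        for pos, mm in _scan_one_strand(genome.sequence, primer, max_mm, True, circular)
    ]
    rc = reverse_complement(primer)
    sites += [
        MatchSite(genome.accession, pos, -1, mm)
        for pos, mm in _scan_one_strand(genome.sequence, rc, max_mm, False, circular)
    ]
    sites.sort(key=lambda s: (s.position, -s.strand))
    cache[key] = sites
    return sites


@dataclass(frozen=True)
class ProductBounds:
    min_product: int = 200
    max_product: int = 3000


DEFAULT_BOUNDS = ProductBounds()


def predict_amplicons(
    pair: PrimerPair,
    genome: MitogenomeRecord,
    max_mm: int = 0,
    bounds: ProductBounds = DEFAULT_BOUNDS,
) -> list[Amplicon]:
    """All products the pair would amplify from one genome.

    The forward primer must sit on the plus strand, the reverse primer on
    the minus strand downstream of it; the product runs from the forward
    window start to the reverse window end.  On circular genomes the product
    may span the origin.
    """
    f_sites = [s for s in find_matches(pair.f_primer.sequence, genome, max_mm) if s.strand == 1]
    if not f_sites:
        return []
    r_sites = [s for s in find_matches(pair.r_primer.sequence, genome, max_mm) if s.strand == -1]
    if not r_sites:
        return []
    n = len(genome)
    circular = genome.topology == "circular"
    out = []
    for f, r in itertools.product(f_sites, r_sites):
        r_end = r.position + len(pair.r_primer.sequence)
        if circular:
            product = (r_end - f.position) % n
            if product == 0:
                product = n
        else:
            product = r_end - f.position
        inner_gap = product - len(pair.f_primer.sequence) - len(pair.r_primer.sequence)
        if inner_gap < 0:
            continue  # primers overlap or reversed orientation (linear)
        if bounds.min_product <= product <= bounds.max_product:
            out.append(Amplicon(genome.accession, f, r, product))
    out.sort(key=lambda a: (a.f_site.position, a.r_site.position))
    return out


def amplifies(
    pair: PrimerPair, genome: MitogenomeRecord, max_mm: int = 0, bounds: ProductBounds = DEFAULT_BOUNDS
) -> bool:
    return bool(predict_amplicons(pair, genome, max_mm, bounds))


def classify_exclusivity(
    group_accessions: Iterable[str],
    pair: PrimerPair,
    universe: Sequence[MitogenomeRecord],
    max_mm: int = 0,
    bounds: ProductBounds = DEFAULT_BOUNDS,
    group_id: str = "",
) -> ExclusivityReport:
    """Screen one pair against every genome and split hits by group membership.

    A pair that amplifies nothing inside its own group is non-exclusive by
    definition: a barcode primer must amplify its targets.
    """
    members = set(group_accessions)
    matched_in, matched_out = set(), set()
    for rec in universe:
        if amplifies(pair, rec, max_mm, bounds):
            (matched_in if rec.accession in members else matched_out).add(rec.accession)
    return ExclusivityReport(group_id, pair, matched_in, matched_out)


@dataclass
class CoverResult:
    """Outcome of greedy minimal-pair coverage of a multispecies group."""

    selected: list[ExclusivityReport] = field(default_factory=list)
    covered: set[str] = field(default_factory=set)
    residual: set[str] = field(default_factory=set)
    assignment: dict[str, PrimerPair] = field(default_factory=dict)


def minimal_pair_cover(
    group_accessions: Iterable[str],
    candidate_pairs: Mapping[str, Sequence[PrimerPair]],
    universe: Sequence[MitogenomeRecord],
    max_mm: int = 0,
    bounds: ProductBounds = DEFAULT_BOUNDS,
    group_id: str = "",
    eligible_scope: set[str] | None = None,
) -> CoverResult:
    """Greedy set cover of a group by exclusive primer pairs.

    Only pairs exclusive to the group are eligible (``eligible_scope`` can
    widen the tolerated amplification set, e.g. at stage 2 where a residual
    pair may also hit its original group).  Repeatedly selects the eligible
    pair amplifying the most still-uncovered members; ties prefer the lower
    pair penalty, then the lexicographically smallest forward sequence.
    Species no selected pair amplifies come back as residuals.
    """
    members = set(group_accessions)
    reports = []
    seen_keys = set()
    for acc in sorted(candidate_pairs):
        for pair in candidate_pairs[acc]:
            if pair.key in seen_keys:
                continue
            seen_keys.add(pair.key)
            rep = classify_exclusivity(members, pair, universe, max_mm, bounds, group_id)
            if eligible_scope is not None:
                # tolerate amplification inside the widened scope
                rep.matched_out_group -= eligible_scope
            if rep.exclusive:
                reports.append(rep)
    result = CoverResult(residual=set(members))
    while result.residual:
        best = None
        for rep in reports:
            gain = len(rep.matched_in_group & result.residual)
            if gain == 0:
                continue
            key = (-gain, rep.pair.pair_penalty, rep.pair.f_primer.sequence, rep.pair.r_primer.sequence)
            if best is None or key < best[0]:
                best = (key, rep)
        if best is None:
            break
        rep = best[1]
        result.selected.append(rep)
        newly = rep.matched_in_group & result.residual
        for acc in newly:
            result.assignment[acc] = rep.pair
        result.covered |= newly
        result.residual -= newly
    return result


def exhaustive_pair_cover(
    group_accessions: Iterable[str],
    candidate_pairs: Mapping[str, Sequence[PrimerPair]],
    universe: Sequence[MitogenomeRecord],
    max_mm: int = 0,
    bounds: ProductBounds = DEFAULT_BOUNDS,
) -> list[PrimerPair] | None:
    """Smallest exclusive cover by exhaustive search (oracle for tiny inputs)."""
    members = set(group_accessions)
    eligible = []
    seen = set()
    for acc in sorted(candidate_pairs):
        for pair in candidate_pairs[acc]:
            if pair.key in seen:
                continue
            seen.add(pair.key)
            rep = classify_exclusivity(members, pair, universe, max_mm, bounds)
            if rep.exclusive:
                eligible.append((pair, frozenset(rep.matched_in_group)))
    for size in range(1, len(eligible) + 1):
        for combo in itertools.combinations(eligible, size):
            covered = frozenset().union(*(c[1] for c in combo))
            if covered == members:
                return [c[0] for c in combo]
    return None
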