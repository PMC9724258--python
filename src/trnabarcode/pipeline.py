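"""Two-stage orchestration of family-exclusive barcode primer discovery.

Stage 1 clusters the universe at the taxonomic family level, designs primer
pairs inside the nearest flanking tRNAs of each member (cycling through
ranked candidates), and resolves multispecies groups with a greedy minimal
exclusive-pair cover.  Escalation then runs in a fixed order, each step
touching only what the previous step left behind:

1. wholly unresolved groups re-design on the next outward tRNA segment
   (flank extension, bounded depth);
2. groups still unresolved are tested for merging with their closest related
   group by COI similarity (re-grouping of likely misclassifications);
3. residual species -- members of partially covered groups, or of groups no
   family-level step could fix -- enter stage 2, where primers are designed
   per species and screened against the whole universe, allowing a pair to
   be shared by residuals of one group but never to amplify outside that
   group.

Species nothing can resolve are emitted with status ``unresolved`` rather
than dropped; the catalog always contains exactly one entry per input
genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import records as rec_mod
from .primers import DEFAULT_CONSTRAINTS, PrimerConstraints, PrimerPair, design_pairs
from .records import MissingCOIError, MitogenomeRecord, extract_flanks
from .screen import (
    DEFAULT_BOUNDS,
    CoverResult,
    ProductBounds,
    minimal_pair_cover,
)
from .similarity import (
    AlignmentParams,
    DEFAULT_ALIGNMENT,
    DEFAULT_MERGE_DELTA,
    DEFAULT_MERGE_THETA,
    MergeDecision,
    evaluate_merge,
    group_similarity,
    pairwise_similarity,
)


@dataclass(frozen=True)
class PipelineConfig:
    constraints: PrimerConstraints = DEFAULT_CONSTRAINTS
    bounds: ProductBounds = DEFAULT_BOUNDS
    max_mm: int = 0
    top_n: int = 5
    stage2_top_n: int = 20
    max_k: int = 2
    merge_delta: int = DEFAULT_MERGE_DELTA
    merge_theta: int = DEFAULT_MERGE_THETA
    alignment: AlignmentParams = DEFAULT_ALIGNMENT


DEFAULT_CONFIG = PipelineConfig()


@dataclass
class FamilyGroup:
    group_id: str
    family_ids: list[str]
    member_accessions: list[str]
    group_kind: str  # single-species | multispecies | multi-family
    status: str = "unresolved"  # exclusive | partially-non-exclusive | unresolved
    resolution: str | None = None  # stage1 | extension | regroup | stage2
    k_used: int = 1
    assignment: dict[str, PrimerPair] = field(default_factory=dict)
    assignment_stage: dict[str, int] = field(default_factory=dict)
    residual_reasons: dict[str, str] = field(default_factory=dict)
    merged_into: str | None = None

    @property
    def assigned_pairs(self) -> list[PrimerPair]:
        seen, out = set(), []
        for acc in sorted(self.assignment):
            pair = self.assignment[acc]
            if pair.key not in seen:
                seen.add(pair.key)
                out.append(pair)
        return out

    @property
    def primer_mode(self) -> str:
        return "multiple-pairs" if len(self.assigned_pairs) > 1 else "single-pair"

    @property
    def residuals(self) -> set[str]:
        return set(self.member_accessions) - set(self.assignment)


@dataclass(frozen=True)
class CatalogEntry:
    accession: str
    organism: str
    family_id: str | None
    group_id: str
    f_primer: str
    r_primer: str
    stage: int | None  # 1 | 2 | None when unresolved
    exclusive: bool
    status: str
    related_species: tuple[str, ...]


@dataclass
class PipelineStats:
    """Group counts by (kind, primer mode, status) after each step."""

    snapshots: list[tuple[str, dict[tuple[str, str, str], int]]] = field(default_factory=list)
    species_totals: dict[str, int] = field(default_factory=dict)

    def record(self, step: str, groups: Sequence[FamilyGroup]) -> None:
        counts: dict[tuple[str, str, str], int] = {}
        total = 0
        for g in groups:
            if g.merged_into is not None:
                continue
            key = (g.group_kind, g.primer_mode, g.status)
            counts[key] = counts.get(key, 0) + 1
            total += len(g.member_accessions)
        self.snapshots.append((step, counts))
        self.species_totals[step] = total

    def to_frame(self):
        import pandas as pd

        rows = []
        for step, counts in self.snapshots:
            for (kind, mode, status), n in sorted(counts.items()):
                rows.append(
                    {"step": step, "group_kind": kind, "primer_mode": mode, "status": status, "n_groups": n}
                )
        return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    groups: list[FamilyGroup]
    catalog: list[CatalogEntry]
    stats: PipelineStats
    merges: list[MergeDecision] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    @property
    def active_groups(self) -> list[FamilyGroup]:
        return [g for g in self.groups if g.merged_into is None]


# ---------------------------------------------------------------------------
# Group construction and screening


def build_groups(universe: Sequence[MitogenomeRecord]) -> list[FamilyGroup]:
    """Cluster the universe at the family level; unlabelled records become
    their own single-species groups (reported, never dropped)."""
    by_family: dict[str, list[str]] = {}
    for rec in universe:
        fid = rec.family_id if rec.family_id is not None else f"unlabelled:{rec.accession}"
        by_family.setdefault(fid, []).append(rec.accession)
    groups = []
    for fid in sorted(by_family):
        members = sorted(by_family[fid])
        groups.append(
            FamilyGroup(
                group_id=fid,
                family_ids=[fid],
                member_accessions=members,
                group_kind="single-species" if len(members) == 1 else "multispecies",
            )
        )
    return groups


def _design_for_members(
    members: Iterable[str],
    by_acc: dict[str, MitogenomeRecord],
    cfg: PipelineConfig,
    k: int,
    top_n: int,
    *,
    require_depth: bool = True,
) -> tuple[dict[str, list[PrimerPair]], dict[str, str]]:
    """Candidate pairs per member at extension depth k, plus failure reasons.

    With ``require_depth`` the design insists on a segment at exactly depth k
    (extension must actually extend); without it the outermost available
    segment is used.
    """
    candidates: dict[str, list[PrimerPair]] = {}
    reasons: dict[str, str] = {}
    for acc in sorted(members):
        try:
            flanks = extract_flanks(by_acc[acc], k)
        except MissingCOIError:
            reasons[acc] = "missing-coi"
            continue
        if require_depth and (flanks.missing_left or flanks.missing_right):
            sides = [s for s, m in (("left", flanks.missing_left), ("right", flanks.missing_right)) if m]
            reasons[acc] = f"missing-flank:{'+'.join(sides)}@k={k}"
            continue
        design = design_pairs(flanks, cfg.constraints, top_n)
        if design.missing_flank or not design.pairs:
            reasons[acc] = "no-passing-candidate"
            continue
        candidates[acc] = design.pairs
    return candidates, reasons


def _screen_group(
    group: FamilyGroup,
    by_acc: dict[str, MitogenomeRecord],
    universe: Sequence[MitogenomeRecord],
    cfg: PipelineConfig,
    k: int,
) -> CoverResult:
    """(Re-)design at depth k and cover the group with exclusive pairs.

    For a single-species group the greedy cover over its ranked candidates
    is exactly candidate cycling: the first exclusive pair wins.
    """
    candidates, reasons = _design_for_members(
        group.member_accessions, by_acc, cfg, k, cfg.top_n
    )
    cover = minimal_pair_cover(
        group.member_accessions,
        candidates,
        universe,
        cfg.max_mm,
        cfg.bounds,
        group.group_id,
    )
    group.k_used = k
    group.assignment = dict(cover.assignment)
    group.assignment_stage = {acc: 1 for acc in cover.assignment}
    group.residual_reasons = {
        acc: reasons.get(acc, "no-exclusive-pair") for acc in cover.residual
    }
    if not cover.residual:
        group.status = "exclusive"
    elif cover.covered:
        group.status = "partially-non-exclusive"
    else:
        group.status = "unresolved"
    return cover


# ---------------------------------------------------------------------------
# Pipeline steps


def run_stage1(
    universe: Sequence[MitogenomeRecord],
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[list[FamilyGroup], PipelineStats, list[FamilyGroup]]:
    """Family-level design and screening at the nearest flanking tRNA."""
    by_acc = {r.accession: r for r in universe}
    groups = build_groups(universe)
    for group in groups:
        _screen_group(group, by_acc, universe, cfg, k=1)
        if group.status == "exclusive":
            group.resolution = "stage1"
    stats = PipelineStats()
    stats.record("stage1", groups)
    unresolved = [g for g in groups if g.status == "unresolved"]
    return groups, stats, unresolved


def resolve_by_extension(
    group: FamilyGroup,
    universe: Sequence[MitogenomeRecord],
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> FamilyGroup:
    """Re-design an unresolved group on successive outward tRNA segments."""
    if group.status == "exclusive":
        return group
    by_acc = {r.accession: r for r in universe}
    for k in range(group.k_used + 1, cfg.max_k + 1):
        _screen_group(group, by_acc, universe, cfg, k=k)
        if group.status == "exclusive":
            group.resolution = "extension"
            return group
    return group


def find_related_group(
    group: FamilyGroup,
    groups: Sequence[FamilyGroup],
    by_acc: dict[str, MitogenomeRecord],
    cfg: PipelineConfig = DEFAULT_CONFIG,
    _rep_cache: dict | None = None,
) -> tuple[FamilyGroup, int] | None:
    """The group whose representative COI is most similar to this group's."""
    cache = _rep_cache if _rep_cache is not None else {}

    def rep_seq(g: FamilyGroup) -> str:
        if g.group_id not in cache:
            seqs = {acc: rec_mod.coi_sequence(by_acc[acc]) for acc in g.member_accessions}
            stats = group_similarity(seqs, g.group_id, "COI", cfg.alignment)
            cache[g.group_id] = seqs[stats.representative]
        return cache[g.group_id]

    best: tuple[int, str, FamilyGroup] | None = None
    for other in groups:
        if other.group_id == group.group_id or other.merged_into is not None:
            continue
        score = pairwise_similarity(rep_seq(group), rep_seq(other), cfg.alignment)
        key = (-score, other.group_id)
        if best is None or key < (-best[0], best[1]):
            best = (score, other.group_id, other)
    if best is None:
        return None
    return best[2], best[0]


def resolve_by_regroup(
    group: FamilyGroup,
    groups: list[FamilyGroup],
    universe: Sequence[MitogenomeRecord],
    cfg: PipelineConfig = DEFAULT_CONFIG,
    _rep_cache: dict | None = None,
) -> tuple[FamilyGroup | None, MergeDecision | None]:
    """Try merging an unresolved group with its closest related group.

    On acceptance the two groups are marked merged and a re-screened
    multi-family group is appended to ``groups``; other groups' statuses are
    never touched.  Returns (new group or None, merge decision or None).
    """
    if group.status == "exclusive" or group.merged_into is not None:
        return None, None
    by_acc = {r.accession: r for r in universe}
    related = find_related_group(group, groups, by_acc, cfg, _rep_cache)
    if related is None:
        return None, None
    other, _score = related
    coi_a = {acc: rec_mod.coi_sequence(by_acc[acc]) for acc in group.member_accessions}
    coi_b = {acc: rec_mod.coi_sequence(by_acc[acc]) for acc in other.member_accessions}
    decision = evaluate_merge(
        coi_a, coi_b, group.group_id, other.group_id,
        cfg.merge_delta, cfg.merge_theta, cfg.alignment,
    )
    if not decision.merged:
        return None, decision
    merged = FamilyGroup(
        group_id=f"{group.group_id}+{other.group_id}",
        family_ids=sorted(set(group.family_ids) | set(other.family_ids)),
        member_accessions=sorted(set(group.member_accessions) | set(other.member_accessions)),
        group_kind="multi-family",
    )
    _screen_group(merged, by_acc, universe, cfg, k=1)
    if merged.status == "exclusive":
        merged.resolution = "regroup"
    group.merged_into = merged.group_id
    other.merged_into = merged.group_id
    groups.append(merged)
    return merged, decision


def run_stage2(
    residuals_by_group: dict[str, set[str]],
    groups: Sequence[FamilyGroup],
    universe: Sequence[MitogenomeRecord],
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> None:
    """Per-species design for residual species, screened universe-wide.

    Candidates are pooled across every available extension depth and a pair
    may amplify other members of the residual's own group, but nothing
    beyond it.  Covered residuals are recorded on their group with stage 2
    provenance; the rest keep their unresolved reasons.
    """
    by_acc = {r.accession: r for r in universe}
    by_id = {g.group_id: g for g in groups}
    for gid in sorted(residuals_by_group):
        residuals = residuals_by_group[gid]
        if not residuals:
            continue
        group = by_id[gid]
        scope = set(group.member_accessions)
        candidates: dict[str, list[PrimerPair]] = {}
        for depth in range(1, cfg.max_k + 1):
            deep, _ = _design_for_members(
                residuals, by_acc, cfg, depth, cfg.stage2_top_n, require_depth=True
            )
            for acc, pairs in deep.items():
                candidates.setdefault(acc, []).extend(pairs)
        cover = minimal_pair_cover(
            residuals, candidates, universe, cfg.max_mm, cfg.bounds, gid,
            eligible_scope=scope,
        )
        for acc in cover.covered:
            group.assignment[acc] = cover.assignment[acc]
            group.assignment_stage[acc] = 2
            group.residual_reasons.pop(acc, None)
        for acc in cover.residual:
            group.residual_reasons.setdefault(acc, "no-exclusive-pair")
        if not group.residuals:
            group.status = "exclusive"
            if group.resolution is None:
                group.resolution = "stage2"
        elif group.assignment:
            group.status = "partially-non-exclusive"


# ---------------------------------------------------------------------------
# Full run and catalog


def run_pipeline(
    universe: Sequence[MitogenomeRecord],
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> PipelineResult:
    """Run stage 1, the escalation ladder and stage 2; emit the catalog."""
    groups, stats, unresolved = run_stage1(universe, cfg)
    log = [f"stage1: {len(groups)} groups, {len(unresolved)} unresolved"]

    for group in unresolved:
        before = group.status
        resolve_by_extension(group, universe, cfg)
        if group.status != before:
            log.append(f"extension: {group.group_id} {before} -> {group.status}")
    stats.record("extension", groups)

    merges = []
    rep_cache: dict = {}
    for group in list(groups):
        if group.status != "unresolved" or group.merged_into is not None:
            continue
        if all(r.startswith("missing-") for r in group.residual_reasons.values()):
            continue  # nothing to align primers from; stage 2 will report it
        merged, decision = resolve_by_regroup(group, groups, universe, cfg, rep_cache)
        if decision is not None:
            merges.append(decision)
        if merged is not None:
            log.append(
                f"regroup: {group.group_id} + {decision.group_b} -> "
                f"{merged.group_id} ({merged.status})"
            )
    stats.record("regroup", groups)

    residuals_by_group = {
        g.group_id: g.residuals
        for g in groups
        if g.merged_into is None and g.residuals
    }
    run_stage2(residuals_by_group, groups, universe, cfg)
    stats.record("stage2", groups)
    log.append(
        "stage2: "
        + ", ".join(f"{gid}:{len(r)} residual(s)" for gid, r in sorted(residuals_by_group.items()))
        if residuals_by_group
        else "stage2: no residuals"
    )

    catalog = emit_catalog(groups, universe)
    return PipelineResult(groups=groups, catalog=catalog, stats=stats, merges=merges, log=log)


def emit_catalog(
    groups: Sequence[FamilyGroup], universe: Sequence[MitogenomeRecord]
) -> list[CatalogEntry]:
    """One entry per universe species, with shared-pair cross references."""
    by_acc = {r.accession: r for r in universe}
    entries = []
    # accessions sharing each primer pair, across all groups
    sharers: dict[tuple[str, str], list[str]] = {}
    for g in groups:
        if g.merged_into is not None:
            continue
        for acc, pair in g.assignment.items():
            sharers.setdefault(pair.key, []).append(acc)
    for g in groups:
        if g.merged_into is not None:
            continue
        for acc in g.member_accessions:
            rec = by_acc[acc]
            pair = g.assignment.get(acc)
            if pair is None:
                entries.append(
                    CatalogEntry(
                        acc, rec.organism, rec.family_id, g.group_id,
                        "", "", None, False, "unresolved", (),
                    )
                )
            else:
                related = tuple(a for a in sorted(sharers[pair.key]) if a != acc)
                entries.append(
                    CatalogEntry(
                        acc, rec.organism, rec.family_id, g.group_id,
                        pair.f_primer.sequence, pair.r_primer.sequence,
                        g.assignment_stage.get(acc, 1), True, "exclusive", related,
                    )
                )
    entries.sort(key=lambda e: e.accession)
    return entries


def lookup(catalog: Sequence[CatalogEntry], query: str) -> list[CatalogEntry]:
    """Case-insensitive substring search over organism names and accessions."""
    q = query.strip().lower()
    if not q:
        return []
    return [
        e for e in catalog if q in e.organism.lower() or q in e.accession.lower()
    ]


def catalog_primers_to_fasta(catalog: Sequence[CatalogEntry], path) -> None:
    """Assigned primers as FASTA, headers accession|F and accession|R."""
    with open(path, "w") as fh:
        for e in catalog:
            if e.f_primer:
                fh.write(f">{e.accession}|F\n{e.f_primer}\n>{e.accession}|R\n{e.r_primer}\n")


def catalog_amplicons_to_fasta(
    catalog: Sequence[CatalogEntry],
    universe: Sequence[MitogenomeRecord],
    path,
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> None:
    """Predicted self-amplicon of each resolved species, as FASTA."""
    from .screen import predict_amplicons

    by_acc = {r.accession: r for r in universe}
    groups_by_id: dict[tuple[str, str], PrimerPair] = {}
    with open(path, "w") as fh:
        for e in catalog:
            if not e.f_primer:
                continue
            rec = by_acc[e.accession]
            pair = groups_by_id.get((e.f_primer, e.r_primer))
            if pair is None:
                from .primers import PrimerCandidate

                pair = PrimerPair(
                    PrimerCandidate(e.f_primer, "L", 1, 0, "forward", 0.0, 0.0, 0.0),
                    PrimerCandidate(e.r_primer, "R", 1, 0, "reverse_complement", 0.0, 0.0, 0.0),
                    0.0,
                )
                groups_by_id[(e.f_primer, e.r_primer)] = pair
            amps = predict_amplicons(pair, rec, cfg.max_mm, cfg.bounds)
            for i, amp in enumerate(amps, start=1):
                end = amp.f_site.position + amp.product_length
                seq = rec.subsequence(amp.f_site.position, end)
                fh.write(f">{e.accession}|amplicon|{i}|len={amp.product_length}\n{seq}\n")


def catalog_to_frame(catalog: Sequence[CatalogEntry]):
    import pandas as pd

    return pd.DataFrame(
        {
            "accession": e.accession,
            "organism": e.organism,
            "family_id": e.family_id,
            "group_id": e.group_id,
            "f_primer": e.f_primer,
            "r_primer": e.r_primer,
            "stage": e.stage,
            "exclusive": e.exclusive,
            "status": e.status,
            "related_species": ";".join(e.related_species),
        }
        for e in catalog
    )
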