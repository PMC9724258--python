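"""Synthetic annotated-mitogenome universes with controlled family structure.

Each species carries a vertebrate-like cassette around the COI locus::

    ... ND2 - tRNA(L2) - tRNA(L1) - COI - tRNA(R1) - tRNA(R2) - COX2 ...

Families diverge independently from one base cassette at a per-site
substitution rate; species within a family diverge from the family ancestor
at a (much lower) intra-family rate.  The mutation model is substitution-only
so mismatch counts between planted sequences are exact ground truth.

Planted scenarios exercise every escalation path of the two-stage pipeline:

* ``confusable`` -- two families whose nearest flanks differ by exactly one
  base (planted at the primer-5' edge of each segment, so a mismatch-tolerant
  screen can never rescue a window via its 3' anchor); their second flanks
  are ordinarily divergent, so extension resolves them.
* ``twin`` -- two families drawn from a single ancestral cassette (a
  taxonomic misclassification), resolvable only by re-grouping.
* ``megafamily`` -- one inflated family in which five species copy a decoy
  family's nearest flanks exactly (so no family-level primer can be
  exclusive for them) while their outermost flanks carry two private
  haplotypes (four species share one, the fifth has its own); only the
  per-species second stage covers them, with exactly two pairs.
* ``missing-flank`` -- species emitted as linear records with the downstream
  tRNA annotations removed, emulating truncated or incompletely annotated
  entries; they can never receive a primer pair and must surface as
  unresolved rather than being dropped.

Segments involved in a planted identity are pinned (exempt from intra-family
mutation) so the planted relationship, not mutation noise, is the only cause
of the intended outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .records import GeneFeature, MitogenomeRecord, write_genbank

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: number of megafamily species forced into the second stage (4 share one
#: outer-flank haplotype, 1 carries its own)
N_MEGAFAMILY_RESIDUALS = 5
_N_SHARED_HAPLOTYPE = 4


@dataclass(frozen=True)
class SimulationConfig:
    n_families: int = 10
    species_per_family: tuple[int, int] = (5, 5)  # inclusive range
    flank_len: int = 70
    coi_len: int = 1545
    n_flanking_trnas_per_side: int = 2
    intra_family_sub_rate: float = 0.01
    inter_family_divergence: float = 0.15
    n_confusable_pairs: int = 0
    n_twin_pairs: int = 0
    n_missing_flank_species: int = 0
    megafamily_size: int = 0
    seed: int = 0

    def validate(self) -> None:
        for rate in (self.intra_family_sub_rate, self.inter_family_divergence):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rates must be in [0,1], got {rate}")
        if min(self.flank_len, self.coi_len, self.n_families) <= 0:
            raise ValueError("lengths and family count must be positive")
        if self.n_flanking_trnas_per_side < 1:
            raise ValueError("need at least one flanking tRNA per side")
        lo, hi = self.species_per_family
        if not 1 <= lo <= hi:
            raise ValueError(f"bad species_per_family range {self.species_per_family}")
        reserved = 2 * self.n_confusable_pairs + 2 * self.n_twin_pairs
        if self.megafamily_size:
            if self.megafamily_size < N_MEGAFAMILY_RESIDUALS + 2:
                raise ValueError(
                    f"megafamily_size must be >= {N_MEGAFAMILY_RESIDUALS + 2} to leave"
                    " resolvable members"
                )
            reserved += 2  # the megafamily itself plus its decoy family
        if reserved > self.n_families:
            raise ValueError(
                f"planted scenarios need {reserved} families but only {self.n_families} exist"
            )
        n_clean = self.n_families - reserved
        if self.n_missing_flank_species > n_clean:
            raise ValueError(
                f"{self.n_missing_flank_species} missing-flank species need as many clean families"
            )


@dataclass
class TruthLabels:
    """Ground truth of a simulated universe, keyed by accession/family."""

    tags: dict[str, str] = field(default_factory=dict)  # accession -> scenario tag
    family_of: dict[str, str] = field(default_factory=dict)
    confusable_pairs: list[tuple[str, str]] = field(default_factory=list)
    twin_pairs: list[tuple[str, str]] = field(default_factory=list)
    megafamily: str | None = None
    decoy_family: str | None = None
    residual_accessions: list[str] = field(default_factory=list)
    seed: int = 0

    #: pipeline outcome each tag predicts (resolution stage, or unresolved)
    EXPECTED_RESOLUTION = {
        "clean": "stage1",
        "megafamily": "stage1",
        "confusable": "extension",
        "decoy": "extension",
        "twin": "regroup",
        "megafamily-residual": "stage2",
        "missing-flank": "unresolved",
    }

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``rate``.

    A substituted site always changes to one of the three other bases
    (uniformly), so ``rate=1`` leaves no position unchanged.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0,1], got {rate}")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        idx = (
            np.searchsorted(_BASES, arr[hit]) + rng.integers(1, 4, size=n_hit)
        ) % 4
        arr[hit] = _BASES[idx]
    return arr.tobytes().decode("ascii")


def substitute_at(seq: str, position: int, rng: np.random.Generator) -> str:
    """Force exactly one substitution at a given position."""
    old = seq[position]
    new = rng.choice([b for b in "ACGT" if b != old])
    return seq[: position] + str(new) + seq[position + 1 :]


# ---------------------------------------------------------------------------
# Cassette layout

_TRNA_NAMES_LEFT = ["trnY", "trnC", "trnN", "trnA", "trnW"]  # nearest first
_TRNA_NAMES_RIGHT = ["trnS2", "trnD", "trnK", "trnG", "trnR"]


def _segment_plan(cfg: SimulationConfig) -> list[tuple[str, str, int]]:
    """(segment name, feature kind, length), genome order."""
    k = cfg.n_flanking_trnas_per_side
    plan: list[tuple[str, str, int]] = [("spacer5", "", 120), ("ND2", "CDS", 240)]
    for i in range(k, 0, -1):  # outermost upstream tRNA first in genome order
        plan.append((f"L{i}", "tRNA", cfg.flank_len))
        plan.append((f"gapL{i}", "", 10 if i > 1 else 2))
    plan.append(("COI", "CDS", cfg.coi_len))
    for i in range(1, k + 1):
        plan.append((f"gapR{i}", "", 2 if i == 1 else 10))
        plan.append((f"R{i}", "tRNA", cfg.flank_len))
    plan.extend([("COX2", "CDS", 240), ("spacer3", "", 120)])
    return plan


def _trna_label(name: str, side: str, rank: int) -> str:
    names = _TRNA_NAMES_LEFT if side == "L" else _TRNA_NAMES_RIGHT
    return names[rank - 1] if rank <= len(names) else f"trn{side}{rank}"


def _assemble(
    accession: str,
    organism: str,
    family_id: str,
    segments: dict[str, str],
    plan: list[tuple[str, str, int]],
    *,
    drop_downstream_trnas: bool = False,
) -> MitogenomeRecord:
    seq_parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for name, kind, _length in plan:
        seg = segments[name]
        if kind:
            past_coi = name == "COI" or any(f.label == "COX1" for f in features)
            keep = not (drop_downstream_trnas and kind == "tRNA" and past_coi and name != "COI")
            if keep:
                if kind == "tRNA":
                    side, rank = name[0], int(name[1:])
                    label = _trna_label(name, side, rank)
                else:
                    label = "COX1" if name == "COI" else name
                features.append(GeneFeature(kind, label, pos, pos + len(seg), 1))
        seq_parts.append(seg)
        pos += len(seg)
    return MitogenomeRecord(
        accession=accession,
        organism=organism,
        family_id=family_id,
        sequence="".join(seq_parts),
        topology="linear" if drop_downstream_trnas else "circular",
        features=features,
    )


def simulate_universe(cfg: SimulationConfig) -> tuple[list[MitogenomeRecord], TruthLabels]:
    """Generate one annotated universe plus its ground-truth labels.

    All randomness flows through a single generator seeded from
    ``cfg.seed``; identical configs produce byte-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    plan = _segment_plan(cfg)
    base = {name: random_dna(rng, length) for name, _, length in plan}
    truth = TruthLabels(seed=cfg.seed)

    # --- allocate scenario roles to family indices (deterministic layout)
    family_ids = [f"F{i:02d}" for i in range(cfg.n_families)]
    roles: dict[str, str] = {fid: "clean" for fid in family_ids}
    cursor = 0
    for _ in range(cfg.n_confusable_pairs):
        a, b = family_ids[cursor], family_ids[cursor + 1]
        roles[a] = roles[b] = "confusable"
        truth.confusable_pairs.append((a, b))
        cursor += 2
    for _ in range(cfg.n_twin_pairs):
        a, b = family_ids[cursor], family_ids[cursor + 1]
        roles[a] = roles[b] = "twin"
        truth.twin_pairs.append((a, b))
        cursor += 2
    if cfg.megafamily_size:
        truth.megafamily = family_ids[cursor]
        truth.decoy_family = family_ids[cursor + 1]
        roles[truth.megafamily] = "megafamily"
        roles[truth.decoy_family] = "decoy"
        cursor += 2
    clean_families = [fid for fid in family_ids if roles[fid] == "clean"]

    # --- family ancestral cassettes
    ancestors: dict[str, dict[str, str]] = {}
    for fid in family_ids:
        if roles[fid] == "twin" and any(fid == b for _, b in truth.twin_pairs):
            a = next(a for a, b in truth.twin_pairs if b == fid)
            ancestors[fid] = dict(ancestors[a])  # shared ancestry: misclassified split
        else:
            ancestors[fid] = {
                name: mutate(seq, cfg.inter_family_divergence, rng)
                for name, seq in base.items()
            }
    # confusable partner: nearest flanks are the partner's with exactly one
    # substitution at the primer-5' edge of each segment
    for a, b in truth.confusable_pairs:
        ancestors[b]["L1"] = substitute_at(ancestors[a]["L1"], 0, rng)
        ancestors[b]["R1"] = substitute_at(ancestors[a]["R1"], cfg.flank_len - 1, rng)

    # segments exempt from intra-family mutation, per family
    flank_names = [f"{side}{i}" for side in "LR" for i in range(1, cfg.n_flanking_trnas_per_side + 1)]
    pinned: dict[str, set[str]] = {fid: set() for fid in family_ids}
    for a, b in truth.confusable_pairs:
        pinned[a] |= {"L1", "R1"}
        pinned[b] |= {"L1", "R1"}
    for a, b in truth.twin_pairs:
        pinned[a] |= set(flank_names)
        pinned[b] |= set(flank_names)
    if truth.decoy_family:
        pinned[truth.decoy_family] |= {"L1", "R1"}

    # private outer-flank haplotypes for the megafamily residual subset
    outer = f"L{cfg.n_flanking_trnas_per_side}", f"R{cfg.n_flanking_trnas_per_side}"
    hap_shared = {name: random_dna(rng, cfg.flank_len) for name in outer}
    hap_private = {name: random_dna(rng, cfg.flank_len) for name in outer}

    # --- species
    records: list[MitogenomeRecord] = []
    missing_quota = {fid: 0 for fid in family_ids}
    for fid in clean_families[: cfg.n_missing_flank_species]:
        missing_quota[fid] = 1

    for fi, fid in enumerate(family_ids):
        if roles[fid] == "megafamily":
            n_species = cfg.megafamily_size
        else:
            lo, hi = cfg.species_per_family
            n_species = int(rng.integers(lo, hi + 1))
        residual_slots = set()
        if roles[fid] == "megafamily":
            residual_slots = set(range(n_species - N_MEGAFAMILY_RESIDUALS, n_species))
        for si in range(n_species):
            acc = f"SYN{fi:02d}{si:02d}"
            organism = f"Synthofish {fid.lower()} sp{si:02d}"
            segments = {}
            for name, _, _ in plan:
                if name in pinned[fid]:
                    segments[name] = ancestors[fid][name]
                else:
                    segments[name] = mutate(ancestors[fid][name], cfg.intra_family_sub_rate, rng)
            tag = roles[fid]
            if si in residual_slots:
                tag = "megafamily-residual"
                # nearest flanks: exact copy of the decoy family's (pinned) flanks
                segments["L1"] = ancestors[truth.decoy_family]["L1"]
                segments["R1"] = ancestors[truth.decoy_family]["R1"]
                hap = (
                    hap_shared
                    if si < min(residual_slots) + _N_SHARED_HAPLOTYPE
                    else hap_private
                )
                for name in outer:
                    segments[name] = hap[name]
                truth.residual_accessions.append(acc)
            drop = False
            if missing_quota[fid] and si == n_species - 1 and tag == "clean":
                tag = "missing-flank"
                drop = True
            records.append(
                _assemble(acc, organism, fid, segments, plan, drop_downstream_trnas=drop)
            )
            truth.tags[acc] = tag
            truth.family_of[acc] = fid
    return records, truth


def write_universe(
    records: list[MitogenomeRecord],
    truth: TruthLabels,
    outdir: str | Path,
    *,
    single_file: bool = True,
) -> None:
    """Write GenBank genome(s), the taxonomy TSV and the truth labels JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if single_file:
        write_genbank(records, outdir / "universe.gb")
    else:
        for rec in records:
            write_genbank([rec], outdir / f"{rec.accession}.gb")
    with open(outdir / "taxonomy.tsv", "w") as fh:
        fh.write("accession\torganism\tfamily_id\tfamily_name\n")
        for rec in records:
            fh.write(f"{rec.accession}\t{rec.organism}\t{rec.family_id}\t{rec.family_id}\n")
    truth.to_json(outdir / "truth.json")
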