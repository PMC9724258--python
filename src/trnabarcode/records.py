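"""Annotated mitochondrial genome records and COI flank extraction.

A mitogenome is held as a plain sequence over {A,C,G,T,N} plus an ordered
list of gene features in 0-based half-open reference-strand coordinates
(GenBank's 1-based inclusive intervals are converted on read and write).
Vertebrate mitogenomes are circular, so feature lookup and flank extraction
wrap the origin unless a record is explicitly linear.

The COI barcode locus is identified purely by its annotation label against a
fixed synonym table -- unknown labels are never fuzzily matched, because a
silent mis-identification would poison every downstream primer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

#: Annotation labels recognised as the COI gene (case-insensitive, after
#: whitespace normalisation).  Fixed on purpose: see module docstring.
COI_SYNONYMS = frozenset(
    {
        "coi",
        "co1",
        "cox1",
        "coxi",
        "cox-1",
        "mt-co1",
        "cytochrome c oxidase subunit 1",
        "cytochrome c oxidase subunit i",
        "cytochrome c oxidase i",
        "cytochrome oxidase subunit 1",
        "cytochrome oxidase subunit i",
    }
)


class FormatError(ValueError):
    """An input file could not be parsed."""


class MissingCOIError(LookupError):
    """A record carries no feature recognised as COI."""


class AmbiguousCOIError(LookupError):
    """A record carries more than one feature recognised as COI."""


def _norm_label(label: str) -> str:
    return " ".join(label.strip().lower().split())


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on the reference strand.

    ``start``/``end`` are 0-based half-open; a feature that spans the origin
    of a circular molecule has ``wraps_origin=True`` and ``end`` counted past
    the sequence length (so ``end - start`` is always the feature length).
    """

    feature_kind: str  # tRNA | CDS | rRNA | other
    label: str
    start: int
    end: int
    strand: int  # +1 | -1
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative feature start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty feature interval [{self.start}, {self.end})")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def is_coi(self) -> bool:
        return _norm_label(self.label) in COI_SYNONYMS


@dataclass
class MitogenomeRecord:
    """One annotated, possibly circular, mitochondrial genome."""

    accession: str
    organism: str
    family_id: str | None
    sequence: str
    topology: str = "circular"  # circular | linear
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.accession}: invalid bases {sorted(bad)}")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int) -> str:
        """Reference-strand slice, wrapping the origin when circular."""
        n = len(self.sequence)
        if end <= n:
            return self.sequence[start:end]
        if self.topology != "circular":
            raise ValueError(f"{self.accession}: slice [{start}, {end}) beyond linear sequence")
        return self.sequence[start:] + self.sequence[: end - n]


@dataclass
class FlankSet:
    """The COI locus plus its k nearest flanking tRNA segments.

    Segments are nearest-first and always reported in reference-strand
    orientation; reverse complementation is the primer designer's job.
    """

    accession: str
    coi: GeneFeature
    left_segments: list[str]
    right_segments: list[str]
    k: int
    missing_left: bool
    missing_right: bool


# ---------------------------------------------------------------------------
# Reading


def read_taxonomy(path: str | Path):
    """Read a taxonomy TSV (accession, organism, family_id[, family_name]).

    Returns a dict mapping both accession and organism (lowercased) to
    family_id, so either key resolves a record.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"accession", "organism", "family_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: taxonomy table lacks columns {sorted(missing)}")
    mapping: dict[str, str] = {}
    for row in df.itertuples(index=False):
        mapping[row.accession] = row.family_id
        mapping[row.organism.strip().lower()] = row.family_id
    return mapping


def _kind_of(feature_type: str) -> str:
    t = feature_type.lower()
    if t == "trna":
        return "tRNA"
    if t == "cds":
        return "CDS"
    if t == "rrna":
        return "rRNA"
    return "other"


def _feature_from_seqfeature(feat: SeqFeature, seq_len: int) -> GeneFeature | None:
    kind = _kind_of(feat.type)
    if kind == "other" and feat.type.lower() in ("source", "gene", "misc_feature", "d-loop"):
        return None
    label = ""
    for key in ("gene", "product", "label", "note"):
        if key in feat.qualifiers:
            label = str(feat.qualifiers[key][0])
            break
    loc = feat.location
    strand = 1 if (loc.strand or 1) >= 0 else -1
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # Origin-spanning annotation: join(a..N, 1..b)
        if len(parts) == 2 and int(parts[0].start) == 0 and int(parts[1].end) == seq_len:
            start = int(parts[1].start)
            end = seq_len + int(parts[0].end)
            return GeneFeature(kind, label, start, end, strand, wraps_origin=True)
        start, end = int(loc.start), int(loc.end)
    else:
        start, end = int(loc.start), int(loc.end)
    return GeneFeature(kind, label, start, end, strand)


def _record_from_seqrecord(rec: SeqRecord, taxonomy: dict[str, str] | None) -> MitogenomeRecord:
    organism = rec.annotations.get("organism", "") or rec.description or rec.id
    topology = rec.annotations.get("topology", "circular")
    if topology not in ("circular", "linear"):
        topology = "circular"
    seq = str(rec.seq)
    feats = []
    for f in rec.features:
        gf = _feature_from_seqfeature(f, len(seq))
        if gf is not None:
            feats.append(gf)
    family_id = None
    if taxonomy is not None:
        family_id = taxonomy.get(rec.id) or taxonomy.get(organism.strip().lower())
    return MitogenomeRecord(
        accession=rec.id,
        organism=organism,
        family_id=family_id,
        sequence=seq,
        topology=topology,
        features=feats,
    )


def _read_feature_table(fasta_path: Path, table_path: Path, taxonomy) -> list[MitogenomeRecord]:
    """FASTA + TSV feature table (accession, kind, label, start_1based,
    end_1based, strand) in the style of MitoAnnotator exports."""
    import pandas as pd

    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    try:
        df = pd.read_csv(table_path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{table_path}: {exc}") from exc
    required = {"accession", "kind", "label", "start_1based", "end_1based", "strand"}
    if required - set(df.columns):
        raise FormatError(
            f"{table_path}: feature table lacks columns {sorted(required - set(df.columns))}"
        )
    by_acc: dict[str, list[GeneFeature]] = {a: [] for a in seqs}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.accession not in seqs:
            raise FormatError(f"{table_path}, line {i}: unknown accession {row.accession!r}")
        try:
            start = int(row.start_1based) - 1
            end = int(row.end_1based)
            strand = int(row.strand)
        except ValueError as exc:
            raise FormatError(f"{table_path}, line {i}: {exc}") from exc
        by_acc[row.accession].append(GeneFeature(_kind_of(row.kind), row.label, start, end, strand))
    out = []
    for acc, seq in seqs.items():
        family_id = taxonomy.get(acc) if taxonomy else None
        out.append(
            MitogenomeRecord(acc, acc, family_id, seq, topology="circular", features=by_acc[acc])
        )
    return out


def read_genomes(
    paths: Sequence[str | Path],
    taxonomy: str | Path | dict[str, str] | None = None,
) -> list[MitogenomeRecord]:
    """Read annotated mitogenomes from GenBank files or FASTA+TSV pairs.

    ``paths`` may mix GenBank flat files and FASTA files; a FASTA file must be
    accompanied by a sibling feature table named ``<stem>.features.tsv``.
    ``taxonomy`` maps accession or organism to family_id (path to a TSV, or a
    prebuilt mapping).  Records without a taxonomy entry are kept, flagged
    with ``family_id=None`` and reported via a warning.
    """
    if isinstance(taxonomy, (str, Path)):
        taxonomy = read_taxonomy(taxonomy)
    records: list[MitogenomeRecord] = []
    if not paths:
        warnings.warn("read_genomes called with an empty input list", stacklevel=2)
        return records
    for path in paths:
        path = Path(path)
        suffix = path.suffix.lower()
        if suffix in (".gb", ".gbk", ".genbank", ".gbff"):
            try:
                parsed = list(SeqIO.parse(str(path), "genbank"))
            except Exception as exc:
                raise FormatError(f"{path}: {exc}") from exc
            if not parsed:
                raise FormatError(f"{path}: no GenBank records found")
            records.extend(_record_from_seqrecord(r, taxonomy) for r in parsed)
        elif suffix in (".fa", ".fasta", ".fna"):
            table = path.with_suffix(".features.tsv")
            if not table.exists():
                raise FormatError(f"{path}: missing feature table {table.name}")
            records.extend(_read_feature_table(path, table, taxonomy))
        else:
            raise FormatError(f"{path}: unrecognised input format {suffix!r}")
    seen: dict[str, str] = {}
    for rec in records:
        if rec.accession in seen:
            raise ValueError(f"duplicate accession {rec.accession!r}")
        seen[rec.accession] = rec.organism
    untagged = [r.accession for r in records if r.family_id is None]
    if untagged and taxonomy is not None:
        warnings.warn(
            f"{len(untagged)} record(s) lack a taxonomy entry: {', '.join(untagged[:10])}",
            stacklevel=2,
        )
    return records


# ---------------------------------------------------------------------------
# COI location and flank extraction


def locate_coi(record: MitogenomeRecord) -> GeneFeature:
    """Return the unique feature recognised as the COI gene."""
    hits = [f for f in record.features if f.is_coi()]
    if not hits:
        raise MissingCOIError(f"{record.accession}: no COI-like feature found")
    if len(hits) > 1:
        labels = ", ".join(f"{f.label}@{f.start}" for f in hits)
        raise AmbiguousCOIError(f"{record.accession}: multiple COI candidates ({labels})")
    return hits[0]


def _circular_upstream_distance(n: int, coi: GeneFeature, feat: GeneFeature) -> int:
    """Gap between a feature's end and COI's start, walking left around the circle."""
    return (coi.start - feat.end) % n


def _circular_downstream_distance(n: int, coi: GeneFeature, feat: GeneFeature) -> int:
    return (feat.start - coi.end % n) % n


def _overlaps_coi(n: int, coi: GeneFeature, feat: GeneFeature) -> bool:
    # Compare on the unrolled circle; features were constructed so end-start
    # is the true length even when wrapping.
    for shift in (0, n):
        a0, a1 = feat.start + shift, feat.end + shift
        if a0 < coi.end and a1 > coi.start:
            return True
    return False


def extract_flanks(record: MitogenomeRecord, k: int) -> FlankSet:
    """Extract the k nearest flanking tRNA segments on each side of COI.

    Upstream means toward lower reference coordinates from ``coi.start``;
    downstream from ``coi.end``.  Circular records wrap the origin, and a
    tRNA is never taken from both sides at the same rank unless the genome
    genuinely places it there (possible on very gene-poor circles).  Segments
    come back nearest-first on the reference strand.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    coi = locate_coi(record)
    n = len(record)
    trnas = [f for f in record.features if f.feature_kind == "tRNA" and not _overlaps_coi(n, coi, f)]

    if record.topology == "circular":
        up = sorted(trnas, key=lambda f: (_circular_upstream_distance(n, coi, f), f.start))
        down = sorted(trnas, key=lambda f: (_circular_downstream_distance(n, coi, f), f.start))
    else:
        up = sorted(
            (f for f in trnas if f.end <= coi.start),
            key=lambda f: coi.start - f.end,
        )
        down = sorted(
            (f for f in trnas if f.start >= coi.end),
            key=lambda f: f.start - coi.end,
        )

    left = [record.subsequence(f.start, f.end) for f in up[:k]]
    right = [record.subsequence(f.start, f.end) for f in down[:k]]
    return FlankSet(
        accession=record.accession,
        coi=coi,
        left_segments=left,
        right_segments=right,
        k=k,
        missing_left=len(left) < k,
        missing_right=len(right) < k,
    )


def coi_sequence(record: MitogenomeRecord) -> str:
    """Reference-strand sequence of the COI locus."""
    coi = locate_coi(record)
    return record.subsequence(coi.start, coi.end)


# ---------------------------------------------------------------------------
# Writing


def flanks_to_fasta(flanksets: Iterable[FlankSet], path: str | Path) -> None:
    """Export flank segments as multi-FASTA with headers accession|side|rank."""
    with open(path, "w") as fh:
        for fs in flanksets:
            for rank, seg in enumerate(fs.left_segments, start=1):
                fh.write(f">{fs.accession}|L|{rank}\n{seg}\n")
            for rank, seg in enumerate(fs.right_segments, start=1):
                fh.write(f">{fs.accession}|R|{rank}\n{seg}\n")


def to_seqrecord(record: MitogenomeRecord) -> SeqRecord:
    """Convert to a Biopython SeqRecord suitable for GenBank output."""
    rec = SeqRecord(Seq(record.sequence), id=record.accession, name=record.accession[:16])
    rec.description = record.organism
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = record.topology
    rec.annotations["organism"] = record.organism
    n = len(record.sequence)
    for f in record.features:
        ftype = {"tRNA": "tRNA", "CDS": "CDS", "rRNA": "rRNA"}.get(f.feature_kind, "misc_feature")
        qualifier_key = "product" if f.feature_kind == "tRNA" else "gene"
        if f.wraps_origin:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start, n, strand=f.strand),
                    SimpleLocation(0, f.end - n, strand=f.strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start, f.end, strand=f.strand)
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers={qualifier_key: [f.label]}))
    return rec


def write_genbank(records: Iterable[MitogenomeRecord], path: str | Path) -> None:
    SeqIO.write([to_seqrecord(r) for r in records], str(path), "genbank")
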