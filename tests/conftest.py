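"""Shared fixtures: hand-built toy genomes and small simulated universes."""

from __future__ import annotations

import numpy as np
import pytest

from trnabarcode.primers import PrimerCandidate, PrimerPair, reverse_complement
from trnabarcode.records import GeneFeature, MitogenomeRecord

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def build_genome(
    accession: str,
    family_id: str | None = "FAM",
    *,
    left_trnas: list[str],
    right_trnas: list[str],
    coi: str,
    spacer: str = "",
    topology: str = "circular",
    organism: str | None = None,
) -> MitogenomeRecord:
    """Assemble a minimal annotated genome: spacer, outer-to-inner upstream
    tRNAs, COI, inner-to-outer downstream tRNAs, spacer.

    ``left_trnas``/``right_trnas`` are nearest-first, matching how flank
    sets report them.
    """
    parts: list[str] = [spacer]
    features: list[GeneFeature] = []
    pos = len(spacer)
    for i, seg in enumerate(reversed(left_trnas)):  # outermost first in genome order
        rank = len(left_trnas) - i
        features.append(GeneFeature("tRNA", f"trnL{rank}", pos, pos + len(seg), 1))
        parts.append(seg)
        pos += len(seg)
    features.append(GeneFeature("CDS", "COX1", pos, pos + len(coi), 1))
    parts.append(coi)
    pos += len(coi)
    for rank, seg in enumerate(right_trnas, start=1):
        features.append(GeneFeature("tRNA", f"trnR{rank}", pos, pos + len(seg), 1))
        parts.append(seg)
        pos += len(seg)
    parts.append(spacer)
    return MitogenomeRecord(
        accession=accession,
        organism=organism or f"Toyfish {accession}",
        family_id=family_id,
        sequence="".join(parts),
        topology=topology,
        features=features,
    )


def make_candidate(seq: str, orientation: str = "forward", side: str = "L") -> PrimerCandidate:
    return PrimerCandidate(
        sequence=seq,
        source_side=side,
        source_rank=1,
        offset=0,
        orientation=orientation,
        penalty=0.0,
        tm=57.5,
        gc=0.5,
    )


def make_pair(f_seq: str, r_seq: str, penalty: float = 0.0) -> PrimerPair:
    f = make_candidate(f_seq, "forward", "L")
    r = make_candidate(r_seq, "reverse_complement", "R")
    return PrimerPair(f, r, pair_penalty=penalty, rank=1)


def cassette_for(pair: PrimerPair, insert_len: int = 200, rng=None) -> str:
    """Genomic stretch the pair amplifies: F + insert + revcomp(R)."""
    rng = rng or np.random.default_rng(0)
    return pair.f_primer.sequence + random_dna(rng, insert_len) + reverse_complement(
        pair.r_primer.sequence
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_universe():
    """Ten clean families of five species, fixed seed (session-cached)."""
    from trnabarcode.simulate import SimulationConfig, simulate_universe

    return simulate_universe(SimulationConfig(seed=11))
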