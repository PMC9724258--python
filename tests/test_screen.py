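"""Primer mapping, amplicon prediction, exclusivity and minimal cover."""

import itertools

import numpy as np
import pytest

from trnabarcode.primers import reverse_complement
from trnabarcode.records import MitogenomeRecord
from trnabarcode.screen import (
    ProductBounds,
    classify_exclusivity,
    find_matches,
    minimal_pair_cover,
    predict_amplicons,
)

from conftest import build_genome, cassette_for, make_pair, random_dna


def _genome(seq, accession="G1", topology="linear", family="FAM"):
    return MitogenomeRecord(accession, f"org {accession}", family, seq, topology=topology)


# ---------------------------------------------------------------------------
# Independent oracle: character-by-character scan with the same match rules.


def naive_find_matches(primer, genome, max_mm):
    n, m = len(genome.sequence), len(primer)
    seq = genome.sequence
    if genome.topology == "circular":
        seq = seq + seq[: m - 1]
    k = min(3, m)
    hits = []
    rc = reverse_complement(primer)
    for pos in range(min(len(seq) - m, n - 1) + 1):
        window = seq[pos : pos + m]
        mm_plus = sum(a != b for a, b in zip(primer, window))
        if mm_plus <= max_mm and primer[m - k :] == window[m - k :]:
            hits.append((pos, 1, mm_plus))
        mm_minus = sum(a != b for a, b in zip(rc, window))
        if mm_minus <= max_mm and rc[:k] == window[:k]:
            hits.append((pos, -1, mm_minus))
    return sorted(hits, key=lambda h: (h[0], -h[1]))


class TestFindMatches:
    def test_exact_unique_substring(self, rng):
        seq = random_dna(rng, 500)
        primer = seq[100:120]
        genome = _genome(seq)
        sites = [s for s in find_matches(primer, genome, 0) if s.strand == 1]
        assert [(s.position, s.mismatches) for s in sites] == [(100, 0)]

    def test_reverse_complement_hits_minus_strand(self, rng):
        seq = random_dna(rng, 500)
        primer = reverse_complement(seq[200:222])
        genome = _genome(seq)
        sites = find_matches(primer, genome, 0)
        assert [(s.position, s.strand) for s in sites] == [(200, -1)]

    def test_three_prime_mismatch_blocks_annealing(self, rng):
        seq = random_dna(rng, 300)
        primer = seq[50:70]
        bad = primer[:-1] + ("A" if primer[-1] != "A" else "C")
        genome = _genome(seq)
        plus = [s for s in find_matches(bad, genome, 2) if s.strand == 1 and s.position == 50]
        assert plus == []

    def test_circular_match_across_origin(self, rng):
        seq = random_dna(rng, 300)
        primer = seq[-10:] + seq[:10]
        hits = find_matches(primer, _genome(seq, topology="circular"), 0)
        assert (290, 1) in [(s.position, s.strand) for s in hits]
        assert find_matches(primer, _genome(seq, topology="linear"), 0) == []

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_equals_naive_scan_random_cases(self, rng, max_mm):
        for trial in range(40):
            n = int(rng.integers(50, 2000))
            genome = _genome(
                random_dna(rng, n),
                topology="circular" if trial % 2 else "linear",
            )
            if trial % 3 == 0:
                # planted near-match: mutate a real substring
                start = int(rng.integers(0, n - 20))
                primer = list(genome.sequence[start : start + 20])
                for pos in rng.choice(17, size=int(rng.integers(0, 3)), replace=False):
                    primer[pos] = "ACGT"[int(rng.integers(4))]
                primer = "".join(primer)
            else:
                primer = random_dna(rng, int(rng.integers(8, 25)))
            got = [(s.position, s.strand, s.mismatches) for s in find_matches(primer, genome, max_mm)]
            assert got == naive_find_matches(primer, genome, max_mm)

    def test_raising_max_mm_never_shrinks_site_set(self, rng):
        genome = _genome(random_dna(rng, 1000), topology="circular")
        primer = genome.sequence[500:520]
        previous = set()
        for max_mm in range(0, 4):
            sites = {(s.position, s.strand) for s in find_matches(primer, genome, max_mm)}
            assert previous <= sites
            previous = sites


class TestPredictAmplicons:
    def test_pair_from_own_flanks_gives_one_amplicon_containing_coi(self, rng):
        from trnabarcode.primers import design_pairs
        from trnabarcode.records import extract_flanks, locate_coi

        rec = build_genome(
            "A1",
            left_trnas=[random_dna(rng, 70)],
            right_trnas=[random_dna(rng, 70)],
            coi=random_dna(rng, 600),
            spacer=random_dna(rng, 150),
        )
        pairs = design_pairs(extract_flanks(rec, 1)).pairs
        assert pairs
        amps = predict_amplicons(pairs[0], rec)
        assert len(amps) == 1
        coi = locate_coi(rec)
        amp = amps[0]
        assert amp.f_site.position <= coi.start
        assert amp.r_site.position + len(pairs[0].r_primer.sequence) >= coi.end
        assert amp.product_length >= coi.length

    def test_no_minus_strand_site_means_no_amplicon(self, rng):
        pair = make_pair(random_dna(rng, 20), random_dna(rng, 20))
        # genome contains F and the reverse primer on the PLUS strand only
        seq = (
            random_dna(rng, 100)
            + pair.f_primer.sequence
            + random_dna(rng, 300)
            + pair.r_primer.sequence
            + random_dna(rng, 100)
        )
        assert predict_amplicons(pair, _genome(seq)) == []

    def test_product_length_bounds_filter(self, rng):
        pair = make_pair(random_dna(rng, 20), random_dna(rng, 20))
        seq = random_dna(rng, 50) + cassette_for(pair, insert_len=400) + random_dna(rng, 50)
        genome = _genome(seq)
        assert len(predict_amplicons(pair, genome)) == 1
        assert predict_amplicons(pair, genome, bounds=ProductBounds(10, 100)) == []
        assert predict_amplicons(pair, genome, bounds=ProductBounds(2000, 3000)) == []

    def test_circular_product_across_origin(self, rng):
        pair = make_pair(random_dna(rng, 20), random_dna(rng, 20))
        cassette = cassette_for(pair, insert_len=300)
        # split the cassette across the origin
        seq = cassette[150:] + random_dna(rng, 400) + cassette[:150]
        amps = predict_amplicons(pair, _genome(seq, topology="circular"))
        assert [a.product_length for a in amps] == [len(cassette)]


class TestExclusivity:
    def test_singleton_universe_is_exclusive(self, rng):
        pair = make_pair(random_dna(rng, 20), random_dna(rng, 20))
        genome = _genome(cassette_for(pair), accession="S1")
        rep = classify_exclusivity(["S1"], pair, [genome])
        assert rep.exclusive and rep.matched_in_group == {"S1"}

    def test_pair_amplifying_nothing_is_non_exclusive(self, rng):
        pair = make_pair(random_dna(rng, 20), random_dna(rng, 20))
        genome = _genome(random_dna(rng, 600), accession="S1")
        rep = classify_exclusivity(["S1"], pair, [genome])
        assert not rep.exclusive

    def test_one_base_flank_difference_cross_amplifies(self, rng):
        """Primers placed to avoid the single differing flank position
        amplify both species even at zero mismatch tolerance."""
        flank_l = random_dna(rng, 70)
        flank_r = random_dna(rng, 70)
        coi_a, coi_b = random_dna(rng, 600), random_dna(rng, 600)
        # species B's flanks differ from A's by one base at segment centre
        flank_l_b = flank_l[:35] + ("A" if flank_l[35] != "A" else "C") + flank_l[36:]
        a = build_genome("A1", "FA", left_trnas=[flank_l], right_trnas=[flank_r], coi=coi_a)
        b = build_genome("B1", "FB", left_trnas=[flank_l_b], right_trnas=[flank_r], coi=coi_b)
        # forward primer from the flank's left half avoids position 35
        pair = make_pair(flank_l[:20], reverse_complement(flank_r[-20:]))
        rep = classify_exclusivity(["A1"], pair, [a, b], max_mm=0)
        assert rep.matched_in_group == {"A1"}
        assert rep.matched_out_group == {"B1"}
        assert not rep.exclusive


# ---------------------------------------------------------------------------
# Minimal cover


def _cover_instance(rng, coverage: dict[str, set[str]], n_species: int, family="FAM"):
    """Universe of n species plus pairs; pair p amplifies exactly coverage[p]."""
    pairs = {name: make_pair(random_dna(rng, 20), random_dna(rng, 20), penalty=i)
             for i, name in enumerate(sorted(coverage))}
    genomes = []
    for i in range(n_species):
        acc = f"S{i}"
        seq = random_dna(rng, 60)
        for name, targets in sorted(coverage.items()):
            if acc in targets:
                seq += cassette_for(pairs[name], insert_len=200, rng=rng) + random_dna(rng, 40)
        seq += random_dna(rng, 60)
        genomes.append(_genome(seq, accession=acc, family=family))
    return pairs, genomes


def naive_minimal_cover_size(members, eligible_coverage):
    """Exhaustive smallest cover size, or None if the members cannot be covered."""
    names = sorted(eligible_coverage)
    for size in range(1, len(names) + 1):
        for combo in itertools.combinations(names, size):
            if set().union(*(eligible_coverage[c] for c in combo)) >= members:
                return size
    return None


class TestMinimalPairCover:
    def test_single_shared_pair_suffices(self, rng):
        pairs, genomes = _cover_instance(rng, {"p0": {"S0", "S1", "S2"}}, 3)
        result = minimal_pair_cover(
            ["S0", "S1", "S2"], {"S0": [pairs["p0"]]}, genomes
        )
        assert len(result.selected) == 1 and not result.residual

    def test_four_plus_one_needs_two_pairs(self, rng):
        cov = {"p0": {"S0", "S1", "S2", "S3"}, "p1": {"S4"}}
        pairs, genomes = _cover_instance(rng, cov, 5)
        result = minimal_pair_cover(
            [f"S{i}" for i in range(5)],
            {"S0": [pairs["p0"]], "S4": [pairs["p1"]]},
            genomes,
        )
        assert len(result.selected) == 2
        assert not result.residual
        assert result.assignment["S4"].key == pairs["p1"].key

    def test_non_exclusive_pairs_ineligible(self, rng):
        # p0 also amplifies an out-group genome and must not be selected
        cov = {"p0": {"S0", "OUT"}, "p1": {"S0"}}
        pairs, genomes = _cover_instance(rng, cov, 1)
        out_seq = cassette_for(pairs["p0"], insert_len=220, rng=rng)
        genomes.append(_genome(out_seq, accession="OUT", family="OTHER"))
        result = minimal_pair_cover(["S0"], {"S0": [pairs["p0"], pairs["p1"]]}, genomes)
        assert len(result.selected) == 1
        assert result.selected[0].pair.key == pairs["p1"].key

    def test_residuals_reported_when_uncoverable(self, rng):
        cov = {"p0": {"S0"}}
        pairs, genomes = _cover_instance(rng, cov, 2)
        result = minimal_pair_cover(["S0", "S1"], {"S0": [pairs["p0"]]}, genomes)
        assert result.residual == {"S1"}
        assert result.covered == {"S0"}

    @pytest.mark.parametrize("trial", range(8))
    def test_greedy_matches_exhaustive_on_random_instances(self, rng, trial):
        n_species = int(rng.integers(3, 9))
        n_pairs = int(rng.integers(2, 7))
        members = {f"S{i}" for i in range(n_species)}
        cov = {}
        for j in range(n_pairs):
            size = int(rng.integers(1, n_species + 1))
            cov[f"p{j}"] = set(rng.choice(sorted(members), size=size, replace=False))
        pairs, genomes = _cover_instance(rng, cov, n_species)
        result = minimal_pair_cover(
            sorted(members), {"S0": [pairs[name] for name in sorted(cov)]}, genomes
        )
        coverable = set().union(*cov.values())
        assert result.covered == coverable & members
        assert result.residual == members - coverable
        if result.residual == set():
            optimal = naive_minimal_cover_size(members, cov)
            # greedy set cover is within the classic ln(n)+1 factor; on these
            # tiny instances it equals the optimum or exceeds it by at most one
            assert optimal <= len(result.selected) <= optimal + 1

    def test_every_selected_pair_is_exclusive_and_useful(self, rng):
        cov = {"p0": {"S0", "S1"}, "p1": {"S1", "S2"}, "p2": {"S2"}}
        pairs, genomes = _cover_instance(rng, cov, 3)
        result = minimal_pair_cover(
            ["S0", "S1", "S2"], {"S0": list(pairs.values())}, genomes
        )
        for rep in result.selected:
            assert rep.exclusive
            assert rep.matched_in_group & result.covered
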