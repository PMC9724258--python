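# Methods

This note documents the models and procedures implemented in `trnabarcode`,
the defaults that matter, and what the synthetic benchmark does and does not
establish.

## Flank extraction

Mitogenomes are held in 0-based half-open reference-strand coordinates;
GenBank's 1-based inclusive intervals are converted on read and write.
Records default to circular topology (vertebrate mitogenomes are circular),
and both feature lookup and flank search wrap the origin; a record declared
linear never wraps. The COI locus is identified strictly by annotation
label against a fixed synonym table (COI, COX1, CO1, "cytochrome c oxidase
subunit I", …). Unknown labels raise an error rather than being fuzzily
matched: a silently mis-identified locus would corrupt every downstream
primer, whereas a hard error is visible and fixable.

`extract_flanks(record, k)` returns the k nearest tRNA genes on each side
of COI, nearest first, always as reference-strand sequence. Some flanking
tRNAs are encoded on the light strand; reporting everything in one fixed
orientation keeps cross-species comparisons well defined, and the primer
designer takes reverse complements where needed. This is a documented
convention, not a biological claim about tRNA coding strands. Sides with
fewer than k tRNAs set a missing flag; on a circular record a "missing"
side can only arise when the record genuinely lacks tRNAs, so truncated or
incompletely annotated genomes are represented as linear records.

## Similarity score

Pairwise similarity is the identity fraction over the columns of one
optimal global alignment, scaled to 0–1000 (1000 = identical; ≥700 high,
400–699 moderate, <400 low). Alignment parameters default to match +1,
mismatch −1, gap open −2, gap extend −1 — standard DNA settings, all
configurable. Two numerical details:

* Co-optimal alignments of (a, b) and (b, a) can differ in column count, so
  the score is computed on the lexicographically sorted pair, making it
  exactly symmetric.
* A `gap_free` mode scores equal-length pairs position-by-position, which
  makes the score exactly monotone in the number of substitutions; it is
  used where that invariant matters (e.g. property tests).

Group statistics: the intra-group mean is taken over all unordered distinct
pairs (1000 by convention for singletons); the representative member
maximises the row mean of the pair matrix, ties broken by smallest
accession for determinism.

**Merge decision.** During re-grouping, a group merges with its closest
related group (highest representative-to-representative COI similarity)
when the pooled intra-group COI mean drops by at most δ points and stays at
or above θ. Defaults δ = 30, θ = 700 (the high-similarity floor). There is
no canonical statistical test for "no significant difference" here; δ and θ
are explicit, configurable stand-ins chosen so that genuine
misclassifications (two names for one clade, with near-identical COI) merge
while 10–30 %-divergent families never do. On the synthetic twin scenario
the observed drop is 0–5 points, far under δ; unrelated families pool to a
mean several hundred points lower and are rejected by both gates.

## Primer model

Candidates are all substring windows of a flank segment with length 18–26
nt (optimum 21). Hard filters: no N, homopolymer runs ≤ 4, GC in
0.30–0.70, and longest self-complementary run ≤ 8 (a cheap inverted-repeat
proxy for hairpin/dimer screening — deliberately not a thermodynamic fold).
Melting temperature uses the Wallace rule below 14 nt and
64.9 + 41·(GC−16.4)/len otherwise; a simple closed form keeps every score
exactly reproducible in tests. The penalty is

```
w_len·|len − 21| + w_tm·|Tm − 57.5| + w_gc·dist(GC, [0.30, 0.70]) + w_clamp·[no 3′ G/C]
```

with defaults w_len=1, w_tm=1, w_gc=2, w_clamp=3. The absolute weights are
arbitrary but fixed; only the ranking they induce feeds the pipeline.
Pairs combine the top candidates of each side (Cartesian product), ranked
by the sum of the two penalties plus a Tm-difference term; ties break on
(offset, length) so identical inputs always give identical rankings.
Designing at extension depth k means designing *inside the k-th nearest
tRNA*, not across the concatenated flank — primers must sit wholly within
one tRNA gene.

## In-silico PCR

A primer matches a site when it aligns end-to-end (no indels) with at most
`max_mm` mismatches and its three 3′-terminal bases match exactly;
polymerase extension tolerates internal mismatches far better than 3′ ones,
which is also the behavioural summary of short-read mappers used for this
purpose. Both strands are scanned, circular genomes across the origin. An
amplicon requires a plus-strand forward site and a minus-strand reverse
site downstream of it with product length in 200–3000 nt (wide enough for
the full COI gene plus both flanks; configurable). The implementation is a
vectorised sliding-window scan; the test suite holds it equal to a naive
character-by-character oracle over hundreds of random instances.

`max_mm` defaults to 0 (strict: "exclusive" means no other genome carries
an exact amplifiable site) and is configurable up to 3. The single-base
confusable scenario is screened at `max_mm = 1`: under exact matching a
one-base flank difference always leaves some discriminating window, so the
failure mode that motivates flank extension only exists under
mismatch-tolerant mapping. That choice mirrors the reference-mapper
behaviour the method assumes, and is fixed before any outcome is measured.

**Exclusivity and cover.** A pair is exclusive for a group when it
amplifies at least one member and nothing outside the group (a pair that
amplifies nothing is non-exclusive — a barcode primer must amplify its
targets). Multispecies groups are covered greedily: repeatedly take the
eligible pair amplifying the most uncovered members, ties broken by lower
penalty then lexicographic forward sequence. Greedy set cover can exceed
the optimum (by at most the classical ln n factor); on instances up to 12
species the tests compare it with exhaustive search and it is optimal or
one pair larger.

## Two-stage orchestration

Escalation order is fixed: candidate cycling (inside stage-1 design) →
flank extension (to depth `max_k`, default 2 — unbounded extension moves
primers away from COI and into ordinary inter-genic variability, so one
extra segment is the default ceiling) → re-grouping → stage 2. Groups with
*no* covered member escalate through extension and re-grouping; groups that
are only partially covered keep their covered members and forward the
residual species directly to stage 2, where primers are designed per
species (candidates pooled over all extension depths, wider candidate
budget `stage2_top_n = 20`) and screened against the full universe. A
stage-2 pair may be shared by residuals of one group and may amplify other
members of that group, but nothing beyond it. Species that still cannot be
resolved (e.g. records missing a flank entirely) are emitted with status
`unresolved` and a reason — never dropped — so the catalog row count always
equals the universe size.

The pipeline itself contains no randomness: given the same records and
configuration, every run produces the identical catalog.

## Synthetic universes

The generator emulates exactly what the extraction logic needs: the
vertebrate-like cassette `ND2 – tRNA – tRNA – COI – tRNA – tRNA – COX2`
with spacers, one base cassette per universe, families diverged from it
independently at `inter_family_divergence` per site (default 0.15, which
yields ≈ 26 % pairwise divergence between two families), and species
diverged from their family ancestor at `intra_family_sub_rate` (default
0.01). Defaults of 10 families × 5 species, 70 nt flanks and a 1545 nt COI
match the scale of a desk-size benchmark while preserving the real
problem's geometry (primer windows inside 60–90 nt tRNAs, amplicon ≈ 1.7
kb). Mutation is substitution-only so planted mismatch counts are exact
ground truth; an indel-free model also keeps gap-free similarity exact.

Planted scenarios pin the segments that carry the planted relationship
(they are exempt from intra-family mutation) so the planted structure, not
mutation noise, is the only cause of the intended outcome:

* **confusable pair** — family B's nearest flanks copy family A's with
  exactly one substitution, placed at the primer-5′ edge of each segment so
  the 3′-exact rule can never rescue a window; second-nearest flanks are
  ordinarily divergent. Expected path: unresolved at k=1, exclusive after
  extension.
* **twin pair** — two families share one ancestral cassette (a
  misclassified split); flanks pinned in both. No extension depth helps;
  re-grouping merges them into one multi-family group whose pairs are
  exclusive to the union.
* **megafamily** — one family is inflated and five of its species copy a
  decoy family's nearest flanks exactly (so no family-level pair can be
  exclusive for them) while their outermost flanks carry private
  haplotypes, four species sharing one and the fifth its own. Expected
  path: the five residuals reach stage 2 and are covered by exactly two
  pairs; the decoy family itself resolves by extension.
* **missing flank** — records emitted as linear with downstream tRNA
  annotations removed. In a singleton family such a species is
  deterministically unresolved; in a multispecies family a sibling's pair
  may still amplify it (the flank *sequence* is present, only the
  annotation is missing), which is faithful to in-silico PCR and left as
  stochastic behaviour.

**What passing these tests shows — and what it does not.** The benchmark
establishes that each mechanism (extension, re-grouping, stage-2 per-species
design, missing-flank reporting) triggers on the failure mode it was built
for and on nothing else, under a clean substitution model with uniform base
composition. Real mitogenomes add indels, strand-asymmetric composition,
annotation noise, uneven family sizes and much finer gradations of flank
similarity; recovery rates measured here do not transfer to real
collections, and exclusivity at `max_mm = 0` on real data may differ from a
production mapper's notion of a hit.

## Known limitations

* Similarity substitutes an identity-fraction pairwise score for a
  consistency-based multiple-alignment score; both anchor identical
  sequences at 1000, but absolute values on diverged sequences are not
  comparable between the two.
* Dimer/hairpin screening is combinatorial, not thermodynamic; no
  cross-pair dimer check is made within a multi-pair cover.
* Tm uses a GC-count formula, not nearest-neighbour thermodynamics.
* Re-grouping considers only the single closest related group per
  unresolved group, one round; chains of merges across several families
  would need iteration.
* No de-novo tRNA annotation: records must arrive annotated.
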