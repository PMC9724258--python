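# trnabarcode

Discovery of **family-exclusive PCR primer pairs inside the tRNA genes
flanking the mitochondrial COI barcode locus**, for building a DNA-barcode
primer catalog over a collection of annotated fish mitochondrial genomes.

## The problem

The COI gene is the standard animal DNA barcode: conserved within a species,
variable between species. To *read* a barcode you first have to amplify it,
and universal COI primers fail for an appreciable number of taxa. An
alternative is to place the forward primer in the tRNA gene immediately
upstream of COI (L-tRNA) and the reverse primer in the tRNA immediately
downstream (R-tRNA), so the amplicon spans the entire barcode. Because the
flanking tRNAs are conserved within a taxonomic family but diverge between
families, a well-chosen pair can be **exclusive**: across the whole genome
collection it amplifies members of its own family group and nothing else.

`trnabarcode` implements the full two-stage discovery strategy:

1. **Stage 1 (per family).** Genomes are clustered at the family level. For
   each member the nearest flanking tRNA segments are extracted and primer
   candidates are enumerated under standard constraints (length 18–26 nt,
   optimum 21 nt, Tm/GC/homopolymer/self-complement filters). Each candidate
   pair is mapped in silico against every genome (end-to-end, mismatch
   tolerant, exact 3′ anchor) and amplicons are predicted; multispecies
   groups are then covered with a minimal set of group-exclusive pairs by
   greedy set cover, cycling through ranked candidates.
2. **Escalation.** Groups with no exclusive pair are re-designed on the next
   outward tRNA segment (*flank extension*); groups that still fail are
   tested for merging with their closest related group by COI similarity
   (*re-grouping* of likely misclassifications, accepted when the pooled
   intra-group similarity barely drops and stays in the high band).
3. **Stage 2 (per species).** Residual species — members no family-level
   pair could cover — get per-species primer design screened against the
   whole universe; a stage-2 pair may be shared by residuals of one group
   but must amplify nothing outside that group.

The result is a catalog with exactly one entry per input genome: primer
pair, resolution stage, exclusivity status and the related species sharing
the same pair. Sequence similarity throughout is reported on a 0–1000 scale
(identity fraction over one optimal global alignment; 1000 = identical,
≥700 = high similarity).

A fully controlled **synthetic mitogenome generator** accompanies the
pipeline: it emulates the vertebrate gene order `…tRNA–tRNA–COI–tRNA–tRNA…`
with family structure and can plant every hard case (single-base-confusable
flank pairs, misclassified twin families, a megafamily with residual
species, truncated records with a missing flank), so each escalation path is
testable without downloading anything.

## Worked example

```python
from trnabarcode import SimulationConfig, simulate_universe, run_pipeline
from trnabarcode.pipeline import PipelineConfig

records, truth = simulate_universe(
    SimulationConfig(n_families=6, species_per_family=(3, 3), n_confusable_pairs=1, seed=42)
)
result = run_pipeline(records, PipelineConfig(max_mm=1))
for group in result.active_groups:
    print(group.group_id, group.status, group.resolution,
          f"pairs={len(group.assigned_pairs)}", f"k={group.k_used}")
entry = result.catalog[0]
print(entry.accession, entry.f_primer, entry.r_primer, f"stage={entry.stage}")
```

prints

```
F00 exclusive extension pairs=1 k=2
F01 exclusive extension pairs=1 k=2
F02 exclusive stage1 pairs=1 k=1
F03 exclusive stage1 pairs=1 k=1
F04 exclusive stage1 pairs=1 k=1
F05 exclusive stage1 pairs=1 k=1
SYN0000 CGCCCAAGCCATTAAAATTAGACGG AGAGGGCCAGCGAATGGCAAC stage=1
```

Families F00/F01 were planted as a *confusable pair*: their nearest flanks
differ by a single base, so under mismatch-tolerant mapping (`max_mm=1`) no
primer in the nearest tRNA can tell them apart. Both are resolved by
extending to the second-nearest tRNA (`k=2`, resolution `extension`); the
four clean families resolve immediately at stage 1 with one exclusive pair
each. The final line is one catalog entry: the species' forward and reverse
primer (5′→3′ as synthesised) and the stage that produced them.

The same runs from a shell:

```
trnabarcode simulate --seed 42 --n-families 6 --species-per-family 3,3 --confusable-pairs 1 -o uni/
trnabarcode pipeline uni/universe.gb --taxonomy uni/taxonomy.tsv -o run/
trnabarcode lookup run/catalog.tsv "sp00"
```

Real collections are read the same way: GenBank flat files (or FASTA plus a
feature-table TSV) and a taxonomy TSV mapping accession/organism to
family_id.

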