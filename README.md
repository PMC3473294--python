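# mitocircle

Comparative structural analysis of circular organelle genomes, built around
the classic two-mitogenome comparison design: decompose two circular genomes
into near-identical syntenic blocks, catalogue repeats inside each genome,
attribute arrangement differences to repeat pairs sitting at block edges,
extract and annotate the non-syntenic ("unique") regions, compare ORF and
SNP content, and reconstruct a master circle from assembler contigs by a
parsimonious covering-walk rule.

The showcase dataset is the radish (*Raphanus sativus*) mitochondrial genome
pair — DDBJ **AB694743** (normal-type cytoplasm, 244,036 bp) and
**AB694744** (Ogura-type male-sterile cytoplasm, 258,426 bp) — but every
stage is generic over a pair of circular DNA sequences and is tested against
synthetic genome pairs with full construction ground truth.

## What is in the box

| module | role |
| --- | --- |
| `mitocircle.genome_io` | FASTA/GenBank/GFF3/BED/TSV I/O; circular-coordinate arithmetic (`CircularGenome`, `CircInterval`) |
| `mitocircle.matcher` | deterministic seed-and-extend local matching (cross- and self-mode), fragment merging |
| `mitocircle.synteny` | chaining into syntenic blocks (default: >3 kb at >=99.9% identity), signed circular block arrangements, dot-plot export |
| `mitocircle.repeats` | within-genome repeat catalog (default: >80 bp at >90% identity), sub-genomic circle prediction from direct repeat pairs |
| `mitocircle.rearrange` | breakpoint (adjacency) diffing, clustering, repeat-evidence attribution of inversions and junction exchanges |
| `mitocircle.unique_regions` | non-syntenic region extraction, mosaic coverage against a panel of related mitogenomes, nested inverted-repeat integration signatures |
| `mitocircle.gene_content` | six-frame circular ORF prediction, genome-specific ORF comparison, SNP calling with synonymous/non-synonymous classification, motif scanning |
| `mitocircle.master_circle` | contig-graph filtering (linkage depth, plastid screen) and minimum-length covering closed walk assembly |
| `mitocircle.synthetic_data` | fully seeded genome-pair / panel / contig-graph generators with validated truth tables |
| `mitocircle.radish` | one-call recomputation of the headline numbers for the deposited radish pair |
| `mitocircle.pipeline`, `mitocircle.cli` | orchestration and the `mitocircle` command |

## CLI

```bash
# full comparison of two circular genomes (+ optional panel / annotations)
mitocircle full genomeA.fasta genomeB.fasta \
    --panel rapeseed.fasta --panel arabidopsis.fasta \
    --annotations genomeA.gff3 --out results/

# individual stages
mitocircle compare genomeA.fasta genomeB.fasta
mitocircle repeats genome.fasta --min-len 80 --min-identity 0.90
mitocircle snps genomeA.fasta genomeB.fasta --annotations genomeA.gff3
mitocircle orfs genome.fasta --min-aa 100
mitocircle assemble contigs.fasta linkages.tsv --min-link-depth 10
mitocircle simulate --seed 7 --length 60000 --out sim/
mitocircle gc genome.fasta
```

`mitocircle full` writes a deterministic report bundle (blocks, arrangements,
repeat catalogs, sub-circle predictions, breakpoints/events, unique regions
with mosaic coverage and integration signatures, genome-specific ORFs, SNPs,
summary JSON) plus the resolved configuration.

## Conventions

- Internal coordinates are 0-based, end-exclusive and wrap-capable
  (`start + span > length` wraps the origin); all text reports are 1-based
  inclusive, BED output is 0-based half-open.
- Identity is matches / alignment columns; merging counts gap columns as
  mismatches.  Repeat thresholds are strict (>80 bp, >90%); block
  thresholds are inclusive (>=3 kb, >=99.9%).
- Genome A is the reference for block numbering and signs (+k direct, −k
  inverted); for the radish pair genome A is the normal type.
- N bases never extend matches and are excluded from the GC denominator.
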