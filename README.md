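# nrscall

Barcode-aware detection and assembly of **non-reference sequence (NRS)
insertions** from linked-read (synthetic long-read) data, together with a
linked-read simulator and a benchmark harness, so the whole method is
testable end-to-end on a laptop with no external binaries or downloads.

The caller runs in four steps on a barcoded, position-sorted BAM:

1. **Read extraction** — build the set *U* of read pairs with at least one
   mate unmapped, mapped with MAPQ < 10, or carrying > 20% soft-clipped
   bases (pairs must have mean base quality > 20).
2. **Orphan assembly** — assemble *U* with a local de Bruijn graph
   assembler; surviving contigs ("orphan contigs") are insertion candidates.
3. **Barcode recruitment and reassembly** — align *U* back to each orphan
   contig *c*, collect the barcode set *B(c)* of the filtered alignments
   (contigs recruiting fewer than *t* = 5 barcodes are discarded), pool
   *every* read pair sharing those barcodes, and reassemble each pool
   (k = 77, coverage cutoff 3). Long molecules covering the insertion give
   the reassembled contig reference anchors on both sides; off-site
   molecule fragments stay below the coverage cutoff and are removed.
4. **Placement** — align anchored contigs to the reference, keep the
   alignment subset maximizing covered contig bases (exact
   weighted-interval scheduling), and call an insertion wherever adjacent
   alignments are close on the reference but far apart on the contig.
   Calls longer than 300 bp with anchor sum > 300 bp go to the VCF;
   everything else goes to a secondary TSV.

All internal coordinates are 0-based half-open; VCF is 1-based only at the
serialization boundary; CLI regions use the samtools 1-based convention.

## Layout

| module | role |
| --- | --- |
| `io_formats` | FASTA/FASTQ (barcode comments), SAM/BAM (BX tags), VCF 4.2 |
| `read_extraction` | the set-*U* filter |
| `dbg_assembler` | canonical-k-mer de Bruijn assembler (cutoff, tips, bubbles) |
| `pairwise_align` | minimizer seed + gapless diagonal extension; global identity |
| `barcode_recruitment` | B(c) extraction, barcode pooling, pool reassembly |
| `insertion_placement` | alignment-subset DP, insertion signature, VCF/secondary emit |
| `linkedread_sim` | simulator (truth BAM + FASTQ), downsampling, molecule stats |
| `evaluation` | truth matching (100 bp / 5%), length-bin summaries, UIS, concordance |
| `coverage_model` | binomial occupancy model of off-site fragment pile-up |
| `pipeline` | orchestration, caching/resume, run report |

External assemblers/aligners remain pluggable (an assembler is any
`reads -> contigs` callable), but nothing in the tested path shells out.

## CLI

```bash
# simulate a linked-read dataset with implanted insertions
nrscall simulate --out-dir sim --reference-length 1000000 --n-insertions 10 \
    --coverage 65 --molecule-length-mean 10000 --seed 7

# detect insertions
nrscall run --bam sim/truth.bam --reference sim/reference.fasta \
    --workdir work --out-vcf calls.vcf

# benchmark against the simulated truth
nrscall evaluate --calls calls.vcf --secondary calls.secondary.tsv \
    --truth sim/truth.vcf --out bench.json

# other tools
nrscall downsample --in-bam sim/truth.bam --out-bam ds.bam --ratio 0.4 --seed 1
nrscall molecule-stats --bam sim/truth.bam --out molecules.tsv
nrscall uis --vcf sampleA a.vcf --vcf sampleB b.vcf
nrscall coverage-model --n-fragments 100 --n-bins 10000 --m 3
```

`nrscall run --config file` reads flat `key = value` files; explicit flags
win over config values.

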