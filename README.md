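# plastedit

RNA-editing analysis for dinoflagellate plastid minicircle genes:

- **editing-site calling** from mapped RNA-seq and DNA-seq reads
  (strand-resolved pileups; coverage, DNA-SNP-exclusion, strand-bias and
  alignment-end position-bias filters),
- **codon-level consequence annotation** (joint application of co-edits
  within a codon, synonymous/non-synonymous calls, stop-codon
  restoration, alternative start codons UUG/AUA/UUU),
- **per-gene and aggregate summary statistics** (editing-type spectrum,
  transversion fraction, codon-position distribution, GC shift, homolog
  identity before/after editing, molecular-weight and GRAVY hydropathy
  shift, Spearman rank correlation),
- **minicircle core-region feature scanning** (GC-rich inverted repeats,
  the conserved `CACCAATGCACC` motif and its CCAAT-box, TSS candidates
  from 5'-end count tracks, windowed GC profile),
- a **truth-tracked simulator** that generates minicircle-like
  references, plants editing events from a configurable 12-category
  substitution spectrum plus SNPs, and emits pre-mapped reads, so the
  whole pipeline is testable offline; plus a packaged per-gene
  editing-count fixture table (`plastedit.simulate.table1_fixture`).

Sequence data are exchanged as FASTA, alignments as a minimal SAM
dialect (match-only CIGARs; parseable by samtools/pysam), sites as TSV
and a VCF-like format, features as GFF3 and JSON. Internal and TSV
coordinates are 0-based half-open; VCF/GFF3 are 1-based.

## Command line

```sh
# simulate references, planted edits/SNPs, pre-mapped reads, a minicircle
plastedit simulate --seed 11 --out-dir sim --n-genes 3

# call editing sites (RNA vs DNA pileups, default thresholds: depth >= 11,
# majority edited fraction, >= 3 edited reads, SNP and bias filters)
plastedit call --references sim/references.fasta \
    --rna sim/rna.sam --dna sim/dna.sam --out-dir called

# codon-level annotation + per-gene summary + aggregate statistics
plastedit consequences --references sim/references.fasta \
    --sites called/sites.tsv --out-dir report

# scan a minicircle for IRs / motif / CCAAT / TSS candidates
plastedit features --fasta sim/minicircle.fasta \
    --five-prime-counts sim/five_prime_counts.tsv --out-dir feat

# summarize the packaged per-gene editing-count table
plastedit summarize --fixture table1 --out-dir fixture_report

# validate a summary table; run the whole pipeline from a YAML config
plastedit validate --summary report/summary.tsv
plastedit run --config pipeline.yaml
```

All outputs embed the tool version, parameter set and seed, and writers
are deterministic (fixed column order and rounding, no timestamps), so
reruns are byte-identical.

The strand/position bias tests are explicit, parameterized stand-ins for
a manual inspection step: strand bias fails only when a two-sided Fisher
exact test is significant *and* all edited-base observations sit on one
strand of a two-strand column; position bias fails when >= 90% of edited
observations lie within 10 nt of an alignment end that is not flush with
a reference boundary. A minimum edited fraction of 0.5 is a
conservative, configurable majority rule. Eubacterial promoter
prediction is not re-implemented; the feature scanner reports CCAAT
boxes and candidate regions only.

## Layout

```
src/plastedit/
  core.py          gene records, translation (table 11, alternative starts),
                   edit-type classification, GRAVY/MW/GC descriptors
  constants.py     Kyte-Doolittle scale, average residue masses
  io.py            minimal SAM dialect, 5'-end count tracks
  simulate.py      simulator + truth records + packaged fixture
  calling.py       pileups, filters, editing-site calling, TSV/VCF writers
  consequences.py  codon annotation, summaries, aggregates, identity,
                   hydropathy/MW shift, Spearman rank
  features.py      inverted repeats, motif/CCAAT scan, TSS, GC profile
  cli.py           click CLI, pipeline config, summary validation
  data/table1.tsv  packaged per-gene editing-count fixture
```
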