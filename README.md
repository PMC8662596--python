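# mttrnaseq

Analysis toolkit for dual-compartment (mitochondrial-isolate vs
total-cellular) tRNA sequencing. It covers the full desk-side workflow:

* **reference_db** — tRNA gene records, intron excision, collapsing of
  identical mature sequences into mapping references (within origin only;
  cross-origin identities are kept separate and warned about), GFF3/GenBank
  annotation parsing to 0-based half-open coordinates, and the mitogenome
  anticodon inventory with CAU decoding-class disambiguation
  (elongator-Met / initiator / Ile-lysidine).
* **read_prep** — length filtering of merged reads (default 50–95 nt),
  collapsing identical reads into families with per-library counts, and the
  minimum-total-count filter (default ≥3).
* **mapper** — explicit Smith–Waterman local alignment (match +1, mismatch
  −1, gap −2, score floor 30; numba-accelerated with a pure-Python fallback)
  with BLAST-style identity (gap columns count) and query-coverage
  percentages; unique-assignment rule (≥90% identity, ≥80% coverage, exactly
  one surviving reference, ties discarded); all-locus genome mapping;
  count matrices; reference-based contaminant screening.
* **cca_survey** — strand-aware detection of post-transcriptional vs
  genome-encoded 3′ CCA tails, closest-feature classification of non-tRNA
  loci into t-elements (≤150 bp from a feature by default) vs orphan
  stem-loops, per-library non-tRNA CCA percentages, and an advisory
  base-pair-maximization fold heuristic with a cloverleaf-shape flag.
* **quantify** — TMM-style scale factors, CPM normalization, the <2 CPM
  expression filter, pseudocount ratio-of-means log2 enrichment
  (mito-isolate vs total-cellular), expression-weighted per-anticodon family
  enrichment, and per-origin compartment depletion summaries.
* **import_analysis** — import/exclusion prediction per cytosolic anticodon
  family from the mitogenome inventory (lysidine rule: mt Ile(CAU) excludes
  cytosolic Ile(UAU)), Welch's t-test of the group separation, and
  cross-species gene-loss shift flags.
* **synthetic_data** — fully seeded simulator producing reference sets, an
  annotated toy mitogenome with t-element/orphan loci, and multinomial
  dual-compartment FASTQ libraries with configurable per-family import
  effects, misincorporation noise and known ground truth.
* **genome_stats** — genome record statistics: length, GC%, longest exact
  substring present at ≥N genomic locations (circular-aware), intact tRNA
  feature counts.

## CLI

```bash
mttrnaseq simulate --config sim.yaml --outdir sim/          # synthetic experiment
mttrnaseq build-refs --table genes.tsv --out-fasta refs.fasta --out-tsv refs.tsv
mttrnaseq map --refs-fasta refs.fasta --refs-tsv refs.tsv \
    --reads-manifest sim/manifest.tsv --outdir map/
mttrnaseq quantify --counts map/counts.tsv --manifest sim/manifest.tsv \
    --refs-tsv refs.tsv --outdir quant/
mttrnaseq import-test --summaries quant/anticodon_summaries.tsv \
    --mito-table mito_genes.tsv --out import.json
mttrnaseq cca-survey --reads-manifest sim/manifest.tsv \
    --genome-fasta sim/mito_genome.fasta --annotation sim/mito_genome.gff3 \
    --outdir cca/
mttrnaseq genome-stats --genbank record.gb
```

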