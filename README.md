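# sigmascan

Comparative-genomics toolkit for sigma-54 (-24/-12) regulation: a
frequency-sum motif similarity score for promoter discovery, rule-based
identification and classification of sigma-54 enhancer-binding proteins
(EBPs), taxonomic presence/absence summaries, and extraction of cross-phylum
conserved function tendencies from genomic context. A seeded synthetic-data
generator produces full input bundles with planted ground truth, so the
whole pipeline can be exercised and verified end to end without external
databases.

## What it does

- **`sigmascan.motif`** — position-frequency matrices (DNA and protein) with
  the frequency-sum similarity score: the score of a sequence is the mean,
  over columns, of the frequency of its symbol in that column (range 0–1, no
  pseudocounts). Includes information-content smoothing/trimming of
  uninformative columns and a degeneracy readout of the build set.
- **`sigmascan.promoters`** — both-strand genome scanning at a fraction of
  the maximum attainable score (default 85%), hit ranking, linkage of hits
  to the nearest gene on each side with signed distances from the motif's
  -11 anchor to the translation start, the -50..300 upstream window filter,
  and 100-nt distance histograms.
- **`sigmascan.ebp`** — sigma-54 ortholog detection (e-value ≤ 1e-20),
  34-seed e-value profiles with product (< 1e-5, computed in log space) and
  sum (< 1) filters, location and rule-based classification of the GAFTGA
  activator loop (functional / putative / inactive, deletions inactive),
  domain-architecture typing (Ia/Ib/Ic/II, <400-aa heuristic for Ic), and
  coarse annotation by the closest verified seed.
- **`sigmascan.survey`** — per-phylum presence counts with mean ± discrete
  (integer-rounded) SD of EBP counts, 1-Mb genome-size binning, motility
  fractions, and EBP-count fraction surfaces.
- **`sigmascan.context`** — operons (same-strand runs, gaps ≤ 300 nt) and
  divergons, ±10-gene context windows, promoter contexts (1 gene upstream,
  ≤10 downstream), per-phylum annotation aggregation, top-10/20 cross-phylum
  conserved-tendency extraction (≥2 phyla), and COG-category
  over-representation flags against a background (one-sided binomial test).
- **`sigmascan.simulate`** — deterministic synthetic genomes with operon
  structure and planted promoter sites, proteins with chosen loop variants
  and engineered e-value profiles, and annotation tables with planted
  enriched terms, all recorded in a ground-truth manifest.
- **`sigmascan.io` / `sigmascan.pipeline` / `sigmascan.cli`** — FASTA, GFF3,
  BLAST outfmt-6, PFM-TSV and annotation/metadata TSV readers and writers,
  a validated pipeline configuration, and the command-line interface.

## CLI

```bash
# generate a seeded synthetic bundle with ground truth
sigmascan simulate --seed 1 --outdir bundle/

# run every stage on it
sigmascan run-all --indir bundle/ --outdir results/

# individual stages on any compatible files
sigmascan build-pfm sites.txt --out pfm.tsv --tss-offset 13 --smooth 0.2
sigmascan scan genome.fasta --pfm pfm.tsv --gff genes.gff3 --out hits.tsv
sigmascan ebp --blast blast.tsv --seeds seeds.tsv --proteins prot.faa \
              --domains domains.tsv --out ebp.tsv
sigmascan survey --metadata metadata.tsv --presence presence.tsv \
                 --ebp-table ebp.tsv --outdir survey/
```

`run-all` accepts `--config config.yaml` to override any
`PipelineConfig` field (flags beat the file; unknown keys are rejected).
Result TSVs use 1-based inclusive coordinates; internally everything is
0-based half-open.

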