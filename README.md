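# fusionkd

Fusion-aware transcript quantification and knockdown/drug-screen analytics
for a fusion-driven sarcoma model, as a tested, reusable pipeline:

- **Split ("edited") reference** construction: each fusion partner gene is
  replaced by a 5' and a 3' half-transcript cut at the breakpoint exon, so
  reads disambiguate fusion-derived from wild-type-derived fragments. A
  junction panel (breakpoint contig plus one diagnostic contig per ±KTS
  splice variant) sits alongside the counting features.
- **Quantification** by exact strand-canonical k-mer seeding: a read pair's
  candidate features are the intersection of feature sets over all indexed
  k-mers of both mates (`unique_only` or `fractional` policies), with RPKM
  normalisation and a conservation guarantee (Σ rpkm·L = 1e9 per sample).
- **Breakpoint detection** at exon resolution from junction-spanning reads,
  and **±KTS isoform counting** via w-mers unique to one junction contig.
- **Target calling** with the two-hairpin intersection rule: genes at least
  25% up- or down-regulated versus the non-targeting control under *both*
  hairpins, gated at 5 RPKM; plus gene-set overlap reports, Z-score gene
  sets, and gene-set mean-expression comparison.
- **Drug-screen analytics**: DMSO normalisation, range-normalised AUC over
  log10 dose, cross-model AUC Z-scores (sample sd), 4PL dose-response
  fitting with IC50, and plasma-concentration hit selection.
- **Synthetic data** generators for all of the above with full truth tables
  (per-read source labels, planted target genes, true 4PL parameters,
  sensitive-compound list), deterministic under a seed.

## Command line

```sh
# generate synthetic inputs (annotation, FASTQ, RPKM tables, screen plates)
fusionkd simulate reads  --seed 7 --outdir sim/
fusionkd simulate rpkm   --seed 7 --outdir sim/
fusionkd simulate screen --seed 7 --outdir sim/

# build the split reference and quantify a sample
fusionkd build-ref --annotation sim/annotation.tsv --fusion sim/fusion.json \
    --flank 30 --out ref.fasta
fusionkd quantify --annotation sim/annotation.tsv --fusion sim/fusion.json \
    --r1 sim/NT_dox_8h_R1.fastq --r2 sim/NT_dox_8h_R2.fastq \
    --k 21 --policy unique_only --out counts.tsv

# call knockdown target genes from an RPKM table
fusionkd call-targets --rpkm sim/rpkm.tsv --meta sim/meta.json \
    --fc 0.25 --cutoff 5 --time 32 --out targets.json

# screen analytics with plasma-level hit selection
fusionkd screen --plates sim/plates.csv --plasma plasma.csv \
    --focus-model model1 --out screen.json
```

`fusionkd simulate` accepts a YAML config (`--config sim.yaml`) overriding
any `SimConfig` field; every generator writes a `truth.json` next to its
outputs.

## Layout

```
src/fusionkd/
  reference.py   gene models, fusion specs, split reference, breakpoint calls
  quantify.py    k-mer index/assignment, RPKM matrices, isoform counts, time-course
  targets.py     target calling, gene sets, overlaps, Z-scores
  screen.py      plate normalisation, AUC, Z-scores, 4PL fits, hits
  synthdata.py   seeded generators + truth tables
  io.py          FASTA/FASTQ/TSV/JSON readers and writers
  cli.py         click command group
```
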