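# cisclust

Composite cis-regulatory cluster scanning and promoter-set enrichment
analysis. The package implements:

- **Motif models** (`cisclust.motif_model`): count-based binding-site
  matrices (JASPAR-like files), log2-odds scoring matrices, *exact*
  theoretical score distributions under an order-0 background computed by
  position-wise convolution on a discretised score grid, and conservative
  upper-tail p-values (reported p-value is never smaller than the exact
  enumeration p-value). Column-permuted null matrices preserve the
  theoretical score distribution while destroying the biological word.
- **Sequence/interval I/O** (`cisclust.sequence_io`): FASTA (case preserved;
  lowercase/N = repeat-masked), BED6, a minimal GFF3 subset, fixed-length
  promoter extraction upstream of TSSs (1 kb / 2 kb / custom, strand-aware,
  truncation logged), and non-coding region complements (default minimum
  length 60 nt). All coordinates are 0-based half-open internally.
- **Scanner** (`cisclust.scanner`): double-stranded window scanning with
  p-value thresholds (masked windows are unscoreable and excluded from
  denominators), anchor+partner composite-cluster detection with an
  edge-to-edge spacing window (default 40 nt, either side, overlap = gap 0),
  and cluster densities per kilobase of unmasked sequence.
- **Enrichment** (`cisclust.enrichment`): observed-vs-theoretical site-rate
  curves over an alpha grid (10^-1 … 10^-6, half-decade steps), control
  bands from random promoter-set draws and from column-permuted matrices
  rescanned on the same promoters, endoderm-vs-ectoderm comparison with a
  declared verdict rule (curve above the permutation band's 97.5th
  percentile at every achievable alpha ≤ 1e-3) plus Bonferroni-adjusted
  one-sided binomial tests.
- **Synthetic data** (`cisclust.synthetic_data`): order-k Markov background
  models (train/sample), consensus-derived stand-in matrices for the three
  Hox/Pbx site classes (TGATTGAT / TGATTAAT / TGATTTAT) and the Meis site
  (TGACAG), lowercase repeat tracts, and promoter sets with planted
  anchor+partner clusters at controlled rates and spacings, with ground
  truth emitted alongside.
- **HX scanning** (`cisclust.hx_motif`): hexapeptide candidates in protein
  sequences — a tryptophan with K/R at offset +2..+5, flagged for
  hydrophobic context at the immediate neighbours, optionally positioned
  relative to an annotated homeodomain.
- **Pipeline + CLI** (`cisclust.pipeline`, `cisclust.cli`): end-to-end
  enrichment and density analyses from a single config with digests,
  per-stage counts and full seed provenance; reruns are byte-identical.

## CLI

```bash
# generate synthetic promoter sets with planted clusters + ground truth
cisclust simulate --n-per-set 38 --length 1000 --seed 1 --out simulated/

# scan sequences with one or more count matrices
cisclust scan --fasta simulated/promoters_endoderm.fa \
    --matrix simulated/matrices/hoxpbx_classII.counts \
    --alpha 1e-4 --background uniform --out hits.bed

# composite clusters (anchor + Meis within 40 nt)
cisclust clusters --fasta simulated/promoters_endoderm.fa \
    --matrix simulated/matrices/hoxpbx_classII.counts \
    --meis-matrix simulated/matrices/meis.counts \
    --alpha 1e-3 --window 40 --out clusters.tsv

# endoderm-vs-ectoderm enrichment with permutation + random-set controls
cisclust enrich --endoderm simulated/promoters_endoderm.fa \
    --ectoderm simulated/promoters_ectoderm.fa \
    --pool simulated/promoters_pool.fa \
    --matrix simulated/matrices/hoxpbx_classII.counts \
    --meis-matrix simulated/matrices/meis.counts \
    --n-perms 100 --n-random 100 --seed 1 --out report/

# cluster density across region sets + permuted-matrix enrichment ratios
cisclust density --regions endo=simulated/promoters_endoderm.fa \
    --regions bg=simulated/promoters_ectoderm.fa \
    --matrix simulated/matrices/hoxpbx_classII.counts \
    --meis-matrix simulated/matrices/meis.counts \
    --seed 1 --out report/

# promoter extraction and hexapeptide scanning
cisclust extract-promoters --genes genes.bed --genome genome.fa \
    --upstream 1000 --out promoters.fa
cisclust hx-scan --proteins proteins.fa --out hx.tsv
```

Exit codes: 0 on success, 2 on validation/usage errors.

## Conventions and defaults

- Pseudocount 0.25 per matrix cell; log base 2; score-grid bin width 0.01
  (column scores are rounded *up* inside the distribution DP, so p-values
  are conservative; use a finer bin width, e.g. 0.001, when calibration at
  alpha ≤ 1e-4 matters).
- Background: order-0 frequencies estimated from the scanned set
  (`--background auto`) or uniform (`--background uniform`). The p-value
  theory is order-0 even when synthetic backgrounds are higher-order Markov.
- Site calling: alpha 1e-4 for anchors, 1e-3 for partner (Meis) sites in
  cluster analyses (a width-6 matrix cannot attain p < 2.4e-4 under a
  uniform background); both configurable.
- "Within 40 nt" = edge-to-edge gap ≤ 40 on either side of the anchor;
  partner strand and side are unconstrained.
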