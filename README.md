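# rohscan

Runs of homozygosity (ROH), genomic inbreeding coefficients, ROH-island
consensus regions and haplotype-based selection scans for dense diploid
SNP panels — the analysis stack used to characterise genetic diversity
and adaptation in small livestock and village-flock populations
(10–50 individuals, ~1 SNP per 1–10 kb).

## What it computes

- **Marker QC** — sample/SNP call-rate filters, an exact conditional
  Hardy–Weinberg test, MAF floor.
- **Diversity** — per-SNP observed/expected heterozygosity
  (Ho, He = 2p(1−p)), per-individual multi-locus heterozygosity
  MLH = (N−O)/N, distance-binned LD decay (r² of dosages), greedy
  sliding-window LD pruning, dosage-standardised PCA, and the
  two-population Weir–Cockerham (1984) Fst with both ratio-of-sums and
  mean-of-ratios genome-wide estimates.
- **ROH detection** — PLINK-style scanning windows: 50-SNP windows with
  ≤ 3 heterozygous and ≤ 5 missing calls, a SNP is in homozygous state
  when ≥ 5% of its covering windows are eligible; runs are split at
  > 1 Mb gaps, trimmed to homozygous end calls, and kept when they have
  ≥ 50 SNPs, ≥ 300 kb, and ≥ 1 SNP per 50 kb; segments are classed
  short (< 1 Mb), medium (1–3 Mb) or long (> 3 Mb).
- **Inbreeding** — F_ROH = ΣL_ROH / L_aut, F_HOM = (O−E)/(L−E),
  the diagonal-GRM estimator F_GRM and the uniting-gametes estimator
  F_UNI, plus their Pearson correlation matrix.
- **ROH islands** — per-SNP incidence (distinct individuals whose ROH
  cover the SNP), top-1% threshold with ties, merging of consecutive
  qualifying SNPs, BED interval annotation and cross-population sharing.
- **Selection scan** — extended haplotype homozygosity
  EHH(x) = Σ C(n_k,2)/C(n,2), integrated iHH per allele (trapezoid over
  physical distance, truncated at EHH < 0.05), uniHS = ln(iHH_A/iHH_D)
  standardised within derived-allele-frequency bins, the tail transform
  p_iHS = −log10(1 − 2|Φ(iHS) − 0.5|), and top-0.1% candidate flagging.
- **Simulation** — a founder-mosaic generator producing phased panels
  with distance-decaying LD, plus planted autozygous tracts, planted
  partial sweeps and Balding–Nichols two-population divergence, so every
  estimator can be validated against known truth.

## Worked example

```bash
rohscan simulate --n-samples 20 --n-snps 6000 --length-bp 30000000 \
    --seed 5 --plant-froh 0.08 --sweep 15000000:0.8:1000000 --out sim.vcf
# wrote 20 samples x 6000 SNPs -> sim.vcf
rohscan qc sim.vcf --maf-min 0.01 --out clean.vcf
# kept 20 samples x 3304 SNPs -> clean.vcf
rohscan roh clean.vcf --out roh.tsv
# detected 57 segments -> roh.tsv
rohscan inbreeding clean.vcf --roh-table roh.tsv --out inb.tsv
# wrote inbreeding table for 20 samples -> inb.tsv
rohscan islands clean.vcf --roh-table roh.tsv --out islands.bed
# called 1 islands -> islands.bed
rohscan ihs sim.vcf --region 1:10000000-20000000 --out ihs.tsv
# scanned 889 SNPs (1 candidates) -> ihs.tsv
```

`inb.tsv` holds one row per individual with its four inbreeding
coefficients: here F_ROH averages 0.125 (planted autozygosity ~0.08–0.11
per sample plus the window-edge overrun expected at this coarse ~9 kb
marker spacing — see `docs/methods.md`), with F_HOM/F_GRM/F_UNI ranking
the samples concordantly. The single called island,
`1  14671102  15155353`, is the genome stretch where ROH pile up across
individuals — the planted sweep region around 15 Mb — and `ihs.tsv`
lists per-SNP iHH areas, standardized iHS, p_iHS and the candidate
flag; the top-0.1% candidate at position 13,370,024 sits on the swept
haplotype.

The same operations are importable as a library
(`rohscan.detect_roh`, `rohscan.ihs_scan`, …); see the docstrings and
`docs/methods.md` for the underlying models.

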