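# imprintatlas

Calling and classifying genomic imprints from reciprocal F1 hybrid
allele-resolved data.

Genomic imprinting is parent-of-origin-dependent monoallelic gene
expression. Crossing two inbred strains in both mother/father
orientations (reciprocal crosses) separates true parent-of-origin
effects from strain effects: an imprinted gene keeps its parental bias
in both crosses, while a strain-biased gene flips. `imprintatlas`
implements the full inference chain used to build an imprinting atlas
from such data in embryonic (epiblast) and extraembryonic (ectoplacental
cone, EPC) tissues:

* **Allelic expression caller** — per transcript and sample the paternal
  expression ratio `p / (p + m)` of allele-resolved read coverage, with
  sentinel codes for unexpressed transcripts (RPKM < 1 → `−2`) and
  insufficient allelic coverage (both allelic RPM < 0.5 → `−1`); a
  two-sided one-sample t test of valid ratios against 0.5 with
  Bonferroni control, a minimum-valid-sample gate, and a blood-expression
  filter that removes maternal EPC calls likely caused by maternal
  decidua contamination.
* **Parental-effect linear model** — per gene,
  `log2(allelic RPM + 0.5) ~ parent + strain` over both alleles of every
  sample, which the reciprocal design renders identifiable; residual
  variances are shrunk by empirical Bayes (scaled-inverse-χ² prior,
  method of moments on log variances, the classic moderated-t
  construction), followed by Benjamini–Hochberg control and a ≥ 4-fold
  allelic-change gate.
* **DMR caller** — allele-resolved CpG methylation is smoothed with a
  coverage-weighted 500-bp window; CpGs with > 10 % smoothed
  maternal–paternal difference and Fisher-exact p < 0.001 are grouped
  into differentially methylated regions (DMRs), which are merged across
  tissues, summarised against oocyte and sperm methylomes, classified as
  gametic (germline imprint), somatic (post-fertilization), or
  gametes-hypermethylated, and filtered at ≥ 2 covered CpGs per sample
  and ≥ 50 % parental difference.
* **Integrator** — joins expression calls, DMRs (5-kb-upstream promoter
  assignment), oocyte H3K27me3 domains and ZFP57 motif scans (hexamer
  `TGCCGC` / reverse complement `GCGGCA`) into a per-gene atlas labelled
  **canonical** (gametic DMR) or **non-canonical** (paternal-specific
  EPC expression without a germline DMR, with somatic maternal DNAme or
  oocyte H3K27me3).
* **Comparative epigenome** — Spearman correlation of marks over
  syntenic 1-kb bins across two genomes, species-specific H3K27me3 bins
  (ΔK27 > 0.5 RPKM with reciprocal ΔDNAme > 75 points), and mark-domain
  calling with 3-kb gap grouping.
* **XCI analysis** — per-sample comparison of X-linked vs autosomal
  paternal-ratio distributions with a rank-sum test, detecting imprinted
  (paternal) X inactivation in extraembryonic samples.
* **Synthetic generator** — reciprocal-cross datasets with known truth:
  negative-binomial totals, beta-binomial allelic splits per gene class,
  planted gametic/somatic DMRs, planted species-specific H3K27me3
  domains, and paternal-X silencing in EPC samples.

## Worked example

```sh
imprintatlas simulate --seed 4 --out simout/
imprintatlas call-expression --counts simout/allelic_counts.tsv \
    --annot simout/annotation.tsv --blood simout/blood_rpkm.tsv \
    --tissue EPC --out simout/calls_epc.tsv
imprintatlas call-dmrs --cpg simout/cpg_report.tsv --out simout/dmrs.bed
imprintatlas xci --counts simout/allelic_counts.tsv \
    --annot simout/annotation.tsv --tissue EPC --out simout/xci.tsv
```

which prints

```
310 transcripts tested, 89 imprinted
7 DMRs written to simout/dmrs.bed
 sample_id  mean_autosome   mean_x              direction
EPC_AxB_r1       0.509275 0.201477 paternal_X_inactivated
EPC_AxB_r2       0.510718 0.194021 paternal_X_inactivated
```

The 310 tested transcripts are those passing the expression and allelic
coverage filters; the 89 imprinted calls include the planted paternal
and maternal imprints, the decidua-contaminated genes (subsequently
flagged by the blood filter), and X-linked transcripts whose maternal
bias in EPC reflects the planted paternal-X inactivation, visible in the
XCI table as X-linked mean ratios near 0.2 against autosomal means near
0.5. The 7 DMRs recover the planted gametic and somatic regions with
their origin labels.

The same operations are available as library functions
(`imprintatlas.call_imprinted_ttest`, `imprintatlas.call_parent_of_origin_dmrs`,
…) on pandas data frames.

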