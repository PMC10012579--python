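# Methods

## The inference problem

In an F1 hybrid from two sequenced inbred strains, reads overlapping
informative variants can be assigned to the maternal or paternal
haplotype. A single cross confounds parent of origin with strain;
reciprocal crosses (A♀×B♂ and B♀×A♂) break the confound because the
strain identity of each parental allele flips while parent of origin
does not. `imprintatlas` operates downstream of alignment and allelic
read assignment: its inputs are per-transcript allelic read counts,
per-CpG allelic methylation counts, binned histone-mark tracks and a
cross-species synteny map, all as plain TSV/BED/bedGraph. Coordinates
are 0-based half-open throughout; CpGs are keyed to the + strand
cytosine (strand collapsing is assumed upstream).

## Expression caller

For transcript *t* and sample *s*, RPKM = reads / (library·10⁻⁶ ×
exonic kb) and allelic RPM = allelic reads / (library·10⁻⁶). Cells of
the transcripts × samples ratio matrix hold the paternal ratio
p/(p+m), or the sentinel −2 when RPKM < 1 (not expressed) or −1 when
both allelic RPM < 0.5 (not allele-resolvable). Sentinels never enter
statistics.

Valid cells are tested per transcript with a two-sided one-sample
t test against 0.5. The null of 0.5 is our choice — balanced biallelic
expression — since departure from balance is what "monoallelic bias"
means here; both reciprocal crosses are pooled into one sample set, so
strain-biased transcripts (ratios straddling 0.5 across crosses) gain
variance rather than signal and are not called. Bonferroni correction
uses, by default, the family of transcripts with at least `min_valid`
valid samples (6; 4 is the conventional choice for sparser designs);
a switch (`family="filtered"`) instead counts every transcript with ≥ 1
valid sample. A call requires adjusted p < 0.05 *and* ≥ `min_valid`
valid samples; direction follows the mean ratio. Zero-variance cell
sets take the t-statistic limit: p = 0 if the common value differs from
0.5, p = 1 otherwise. No minimum effect-size gate is applied on this
path (the linear-model path has one).

Extraembryonic (EPC) tissue is dissected from maternal decidua, so
maternal RNA contamination can masquerade as maternal imprinting.
Maternal EPC calls whose transcript is expressed in adult blood
(RPKM > 1) are therefore flagged `blood_expressed` and excluded from the
final maternal list; rows are retained with the flag so the evidence is
auditable. Paternal and epiblast calls are unaffected.

## Parental-effect linear model

Genes with allelic RPM ≥ 0.5 on either allele in ≥ 2 replicates in
*both* crosses contribute two observations per sample,
y = log2(allelic RPM + 0.5), with covariates parent ∈ {−1, +1} and
strain ∈ {−1, +1}. Within one cross the two covariates are collinear;
jointly over reciprocal crosses they are identifiable — this is the
minimal design the reciprocal layout supports. We fit per tissue
separately (whether tissue should enter one joint model is genuinely
open; separate fits keep the contrasts interpretable). `beta_parent`
is reported as the paternal−maternal log2 difference (twice the ±1
coefficient), so the ≥ 4-fold gate reads |beta_parent| ≥ 2.

Variance moderation follows the classic moderated-t construction:
gene residual variances s² with d degrees of freedom are modelled as
s² ~ s0²·(χ²_d/d)·(d0/χ²_{d0}); d0 and s0² are estimated by method of
moments on log s² (digamma/trigamma matching, trigamma inverted by
Newton iteration), and the posterior variance (d0·s0² + d·s²)/(d0 + d)
on d0 + d degrees of freedom feeds the t statistic. When the observed
spread of log s² does not exceed its sampling component, d0 = ∞ and all
posterior variances collapse to s0² (equal to the common value when
variances are literally identical); at d0 = 0 the statistic reduces to
the ordinary t. The implementation is numerically identical to the
reference R implementation of this estimator (cross-checked in the test
suite). With a single parent contrast the F statistic equals t², so a
two-sided moderated t is used. Calls require Benjamini–Hochberg
adjusted p < 0.05 and the fold-change gate, with direction by sign.

Known limitation: the log-pseudocount transform attenuates the
estimated parental effect when allelic RPM is comparable to the
pseudocount; at RPM ≳ 10 on the minor allele the bias is below
0.1 log2. The pseudocount is configurable.

## DMR caller

Replicates and reciprocal crosses are pooled by summing counts per CpG
per parental allele. Smoothed methylation per allele is the
coverage-weighted mean of raw fractions within ± 250 bp (an isolated
CpG keeps its raw fraction) — a transparent, oracle-checkable smoother
chosen in place of a published kernel smoother whose internals are not
restated here; the screening thresholds (delta > 10 points, p < 0.001)
are kept. The per-CpG p-value is a two-sided Fisher exact test on the
pooled raw 2×2 counts, evaluated for CpGs passing the delta screen;
candidacy requires both. Candidates are grouped greedily per chromosome
with inter-CpG gaps ≤ 300 bp; groups need ≥ 3 candidate CpGs and a
span ≥ 50 bp (grouping defaults are ours; all configurable). Per-tissue
DMR sets are interval-union merged.

Each merged DMR is summarised per sample: unweighted mean methylation
(percent) over CpGs covered by ≥ 5 reads (total tracks) or ≥ 1 read
(allele-resolved tracks, gametes included). Origin classification, in
precedence order gametic > gametes-hypermethylated > somatic >
ambiguous:

* gametic_maternal — oocyte − sperm ≥ 50 points and tissue
  maternal − paternal ≥ 50 in the same direction (mirror for paternal);
* gametes_hypermethylated — both gametes ≥ 75 % (cutoff ours,
  configurable);
* somatic_maternal/paternal — |oocyte − sperm| < 50 with a tissue
  allelic delta ≥ 50 (methylation acquired post-fertilization, the
  DNAme signature of non-canonical imprinting);
* ambiguous otherwise, including missing gamete data (flagged).

The final filter keeps DMRs in which every required sample has ≥ 2
covered CpGs and some tissue parental delta is ≥ 50 points. Because the
smoother and per-CpG test are deliberate substitutes for a published
package's defaults, genome-scale DMR *counts* from that package are not
reproduced; correctness is validated against planted truth instead
(boundary Jaccard, origin labels, null behaviour).

## Integrator

The DMR nearest each gene's TSS (ties to the smaller start) is related
as promoter (overlapping the TSS or the 5-kb window immediately
upstream, strand aware), intragenic, or distal with signed TSS
distance. ZFP57 sites are all occurrences of the hexamer TGCCGC on
either strand — reported on the + sequence as TGCCGC (+) or its reverse
complement GCGGCA (−); overlapping matches all count. The hexamer is
pinned by the documented gain substitution GCAGCG→GCGGCA, with GCGACA
as the known abrogating variant.

Mode labels are deterministic given upstream calls: **canonical** =
imprinted in ≥ 1 tissue with an assigned gametic DMR;
**non_canonical** = paternal in EPC, not paternal in epiblast (a weak
non-significant same-direction epiblast bias above ratio 0.7 does not
block the label; configurable), no gametic DMR, and a somatic-maternal
DMR or oocyte H3K27me3 overlap; **transient_candidate** = H3K27me3
overlap with biallelic expression in both tissues ("primed" loci);
otherwise unclassified. Maternal EPC calls flagged `blood_expressed` do
not count as imprinted but remain in the atlas with their flag. Two-DMR
manual curations in real data are supported by passing an override DMR
list rather than encoding curation.

## Comparative epigenome and XCI

Syntenic 1-kb bin pairs are joined into one row per pair (bins missing a
value are dropped and counted). Spearman correlation uses average ranks;
constant vectors are flagged rather than silently returned. A bin is
genome-A-specific H3K27me3 when K27(A) − K27(B) > 0.5 RPKM and
DNAme(B) − DNAme(A) > 75 points (mirror for B) — the pattern of a
Polycomb domain in one species standing in for DNA methylation present
in the other. Mark domains are maximal runs of bins ≥ a threshold (by
default the 90th percentile of nonzero levels, since peak-caller
internals are not restated; an absolute threshold is supported), merged
across gaps ≤ 3 kb; domain-size comparison reports mean_A − mean_B in
bp and as a percentage of mean_A, so (10 kb, 37 %) reads "B's domains
are 10 kb (37 %) smaller".

For XCI, each sample's valid X-linked ratios are compared with its
autosomal ratios. The underlying observation is distributional, so a
Wilcoxon rank-sum location test (our addition, alpha 0.05) makes the
skew assertable: significant with X mean below the autosomal mean ⇒
paternal_X_inactivated (the rodent extraembryonic pattern), mirror ⇒
maternal_X_inactivated. Samples with no valid X cells (the signature of
an XO genotype) receive a QC flag rather than auto-exclusion.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the inference relies
on, with defaults fixed once as the package's study conditions:

* two reciprocal crosses × 3 replicates × 2 tissues (duplicate-or-
  triplicate designs are the field norm at these embryo stages);
* totals negative binomial (mean 500 per exonic kb, dispersion 0.05),
  30 % of reads allele-informative, allelic splits beta-binomial with
  concentration 200 — replicate overdispersion the t test must survive;
* class ratios: biallelic 0.5; paternal/maternal imprints 0.95/0.05;
  strain-biased 0.8 toward one strain (flipping between crosses,
  parent-of-origin mean 0.5); EPC X-linked 0.2 (imprinted XCI); decidua
  contamination as additive maternal EPC reads proportional to the
  gene's blood RPKM;
* methylomes on a 400-kb chromosome, ~8000 background CpGs with a
  common bimodal per-CpG level across groups, planted 2-kb DMRs made
  CpG-dense (CpG-island-like, as real imprinted DMRs are), gametic
  levels 90/8 %, somatic maternal gain restricted to EPC; coverage
  Poisson with tissue-allele means reflecting replicate-merged counts;
* paired 1-kb mark tracks with exponential margins of a latent Gaussian
  (K27–K36 correlation −0.5), 80 % of latent signal shared across
  genomes over syntenic bins (epigenomes of close relatives are
  conserved), planted 30:10 species-specific K27 domains with
  reciprocal DNAme.

Not modelled: read-level sampling, variant density and mappability
biases, isoform structure, reference-quality asymmetries between
strains, biological replicate dispersion in methylation, and genuine
genome-scale DMR abundance. Passing tests therefore demonstrate the
correctness and calibration of the inference on data satisfying its
assumptions, not performance on any particular real dataset.

## Numerical and testing choices

All generators are deterministic under `SimConfig.seed` (independent
streams per generator). Simulation sizes in tests and the acceptance
script (5 expression repeats, 25–40 null repeats, 5000 genes for
hyperparameter recovery, 50 000 bins) were chosen to give stable
statistics at desk scale. Nominal-level properties (familywise type-I
control, XCI null behaviour) are asserted against exact binomial
critical values at the 0.1 % exceedance level, which checks calibration
without making the suite a coin flip on the realized rejection count.
Degenerate inputs take documented limits: zero-variance t cells,
identical variances in moderation (d0 = ∞), constant vectors in
Spearman (flagged), empty DMR/domain sets (empty outputs), missing
gamete summaries (ambiguous with flag).
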