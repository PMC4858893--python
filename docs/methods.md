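# Methods

## Scope and model

The package analyses paired single-cell data: per-cell CpG methylation
call tables from single-cell RRBS and per-cell expression matrices from
cytosolic RNA-seq of the same cells, on a shared genome annotation with
gene models and CpG-island (CGI) intervals. All coordinates are 0-based
half-open; 1-based dialects (CGmap-like tables, VCF) are converted at the
parser boundary.

A site's methylation level is β = m/t (methylated / total reads). In a
diploid single cell β can only take the values 0, ½ and 1 when both
alleles are observed; allele dropout during library preparation collapses
observation to one allele and pushes levels to {0, 1}. This digitization
is the central measurement model: it drives the variance structure of
single-cell methylomes, the interpretation of intermediate levels, and
the allelic analysis.

## Analysis stages and thresholds

**In silico digestion.** MspI is modeled as a blunt cut at offset 1
within `CCGG` on the forward strand; end-repair chemistry is not modeled.
Fragments tile each chromosome exactly before size selection. The default
genomic-insert window is 40–220 bp (standard RRBS); published library
sizes (180–500 bp) include adapters, so the insert window is exposed as a
parameter (`scmt digest --min/--max`). A feature counts as covered when
it overlaps a retained fragment by ≥1 bp.

**Conversion QC.** Lambda spike-in DNA carries no CpG methylation, so the
conversion rate is 1 − Σm/Σt over lambda sites.

**Feature aggregation.** Promoter = 500 bp immediately 5′ of the TSS,
strand-aware (minus-strand TSS t gives [t+1, t+501)). Gene body =
TSS–TES. A promoter entry requires ≥5 detected CpGs ("more than 5" is
read inclusively; strict `>` is available via `strict_site_count`); a
gene-body entry requires the detected CpGs to span ≥500 bp. Sites enter
aggregation at ≥5× depth; values are the unweighted mean of site β
(a site-fraction mode — the share of sites with β ≥ 0.5 — is available
via `site_fraction=True`). Whether depth-weighting should be used is an
open choice; unweighted means use each site equally and keep the value
interpretable as "fraction of methylated site-alleles".

**Variable-site screen.** Sites covered in more than half of the cells
(default `min_cells = floor(N/2)+1`, i.e. 8 of 15; the alternative read
"n > 8" ⇒ 9 of 15 is a config knob) are tested at 1× depth — the screen
targets shared coverage, not per-site precision. The null variance σ₀² is
the pooled mean of per-site sample variances over all tested sites and is
treated as known (denominator df → ∞), so the variance-ratio statistic
(nᵢ−1)sᵢ²/σ₀² is referred to the upper tail of χ²(nᵢ−1) rather than an
F distribution. BH-FDR is applied across all tested sites; the default
significance gate is q < 0.01. The screen refuses to run below 10 tested
rows (the pooled null is unstable). On iid-null data the p-values are
approximately uniform and the flagged fraction is controlled at the
nominal FDR (both are tested).

**Enrichment.** Significant sites are classified with precedence
CGI promoter > non-CGI promoter > CGI > exon > intron > intergenic
(a promoter is CGI-class when its window overlaps a CGI interval). Each
class's fold is (obs/N_obs)/(bg/N_bg) against the census of all tested
sites, with a two-sided exact binomial p.

**Expression.** RPKM = counts·10⁹/(exon length · mapped reads). Genes
with cross-cell mean RPKM < 0.1 are removed, then quantile normalization
equalizes the per-cell distributions exactly (ties receive the mean of
their spanned rank values). Percentile rank is 100·rank/n with average
ranks for ties, so the maximum is 100 and a constant vector maps to
100(n+1)/2n; the n−1 denominator variant is available in config.
log2(RPKM+1) is the working transform for PCA and concordance analyses.
Detection means RPKM > 0.1. Libraries fail QC below 20 % alignment or
3000 genes with RPKM > 1.

**Integration.** Per-cell correlations are Pearson r between feature
methylation and expression percentile over genes carrying both values,
within CGI / non-CGI promoter strata (reported when n ≥ 10 pairs and both
vectors vary); all genes with a promoter entry are used, not only
expressed genes (a flag restricts). Per-gene cross-cell correlations
require ≥5 detected cells; significance uses the Fisher transform
z = atanh(r)·√(n−3) with r clamped at |r| ≤ 0.999999 so collinear vectors
get a finite z, and p is reported only for n ≥ 4. "Variably methylated"
features are flagged when cross-cell range ≥ 0.3 AND the feature-level
pooled-variance test gives q < 0.05 — the criterion is not uniquely
determined by the phenomenon, so the flagged counts are understood as
criterion-dependent. Gene patterns: promoter state hypomethylated
(mean ≤ 0.1) / hypermethylated (≥ 0.9) / variable (flagged) /
intermediate; expression is "dynamic" when the percentile IQR exceeds 25
(chosen to separate a bimodal high/low profile from constant ones), else
stable-high/low by median; the correlation call uses the Fisher p at 0.05.

**Allelic analysis.** C/T SNPs are indistinguishable from bisulfite
conversion on the forward strand; G/A SNPs are the reverse-strand image
of the same confound and are excluded as well (a strict C/T-only mode
exists). SNPs need ≥5 DNA-fraction reads. A fragment (per cell) is
indeterminate when no informative SNP reaches 5 reads, bi-allelic when
the qualifying SNPs show both strain alleles with ≥1 read, else
mono-allelic. Sites are attributed to the retained in-silico fragment
containing them; sites outside any retained fragment are excluded from
allelic analysis. Digitization histograms assign a site to the nearest of
{0, ½, 1} within tolerance 0.05, else "other". Allelic expression is the
mean alternate-allele balance over a gene's covered SNPs times the gene's
RPKM; only genes with RPKM ≥ 5 are evaluated (allelic balance is unstable
for lowly expressed genes; the cutoff is a configurable stand-in, as no
canonical value exists).

## The synthetic study

The generator emits the study conditions all tests run under: 15 cells,
2000 genes on 2 × 5 Mb chromosomes, half the genes with CGI promoters.
The background sequence is CG-free, so every CpG and every MspI site is
planted and known; CGI intervals coincide exactly with CGI-class promoter
windows. Non-CGI promoters carry 8–20 CpGs; CGI promoters, being
CG-dense islands, carry 20–40. Promoters and gene bodies are tiled with
`CCGG` so their fragments fall inside the 40–220 bp window; 9 % of
promoters receive no MspI site, making their CGIs genuinely uncoverable
(in silico CGI coverage lands near 91 % rather than a trivial 100 %).

Methylation is generated per allele as binary states:

- CGI promoter sites: propensity 0.03 in every cell (constitutively
  hypomethylated).
- Non-CGI promoter sites: a per-gene baseline spread over [0.03, 0.97]
  with small per-cell jitter (SD 0.08); 30 planted "variable" promoters
  instead alternate between 0.08 and 0.92 across cells.
- Gene bodies and intergenic CpGs are **site-patterned**: each site is
  constitutively methylated (0.97) or not (0.03), with the methylated-site
  density varying across genes (CGI-promoter genes: 0.5 ± 0.25·N(0,1);
  others: ≈0.9). The density spread across genes carries the gene-body
  expression coupling, while cross-cell site variance stays low. This
  choice is deliberate: under digitized single-allele observation a site
  with a mid-range *cell-fluctuating* propensity is indistinguishable in
  variance from a maximally variable one, and had gene bodies been
  modeled that way the pooled null σ₀² would swallow the variance screen
  entirely. Real RRBS data behaves like the patterned model — most
  covered CpGs are constitutively extreme — which is exactly what makes
  the pooled-variance screen informative. 60 planted variable gene bodies
  fluctuate across cells (0.15/0.85).

Observation: each retained fragment is captured per cell with probability
0.55; a captured fragment samples a single allele with probability
`allele_dropout` (default 0.9) — dropout is applied per fragment, not per
site, so sites on one fragment share the sampled allele, matching
fragment-level mono-allelic observation (the per-fragment vs per-site
split of real dropout is unmeasured; this is a modeling decision flagged
in config). Depth is Poisson(8) per site; reads from unmethylated alleles
report methylated at the conversion-failure rate (0.005), and the lambda
table (2000 sites) is fully unmethylated before that failure. An
`infinite_depth` mode reports exact expected levels for the digitization
limit tests.

Expression is log-normal: log2 means carry a gene-level SD of ~1 plus a
per-cell SD of 0.6. The planted couplings enter through shared latents:
the non-CGI promoter methylation axis enters the log2-mean with slope
−0.30 and the CGI gene-body density axis with slope +0.10. These slopes
were calibrated once by simulation so that the *observed* downstream
per-cell correlations land on the configured targets (−0.22 and +0.13)
under the default measurement model — they absorb the attenuation from
finite depth, dropout, capture sparsity and the percentile transform —
and scale linearly when a user configures different targets. Counts are
Poisson from RPKM × exon length × library size (1.5–3 M reads); 40 ERCC
spike-ins share concentrations across cells with 10 % multiplicative
noise; 8 % of genes are silent (RPKM ≈ 0.06) to exercise the expression
filter. Ten non-CGI genes are planted hypermethylated-and-high (promoter
propensity 0.95, high expression) as stable-high exemplars, and variable
promoters/gene bodies drive expression dynamically (negative/positive
respectively), giving the pattern classifier real targets.

Allelics: 300 SNPs are placed inside retained gene-body fragments (~30 %
deliberately bisulfite-confounded to exercise the filter). DNA allele
counts at SNPs reuse the same per-fragment capture/dropout events as the
methylation reads. Twenty "allelic" genes carry a per-cell binary state
that sets both the alternate-allele gene-body methylation (0.15 vs 0.85)
and the alternate-allele expression balance (0.25 vs 0.75), planting the
positive allele-specific methylation–expression coupling the allelic
correlation recovers.

What the generator does **not** emulate: read-level artifacts (PCR
duplicates, mapping bias, non-CpG methylation), realistic chromosome-scale
CpG spacing, cell-type structure in expression, and imprinting. Passing
tests therefore demonstrate correctness of the analysis logic under the
stated measurement model, not performance on any particular real dataset.

## Numerical choices

- Determinism: all randomness flows from `numpy.random.default_rng`
  seeded per component (`[seed, 0]` reference, `[seed, 1]` cells); output
  files are bit-identical across reruns.
- Problem sizes in the test suite: the acceptance checks run 20 seeds of
  the full default study for coupling recovery and 2000-site × 15-cell
  matrices for FDR/power; the remaining tests use a 120-gene / 8-cell
  study that preserves every planted feature class.
- Degenerate inputs: constant vectors yield undefined r (reported NaN,
  never 0); zero-variance spike-in columns yield missing correlation
  pairs; empty call tables and all-filtered matrices raise rather than
  return empty results; the variance screen refuses unstable nulls
  (<10 rows).
- Ties: percentile rank averages ranks; quantile normalization averages
  spanned rank-means, making both invariant to input order.

## Known limitations

- The pooled-variance χ² screen treats σ₀² as known; with few tested
  sites the null is noisy (hence the hard floor of 10 rows).
- The 91 % CGI-coverage figure for a real genome depends on the CGI track
  and insert window used; with the synthetic genome the quantity is exact
  by construction.
- Variably-methylated feature counts depend on the (range, FDR) criterion;
  no canonical definition exists.
- Allelic balance assumes no reference-mapping bias; real bisulfite data
  would need an allele-aware aligner upstream.
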