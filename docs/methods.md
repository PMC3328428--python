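# Methods

## Segregation model and detection rule

The detector assumes a family of known-sex individuals from an inbred XY
line, genotyped at biallelic SNVs with per-allele read depths (VCF FORMAT GT
and AD). A site is called sex-linked when every male is heterozygous and
every female is homozygous for the same allele; that shared female allele is
assigned X, the other Y. A contig is sex-linked with at least one such SNP
and "strict" with at least two. Any individual with a missing call
disqualifies the site (not the contig): the pattern must hold in *all*
individuals, and per-site disqualification keeps the remaining sites usable.

Female genotypes are taken verbatim from the upstream caller, which is
reliable for balanced X/X expression. Male genotypes are re-inferred from
depths, because a diploid caller under-calls heterozygotes whose Y allele is
weakly expressed. The default rule is maximally permissive: heterozygous iff
both alleles have at least `min_y_reads` (default 1) supporting reads and
the minor-allele fraction is at least `min_minor_fraction` (default 0);
equal depths are heterozygous (the rule is support-based, not ratio-based).
An alternative binomial caller treats the male as heterozygous only when the
minor-allele depth is improbable under base-call error alone
(P(≥ minor | depth, e) < α, defaults e = 0.005, α = 0.05); it trades
sensitivity to weak Y alleles for robustness to sequencing error. An
optional strict-female mode re-checks female homozygosity from depths
(minor fraction ≤ 0.05), guarding against caller artifacts.

The permissive default has a structural consequence: a contig whose Y copy
is completely silent in some male can never be detected, so the detected set
contains no contig with Y/X = 0, and male X summaries of zero cannot arise
for detected contigs. The degenerate case is still handled (top ratio bin,
flagged excluded).

X-chromosome polymorphism on a sex-linked contig is flagged from its
remaining, non-diagnostic sites: any individual heterozygous, or all
homozygous but not for the same allele. This check uses the upstream GT for
all individuals, males included — re-using the permissive depth rule here
would let a single error read flag nearly every contig.

Multi-allelic VCF rows are decomposed into biallelic ref/alt records
(alternate alleles without read support anywhere are dropped); indel rows
are skipped. Coordinates stay 1-based as in VCF.

## Expression normalization

Reads are counted at sex-linked SNP positions only, never over whole
contigs, so X- and Y-derived reads stay separated. For one contig,
individual and allele class (X-in-male, Y-in-male, both-X-in-female):

E = r / (n · l), with r the summed class depth over the contig's diagnostic
SNPs, n their number and l the normalized library size. l subtracts rRNA,
mitochondrial, chloroplast and TE reads from the total mapped reads and
divides by 10^6: these categories differ systematically between sexes and
sequencing runs, and removing them (rather than rescaling by them) keeps l
in interpretable units of nuclear-mRNA millions. The RPKM variant divides by
contig length instead of SNP count, r / ((length/1000) · l); the pipeline
uses the same corrected l as the "million mapped reads" denominator so that
sex-biased organellar/TE content cannot masquerade as a nuclear expression
difference.

Per-contig ratios aggregate across individuals *first* (mean by default,
median available), then form the ratio: Y/X = summary(E_Y)/summary(E_X) over
males, Xmale/2Xfemale = summary male E_X over summary female E_XX. The
ratio-of-summaries order matches how a single noisy individual should be
damped before division; a per-individual-ratio sensitivity mode would be a
one-line change on the summary table and is deliberately not a pipeline
option.

## Dosage statistics

Contigs are binned by Y/X ratio into [0,0.25), [0.25,0.5), [0.5,0.75),
[0.75,1), [1,1.5), [1.5,∞). Contigs with Y/X > 1.5 or Xmale/2Xfemale > 2
are flagged excluded (male-biased expression suggests sexually antagonistic
genes, whose dynamics differ and for which no compensation is expected);
boundary equality is retained — the exclusions are strict inequalities.

Two Wilcoxon signed-rank tests are reported two-sided with a direction
(one-sided available): X vs Y expression paired within contigs, and
Xmale/2Xfemale against the 0.5 no-compensation reference. Zero differences
are dropped per the standard signed-rank convention; an all-zero difference
vector reports p = 1 rather than crashing.

The dosage profile pools RPKM values over contigs and same-sex individuals
within each Y/X bin and reports medians of four classes — XX females,
X males, Y males, XY males (X + Y per male, summed before pooling) — each
rescaled by the female median so females sit at 1. Confidence intervals are
a percentile bootstrap over contigs (default 1,000 resamples, seeded);
resampling contigs rather than pooled values respects the within-contig
correlation of individuals. Empty bins are reported with n = 0 and no CI.

The heterozygosity comparison cross-tabulates the X-polymorphism flag
against a compensated/uncompensated split (default: Y/X < 0.5 and
Xmale/2Xfemale ≥ 0.75 vs the complement, both configurable) and applies
Fisher's exact test. A depleted compensated stratum is the signature
expected if compensation acted through monoallelic X expression.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the sequencing itself: no reads, no assembly artifacts, no paralogs. Each
dataset has `n_males` + `n_females` individuals (defaults 3 + 3, alternating
two run batches), sex-linked contigs carrying X/Y SNP pairs and autosomal
contigs with residual heterozygosity.

Depths are negative binomial per site and individual (mean m, dispersion k;
variance m + m²/k), the standard overdispersed model for RNA-seq counts;
k defaults to 10, a moderate overdispersion typical of biological
replicates. `depth_mean` (default 50) is the expected total depth at a site
whose carrier expresses two allele copies at baseline, so the per-allele
baseline is b = depth_mean/2. For a sex-linked contig with degeneration d
and male-X coefficient cx:

* female: homozygous X/X, total depth ~ NB(2b)
* male X: ~ NB(cx·b); male Y: ~ NB(d·cx·b)

Compensation modes set cx: `none` → 1 (Xmale/2Xfemale expectation 0.5),
`proportional` → 2/(1+d) (total male output exactly equals total female
output), `full` → 2 (the single male X upregulated to the output of both
female copies; expectation 1.0). Tying Y to the *compensated* X means the
measured Y/X ratio estimates d under every mode, which is what makes
degeneration recovery a well-posed check; "full" is the Ohno-style twofold
X upregulation, chosen over output-equalizing variants because it gives the
clean 0.5-vs-1.0 contrast the two calibration conditions are designed
around. Per-contig d is sampled from a configurable distribution (default
lognormal with median 0.77, σ = 0.5, matching the degeneration typically
seen in young XY systems; support must be positive — d is a ratio of
expression levels, and a contig with a fully silent Y is undetectable by
construction).

Each read is mis-assigned to the other allele with probability e (default
0.001). Inbreeding is collapsed into a single residual per-site
heterozygosity h (default 0.05, roughly what ten generations of sib-mating
leaves standing): each individual at each autosomal site is heterozygous
with probability h, otherwise homozygous ref or alt at 1/2 independently.
Only the genotype-pattern frequencies matter downstream, so an explicit
pedigree would add machinery without changing any tested quantity; the
all-males-het/all-females-hom-same null pattern then has closed-form
probability h³(1−h)³/4 (for 3+3), which the tests verify empirically. A
fraction of sex-linked contigs (default 0.1) carries one extra X-polymorphic
site (one female heterozygous) to exercise the polymorphism flag.

Library composition is emitted with rRNA fractions differing by run batch
(0.12 vs 0.05) and organellar/TE fractions differing by sex, around a base
of 10⁷ nuclear reads with lognormal per-individual scale (σ = 0.15); site
depths track the realized nuclear library size, so the E normalization must
cancel the scale — a generator/pipeline consistency that the calibration
tests exercise end to end. An upstream-caller emulation writes GT from
depths (het at minor ≥ 2 reads and ≥ 10%), reproducing the very failure
mode (missed weak-Y male heterozygotes) that motivates male re-genotyping.

Everything is drawn from one seeded generator: identical configs produce
byte-identical files.

What passing tests on this generator do **not** show: robustness to
assembly chimerism (X and Y copies split or fused across contigs), paralog
collapse creating pseudo-heterozygosity, mapping bias toward the reference
allele, or non-NB depth pathologies. On real data those inflate both false
positives and false negatives beyond anything measured here, and the
simulation-based false-positive rate is comparable to an empirical one in
order of magnitude only.

## Problem sizes and numerical choices

The packaged study conditions are desk-scale by design: calibration runs use
500 sex-linked contigs at depth 50 (the median ratio then sits within ±0.05
of its expectation with comfortable Monte-Carlo margin), null-soundness and
false-positive runs use 10,000 autosomal contigs (×5 replicates for the
rate estimate, giving a one-sided resolution well below the 10⁻³ scale of
interest). False-positive intervals are Clopper–Pearson. Ratios with a zero
denominator go to the top bin and are excluded from profiles. All reports
are written with %.10g float formatting, which makes byte-level
reproducibility checks meaningful.

## Known limitations

* The detector requires expressed Y alleles; hemizygous (Y-lost) genes are
  invisible to it, so Y-degeneration estimates are conditioned on Y
  expression and biased upward as a genome-wide statement.
* With three individuals per sex, per-contig ratios are noisy; the analysis
  is designed around medians over many contigs, not per-contig inference.
* The library-size correction subtracts contaminant categories; if
  contaminant mapping itself is biased between sexes, the correction
  inherits that bias.
* The X-polymorphism flag is GT-based and inherits the upstream caller's
  blind spots at low depth.
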