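# Methods

This note documents the models and procedures implemented in `panelgwas`,
their assumptions, the parameters that matter, and the numerical choices
made where the design was genuinely open.

## Data model

Genotypes are held as a marker × accession matrix of dosage calls
{0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate,
−1 = missing}.  Because each accession is genotyped as a pooled DNA sample
of several inbred plants, "heterozygosity" really means within-accession
heterogeneity (or reads collapsed from homoeologous loci); it is kept as a
single unphased state.  Coordinates are 1-based throughout (VCF
convention).  VCF is the canonical on-disk genotype format; a marker ×
accession TSV dialect exists for fixtures.  Chromosome names are free
strings; `Un` (unplaced contigs) is excluded from position-dependent scans.

## Panel-design QC

A SNP is targetable by an enrichment probe only if (a) the fragment around
it occurs exactly once in the genome and (b) a probe with workable GC
content exists.  `count_exact_matches` counts occurrences of the full
flank and its reverse complement across all reference sequences,
overlapping occurrences included; a position where the forward and
reverse-complement matches coincide (palindromic fragment) counts once.
Using the full flank as the query is the deterministic analogue of taking
the longest exact match from an aligner, and is reproducible without one;
the strand-collapsing convention is a declared design decision.  GC content
excludes `N` bases from the denominator and is NaN for all-N input.  Probe
feasibility defaults to a GC window of [0.30, 0.70]; the empirically
observed band of successful probes ([0.33, 0.70]) is reported, not
enforced.  One or two probes per SNP are supported; one passing probe
suffices.

## Filter cascade

Stages apply in order: call rate ≥ 0.90 (inclusive), heterozygosity among
called genotypes ≤ 0.10 (inclusive), MAF > 0.05 (strict), each statistic
computed on called genotypes only.  The strictness of each bound follows
the stated thresholds literally ("90% or more", "no more than 10%",
"greater than 0.05").  Filtering precedes imputation, so the missingness
signal used by the translocation scan is intact.  The funnel table reports
survivors per selection category (A = MAS-derived, B = prior-GWAS,
C = GenBank-gene, D = protein-changing, G = gap-filling) after each stage;
counts are non-increasing by construction.

## LD-kNNi imputation

For a missing call at site *s*, accession *i*: candidate sites are those on
the same chromosome within 1 Mb (default) of *s*; the l = 30 with highest
r² (squared Pearson correlation of dosages over pairwise-complete
accessions; zero variance ⇒ r² = 0) form the LD panel.  The distance from
*i* to every other accession *j* is the mean squared dosage difference over
the LD sites where both are called (j skipped if no overlap or missing at
*s*).  The k = 10 nearest neighbors vote with weight 1/d², d floored at
ε = 1e−8 so identical neighbors dominate rather than divide by zero; the
imputed dosage maximizes the summed weight.  Ties break toward the more
frequent genotype at *s*, then the lower dosage; candidate and neighbor
ranking ties break by index order — the whole procedure is deterministic.
Cells with no usable LD sites or neighbors fall back to the site mode (or
stay missing with `fallback="leave_missing"`).  Cross-chromosome LD is
excluded; the distance formula over shared-called sites is a declared
decision where the source method leaves the missing-pair handling
unstated.  Observed calls are never altered.

## Translocation scan

Probes designed against the reference fail on chromatin replaced by alien
chromatin, so carriers of an arm replacement show a contiguous
high-missingness block.  Per-accession missing counts inside an inclusive
window (given by bp or marker ids) are split by the *two-largest-gaps*
rule: the largest gap in the sorted count distribution separates carriers
from non-carriers; when the second-largest gap is ≥ half the largest, the
region between the gaps becomes an intermediate class (the automatic
analogue of reading a trimodal histogram by eye).  Counts ≤ t_low are
non-carriers, ≥ t_high carriers.  A distribution whose largest gap is
below 2 counts is treated as unimodal: everyone is a non-carrier.  Counts
are raw (not fractions) to mirror how such histograms are read.  Manual
thresholds are accepted for exact reproduction of published splits.
Concordance against validation labels excludes intermediates from the 2×2
table and reports them separately.

## Population structure

**Kinship.** Centered IBS: K = W′W / c with W the marker-centered dosage
matrix and c = Σₘ 2pₘ(1−pₘ); symmetric PSD by construction and scaled so
diagonal elements average ≈ 1 for a panel in Hardy–Weinberg-ish
proportions.

**IBS distance.** Pair score 1 / 0.5 / 0 for identical / one-shared-allele
/ opposite homozygote calls, equivalently d = mean |xᵢ−xⱼ| / 2 over
pairwise-complete markers.

**PCA.** SVD of the marker-centered (not variance-scaled) dosage matrix;
variance fractions are squared singular values over their total; component
signs are fixed by forcing the largest-magnitude loading positive.

**Neighbor joining.** Saitou–Nei agglomeration implemented in-package
because the conventions are pinned: negative branch lengths are clamped to
zero with the deficit moved to the sister edge (pairwise path lengths are
preserved, so additive matrices are still recovered exactly), and Q-matrix
ties break toward the smallest (i, j) pair.  Midpoint rooting (via skbio)
is the default.  skbio's own NJ serves as an independent cross-check in the
tests.

**Admixture model.** Each dosage is treated as a Binomial(2, qᵢ·pₘ)
observation — an approximation given the heterogeneity-as-heterozygote
encoding of pooled samples.  The log-likelihood is maximized by EM
(responsibility-weighted allele counts), with frequencies clipped to
[1e−6, 1−1e−6]; the likelihood is monotone non-decreasing and iteration
stops when the improvement drops below 1e−4.  K = 1 is returned in closed
form (P = observed frequencies).  A Bayesian MCMC implementation of the
same model family is replaced by this maximum-likelihood EM with multiple
random restarts standing in for replicate runs; the ΔK statistic consumes
replicate log-likelihoods identically.

**Evanno ΔK.** ΔK(K) = mean over replicates of
|L(K+1) − 2L(K) + L(K−1)| divided by the sample sd (ddof = 1) of L(K)
across replicates, defined for interior K of a contiguous range with ≥ 2
replicates per K; replicates are paired by index across K.  sd = 0 yields
NaN (flagged undefined rather than infinite).

## GWAS

**BLUEs.** value ~ accession + year, both fixed, year sum-to-zero coded;
the accession coefficient is the adjusted value.  Balanced data reduce to
per-accession means; single-year data pass through unchanged.

**Mixed model.** y = μ + PCs·γ + x·β + u + e with u ~ N(0, σ²g K).  The
kinship eigendecomposition K = U S U′ rotates the model so V is diagonal;
λ = σ²e/σ²g is estimated by bounded scalar REML optimization on log λ ∈
[−12, 12].  P3D (λ estimated once under the covariate-only null and reused
per marker) is the default; per-marker REML is available.  Each marker
gets an F(1, n − rank) test of β = 0 with no Satterthwaite adjustment.  A
marker collinear with the covariates (including constant dosage) is
flagged with p = 1 rather than dropped.  With K = 0 the model collapses
to OLS exactly, which the tests exploit as an oracle.  Binary/ordinal
traits are analyzed with the same linear MLM — a documented limitation,
matching common practice for such panels.

**SimpleM.** Per chromosome, the marker–marker dosage correlation matrix is
eigen-decomposed after dropping zero-variance markers; Meff per chromosome
is the smallest number of leading eigenvalues reaching 99.5% of the
eigenvalue total (the method's published default, fixed here because the
cutoff is otherwise unstated); Meff sums over chromosomes, keeping memory
O(max per-chromosome block²).  The corrected threshold is α / Meff.

**Enrichment.** Per category, the fraction of markers with ≥ 1 significant
association; pairwise two-sided Fisher exact tests (hypergeometric tail
sums via scipy); homogeneous-group letters are maximal cliques of the
non-significance graph at α = 0.05.

## Synthetic-data generator

The generator emulates the study design, not any particular dataset:

- **Population.** Ancestral allele frequencies ~ U(0.05, 0.95); per
  subpopulation Balding–Nichols Beta draws with divergence parameter F
  (default 0.15, two subpopulations) — one parameter controls cluster
  separation.  A fraction (default 0.2) of accessions get Dirichlet(1)
  admixed ancestry; the rest are pure.  Genotypes are Binomial(2, qᵢ·pₘ).
- **Heterozygosity.** Heterozygote calls are resampled to homozygotes with
  probability 1 − target/current so the realized het rate matches the
  config (default 0.01, i.e. nearly-inbred material).
- **Map.** Marker positions have Beta(0.45, 0.45) density along each
  chromosome (distal clustering, mimicking gene-rich chromosome ends) with
  a uniform option; ~1% of markers land on `Un`.  Optional block-LD
  structure copies a latent block genotype along runs of consecutive
  markers (block size and switch probability configurable) — the LD
  strength is a free parameter of the generator, not an emulation claim,
  since the emulated panel's LD decay is not characterized.
- **Translocation.** A configurable carrier subset (default 39 of 200)
  loses each call inside the 1B-short-arm interval independently with rate
  0.9, on top of 2% background missingness.
- **Traits.** y = Σ β·dosage + polygenic + year + noise; the polygenic term
  is multivariate normal with covariance proportional to the panel's own
  centered-IBS kinship, scaled so major loci + polygenic variance hit the
  target heritability; year effects are additive; binary traits threshold
  the liability at a configured prevalence.  Effects are specified in
  phenotypic SD units per dosage unit.
- **Reference.** Toy chromosomes (default 20 kb) carry each marker's
  odd-length flank at non-overlapping slots placed independently of the
  genetic map coordinates; a deterministic count round(fraction × n) of
  flanks reappears once on a decoy contig, mimicking homoeologous
  duplication without disturbing other flanks.  Probes are drawn upstream
  of the SNP with 3′-end 5–25 bp away.

All randomness flows from one root seed through named child streams
(reference / population / translocation / traits), so stages are
independently re-runnable and byte-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level error processes, genuine LD decay
with recombination distance, allele-frequency spectra shaped by selection
and breeding history, genotype–environment interaction in traits, and
probe failure correlated with GC content.  Tests on this generator
demonstrate algorithmic correctness and calibration under the declared
generative model, not field performance.

## Problem sizes

Desk-scale sizes are used throughout so the whole suite runs in minutes on
one CPU: calibration experiments use 100–200 accessions × 120–250 markers
with 10–20 seeds; structure/ΔK experiments use K ≤ 5 with 10 EM replicates;
the end-to-end acceptance run simulates 200 accessions × 1,200 markers and
thins to 250 markers for the structure stage.  These sizes are the
package's own choice of test conditions; every quantity reported by
`scripts/acceptance.py` is computed fresh from these runs.

## Known limitations

- The admixture EM finds local optima; multiple restarts mitigate but do
  not guarantee the global maximum, which is why ΔK consumes replicate
  spread rather than a single fit.
- The binomial dosage likelihood mis-models pooled-sample heterogeneity
  when within-accession mixtures are common.
- The missingness scan assumes carrier blocks are contiguous and
  missingness elsewhere is uniform; mosaic or small events below the
  window's marker resolution will be missed.
- P3D reuses null variance components; markers with very large effects can
  have slightly conservative tests compared to per-marker REML.
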