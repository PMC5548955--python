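# Methods

This note documents the statistical models implemented in `trapshift`, the
assumptions of the synthetic-data generator, the numerical choices, and
the limitations a user should know before applying the pipeline to real
TRAP-seq data.

## Study design and data model

The pipeline targets a paired translatome-profiling design: P littermate
pairs (default P = 6), each pair contributing one wild-type (WT) and one
knockout (KO) animal, each animal one Input (total RNA) and one IP
(ribosome-bound) library — 4P samples in all. Littermate pairing is a
blocking factor: animals within a pair share age, litter and processing
batch, so the pair enters the model as a fixed effect.

Counts are modeled per gene as negative binomial (NB2),

    K_gj ~ NB(mean μ_gj, dispersion α_g),   Var(K) = μ + α μ²,

with a log link and the sample's size factor as offset:

    log μ_gj = log s_j + β₀g + Σ_p β_{g,pair(p)} + β_{g,KO}·1[KO].

IP and Input fractions are analyzed separately; no interaction model is
fitted. The two fraction analyses mirror the biological question: an effect
present in IP but absent in Input indicates altered translation rather than
altered transcript abundance.

## Normalization

Size factors are median-of-ratios: for genes with a positive count in every
sample, compute the per-gene geometric mean across samples, take each
sample's count/geometric-mean ratios, and set s_j to exp of the median log
ratio. No pseudocounts are used; if no gene is positive everywhere the
operation fails loudly rather than silently switching reference. TPM is
computed at gene level from counts and effective lengths
(rate = count/length, scaled to 1e6 per column). Heatmap normalization
divides each gene by its WT-mean TPM and then row-scales to zero mean and
unit variance (the row-scaling convention of standard heatmap tools — the
choice of row over column scaling is an assumption, documented here).
RT-qPCR relative quantification is ΔΔCt with efficiency fixed at 2: first
normalize to the reference gene, then each IP to its matched Input.

## Dispersion estimation

The dispersion machinery is deliberately simple and auditable rather than a
numerical clone of DESeq2's:

1. **Gene-wise (method of moments).** On size-factor-normalized counts q,
   using within-genotype residual variance (pooled over the two genotype
   groups, df = n − 2): α̂ = max((var_within − mean_q)/mean_q², 1e-8).
   Grouping by genotype keeps genuine genotype effects out of the variance;
   pair effects do remain in it, biasing α̂ slightly upward (conservative).
2. **Trend.** α_tr(μ) = a₁/μ + a₀, fitted over genes above the floor by
   iteratively trimmed, inverse-variance-weighted least squares (trim ratio
   outside [1e-4, 15], ten rounds).
3. **Shrinkage.** ln α* = w·ln α̂ + (1−w)·ln α_tr with
   w = σ²_prior / (σ²_prior + trigamma(df/2)), prior sd σ_prior = 0.5 on the
   log scale. Genes whose moment estimate is at the floor take the trend
   value (there is no information to shrink); genes with α̂ > 10·α_tr keep
   α̂ (dispersion outliers must not be shrunk into false positives).

## Wald inference and the moderated t reference

The GLM is solved by iteratively reweighted least squares, vectorized
across genes (all genes share the design matrix), with convergence declared
when the NB deviance change falls below 1e-8 relative and standard errors
taken from the inverse expected information. The KO coefficient is reported
in log₂; Wald = coefficient/SE.

The Wald statistic is referred, two-sided, to a **t distribution with
df = (n − 2) + d₀**, where d₀ solves trigamma(d₀/2) = σ²_prior — the number
of pseudo-observations carried by the dispersion prior (d₀ ≈ 9 at
σ_prior = 0.5). Rationale: with ~12 samples, moment-based dispersion
estimates retain enough noise that a standard-normal reference is
anticonservative in the extreme tail — on 15,000-gene global-null
simulations it produces 10–20 BH discoveries per replicate, and a reference
NB-GLM tool run on identical data shows the same tail inflation, so this is
a property of plugging estimated dispersions into a normal reference, not
of this implementation. Accounting for the finite information in α* via a
moderated t (the quasi-likelihood convention) restores a clean null
(0 discoveries per replicate, bulk p-values at the nominal rate) while
leaving power for 2-fold effects essentially untouched (sensitivity ≈ 0.99
at FDR 0.1 in the default recovery simulation). The standard-normal
reference remains available (`DEConfig(wald_reference="normal")`).

Multiple testing is Benjamini–Hochberg step-up with monotonicity
enforcement; NAs are excluded from the test count and propagate. Genes that
are all-zero, below the baseMean filter (default 0.5), or non-converged are
reported untested with NA statistics. No fold-change shrinkage, no Cook's
distance outlier handling, and no independent-filtering optimization are
applied — these are deliberate omissions that keep the stage auditable; the
baseMean filter is the only pre-test filter.

## Abundance-matched shift test

Expression level confounds fold-change comparisons, so a target set is
compared only against genes of similar abundance: the closed window
10^lo ≤ baseMean ≤ 10^hi, with fraction-specific default exponents
(Input 2.5–4.25; IP 2.75–4.75). "Between" is read as inclusive; the closed
interval is a documented choice. The background deliberately **includes**
the target genes (the comparison is "targets vs all window genes"); a
targets-excluded background is available by flag, and for target sets much
smaller than the window the two differ negligibly.

The test statistic is the two-sample Kolmogorov–Smirnov
D = sup |ECDF_target − ECDF_background|, evaluated at all pooled points
with right-continuous ECDFs (ties handled by pooled sorting). The p-value
uses the asymptotic Kolmogorov tail Q(λ) = 2Σ_{j≥1}(−1)^{j−1}e^{−2j²λ²}
with the small-sample correction λ = (√n_e + 0.12 + 0.11/√n_e)·D,
n_e = nm/(n+m), clamped into (0, 1]. Because D at equal sample sizes lives
on a lattice, the asymptotic p corresponds to the mid-p of the discrete
permutation null; the acceptance suite verifies agreement within 10%
against an exact lattice-path enumeration of that null.

Two companions accompany the K-S test: k = 5 random gene sets of the same
size, drawn without replacement from the window (deterministic given a
seed), each tested identically — a resampling null showing what "no
enrichment" looks like; and a Fisher test comparing the up/down sign split
of targets vs non-target window genes. Whether random sets should be drawn
from the window or from all expressed genes is an open choice; window-drawn
is the default since it preserves the abundance matching.

## Clan enrichment

The background is *gene-based*: every gene with TPM > 0 in at least one
sample, whether or not it has a clan annotation — unannotated genes remain
in the "outside clan" cells and dilute enrichment, which is the correct
behavior for a background defined as "all detected genes". A target list is
first adjusted to genes detected (TPM > 0) in at least one IP sample. Each
clan with at least one list gene gets a two-sided Fisher test on
(in list / not) × (in clan / not); the enriched flag additionally requires
overrepresentation in the list. No multiplicity correction is applied by
default (the fixed p < 0.01 convention); BH is available behind a flag.
A gene in several clans counts once in each clan's table. Odds ratios use
Haldane 0.5 continuity only when a cell is zero, flagged.

## Exact 2×2 statistics

`fisher_exact` conditions on both margins and sums hypergeometric
probabilities of all tables whose probability is ≤ the observed one times
(1 + 1e-7) — the probability-mass two-sided rule of mainstream statistical
environments; terms are computed via log-gamma so large tables cannot
overflow. It agrees exactly (to float precision) with a rational-arithmetic
enumeration oracle over every table with margins ≤ 12, and with
transposition/row-column-swap invariance.

Seizure summaries use the maximal-stage convention: each animal contributes
only to its most severe stage (wild running < clonic < tonic), so stage
counts partition the seizing animals; percentages are rounded to the
nearest integer, half away from zero.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
the sequencing process. Per gene: a log-normal baseline (ln-mean ln 1000,
ln-sd 1.2, putting ≈80% of genes inside the Input abundance window — the
regime where the shift analysis operates), a log-normal IP-enrichment
multiplier (ln-sd 0.7, representing variable ribosome occupancy), and a
dispersion from the trend 2/μ + 0.01 with log-normal gene noise (sd 0.3) —
plausible bulk-RNA-seq values; the real study's library sizes and
dispersions are unknown, so these are assumptions, not estimates. Per
sample: a log-normal library-size factor (ln-sd 0.15) and a per-pair
multiplier (ln-sd 0.1) shared by all of a pair's samples, giving the
blocking structure the paired design removes.

Three planted gene sets drive the recovery tests: 90 up (log₂ ≈ +1) and 31
down (log₂ ≈ −1) genes with **IP-only** effects — translation-level changes
invisible in Input — and an 800-gene target set with a small negative shift
(log₂ ≈ −0.2, sd 0.05) applied in **both** fractions, since the phenomenon
it emulates appears in Input and IP alike. Planted sets are disjoint and
drawn from genes with baseline ≥ 100 counts, because the phenomena they
model concern genes inside the analyzed abundance range. Of 40 clans
(60% of genes carry one, 10% a second), two are made overrepresented in the
up-set (≈30% of up genes added to each), giving clan-enrichment recovery a
known answer.

All randomness flows from the single config seed through named
`SeedSequence` child streams, so outputs are byte-identical across runs.
What the generator does **not** emulate — GC/length bias, batch effects
beyond pair blocking, outlier samples, correlated genes, zero-inflation —
bounds what passing tests show: they validate the statistical machinery
under the stated model, not robustness to real-data pathologies.

## Problem sizes and numerical choices

Simulation-based checks use the full study design (15,000 genes × 24
samples; 20 replicates for null calibration), which runs in seconds thanks
to the genes-vectorized IRLS. Convergence: deviance tolerance 1e-8, 50
iterations max, linear predictor clipped to ±30, a 1e-10 ridge on the
normal equations; non-converged genes are flagged untested rather than
reported. Dispersions are clipped to [1e-8, 30]. K-S p is clamped to
(0, 1]; BH enforces monotonicity explicitly. Degenerate inputs (all-zero
genes or columns, empty windows, empty adjusted target lists) produce
warnings or flagged results rather than silent numbers.

## Limitations

- The DE stage is a transparent re-implementation of the NB-GLM/Wald
  pipeline, not a numerical replica of any specific tool release; exact
  significant-gene counts from published datasets are not expected to
  reproduce.
- The dispersion estimator is moment-based; for very small counts its
  information is limited and the moderated t reference compensates rather
  than removes that.
- The asymptotic K-S p is accurate in the regimes tested (n ≥ ~50 per
  sample, p ≥ 1e-3); far-tail p-values (e.g. 1e-13) are extrapolations of
  the asymptotic series, as is conventional.
- Fraction-specific abundance windows assume baseMean is comparable across
  genes within a fraction; no gene-length adjustment is applied there.
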