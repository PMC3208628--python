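# Methods

This note documents the statistical machinery implemented in `tfcohort`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Problem setting

Given (i) two-class expression matrices for several case/control comparisons
(e.g. pluripotent stem cell lines versus matched fibroblasts), (ii) promoter
sequences per gene, (iii) a library of transcription-factor position weight
matrices (PWMs), and (iv) gene-group definitions, the pipeline asks two
questions:

1. **Transcription-factor activity (TFA).** Is there system-level evidence
   that a factor directly drives the observed differential expression —
   i.e. are genes with high predicted binding-site density over-represented
   among the most differentially expressed genes?
2. **Target-cohort detection.** Which functional gene groups contain a
   subset of high-binding-propensity members whose expression behaviour
   (magnitude and similarity to the regulator's own profile) marks them as
   probable direct targets?

## Differential expression scoring

Per comparison, each gene receives a moderated two-sample statistic
d = (x̄_case − x̄_control) / (s + s0), where s is the pooled standard error
of the mean difference and s0 a positive fudge constant guarding against
tiny-variance genes. The default s0 is the median of the per-gene s values —
deterministic and close in practice to the coefficient-of-variation
minimiser, which is available via `s0_rule="tusher"`. Per comparison, d is
standardised to mean 0 / sd 1 using population (1/N) moments; this keeps the
scaling internally consistent with the population-covariance similarity
metric, and the 1/N-vs-1/(N−1) distinction is immaterial at genome scale.

Pooling over n comparisons: `de_score` = mean |z|. Similarity of gene B to
the regulator A over comparisons: `dp` = Σ a_c·b_c (raw dot product, no 1/n)
and `cov` = population covariance. The raw-sum convention for `dp` makes its
scale grow with the number of comparisons (|dp| of order a few units over 7
comparisons of unit-variance scores) while `cov` stays of order 0.1 — these
are the scales on which the shipped reference envelope cutoffs (|dp| > 3.2,
|cov| > 0.135, etc.) were defined. Group-level versions are unweighted means
over members — the only aggregation consistent with comparing subsets of
different sizes across propensity thresholds.

Probe handling: identifiers ending in `_a_at`, `_s_at`, `_x_at`
(cross-hybridising Affymetrix probe classes) are dropped; the same symbol at
different loci is kept as distinct entries. The gene universe is the
intersection of all comparisons after filtering.

## Promoter scanning and target propensity

PWMs are parsed from TRANSFAC flat files with a pseudo-count of 1 added to
every cell before normalisation. Position i carries information weight
I(i) = Σ_b f(i,b) ln(4 f(i,b)); the *core* is the contiguous window of five
positions (or the whole matrix when shorter) maximising summed information.
A window scores `current = Σ I(i) f(i, b_i)`; the matrix similarity score
MSS = (current − min)/(max − min) normalises between the worst and best
attainable scores, and CSS does the same over the core. Hits must pass both
cutoffs (defaults MSS ≥ 0.75, CSS ≥ 0.90 — permissive, in the spirit of a
minimum-false-negative profile). Both strands are scanned; overlapping hits
all count; `N` bases contribute a position's minimum frequency so masked
sequence degrades rather than truncates a score.

Target propensity of a gene with J alternative promoters:

    tp = (1/J) Σ_j n_j / (ρ · l_j),   ρ = Σ_i n_i / Σ_i l_i ,

the mean promoter site density relative to the global background density ρ.
A background-like gene has tp ≈ 1 and a separation threshold of ~5 reads as
"five-fold background density". Note that at permissive cutoffs a
substantial share of counted sites are chance matches; these dilute the
observed contrast between true targets and background genes (a planted
five-fold density ratio is recovered as roughly 1.3–1.5-fold at the default
cutoffs, and approaches five-fold only at stringent cutoffs where chance
matches vanish). This dilution is a property of any density-based propensity
score and is why the screens work with ranks rather than absolute ratios.

## The maximum chi-square TFA statistic

For a (PWM, comparison, direction) cell, genes are ranked by signed scaled
SAM score (descending for the up screen, ascending for down — absolute
values are never used for ranking) and by descending propensity, ties broken
by gene ID. For rank thresholds (r_s, r_t) the 2×2 table of top/bottom
membership is scored with the Yates-corrected chi-square

    χ² = N (|ad − bc| − N/2)² / ((a+b)(c+d)(a+c)(b+d)).

Admissibility: the expected count in **every** cell must exceed
`min_expected` (default 10), and the observed overlap must exceed its
expectation. Guarding all four cells (Cochran's classical validity rule)
rather than the overlap cell alone is essential: near-corner tables with a
tiny expected complement cell otherwise reach χ² in the hundreds under pure
permutation noise, destroying both the reliability of the statistic and the
log-linearity of its null tail.

The test statistic is the maximum χ² over all admissible threshold pairs,
computed with incremental prefix counts over the two sorted orders (O(1) per
table after sorting; exact at `grid_step=1`, and for N > 2000 a default rank
grid of step ⌈N/2000⌉ keeps the scan quadratic in 2000 regardless of N).
Because true targets need not occupy the very top expression ranks, the scan
is repeated with the top-k SAM genes removed, k spaced over
[0, r_s of the base maximiser] in five depths, and the overall maximum taken.
The depth count bounds the cost per permutation; since the identical scan
runs inside the null, the test remains exchangeable (hence valid) for any
choice.

### Permutation null and P-value extrapolation

The null randomises the propensity ranking relative to the SAM ranking
(n_perm = 10 000 by default) and recomputes the identical statistic. The
null therefore depends on the input only through the gene count and the scan
configuration, so one null sample is shared across all cells of a screen.
The empirical tail probability is close to log-linear in the statistic:
−log10 p̂ is fitted by OLS against the null values whose tail probability
lies in [10/n_perm, 0.5] (excluding both the noisy extreme tail and the
non-linear bulk), and the fitted line extrapolates −log10 P far beyond the
permutation resolution (fit R² ≈ 0.994 at N = 5000). Inside the sampled
range the result is floored at the empirical value, so extrapolation never
*reduces* significance. Per PWM and direction the screen reports the mean
and median −log10 P across comparisons, the number of comparisons with
−log10 P ≥ 2, and a consistency flag (≥ 6 of 7 comparisons by default); the
mean −log10 P ranks candidates.

## Min-P target-cohort test

For a group of m genes and metric ∈ {de, dp, cov}, the score increment at
propensity threshold τ is Δ(τ) = mean(metric | tp ≥ τ) − mean(metric), with
the whole-group mean as baseline (stable when the below-τ set is small; an
above-minus-below variant exists). Thresholds are the within-group tp
deciles; inadmissible thresholds (no members on one side) are skipped. The
null fixes the group's tp values and redraws member metric values without
replacement from the global gene pool (B = 1000 draws; a "rows" mode redraws
whole gene rows, preserving inter-metric correlation, for users who want a
joint null). Interim P at τ is the +1-smoothed exceedance proportion; the
final P compares the observed minimum interim P across thresholds with each
sampled group's own minimum (computed leave-self-in, the conservative
choice), a min-P family-wise adjustment that is valid for any threshold grid.
All permutation P-values lie in [1/(B+1), 1] and the final P never
undercuts the minimum interim P.

Across groups, q-values use the smoother-based estimate of the null
proportion π0 (cubic smoothing spline of π0(λ) over λ = 0.05…0.95 evaluated
at λ = 0.95), with π0 fixed at 1 below ten tests.

### Separation threshold, envelope, cohort genes

For a significant group, the per-threshold average of −log10 interim P
across the three metrics typically rises as τ decreases and then plateaus.
The separation threshold τ* is the largest τ whose profile value is within
10 % of the maximum — the plateau onset; a manual override is first-class
because such thresholds are often chosen by inspection, and the shipped
reference configurations (`wnt`, `wnt_exploratory`, `fgf`) record published
inspection-chosen values. Envelope cutoffs are the maxima of the below-τ*
members per metric (absolute values for dp and cov) after discarding
outliers above Q3 + 1.5·IQR; the *target-cohort* is the set of members with
tp ≥ τ*, de above the de cutoff, and |dp| or |cov| above theirs.

## Synthetic data: what it emulates, what it does not

The generator plants a 10-position regulator motif with degenerate consensus
NTTTSSCGSS plus column-shuffled decoys (same base composition, hence the
same background hit rate, but no planted word). Promoters are i.i.d. uniform
ACGT with motif instances drawn from the PWM's own base distribution,
planted non-overlapping at Poisson rates — `background_site_rate` (default
0.002 sites/base, i.e. ~1.2 sites per 600-base promoter) for background
genes, `site_density_ratio` (default 5) times that for the `n_targets`
(default 200 of 5000) target genes. Expression is Gaussian noise
(sd 1) with the case class of target genes up-shifted by
`effect_size` (default 3) scaled by the gene's planted density relative to
the mean target density; the designated regulator gene is up-shifted too, so
similarity metrics have a signed reference, and target similarity is
positive by construction. Groups (default 100 of size 50) include five
enriched groups drawing 40 % of members from targets. Seven comparisons with
three replicates per class mirror a small multi-study two-class design.
All stages draw from independent streams derived from one seed; outputs are
pure functions of the configuration.

Deliberately not modelled: promoter base-composition bias and dinucleotide
structure, probe-level microarray noise, batch effects, correlated genes,
and hierarchical group overlap. Passing the synthetic recovery tests
therefore demonstrates the statistical machinery (calibration, power against
planted signal, exact maximisation, determinism) — not performance on real
promoters, where composition bias inflates motif-specific background rates.

## Numerical conventions

- Coordinates 0-based half-open; promoter FASTA headers `gene|promoter`.
- Ties in any ranking break by gene ID with stable sorts, identically in
  observed and permuted data.
- Degenerate inputs fail loudly: zero-variance genes with s0 = 0, zero
  global site density, empty matrices, flat significance profiles.
- Permutation P-values are +1-smoothed; extrapolated P-values are floored
  at their empirical counterparts inside the sampled range.
- Problem sizes in the validation suite (e.g. 5000-gene screens, 10 000
  permutations for the linearity check, reduced n_perm = 500 for repeated
  calibration replicates) are chosen to make each property measurable with
  comfortable statistical resolution on a single CPU.

## Known limitations

- The TRANSFAC minimum-false-negative cutoff profiles are proprietary; the
  fixed permissive defaults imitate their intent but not their per-matrix
  values.
- The propensity score inherits the scan's false-positive load; absolute tp
  values are therefore cutoff-dependent (ranks are stable).
- The min-P test's leave-self-in convention makes final P-values very
  slightly conservative at small B (order 1/B).
- The min-P null is "member values exchangeable with the global pool".  Any
  finite universe carries a small *realized* correlation between propensity
  and scores, which the test correctly treats as signal; calibration
  experiments therefore redraw the universe per replicate, and P-values for
  many groups screened against one universe share that (tiny) common
  component.
- π0 estimation by spline smoother is unstable for few tests; it is fixed
  at 1 there, which only makes q-values conservative.
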