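# Methods

This note documents the models, parameter choices and numerical decisions
behind lbt2kit, and what the synthetic-data generator does and does not
emulate.

## Count model

All simulated counts are gamma-Poisson: a count with expectation λ and
dispersion φ has variance λ + φλ². φ = 0 degenerates to Poisson. The same
parameterization is used by the method-of-moments dispersion estimator in
the single-cell DE stage, so simulator and estimator speak one language.

## Synthetic single-cell and bulk data

A ground-truth draw fixes per-gene base means μ_g (log-normal, location 0,
scale 1.5, rescaled to sum to the mean per-cell depth), gene lengths
(log-normal around 2 kb), five disjoint phase-marker sets, and a set of
treatment-responsive genes with log2 fold changes |β| ~ N(3, 1) clipped at
1, 85% upregulated (stimulus-response transcriptomes of this kind are
dominated by induction of immediate-early genes). Per cell: a cycle phase
drawn from the phase fractions (0.30, 0.20, 0.20, 0.15, 0.15 — G1 largest,
as in an asynchronously cycling culture), a log-normal(0, 0.3) library-size
factor, and NB counts with expectation s_c·μ_g·m_{g,k}·2^{β_g·I(treated)}.

Phase markers multiply expression by a clipped-cosine profile over cyclic
phase distance: amplitude (default 4×) at the marker's own phase, a
shoulder (~1.9×) at adjacent phases, nothing further away. This mirrors the
empirical behavior of canonical markers (e.g. an M-phase gene peaking at M
with high expression at G2/M). Marker genes are drawn from the upper half
of the base-mean distribution: curated phase signatures consist of
reliably detected transcripts, and markers buried below the detection
limit would say nothing about the scoring procedure.

Defaults were calibrated once, analytically, to the study structure the
generator emulates: 10,000 genes, 2,000 cells per condition, and a mean
depth of 12,000 UMIs/cell, which gives ~4,000 detected genes per cell
(computed from P(detect) = 1 − (1 + φλ)^(−1/φ) summed over genes). Global
dispersion φ = 0.1 is a typical droplet-data value combining technical
(Poisson) and modest biological variation.

Bulk replicate counts share the ground truth with the cells. The read-count
expectation includes a gene-length factor (reads sample bases, not
molecules), so bulk TPM — which divides by length — estimates molecular
abundance and is directly comparable to cell-averaged UMI expression.
Cell phases are integrated out using the phase-averaged multiplier. Bulk
biological dispersion defaults to φ = 0.05 across n = 4 replicates per
condition.

What the generator does **not** emulate: ambient RNA, doublets, barcode
errors, gene-length bias within UMI counts, batch structure, and any
correlation structure between genes beyond the planted phase and treatment
effects. Passing recovery tests on these data therefore demonstrates the
correctness of the procedures under the stated generative model, not
robustness to every artifact of real droplet data.

## Bulk differential expression

The stage tests two groups on y = log2(CPM + 0.5) with an unweighted
linear model and empirical-Bayes variance moderation: per-gene pooled
variances s²_g with d = n₁ + n₂ − 2 degrees of freedom are shrunk to
s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d), and t̃_g = log2FC/SE(s̃_g) is referred to
a t distribution with min(d₀ + d, total pooled df) degrees of freedom.
(d₀, s₀²) are estimated by method of moments on log s²_g via the scaled-F
moment equations (trigamma inversion by Newton iteration); when the
observed spread of log s²_g does not exceed residual sampling variation,
d₀ = ∞ and all genes share s₀². A non-finite moment estimate falls back to
d₀ = 4. The mean-variance precision weighting used by full voom-style
pipelines is deliberately not reproduced: the downstream product is the
FC/FDR gene list, and on the data simulated here the unweighted moderated
test is calibrated (type-I ≈ 0.05) and recovers planted 16-fold effects
completely. The implementation is cross-checked in the test suite against
an independent reference (R limma's lmFit + eBayes) to 1e-6.

Fold-change filtering is applied after testing (selected = q < 0.05 and
|log2FC| ≥ 2), not as a composite null; the 16-fold tier (|log2FC| ≥ 4)
is emitted alongside.

BH q-values implement the step-up rule q_(i) = min_{j≥i} p_(j)·m/j capped
at 1; NaN p-values propagate and are excluded from m.

## Single-cell analytics

"SC-TPM" scales each cell to 10⁶ total counts with no length term (UMI
counts carry no length bias); bulk TPM retains length. Comparisons between
the two run on log2(x + 1), where the length discrepancy behaves as an
approximately affine offset. Split-half reproducibility partitions cells
into two equal random halves and correlates per-gene mean SC-TPM on the
log scale over detected genes; the pseudobulk comparison correlates
cell-averaged SC-TPM with replicate-averaged bulk TPM over genes detected
in both assays.

The noise decomposition compares each gene's total CV to the Poisson
technical reference 1/√μ on raw counts; genes above the line by more than
20% (relative, configurable) are flagged as showing excess (biological)
variation. The NB closed form CV = √(1/μ + φ) gives the expected asymptote.

### sSeq-style exact test

Per gene, dispersions are method-of-moments on size-factor-normalized
counts pooled over both groups, φ̂_g = max(0, (s² − μ)/μ²), and shrunk
toward the target ξ = mean(φ̂): φ̃ = δξ + (1−δ)φ̂ with
δ = [Σ(φ̂−ξ)²/(G−1)] / [Σ(φ̂−φ̄)²/(G−2)], clamped to [0, 1]. With a
homogeneous true dispersion δ → 1 (full shrinkage), which is both the
intended sSeq behavior for zero-rich droplet data and correct under the
generator. Size factors are per-cell totals scaled to median 1. The test
conditions on the gene's total count t: group sums are NB with mean S_A·q
(q the pooled rate) and variance S_A·q + φ̃q²Σs²_c, and the two-sided
p-value sums the probabilities of all splits a + b = t whose joint
probability does not exceed the observed one (tolerance 1e-8 in log space).
The implementation is anchored by an exhaustive-enumeration oracle
(convolution of per-cell NB pmfs) in the test suite, which agrees to
machine precision.

Total-count size factors are sensitive to strong composition shifts: if
planted effects carry a large fraction of transcript mass, null genes
appear shifted in compensation. At the composition this package simulates
by default (responders a small mass fraction) the test is calibrated and
fully sensitive to 4-fold effects at 500 cells/group.

## Cell-cycle scoring

Expression enters as log2(SC-TPM + 1), standardized per gene across cells.
The raw phase score is the mean standardized expression over the set's
genes present in the matrix. Refinement (on by default, threshold 0.3 —
the published choice for this family of scoring procedures) keeps genes
whose correlation with their phase's raw score is at least the threshold
and recomputes; an emptied set falls back to the unrefined genes with a
warning. Scores are then z-scored across cells within each phase and
across phases within each cell (sample, n−1, standard deviation
throughout; zero-variance slices become 0 with a warning).

Assignment is the within-cell argmax; ties break toward the earlier phase
in the cyclic order [G1/S, S, G2/M, M, M/G1]. Cells are ordered around the
cycle by grouping on assigned phase and sorting within a phase by
(z of next phase − z of previous phase) ascending, so cells entering a
phase precede cells leaving it. This contrast rule is one monotone
traversal among several defensible ones; it is isolated in
`assign_and_order` and covariant under cyclic relabeling.

Phase-conditioned response testing reports per phase × condition n, mean
and SD, a Kruskal–Wallis test of phase effect within each condition and a
Wilcoxon rank-sum test of treatment effect within each phase, BH-corrected
jointly over genes × tests; strata under 3 cells are flagged and skipped.
These nonparametric tests are this package's operationalization of the
visual mean ± SD comparison such studies present.

## ATAC analytics

Fragment lengths are modeled as a mixture of a subnucleosomal component
(38 + Exp(45) bp) and mono/di/tri-nucleosomal Gaussians at 1×, 2×, 3× the
nucleosome spacing (default 200 bp, sd 0.14× spacing, weights
0.6/0.3/0.1). The periodicity estimator histograms lengths at 1 bp,
subtracts a 151-bp running median, and takes the argmax of the
autocorrelation over lags 120–350 bp, using only histogram bins ≥ 100 bp:
the sharp subnucleosomal onset leaves a detrending residual whose
cross-correlation with the mononucleosome bump peaks near 150 bp and would
otherwise mask the true 200 bp ladder. Significance is a permutation test
shuffling the detrended bins (default 200 permutations). The estimator
recovers 198–200 bp across seeds at 200,000 fragments and is invariant to
fragment order and subsampling.

Peak classification is single-label at the summit (midpoint fallback) with
precedence promoter > exon > intron > intergenic; the promoter window is
(−1000, +100) strand-aware around the TSS — no standard definition exists,
so it is exposed as configuration. Accessibility–expression integration
assigns each peak to the gene with the nearest TSS (ties to the upstream
gene) and keeps the maximum score per gene; genes without peaks score 0.
TSS meta-profiles aggregate fragment midpoints (cut-site shifts are out of
scope along with alignment), orient by strand, and normalize the outer 10%
of bins to mean 1.

Footprint notches are maximal runs of per-base coverage below
(1 − 0.5) × the local flank mean (20 bp each side; the global median seeds
candidate runs), with width 6–30 bp; an optional PWM gate requires a
log-odds motif match overlapping the notch. For sparse per-base cut-site
signals, `cut_site_coverage` applies a 5-bp boxcar before detection;
`detect_notch` itself performs no smoothing so its arithmetic is exact on
constructed inputs. The simulator plants footprints by resampling
fragments whose cut sites fall in the notch, emulating transposase
exclusion by a bound factor.

## qPCR

E = 2500 × 1.93^(Ct_ref − Ct_gene); the constants are treated as fixed
assay calibration values (1.93 the per-cycle amplification efficiency).
Technical replicates are averaged on the Ct scale before the transform —
the standard convention, and the order of operations is documented because
averaging on the E scale would differ. Ct = 40 (the assay's cycle cap)
marks below-detection measurements. The simulator generates
Ct = 35 − log_1.93(expression) + N(0, 0.2) per technical replicate.

## Problem sizes

The test suite runs most recovery tests on a 2,000-gene × 400-cell
configuration and one full-scale (10,000 × 2,000 per condition) run for
the end-to-end phase-scoring and reproducibility checks; the acceptance
script uses the full scale with 5 seeds per quantity and 200,000 fragments
for the periodicity estimate. These sizes give Monte-Carlo stability at
interactive runtimes on a single CPU.

## Known limitations

- The bulk stage supports only two-group designs, by construction.
- The sSeq exact test enumerates all splits of a gene's total count;
  extremely deep genes make this linear-in-total work (still vectorized).
- Composition-robust size factors (median-of-ratios style) are not
  implemented; see the note on total-count scaling above.
- The cell-cycle progression rank is a discrete five-phase traversal, not
  a continuous pseudotime.
- Peak calling, alignment, UMI demultiplexing and motif discovery are out
  of scope; the toolkit starts from count matrices, fragments and peaks.
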