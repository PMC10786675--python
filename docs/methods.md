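# Methods

## The model

Single-cell bisulfite sequencing yields, for cell *i* of group *g* in genomic
region *j*, a pair of counts (x, n): methylated reads and total reads summed
over the region's CpG sites.  Coverage is very low (most sites carry 1–3
reads) and per-cell methylation fractions pile up at exactly 0 and 1.

Within one region and group, each cell's latent methylation fraction p is
modelled by a zero–one inflated beta (ZOIB) law

    p = 0            with probability pi0
    p = 1            with probability pi1
    p ~ Beta(a, b)   with probability 1 - pi0 - pi1

and, given p, the cell's methylated count is x ~ Binomial(n, p).  All sites of
a cell in a region share that cell's p, so summing the cell's site counts
keeps the binomial form; marginally the continuous component is beta-binomial.
The parameter vector per group and region is theta = (pi0, pi1, a, b), and the
quantity tested is the expected methylation rate

    g(theta) = pi1 + (1 - pi0 - pi1) * a / (a + b).

## Estimation

theta is estimated per (region, group) by EM over the latent component of each
cell.  The zero spike is reachable only by cells with x = 0, the one spike
only by cells with x = n.  The E-step computes the three responsibilities from
the current mixture pmf; the M-step sets pi0, pi1 to mean responsibilities and
maximises the responsibility-weighted beta-binomial log-likelihood over
(log a, log b) by damped Newton with analytic digamma/trigamma derivatives,
with an active-set pass when a shape sits on its bound and a coarse log-grid
fallback if no step improves.  Iteration stops when the relative change of the
marginal log-likelihood falls below 1e-8 (at most 500 iterations); the
marginal log-likelihood is non-decreasing across iterations by construction.

Numerical choices that matter:

* **Bounds.** a, b are confined to [1e-3, 1e4]; spike weights hit 0 exactly
  when their responsibility sum vanishes.
* **Initialisation and restarts.** The primary start puts half of the
  fully-unmethylated (resp. fully-methylated) cell fraction into each spike
  and sets (a, b) by method of moments on interior rates.  On small or
  low-depth groups (fewer than 10 cells, or mean coverage below 8 reads) the
  likelihood carries several near-tied maxima whose basins reveal themselves
  only slowly, so every deterministic start — four structural ones plus the
  best points of a coarse likelihood grid — is run to convergence and the best
  kept; at realistic aggregated depths a short burn-in selects the two most
  promising starts instead.  A final polish flushes vestigial spikes below
  0.01 to exactly zero (EM shrinks a vanishing spike only geometrically) and
  keeps the result if it improves the likelihood.
* **Degenerate groups.** A group where every cell is fully unmethylated
  (methylated) gets the boundary fit pi0 = 1 (pi1 = 1); with at least two
  covered cells this is treated as informative, so an all-zero versus all-one
  region is decisively called.  Groups with fewer than two covered cells are
  untestable and force P = 1.
* **Information.** The observed information (negative Hessian of the marginal
  log-likelihood, computed analytically) is used in the block-diagonal form:
  the (pi0, pi1) block and the (a, b) block, with cross-blocks set to zero.
  Expected information would require a model for the depth distribution;
  observed information needs none and the block structure mirrors the
  asymptotic factorisation of the two parameter groups.

## Testing and DMR calling

For each region the two groups are fitted separately and the hypothesis
g(theta_1) = g(theta_2) is tested with the delta-method Wald statistic

    T = (g(theta1_hat) - g(theta2_hat)) / sqrt(v1 + v2),
    v_g = grad_pi' I_pi^{-1} grad_pi  +  grad_ab' I_ab^{-1} grad_ab,

inverting each information block by pseudo-inverse (boundary fits can make a
block singular).  Under the null T is asymptotically standard normal; the
two-sided P-value is 2(1 - Phi(|T|)).  A non-positive or non-finite variance
marks the region untestable (P = 1).

A region is called a DMR when P <= p_cutoff **and** Delta >= delta_cutoff,
both boundaries inclusive, where Delta is the absolute difference of the two
groups' weighted methylation levels (pooled reads sum(x)/sum(n)).  Defaults
are p_cutoff = 0.01, delta_cutoff = 0.1; the evaluation grid spans
P in {0.001, 0.005, 0.01, 0.05} and Delta in {0, 0.1, 0.15, 0.2}.  The signed
difference is also reported for hyper-/hypo-methylation classification, and a
Benjamini–Hochberg column is emitted for convenience — calling itself uses
raw P-values.

## Preprocessing

Sites with zero coverage in more than 50% of all cells (both groups pooled)
are removed.  Each chromosome is then scanned left to right: a region opens at
the first unassigned site and extends while the 1-based inclusive span stays
within 300 bp; closed fragments with fewer than 3 sites are discarded and the
scan restarts at the next unassigned site.  "Missing" means zero coverage at
the site; span is last - first + 1.  Site counts are summed per cell within
each region, and cells with zero summed coverage are dropped.

## The simulator and what it does (not) capture

The generator reproduces the structure of a two-group embryo-stage comparison:
48 cells versus 25 cells, 1000 regions of 10 consecutive CpG sites (30 bp
apart, regions 1 kb apart), per-site depths resampled with replacement from an
empirical-style pool over 1..30 reads with geometrically decaying frequencies
(mean ≈ 3.2 reads — scBS-seq sites are mostly covered 1–3x), and one ZOIB
draw per (cell, region) shared by the region's sites.  Difference experiments
draw the groups from distinct laws; indifference experiments draw both from
the group-1 law.  Region k is generated from an independent child stream of
the root seed, so datasets are bit-reproducible and region k does not depend
on the number of regions.

Default parameters were calibrated once against the observable features of
the motivating data and then frozen:

* theta1 = (pi0 = 0.015, pi1 = 0.015, a = 50, b = 50) for the 48-cell group —
  a concentrated law; methylation of cells at the same developmental stage is
  stable, which is what makes within-group (null) comparisons nearly
  call-free;
* theta2 = (pi0 = 0.40, pi1 = 0.10, a = 0.9, b = 2.1) for the 25-cell group —
  strongly zero/one inflated and over-dispersed;
* the expected rates differ by g(theta1) - g(theta2) = 0.25, and the fraction
  of covered per-site per-cell rates equal to exactly 0 or 1 is ≈ 0.66 (the
  zero/one inflation is a site-level, low-depth phenomenon: real scBS-seq data
  exceeds 0.9 by this measure).

What the simulator does **not** emulate: genomic position realism (CpG
clustering, chromosome structure), per-cell coverage correlation (a shallow
cell is shallow everywhere), region-to-region parameter variation within an
experiment, bisulfite conversion errors, and doublets.  Tests passing on this
generator therefore validate the estimator, the test's calibration and the
calling logic under the model's own assumptions plus realistic sparsity — not
robustness to the full messiness of real libraries.

## Evaluation

In difference experiments every region is a true DMR; in indifference
experiments every call is false.  Sensitivity = TP/(TP+FN),
precision = TP/(TP+FP), FPR = FP/(FP+TN), FDR = 1 - precision, each computed
per cutoff pair; replicate experiments are pooled by summing counts (a
replicate with no calls would otherwise contribute an undefined ratio).  For
real data without truth, the split-half design treats between-group calls as
true and within-group calls (one group split into random equal halves) as
false: P' = TP'/(TP'+FP').

## Problem sizes

The packaged study runs five replicate seeds of 1000 + 1000 regions (about
10 000 region fits per group pair); the null-calibration check uses 2000
replicates of 200-cell groups at depth 30.  These sizes keep the full suite in
the minutes range on one core while leaving the binomial counting error on
the reported rates well below the tolerances being checked.

## Known limitations

* The Wald variance ignores the cross-information between the spike weights
  and the beta shapes; at 25–50 cells this makes the test mildly conservative
  (its null statistic has standard deviation below 1), which suits a caller
  whose priority is precision.
* P-values for regions near parameter boundaries lean on pseudo-inverted
  information blocks; they are conservative rather than exact.
* Two groups only; no covariates; no merging of adjacent DMRs.
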