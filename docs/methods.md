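# Methods

This note records the statistical model behind `rewireprio`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not establish.

## Data model and staging

Input is a genes × samples matrix **X** (M genes, n samples) of finite
non-negative expression values, plus per-sample metadata giving the
condition (treatment/control), the sampling week and a replicate number.
The binary response Y is 1 for treated samples.  Weeks are grouped into
contiguous developmental stages of `weeks_per_stage` weeks (default 3,
first week 3, so weeks 3–17 give five stages); all screening, network
construction and prioritization are per stage, since co-expression
patterns are expected to change over development.  Expression values are
used exactly as provided — the method is rank-based at the screening
step and scale-aware only through the GCC — with an optional
`log2(x + 1)` transform behind a flag (default off).  Missing values are
rejected by default; per-gene mean imputation is available behind an
explicit flag.

## MV screening

The MV index is the weighted L2 discrepancy between conditional and
marginal empirical CDFs (the `<=` convention; ties are kept, never
jittered).  It depends on the data only through ranks, so any strictly
increasing transform of the expression scale leaves it unchanged — a
property the tests assert.  P-values come from K uniform permutations of
the response (default K = 5000):

    p = (1/K) * #{ permuted T >= observed T }

so p is lattice-valued on multiples of 1/K and p = 0 is representable.
Candidates are genes with p <= 0.01 (boundary inclusive).  Per-gene
permutation streams derive deterministically from `(master seed, gene
index)` via `numpy.random.SeedSequence`, so results are reproducible and
independent of execution order.  Comparisons between permuted and
observed statistics use an absolute guard of 1e-15 so that a permutation
numerically equal to the identity is always counted; this can only
increase p-values, preserving the super-uniformity of the test.  Each
permutation null is generated per gene (the procedure is defined
gene-wise); no multiple-testing correction is applied, since the
downstream model consumes the raw p-values.

## Gray correlation and the rewiring network

For reference gene p the GCC numerator/denominator use the global
minimum and maximum of |x_tp − x_ts| over *all* comparison genes s in
the candidate set and all samples t.  Because s = p is included, the
global minimum is identically zero; the formula is implemented exactly
as written, and a pairwise-extremes variant is available behind a flag
(default off).  Consequences worth knowing:

* r_pq depends on the whole candidate set of the stage, not just the
  pair (p, q);
* the resolution ratio ρ (default 0.5) sets how strongly the global
  maximum damps the per-sample terms;
* if every candidate profile is identical in a condition (Δmax = 0) the
  row is defined as 1 with a warning.

The comparison set is the *candidate* set of the stage (screening always
precedes network construction in this pipeline), not the full
transcriptome.  The asymmetric coefficients are corrected to
(r_pq + r_qp)/2; the matrix is symmetric with unit diagonal and entries
in (0, 1].  The m × m computation streams one reference row at a time
(O(m·n) extra memory per reference gene).

An edge joins p and q when (r_treat − r0)(r_ctrl − r0) <= 0 with
r0 = 0.9, weighted by rewire = |r_treat − r_ctrl|.  Edges with exactly
zero weight (both coefficients equal to r0) are dropped: every
downstream Ising term multiplies by the weight, so such edges are inert
and would only inflate density.  All candidates remain nodes, including
isolated ones.

## HMRF model and ICM

Labels ω ∈ {−1, +1}^m follow an Ising prior on the rewiring network
with field h, coupling τ₁ on associated pairs and τ₂ on null pairs
joined by strong edges (weight > δ = 0.95); τ₁ = τ₂ = 0.01 by default.
The per-gene full conditional is logistic in

    Q_p = ln(f1(ξ_p)/f0(ξ_p)) − h
          + τ₁ Σ_{pq∈E} w_pq I(ω_q=+1)
          + τ₂ Σ_{pq∈E, w_pq>δ} w_pq I(ω_q=−1)

which the tests verify against exhaustive enumeration of the joint with
an explicit partition function on small graphs — the main correctness
surface for sign conventions.

**Evidence densities.**  ξ_p = Φ⁻¹(1 − p_MV), with p clamped into
[1/(2K), 1 − 1/(2K)] so ξ is always finite even at p = 0.  Under the
null f0 is standard normal.  Under association the location/scale pair
(μ_p, σ_p²) carries a Normal/Inverse-Gamma conjugate prior
(μ_p|σ_p² ~ N(μ̄, σ_p²/a), σ_p² ~ InvGamma(g/2, gd/2)); rather than
estimating per-gene parameters from a single observation, f1 is the
closed-form prior-predictive marginal: a Student-t with ν = g degrees of
freedom, location μ̄ and squared scale d(1 + 1/a).  Defaults μ̄ = 2,
a = g = d = 1 place the alternative mode near ξ ≈ 2 with heavy tails;
the posterior ranking is insensitive to moderate changes because every
candidate shares the same f1/f0 curve.  One consequence of the
heavy-tailed alternative: ln(f1/f0) is non-monotone for strongly
negative ξ (the t tail dominates the normal tail on both sides).  This
regime is unreachable for screened candidates, which always satisfy
ξ >= Φ⁻¹(0.99) ≈ 2.33; the monotonicity tests therefore cover the
attainable range.

**Field h and initialization.**  Initial labels are +1 for p_MV <= 0.005
and −1 otherwise (all candidates already satisfy p_MV <= 0.01; anything
larger is rejected as pipeline misuse).  Each gene's association
potential is the τ-weighted sum of its +1-neighbor weights plus strong
−1-neighbor weights, and h is the empirical 0.90 quantile of the
potential vector (numpy's linear-interpolation convention, the fixed and
documented choice) — expressing the belief that marginally significant
genes may still be associated.  h is computed once from the initial
labeling and held fixed (τ₁, τ₂ likewise); a `refresh_h` option
recomputes it each sweep.  Which parameters a fuller treatment should
re-estimate during inference remains an open modeling question; holding
them fixed keeps ICM a deterministic coordinate ascent.

**ICM.**  Full sweeps in fixed ascending gene order (a seeded random
order is available) set each label to its conditional mode, with the tie
at probability exactly 0.5 resolved to +1 (consistent with the
marginal-gene belief behind h).  Convergence is a sweep with zero flips;
non-convergence within `max_sweeps` (default 100) warns and flags the
state rather than erroring.  Posteriors are the conditional
probabilities at the converged configuration, computed with
numerically stable logistic evaluation.  Ranking sorts by posterior
descending with ties broken by larger ξ then lexicographic gene id.
The discrimination ability R = (#unique scores)/m quantifies ranking
resolution; permutation p-values at small K are lattice-valued, so the
continuous posterior essentially always resolves more genes.

## DEG classification

Fold change is the ratio of condition means with a pseudo-count of 1 in
both numerator and denominator (guards zero means and log of zero).
Volcano categories follow the two-threshold rule: significant
up/down-regulation needs |log2FC| strictly > 1 with p < 0.05; FC-only
classes use |log2FC| >= 1 with non-significant p; P-only is p < 0.05
with |log2FC| < 1; everything else (including the measure-zero boundary
|log2FC| = 1 with significant p) is NoDiff.  When no external
differential-expression p-values are supplied, per-gene Welch t-tests
are used.

## Multilayer summaries

Layers are induced subgraphs of each stage's WGDCN over that stage's
top-k genes (k = 20 by default); interlayer edges connect the same gene
in different layers.  Layer statistics are computed on the unweighted
topology: density 2E/(V(V−1)), average degree 2E/V, average shortest
path over *connected pairs only* (finite even on disconnected 20-node
subnetworks; 0 when no pair is connected), and mean local clustering
with degree < 2 nodes contributing 0 (a flag can exclude them).  Set
overlap between stages is the Jaccard coefficient, with the 0/0 case of
two empty sets defined as 0 with a warning.

## Synthetic data

The generator emulates the statistical structure the method detects, on
a Gaussian latent scale: null genes are i.i.d.; DE genes get a
conditional mean shift (default 2 s.d.); a module of genes shares an
equicorrelated latent factor whose pairwise correlation differs between
conditions (default 0.9 treatment vs 0.1 control).  Module genes also
receive the mean shift: the pipeline's own screening step would
otherwise remove genes whose marginals are identical across conditions,
and phenotype-driven genes in real data typically both shift and rewire.
Latent values are exponentiated by default so the emitted matrix is
positive and right-skewed like processed RNA-seq abundances; the
rank-based screen is unchanged by this monotone transform, while the
GCC operates on the positive scale, where a pilot of the coefficient
distribution showed the r0 = 0.9 threshold separating rewired from
stable pairs — mirroring how the threshold was matched to data
characteristics in the first place.

Default sizes (60 null + 15 DE + 10 module genes, 12 + 12 samples per
stage) keep a full pipeline run under a few seconds while leaving the
screen non-trivial.  What passing tests show: the statistics agree with
brute-force oracles; the permutation test is calibrated; planted signal
is recovered (AUROC and top-k).  What they do not show: behavior under
library-size artifacts, count noise, batch effects, or transcriptome-
scale multiple testing — the generator produces clean continuous
abundances, not read counts.

## Numerical and reproducibility notes

* All stochastic steps flow from a single master seed through
  `SeedSequence` spawn keys; reruns are byte-identical.
* Logistic probabilities use `scipy.special.expit`; evidence ratios are
  computed in log space.
* Oracle tolerances: 1e-12 for MV and GCC equivalence, 1e-10 for the
  Ising conditionals (enumeration in plain floating point).
* Quantiles (for h) use numpy's default linear interpolation.

## Known limitations

* The GCC's global extremes make every coefficient depend on the whole
  candidate set; adding or removing a candidate changes all values.
  This is inherent to the definition used.
* ICM finds a local maximum only; no uncertainty is attached to the
  labels beyond the converged conditionals (no MCMC by design).
* h, τ₁, τ₂ are fixed rather than estimated; the τ defaults equate the
  contribution of associated and unassociated pairs.
* Hard thresholds (P_MV <= 0.01, r0 = 0.9, δ = 0.95) trade information
  loss against network density and compute; they are configurable but
  interact, and no automatic selection is attempted.
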