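# Methods

## The linear Poisson model

For a gene with I annotated isoforms observed in K conditions, the unit
of observation is the *read type*: the equivalence class of reads whose
genomic footprint is identical. Under uniform single-end sampling every
start position on a transcript generates its read type at the same rate,
so the sampling rate of read type j from isoform i in condition k is
a_kij = d_k if the footprint is contiguous in isoform i's transcript
coordinates and 0 otherwise, where d_k is the per-condition depth scale.
The count of reads of type j is Poisson with mean Σ_i a_kij·θ_ki, reads
independent across types and conditions. The log-likelihood of condition
k (dropping additive terms free of θ) is

    l_k(θ_k) = Σ_j n_kj log(Σ_i a_kij θ_ki) − Σ_i a_ki θ_ki ,

with a_ki = Σ_j a_kij = d_k·(L_i − r + 1) the total sampling rate of
isoform i (L_i transcript length, r read length).

Read types with identical compatibility patterns are merged into *read
categories* — counts add, rate vectors add — which changes the
log-likelihood only by a constant in θ (each member type of a category
has the same rate vector, so Σ n_j log(a·θ) regroups exactly up to the
Σ n_c log m_c term). The per-isoform totals a_ki keep their full-model
values, so the penalty term is untouched. All estimation operates on
categories; the equivalence is property-tested.

**Units and depth scale.** θ is expressed in RPKM-like units with
d_k = (total mapped reads in condition k)/10⁹, so abundances are
comparable across conditions of different depth. Any common rescaling of
(rates, θ) by (c, 1/c) leaves both the category means and the fitted
log-likelihood unchanged.

**Coordinates** are 0-based half-open throughout (BED convention); GTF
input is converted on read. Strand is recorded but ignored by the rate
construction. Exons that abut genomically are merged inside a footprint,
since the genome cannot distinguish them. Paired-end alignments are
rejected explicitly: the insert-length sampling model is out of scope,
and silently treating mates as single-end reads would bias the rates.

## The three nested models and their EM fits

* **Model 0** (θ_k ≡ θ̃, I free parameters): fitted by EM on the stacked
  categories of all conditions with pooled totals Σ_k a_ki.
* **Model 1** (θ_k = τ_k·θ̃, I + K − 1 free parameters): fitted by an
  expectation/conditional-maximization scheme. The E-step computes
  expected per-isoform read counts E_ki (the τ's cancel in the
  responsibilities); the conditional M-steps are
  θ̃_i ← Σ_k E_ki / Σ_k τ_k a_ki followed by τ_k ← Σ_i E_ki / Σ_i a_ki θ̃_i,
  each maximizing the same minorizing function, so the likelihood is
  monotone. After convergence (θ̃, τ) is rescaled to the identifiability
  constraint Σ_k τ_k = K — chosen so that τ ≡ 1 coincides with model 0
  and the parameterization is symmetric in conditions; any other linear
  constraint is a likelihood-preserving reparameterization. K = 1 is
  refused (model 1 degenerates to model 0).
* **Model 2** (free θ_k, K·I parameters): independent per-condition EM
  with the classic multinomial-Poisson update
  θ_i ← (Σ_j n_j r_ij)/a_i, r_ij the read-assignment responsibility.

**Initialization** is uniform, θ_i = N/(Σ_i a_i · I) (τ = 1), which is
strictly positive wherever a_i > 0; EM cannot leave the boundary, so
isoforms with a_i = 0 are pinned at 0 and excluded from updates.
**Convergence** is declared when the relative log-likelihood change
drops below 1e-10 (cap 10 000 iterations; non-convergence is reported,
never raised). The tight threshold matters: EM converges linearly, and a
looser per-iteration change criterion can stop ~1e-4 short of the
optimum, which is the same order as the agreement the test suite demands
between EM and an independent numerical optimizer. Per-iteration
log-likelihoods are retained so monotonicity is testable.

The single-condition likelihood is concave in θ; the model-1 joint
likelihood in (θ̃, τ) is treated as possibly multi-modal — the
alternating scheme is monotone regardless, and the test suite compares
its optimum against a multi-start generic optimizer.

## Confidence intervals

Wald intervals from the observed Fisher information of the fitted
model's free parameters. For models 0 and 2 the information is analytic,
I_obs[i,i′] = Σ_j n_j a_ij a_i′j / μ_j² (the penalty term is linear and
contributes nothing). For model 1 the information of
(θ̃, τ_1..τ_{K−1}) is a central-difference Hessian of the profile-free
parameterization (τ_K = K − Σ), with the τ_K interval via the delta
method. Intervals are truncated below at 0; a parameter estimated *at*
the 0 boundary, where Wald theory fails, instead gets the one-sided
exact-Poisson bound [0, −ln(1−level)/a_i] (the largest abundance whose
zero-count probability still exceeds 1−level). A singular information
matrix yields NA bounds rather than an error.

## Hierarchical likelihood ratio test

Two parallel first-round tests at level α/2: Λ01 = −2(l₀−l₁) against
χ²_{K−1} and Λ02 = −2(l₀−l₂) against χ²_{(K−1)·I}. No rejection →
model 0; one rejection → that model; both → second round,
Λ12 = −2(l₁−l₂) against χ²_{(K−1)·(I−1)} at level α, significant →
model 2, else model 1. With I = 1 the second-round df is zero (models 1
and 2 coincide); the less complex model 1 is reported and p12 is NA.
Negative Λ from numerical noise is clamped at 0 (logged above 1e-6).
Boundary estimates (some θ̂ = 0) formally violate the χ² asymptotics; the
plain χ² reference is used regardless and such genes are flagged.

No multiple-testing correction is applied across genes: selection is
per-gene at fixed α and downstream ranking is by T or by p-value;
genome-wide FDR control is left to the user on the reported p-values.

The default low-count filter drops genes with fewer than 5 mapped reads
in *every* condition (a gene with 5+ reads in any one condition is
kept).

## Ranking and ψ

T = ½‖θ̂₁/‖θ̂₁‖₁ − θ̂₂/‖θ̂₂‖₁‖₁ is reported for two-condition analyses;
the ½ bounds it in [0,1]. Genes selected as model 0 or 1 report T = 0
identically — their fitted rows are proportional by construction — and
the pipeline assigns the exact zero rather than recomputing a
floating-point difference of proportional vectors. T for K > 2 is
undefined and refused. Ranking is a stable sort (descending T or
ascending p02) with model-0/filtered genes at the bottom and gene-id
tie-breaks for determinism.

For a cassette exon observed through junction counts (UJC, DJC upstream
and downstream inclusion junctions, SJC skipping junction), the event is
recast as a two-isoform gene: the inclusion isoform carries the two
84 bp junction windows, the skipping isoform one. Each window is a
single read type, so the isoform total rates are (2, 1) at unit depth
scale and the MLE has the closed form θ̂_long = (UJC+DJC)/2,
θ̂_short = SJC, giving ψ̂ = (UJC+DJC)/((UJC+DJC)+2·SJC). The closed form
is validated against the EM fit of the constructed category table to
1e-8. ψ from full-length isoform abundances divides the abundance of
exon-containing isoforms by the total over *all* isoforms of the gene,
using the information in the complete isoform structure rather than the
local event only; an exon present in all or in no isoform is not an
inclusion event and yields NA.

## The simulator and what it does (not) capture

The simulation gene is a two-isoform cassette-exon structure: exons of
1200, 60 and 600 bp, isoform A (1860 bp) including and isoform B
(1800 bp) skipping the middle exon. At read length 50 its read types
partition into three categories — 1702 shared, 109 A-specific (touching
the short exon or its junctions), 49 B-specific (spanning the skip
junction). Counts are drawn Poisson per category; a Poisson sum over
member read types equals a Poisson draw at the summed category rate, so
category-level simulation is distributionally identical to read-level
simulation followed by reduction.

Study conditions: depths 50M and 55M reads, read length 50 bp (a typical
single-end design), α = 0.05, gene abundance G scanned over a grid, 1000
replicate pairs per G by default. Scenario mappings: G is the total gene
abundance in RPKM-like units with a 50/50 isoform split at baseline;
model-1 scenarios use τ = (2/3, 4/3) (a two-fold change); model-2
scenarios swap splits (0.8, 0.2) ↔ (0.2, 0.8). All are overridable in
`SimulationConfig`.

The acceptance script uses 500 replicates for the type-I error estimate,
with the binomial standard error accounted for in the test bound
(0.05 + 3·√(0.05·0.95/500) ≈ 0.079), and G = 10 — about 900 expected
reads, a moderately-to-highly expressed gene. The parameter-recovery
check runs at G = 500 (a highly expressed gene) and summarizes accuracy
as the per-condition relative L1 error of θ̂, the natural aggregate for a
vector estimate.

What the simulator does **not** emulate: mapping errors and multi-mapped
reads, positional/GC bias (rates are uniform), biological variation
between replicates (counts are exactly Poisson; real data are
over-dispersed, which inflates the type-I error of any Poisson-based
test when biological replicates are pooled), incomplete or wrong
annotation, and paired-end sampling. Passing tests therefore demonstrate
correctness of the estimator and test under the stated model, not
robustness to these real-data violations; the model-variance limitation
is the standard caveat for Poisson-likelihood RNA-Seq methods.

## Numerical and design choices

* Category tables store only non-zero-count categories; isoform totals
  always refer to the full read-type set.
* Reads on footprints compatible with no isoform are excluded with a
  warning and counted as unassignable.
* Duplicate category rows read from TSV are merged defensively; output
  floats use 6 significant digits and NA for missing.
* Per-gene analysis failures (non-convergence, degenerate input) are
  logged and reported as status NA; a run never aborts on one gene.
* Empirical-Bayes shrinkage, negative-binomial dispersion, bias
  correction and novel-isoform discovery are explicitly out of scope.
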