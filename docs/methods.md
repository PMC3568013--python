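# Methods

This note documents the statistical procedure implemented by `apmscreen`,
its assumptions, the tunable parameters and their defaults, the stated world
of the synthetic-data generator, and the numerical choices made where the
design was genuinely open.

## 1. Data model

The atomic record is one identified peptide occurrence in one experimental
replicate: `(replicate_id, protein_id, peptide_seq, score, probability?,
spectral_count?)`. A bait or control **experiment set** is K uniquely
identified replicates with their evidence. Protein identity is the
accession string verbatim; peptide-level duplicates are distinct spectra.
All occurrence statistics are computed on sets per (protein, replicate):
several peptides of one protein in one replicate count once.

## 2. Prefiltering (MST)

Search-engine identification scores relate monotonically but dataset-
specifically to identification probabilities. The prefilter threshold (MST)
is the smallest score at which the fitted median probability reaches
`prob_threshold` (default 0.5).

* Fit: quantile regression at τ = 0.5 (plus quartiles for plotting) on a
  cubic B-spline basis with 5 interior knots at score quantiles, then an
  isotonic (non-decreasing) projection, clipped to [0, 1]. The monotone
  projection is a modelling choice: a median identification probability
  should not fall as the reliability score rises.
* Requires ≥ 20 rows with both score and probability; otherwise the user
  supplies an explicit threshold (`--mst`).
* Degenerate inputs: constant probabilities give a constant curve; a median
  that never reaches the threshold is an estimation error (no silent
  fallback).
* Prefiltering keeps proteins with ≥ 1 peptide scoring ≥ MST (closed
  comparison everywhere) and drops sub-threshold evidence rows from every
  downstream view.

## 3. Reproducibility index, indicators, reproducible replicates

RI(s) = (1/(K·P(s))) Σ_j Σ_k 1(P_j ∈ E_k ∧ Score_k(P_j) ≥ s), where P(s)
counts proteins whose best peptide score anywhere reaches s and an
occurrence counts only when the protein has a peptide scoring ≥ s **in that
replicate** (per-replicate max). The per-replicate reading matters: with a
protein-global score, RI(s) → occupancy of the single top-scoring protein
as s grows and degenerates to 1.0 on any dataset containing one
always-present high scorer, which collapses the indicator set to a
singleton. With the per-replicate reading RI robustly rises (sporadic
low-score identifications drop out) and then falls (reproducible
occurrences start failing the threshold), producing the interior maximum
the screen exploits.

* RIT = smallest grid score attaining max RI (grid = distinct protein
  max-scores ≥ MST); ties break toward the most inclusive threshold.
* Indicator candidates: proteins with max-peptide score ≥ RIT (protein-
  level rule — membership is about the protein's best evidence).
* Marginal inclusion probability of a candidate: plain empirical occurrence
  frequency over all K replicates (no shrinkage; the estimator that
  reproduces the reference tables' rational values).
* Indicators: candidates with marginal inclusion ≥ p̃_min (closed).
  Default p̃_min = 0.75 on both sides. The threshold is admissible only if
  it leaves a non-empty reproducible set; the smallest admissible value on
  the 0.00–1.00 (step 0.05) grid is computed and either reported in the
  error (default) or substituted automatically (`adjust_pmin=True`, always
  used inside decoy re-runs, where degenerate samples are routine).
* Reproducible replicates F: replicates containing **all** indicators
  simultaneously. An empty indicator set flags all replicates (vacuous
  conjunction). Joint inclusion probability: product of the selected
  indicators' marginals — an independence working assumption adopted
  because it exactly reproduces the published example values (0.538 from
  marginals 1⁸·(8/9)·(7/9)², and 1.000 for the empty set).
* Stage R: prefiltered proteins occurring in ≥ 1 replicate of F.

## 4. Confidence score and specific preys

CS(j) = sign(p′_B − p′_C)·p′_B with p′ the marginal inclusion over the
respective reproducible replicate sets; p′_C = 0 for preys absent from the
prefiltered control; CS = 0 at p′_B = p′_C (including 0/0), which keeps such
preys below any positive cutoff. Specific preys: CS ≥ cutoff, cutoff
restricted to (0, 1) to avoid the singular endpoints.

## 5. Automatic cutoff estimation

Grid: (0, 0.2] step 0.01 (the optimum falls in this short positive range in
practice; pass `cutoff_grid` to widen).

**Decoy FDR.** Each of `n_mc` (default 200) Monte-Carlo replicates draws
N_B proteins (the bait's naive universe size) from the control's naive
universe — without replacement when possible, with replacement and a logged
warning otherwise — keeps the control evidence of those proteins on K_B
sampled control replicates, and re-runs the entire chain (prefilter at the
control MST → RIT → indicators → F → R → CS against the fixed control
marginals). Decoy preys at or above a cutoff are false positives;
FDR(c) = mean decoy count / observed bait discoveries at c, capped at 1,
undefined where the bait has no discoveries. Decoys that degenerate
(nothing survives prefiltering; no reproducible replicate at any threshold)
contribute zero discoveries. Diagnostics report log10(10⁻³ + FDR).

**Similarity distance.** With an ontology and an annotated bait, the
"S side" at cutoff c takes the Resnik bait–prey similarities (max over
annotation-term pairs, per aspect, default MF) of the selected preys; the
"N side" takes `b_reps` (default 1024) random size-matched samples from the
naive prey pool, recomputed per cutoff, averaging per-sample medians and
IQRs. d(c) = LB_S − UB_N with McGill's median CI M ± c·IQR/(1.08·√n);
c = 1.386 when group sizes and spreads are within 2× of each other, 1.960
otherwise (`c_coef` overrides). d is missing where the selection is empty
or unannotated.

**Decision rule.** Among cutoffs attaining the minimal FDR, take the one
with the largest d; if no candidate has d > 0 (or no ontology is given),
fall back to the min-FDR cutoff with a warning flag, breaking residual ties
toward the **largest** cutoff — the FDR criterion controls specificity, so
absent similarity information the conservative member of an equally-good
tie is preferred.

Information content: IC(c) = −log of the fraction of annotated proteins in
c's descendant closure, over the supplied annotation corpus (root IC = 0,
IC non-increasing toward ancestors). Resnik term similarity = IC of the
most informative common ancestor, each term subsuming itself. List-level
similarity is a best-match average over the pooled term sets with pairwise
normalization IC(MICA)/max(IC(t₁), IC(t₂)) — chosen so that identical lists
score exactly 1 and root-only common ancestry scores 0.

## 6. Multiscale-bootstrap stability and K̂min

For scales k from 2 to K, `b1` (default 10) bootstrap samples of k
replicates are drawn with replacement; within each sample indicators are
re-selected at p̃_min and the estimate is **L\*/k**, the fraction of sampled
replicates containing all of them (the bootstrapped reproducible-replicate
count over the sample size; an event frequency, which is what the
normal-quantile machinery below assumes). The procedure repeats `b2`
(default 128) times for means and standard errors. `b1=None` enumerates all
K^k samples exactly (only sensible for K ≤ 4; used by the oracle tests).

Bias correction: per outer replicate, z(k) = Φ⁻¹(1 − BP(k)) is fitted by
least squares as v·τ + c/τ with τ = √(K/k) (signed distance v, curvature c)
on the non-degenerate scales (BP within the granularity bound 1/(2·b1) of
neither 0 nor 1), and each scale's value is reported with the fitted trend
replaced by its full-scale value: z_corr(k) = z(k) − (v·τ + c/τ) + (v + c).
By construction the corrected estimate equals the raw one at k = K, scales
consistent with the two-parameter model land on a common plateau, and
scales whose bootstrap probabilities cannot be reconciled with it (the
coarse-quantization breakdown at small k, where any protein present in the
few sampled replicates attains marginal 1 and selection saturates) stand
out. Constant profiles and profiles with < 2 usable scales are returned
uncorrected.

K̂min: the curve is LOESS-smoothed (span 0.5, non-robust on purpose — the
small-scale inflation is the signal, not an outlier); the plateau is the
mean smoothed value over the upper half of the scale grid and its noise
scale is the residual SD of the curve around its smooth over that same
range; K̂min is the smallest k from which the smoothed curve stays within
`tolerance_se_mult` (default 2) × max(SE, residual SD) of the plateau. The
residual-SD floor is needed because the SE of the mean vanishes as b2 grows
while systematic threshold-quantization residuals (the ⌈p̃·k⌉/k effective
threshold oscillates with k) do not; a band built from the SE alone admits
no plateau on any stochastic curve.

## 7. Validation statistics

* **Overlap significance**: hypergeometric with universe N, selection S,
  reference B. The default convention is the point probability
  P(X = x | N, S, B) — the convention under which the package reproduces
  its reference values exactly — with `upper` (P(X ≥ x), the standard
  enrichment tail) and `strict` available.
* **Stagewise CV**: per stage protein set, the CV across replicates of the
  per-replicate mean occurrence indicator (sample SD / mean; missing at
  mean 0). A screen that does not inflate this CV from stage N to S is not
  buying specificity with irreproducibility.
* **Aggregate FDR from posteriors**: mean of (1 − p) over a selection
  scored by an external posterior-probability method.

## 8. The synthetic generator's stated world

Defaults (`SynthConfig`): 8 bait and 40 control replicates; 20 bait-specific
preys at per-replicate inclusion 0.99; 200 contaminants with per-protein
inclusion uniform on (0.02, 0.98) occurring at the same rate in bait and
control; 25% outlier bait replicates with all inclusions multiplied by
(1 − 0.6); 1–3 peptides per present protein; Gamma(shape 4) scores with
mean 80 for the reliable class and 8 for the noise class; identification
probabilities generated through the logistic link
p = 1/(1 + exp(−0.5·(score − 25))), so the score–probability calibration
is exactly recoverable and the true MST is 25.

Contaminants at or above inclusion 0.93 form the "core" background
(keratin-like ubiquitous matrix binders) and carry reliable scores; the
sporadic rest carries noise scores. This head/tail split mirrors real
control series, where a handful of proteins recur in ≥ 90% of hundreds of
control runs while the bulk of background identifications are rare and
low-scoring (in the reference control data, prefiltering removes ~83% of
protein identifications and only 2 of 542 candidates exceed marginal
inclusion 0.9). It is also what makes the confidence score work: core
contaminants are selected as control indicators, so the control's
reproducible replicates contain them all by construction, their p′_C is
exactly 1, and they can never score positive in the bait.

What a green test on this world does establish: threshold recovery (MST
within ±1 of the planted midpoint), indicator-based exclusion of the
planted outliers, recovery of the planted preys at the estimated cutoff,
null behaviour of the decoy FDR (a contaminant-only bait drives it to 1),
and a stability change point at small replicate counts. What it does not:
instrument-level effects (retention-time drift, intensity-dependent
identification), correlated presence across proteins (complex
co-purification), realistic peptide sequences/masses, or abundance-
dependent spectral counts — presence is independent Bernoulli per
(protein, replicate) by design, the simplest model matching the
frequency-of-occurrence statistics the screen consumes.

A known method-level limitation the planted-truth tests expose: with L̂
reproducible bait replicates, CS is quantized at multiples of 1/L̂, so for
L̂ ≤ 5 a sporadic contaminant observed once in a reproducible replicate and
absent from the prefiltered control scores CS = 1/L̂ ≥ 0.2, above every
admissible cutoff in (0, 0.2]. Such one-hit preys are indistinguishable,
on the evidence the score sees, from rare genuine interactors; truth-level
FDR at small L̂ is correspondingly optimistic even when the decoy estimate
is near zero.

## 9. Degenerate inputs and tie-breaks (summary)

* Closed (≥) comparisons for every threshold; argmax ties toward the
  smallest score (RIT) and the largest cutoff (FDR ties without d).
* Empty indicator set ⇒ F = all replicates, joint inclusion 1.
* CS at p′_B = p′_C (incl. 0/0) ⇒ 0.
* FDR with zero bait discoveries ⇒ missing (never 0/0).
* d with empty or unannotated selection ⇒ missing at that cutoff.
* Decoy universe smaller than N_B ⇒ sampling with replacement, logged.
* Bootstrap probability exactly 0/1 across all scales ⇒ no correction.
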