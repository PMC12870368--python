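# Methods

This note records the models, default parameters and numerical choices
behind `microsem`, and what the synthetic validation does and does not
demonstrate about real data.

## The synthetic study generator

The generator emulates a field trial in which laying-hen houses (farms)
are assigned to a compost-extract arm (HS-Comp), an untreated control arm
(HS-CON) or a short-exposure reference arm (Ref), and faecal samples are
collected before and after administration.

**Structural core.** A binary treatment indicator Cmp drives four latent
variables — acetate (Ace), butyrate (Bty) and the genera Romboutsia (Rmb)
and Turicibacter (Trc) — through a linear acyclic structural model.  The
default edges are Cmp→Ace +0.8, Cmp→Bty +0.6, Cmp→Rmb −0.8, Cmp→Trc −0.5,
Rmb→Trc +0.5, Bty→Ace +0.4; all are configurable.  Structural noise is
uniform on [−√3·s, √3·s] (variance s²) by default: bounded, strongly
sub-Gaussian, and therefore satisfying the identifiability prerequisite of
linear non-Gaussian causal discovery.  A Gaussian family is available as a
negative control and tags the truth object `lingam_identifiable = False`
so tests only assert direction recovery on non-Gaussian runs.  Noise
scales default to 0.5 for the metabolite latents and 0.3 for the genus
latents — faecal SCFA pools swing more between birds than log genus
abundances do.

**Embedding.** Genus counts: a baseline log-abundance spectrum is drawn
once per study from N(0, 1.5²) (a few dominant genera, a long rare tail);
the four planted genera are pinned at baseline log-abundance 2.0, making
them dominant community members (several percent each), as the genus
panels such studies report.  Per-taxon farm intercepts ~ N(0, 0.3²) are
added on the log scale, the Rmb/Trc latents are added to their mapped
genera with an embedding gain of 2 (one latent unit ≈ 2 CLR units, i.e. a
severalfold abundance change), and two further genera receive direct
treatment effects of +2.0 (a Lactobacillus analogue) and −2.0 (an
Escherichia–Shigella analogue) CLR units.  The log-composition is closed,
perturbed by a Dirichlet draw with concentration 200 (mild realistic
overdispersion) and sampled by a multinomial at a Poisson(20 000) depth,
so count rows sum to their depths exactly.  Metabolites: eight compounds
with lognormal concentrations; the Ace/Bty latents shift the log-means of
acetate and butyrate, the rest are null.

**Design defaults.** 5 HS-Comp, 2 HS-CON and 3 Ref farms, 12 samples per
farm split evenly between a pre and a post phase; Ref-arm post samples
receive the treatment effect attenuated to 0.25 (short exposure).  Farm
counts follow the contrastable-arm layout of the emulated trial; 12
faecal samples per house is ordinary practice for 16S panels.  At these
settings the planted genera are detectable by the DID screen — the point
of the emulation, since the studies being modelled do detect their
targets — while ~56 null genera calibrate its error rates.

**What passing tests show.** The generator produces farm-clustered,
compositional, overdispersed, non-Gaussian data with known truth; it does
not model read-level artefacts, chimeras, taxonomic misassignment,
seasonal drift within a phase, or genus-genus ecological interactions
beyond the planted DAG.  Recovery results certify the estimators under
the stated generative assumptions, not performance on any particular real
dataset.

## Preprocessing

CLR uses a pseudocount of 0.5 added to counts before closure (simplest
auditable zero handling; configurable), the metabolite log transform an
offset of 0.5.  Natural logarithms are used internally everywhere; base 2
appears only in DID reporting.  Median binarization maps ties at the
median to 1 (the "< M → 0, > M → 1" rule leaves = M undefined; a
deterministic completion is required and is recorded with the threshold).
Simpson diversity is reported as Gini–Simpson (1 − Σp²).  Shapiro–Wilk
(default) or Jarque–Bera flags non-Gaussian features at α = 0.05; the
pipeline records the flag and uses robust SEM statistics throughout.

## DID inference

The DID effect is the arm × phase interaction of an ordinary linear model
on CLR/log values with farm fixed effects — a transparent reading of the
difference-in-differences label, not a reproduction of any count-model
package.  Treatment is assigned at the farm level, so the permutation
test permutes the farm→arm map, enumerating all C(farms, treated)
assignments when that is below `n_perm` (21 assignments at the default
5+2 layout) and sampling with the add-one rule (b+1)/(B+1) otherwise.
Because 21 assignments quantise the permutation p at 0.048, the
significance flag and the BH-FDR run on the parametric interaction p —
the single-p rule "(p < 0.05; FDR < 0.1)" — while the permutation p is
reported per feature as a clustering-robustness check.  Its type-I rate
is calibration-tested at the default layout.

## Feature selection

Apriori mining runs level-wise on the binarized dataset with complement
("low") items added, so depletion under treatment can form antecedents;
rules with the treatment item as consequent are ranked by lift, then
confidence, then support.  Defaults: min support 0.2, min confidence 0.6,
itemsets up to 3 items, 20 candidates.  When rules are sparse the
candidate slate is padded by marginal |AUC − 0.5| rank.  Supervised
scoring uses 1000 bagged trees (Gini importance) and 100 boosting rounds
at depth 3, learning rate 0.3 (gain importance), both seeded; AUC uses
the Mann–Whitney mid-rank identity with the treated class as positive,
and ranks |AUC − 0.5| so depleted features score.  The consensus rank is
the mean of the three per-method ordinal ranks (lexicographic
tie-breaks, recorded); top-8 advance.  No intersection rule is claimed —
rank-averaging with k = 8 is this package's explicit choice.

## EFA

Minres minimises the summed squared off-diagonal residuals of R − ΛΛᵀ
over uniquenesses bounded in (0.005, 1) via L-BFGS-B from 1 − SMC starts;
loadings come from the eigen-decomposition of the reduced matrix, with
the largest-|loading| entry of each column made positive.  Promax follows
Hendrickson–White: Kaiser-normalised varimax, element-wise power-κ target
(κ = 4), least-squares oblique transform; κ = 1 reproduces varimax.  The
rotation is chosen automatically — promax when any off-diagonal Spearman
|ρ| among the components exceeds 0.4, varimax otherwise — and can be
overridden.  h2 = diag(ΛΦΛᵀ) after oblique rotation, u2 = 1 − h2,
com = (Σλ²)²/Σλ⁴.

VSS simplifies the (varimax-rotated) loadings to the c = 1 largest entry
per row and scores 1 − SS(residual)/SS(off-diagonal R).  Selection uses a
plateau rule: the smallest k that no larger candidate beats by more than
0.2.  Surplus factors always absorb a little sampling noise, so the raw
curve drifts upward and its argmax overfactors; the tolerance sits
between the gain genuine factors contribute (≥ 0.45 in the validation
conditions) and what noise absorption yields (median 0.08).

## SEM

Path models are observed-variable only: Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ, B
acyclic, Ψ diagonal plus declared residual covariances.  The binary
treatment enters as an exogenous variable with its variance fixed at the
sample value (not estimated), the standard treatment-dummy convention.
F_ML is minimised by BFGS with an analytic gradient from per-equation OLS
starts — for recursive diagonal-Ψ models the start is already the exact
solution — with a Nelder–Mead polish only if the gradient norm indicates
a genuine stall.  T = (n−1)·F_ML with S computed at ddof = 1.

The robust correction is a mean-scaled Satorra–Bentler-type statistic:
c = tr(UΓ)/df with U the normal-theory residual weight and Γ the
fourth-order moment (ADF) matrix of vech(S); T_sc = T/c feeds the χ² p
and the robust CFI/TLI.  Exact replication of any one package's "MLR"
variant is not attempted; on Gaussian data, where variants coincide, c is
calibration-tested to lie near 1.  Analytic SEs come from the expected
information (ΔᵀWΔ)⁻¹/(n−1); standardized residuals divide s − σ̂ by their
normal-theory asymptotic SDs and are reported as a matrix.  The
independence model (free variances, zero covariances) is the baseline.

Model selection: stage 1 filters on χ² p_sc > 0.05, robust CFI and
TLI > 0.95, RMSEA < 0.07, SRMR < 0.08, GFI > 0.95, AGFI > 0.95 and
max|SR| < 2.58; stage 2 shortlists models whose GFI−AGFI gap is within
0.01 of the smallest gap among the passers ("little difference between
GFI and AGFI" read as a soft filter, since exact gap ties are measure
zero); stage 3 takes minimal AIC.  An empty stage-1 set returns no
selection with full per-model diagnostics — a legitimate outcome: at the
default study size (n = 84 analysis samples, p = 5) AGFI > 0.95 is a hard
bar, and some study draws clear it while others do not.  Orientation
ties are real too: candidates sharing a skeleton and v-structures are
Markov-equivalent and fit identically; the ledger cannot and does not
pretend to distinguish them — that is what the LiNGAM stage is for.
Bootstrap SEs are case-resampling percentile bootstraps (default 1000
draws); non-converged replicates are dropped and counted, with an error
above 20%.

## Causal inference

Mediation fits mediator ~ treatment and outcome ~ treatment + mediator by
least squares (no treatment × mediator interaction by default), giving
ACME = a·b, ADE = c′ and the exact linear identity ACME + ADE = total;
CIs are case-resampling percentile bootstraps (default 1000 draws).

DirectLiNGAM selects the most exogenous variable by the pairwise
likelihood-ratio measure built from the maximum-entropy negentropy
approximation with the published constants k₁ = 79.047, k₂ = 7.4129,
γ = 0.37457, regresses it out, and recurses; B is then estimated by OLS
in the causal order and pruned where the per-coefficient t-test p ≥ 0.05
(deterministic and dependency-light; an adaptive-lasso variant is left as
a flag for future work).

The Bayesian scorer enumerates every labeled DAG on ≤ 4 variables
(counts 1, 3, 25, 543 for 1–4 nodes, verified against a brute-force
acyclicity filter), models each variable as linear in its parents with a
two-component Gaussian-mixture error, and Laplace-approximates the
marginal likelihood around the posterior mode (three deterministic
starts; family scores cached by (child, parent-set)).  Priors:
coefficients N(0, 1) on standardized data, component means N(0, 1),
log-variances N(0, 2²), mixture weight flat.  Free component means are
essential: a zero-mean scale mixture is always super-Gaussian and cannot
represent uniform (sub-Gaussian) errors, which empirically reverses
inferred directions.  The posterior is uniform-prior normalised and
invariant to affine rescaling of any column.  When the treatment is
omitted from the scored subset it acts as a hidden confounder, so the
posterior concentrates on denser DAGs than the generating graph; the
reported quantity of interest is the presence and direction of the
component-component edges and the cumulative top-6 mass.

## Pipeline and reproducibility

Stages communicate only via files; each stage's seed is
CRC32-mixed from (global seed, stage name); numeric text output is pinned
to 12 significant digits; re-running with identical config and seed is
byte-identical (tested by hashing).  The analysis chain past the DID
screen uses the HS-Comp and HS-CON arms with the binary item
`Compost_ex` = 1 for treated-arm post samples; the Ref arm appears only
in its own DID contrast.  The SEM/mediation/LiNGAM stages run on the
treatment plus the top-4 consensus components.  Validation problem sizes
(100-replicate recovery runs at n = 600–2000 for the estimator suites;
one full study of 144 samples × 60 genera for the end-to-end chain) are
chosen so each estimator operates in the regime its asymptotics assume
while the whole suite stays comfortably interactive.

## Known limitations

- The DID estimator is linear on transformed values; no count-model
  (negative-binomial) screen is provided.
- The SEM is observed-variable path analysis; latent measurement models,
  ordinal estimators and missing-data likelihoods are out of scope.
- The Bayesian DAG scorer is capped at 4 variables by exhaustive
  enumeration; larger graphs need the DirectLiNGAM route.
- Mediation assumes linearity and no unmodelled confounding of the
  mediator-outcome relation; farm structure is not explicitly modelled in
  the mediation regressions.
- With only a handful of farms the farm-level permutation p is coarse by
  construction; it complements rather than replaces the parametric p.
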