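# Methods

## Model

The phenotype model for weekly average daily gain (ADG, g/d) of a
group-housed animal is a linear mixed model with five random terms and
no explicit residual:

    y_ilm(w_j) = mu(w_j) + DGE_i(w_j) + sum_{k in mates(i)} IGE_k(w_j)
                 + l_l(w_j) + g_m(w_j) + p_i(w_j)

* `DGE_i` — direct genetic effect of the animal on its own gain;
* `IGE_k` — indirect genetic effect of each of its cage mates on the
  focal animal's gain (with cages of 8, every record carries seven IGE
  contributions);
* `l_l`, `g_m` — litter and cage (group) environmental effects;
* `p_i` — a pseudo-permanent animal effect that also plays the role of
  the residual.  Omitting a separate residual removes the classical
  confounding between a structured within-animal covariance and an
  i.i.d. residual, at the price that `Sigma_p` absorbs measurement
  noise.

Each effect has a week-by-week covariance generated by a structured
antedependence (SAD) process on the grid `w_1..w_J` (default: week
indices 1..5): the current value is a regression on its `alpha`
predecessors plus an innovation, with the regression coefficients
`theta_s(w)` polynomials in time and the innovation variance
`exp(polynomial(w))`.  A model is named `SADa-b1..bA g` by its order,
coefficient degrees and log-variance degree.  The direct and indirect
genetic effects are correlated: the direct process additionally
regresses on the same-week indirect value through a polynomial
cross-antedependence coefficient `delta(w)`, and the stacked pair is
`N(0, A ⊗ Sigma_GE)` over the pedigree (A = additive relationship
matrix, Meuwissen–Luo inbreeding accounted for in its sparse inverse).
The implied covariance of any effect is `Sigma = (L' D^-1 L)^-1`,
where `L` is unit lower triangular holding the negated antedependence
coefficients (for the genetic pair, a 2J×2J system ordered so the
same-week cross reference stays lower triangular) and `D` is the
diagonal of innovation variances.  At the start of the grid the
recursion is truncated to the available lags.

Time coding: polynomials are evaluated at raw week indices by default;
`TimeGrid` exposes an affine re-coding `(w - shift)/scale`.  The
fitting templates use `shift = 3` (centred weeks).  This spans exactly
the same model space — only the coefficient basis changes — but keeps
the constant and slope of each polynomial nearly orthogonal, which
conditions the REML surface markedly better.

## REML estimation

The restricted likelihood is evaluated through sparse mixed-model
equations in which the permanent effect serves as the GLS residual
(its covariance is block diagonal by animal, one block per observed
week pattern):

    -2 l_R = log|R| + log|G| + log|C| + y'Py + (n - p) log 2pi

This equals the dense-matrix expression `log|V| + log|X'V^-1X| + y'Py`
exactly; the test suite verifies the identity against an independent
dense implementation on small designs.  For the balanced nucleus
design used in the simulation studies (founder parents without
records, complete cages of equal size) a second, exact evaluation path
integrates out the offsprings' Mendelian sampling deviations (reduced
animal model).  The residual covariance then has one identical
`KJ × KJ` block per cage built from

    B_diag = Sigma_DD/2 + (K-1) Sigma_II/2 + Sigma_p + Sigma_g
    B_off  = (Sigma_DI + Sigma_DI')/2 + (K-2) Sigma_II/2 + Sigma_g

and the only genetic unknowns are the founders' trajectories, shrinking
the equations from ~11,700 to ~1,505 for the default design.  Both
paths agree to machine precision (tested).

Optimization: the coefficient vector (18 parameters for the full
SAD1-11 model with IGE) is maximized with L-BFGS-B.  The REML surface
exhibits long, curved, nearly-flat valleys — analyses of this design
report large information-matrix condition numbers and 21–52%
non-convergence rates — so the protocol is:

1. **Starting values.**  For the balanced nucleus design the default
   start is a method-of-moments pre-estimate: average outer products
   of weekly deviation vectors over six pair classes (self, cage mate
   of a different / the same family, out-of-cage full sib, out-of-cage
   paternal half sib, and non-family cage mates of out-of-cage sibs)
   form a full-rank linear system in the covariance blocks, because
   each class weights them with different expected-relatedness
   coefficients; the solved blocks are floored to positive
   definiteness and projected onto the SAD structure.  A purely
   data-driven start in the right basin removes the systematic
   drift (inflated edge-week direct variances, collapsing indirect
   variances) that generic starts exhibit on this surface.  For
   general designs a step-up ladder start is used instead: the
   constant terms of all polynomials are fitted first, holding the
   indirect/cross constants at their prior scale (the reduced model
   otherwise absorbs the small indirect variance into the group term
   and strands the full fit at that boundary).
2. **Restart-stabilized L-BFGS-B**: up to 4 cold restarts of 400
   evaluations; a fit is declared converged when a restart improves
   the likelihood by < 0.25 units.  Cold restarts rebuild the
   curvature memory, which empirically gains more per evaluation than
   a single long run in these valleys.
3. **Boundary flag**: solutions in which any innovation variance
   collapses below 1e-4 of the phenotypic variance are flagged
   `at_boundary`; simulation summaries exclude them together with
   non-converged fits.
4. Models with ≤ 8 parameters get a final Nelder–Mead polish past the
   finite-difference accuracy floor (used by the closed-form oracle
   tests and the likelihood-ratio null calibration).

The observed information is a central finite-difference Hessian of the
restricted likelihood (relative step 1e-4).  Identifiability
diagnostics report the condition number sqrt(λ_max/λ_min) and the
correlation matrix of the estimates from its inverse; |ρ| > 0.6 flags
pairs the data cannot separate.

The likelihood-ratio test uses twice the log-likelihood difference
with degrees of freedom equal to the literal difference in free
parameter counts; for SAD1-11 with a degree-1 cross term versus the
same model without IGE that difference is 6 (the indirect
antedependence, cross and indirect innovation polynomials).

## Quantitative-genetics summaries

For groups of `n` with mean additive relatedness `r` among cage mates
(default 0.16, or computed from the pedigree):

    sigma2_T   = sigma2_DGE + (n-1) sigma2_IGE
                 + (n-1) r [2 sigma_DGE,IGE + (n-2) sigma2_IGE]
                 + sigma2_l + sigma2_g + sigma2_p
    sigma2_TBV = sigma2_DGE + 2(n-1) sigma_DGE,IGE + (n-1)^2 sigma2_IGE

Direct heritability is `sigma2_DGE/sigma2_T`, indirect
`(n-1)^2 sigma2_IGE / sigma2_T`, total `sigma2_TBV / sigma2_T`;
indirect and total ratios can exceed 1 or go negative in pathological
samples and are reported unclamped.  Standard errors come from
multivariate-normal sampling of the coefficient estimates
(`omega ~ N(omega_hat, H)`, 10,000 draws by default), rebuilding every
covariance per draw and discarding draws with a non-PSD matrix
(smallest eigenvalue below −1e-8 × trace); the same draws give the
correlation matrix among (co)variance-component estimates.

## Simulation truth (bundled parameter values)

The original data are not public, and the exact simulation covariances
(supplementary material) are unavailable; the bundled values are
documented approximations.  Each default matrix is the covariance
implied by a SAD1-11 function whose coefficients were calibrated once,
by weighted least squares, to the published weekly profiles: direct
genetic variance ~8 → ~13 (week 3) → ~6 (g/d)², indirect ~0.43 → ~0.22
with a week-5 uptick, litter ~8.7 → ~4.2, group ~5.7 → ~16.4,
permanent ~23 → ~53, and the reported correlation patterns (direct
0.46–0.86 decaying with the interval; indirect week 1 decoupled from
weeks 2–5; all direct–indirect correlations negative).  Keeping the
truth on the SAD manifold mirrors how such simulation values are
produced in practice (from a fitted SAD model) and avoids estimation
artifacts caused by a strongly non-representable truth.  The weekly
means are 26.5, 37.5, 42.0, 40.1, 41.2 g/d.

The three antagonism levels divide the direct–indirect cross block by
1, 2 or 4 — a convex combination with the block-diagonal part, so
positive semi-definiteness is preserved by construction.

Known consequence: the calibrated within-week direct–indirect
correlations span −0.78…−0.46 against a published span of −0.89…−0.57
(which week is strongest is not published; week 1 was chosen).  The
product `(n-1) |r_DI| sigma_I / sigma_D` governing how much indirect
response cancels direct response is therefore slightly below 1, and
selection ignoring IGE retains a small positive response under strong
antagonism rather than none.

## Breeding simulation

Closed nucleus, discrete generations: 30 unrelated sires × 120
unrelated dams, four dams per sire, eight offspring per mating
(sexes exactly balanced within litter), giving cohorts of 960.  Cages
of eight are formed from four full-sib families contributing two kits
each (families chunked at random).  Phenotypes follow the model above
without the litter term.  True breeding values are drawn from the
unstructured bundled matrices: founders i.i.d.
`N(0, Sigma_GE)`, offspring = parent average + Mendelian deviation
`N(0, Sigma_GE/2)` (the 1/2 scalar is kept throughout; inbreeding of
later cohorts is not fed back into the Mendelian variance).

Variance components are estimated once on the 4,800 base-cohort
records — with IGE (scenarios 2 and 3) or without (scenario 1) — then
fixed for all EBV predictions.  Each generation, EBVs are predicted
from the current cohort's records with the complete pedigree (the
cumulative-records alternative gives the same qualitative responses at
about five times the cost and is available via
`SimulationConfig(evaluation_window="cumulative")`).  Selection keeps
the best male per sire family and the best 120 females (ties to the
lowest id) on the scenario's criterion — summed weekly direct EBVs
(1), week-1 total EBV (2), summed weekly total EBVs (3), with
TEBV = direct + (n−1) × indirect — and mates each male to four females
at random avoiding shared sire families.  Scenario comparisons within
a replicate share the base population and per-generation random draws
(common random numbers).

## Study sizes

Chosen for a single-CPU run: the test suite runs 3 replicates per
antagonism level for the parameter-recovery study, reusing the strong-
and moderate-antagonism fits for the selection study (7 generations,
scenarios 1–3); tolerance bands are 3 Monte-Carlo standard errors at
those counts, with dispersion estimated from the replicates.  The
acceptance script runs 3 recovery replicates (strong), 2 selection
replicates per level, and one synthetic-data fit of 30 cages.  Larger
studies are a matter of raising the replicate arguments.

## What the synthetic generator does and does not emulate

The generator reproduces the design's statistical skeleton: full-sib
litters (half-sib ties through shared sires), cages mixing four
litters, five weekly records, cage-level attrition calibrated to the
published decline of record counts (whole cages leave the experiment
from a week onward; optional per-animal dropout behind a flag), and
all random effects drawn from their model distributions with
pedigree-recursive genetic sampling (cost linear in animals).  It does
not emulate: growth-curve dynamics (week means are fixed constants),
feed-intake mechanisms, batch/parity/body-size fixed effects of the
real husbandry, selection history in the founder population, or
non-normal tails.  Passing tests therefore demonstrate correctness of
the estimation machinery under the model's own assumptions, not
robustness to the ways real data violate them.

## Numerical choices and limitations

* PSD tolerance for sampling filters: smallest eigenvalue ≥ −1e-8 ×
  trace.  Innovation variances are hard-bounded away from overflow
  (|log variance| ≤ 300).
* `(L'D^-1L)^-1` is symmetrized after inversion to remove round-off
  asymmetry.
* Ties anywhere in selection/sorting break by lowest animal id.
* The REML surface for the full model is genuinely weakly identified
  in the indirect-effect directions (small variance amplified by
  (n−1)² in the phenotype); estimates of `sigma2_IGE` carry large
  sampling variance and some replicates end at the parameter boundary.
  This is a property of the design, not of the implementation, and is
  the reason for the convergence protocol above.
* The general sparse path handles arbitrary unbalanced designs but at
  ~0.1–0.3 s per likelihood evaluation for thousands of animals;
  the fast nucleus path is restricted to the balanced base-cohort
  layout.
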