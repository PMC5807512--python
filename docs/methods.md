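# Methods

This note records the models, the numerical choices and the limits of
what the synthetic cohorts can and cannot demonstrate.

## Current-status models of dissemination and colonisation

Each patient contributes one observation: tumour thickness `t` at
sentinel-node biopsy and a binary status (dissemination: any gp100⁺ cell
in the node; colonisation: DCCD > 100 per 10⁶ node cells). If the event
has occurred, the thickness at the event lies in `[0, t]`; otherwise in
`(t, ∞)` — current-status censoring with thickness as the time-like axis.

**Nonparametric estimate.** `turnbull_npmle` runs the self-consistency
(EM) iteration on the innermost censoring intervals. For current-status
data these intervals are delimited by a left endpoint (0 or an
event-free observation) immediately followed by a right endpoint (an
event observation or ∞). Convergence: maximum absolute mass change
below 1e-9 (default), masses below 1e-12 pruned, log-likelihood checked
non-decreasing at every step. The estimator equals the isotonic
(pool-adjacent-violators) regression of the event indicators on
thickness at the observation points; the test suite verifies that
equivalence against `sklearn`'s isotonic regression on random datasets,
at 1e-4, reflecting the EM's sublinear tail convergence.

**Parametric families.** `P(t) = π·F0(t)` with asymptote (cure
parameter) `π ∈ (0, 1]`: the maximum proportion of patients that ever
experience the event. Families and their base parameters:

| family            | F0(t)                   | base params |
|-------------------|--------------------------|-------------|
| std_log_logistic  | t/(t+θ)                  | θ (median)  |
| exponential       | 1−exp(−t/θ)              | θ (scale; median θ·ln 2) |
| weibull           | 1−exp(−(t/θ)^k)          | θ, k        |
| log_normal        | Φ((ln t − µ)/σ)          | µ, σ        |
| frechet           | exp(−(t/θ)^−k)           | θ, k        |

The "standard" log-logistic fixes the shape at 1; its quantiles obey
`t_q = θ·q/(1−q)`, which is why a colonisation TD50 of 13.4 mm forces
TD15 = 13.4·0.15/0.85 ≈ 2.4 mm. Dissemination fits carry a free π;
colonisation fits fix π = 1 (every DCC-positive node can in principle
colonise), so the exponential colonisation model has a single parameter.

**Optimisation.** Gradient-free Nelder–Mead on transformed parameters
(logit π, log scales/shapes; µ untransformed), eight deterministic
starts built from data quantiles and a grid of shapes and event rates,
tolerances 1e-9. Cure likelihoods are flat when few thick tumours pin
the plateau; multi-start plus the transform keeps the optimiser off the
boundary, and optima with π within 1e-4 of 0/1 or scales far outside
the data range are flagged (`boundary`), not silently returned.

**Model selection and fit.** `BIC = −2·loglik + n_params·ln(n_obs)`,
ascending, ties broken by fewer parameters; families that fail to fit
are reported with the error. Goodness of fit groups observations into
thickness quantile classes (deciles for dissemination, quintiles for
colonisation in the headline analyses), compares observed event counts
with `Σ P(t_i)` per group by χ², with `df = k − 1 − n_params` floored
at 1 — the df convention is this package's choice; only "number of
categories and number of estimated parameters are taken into account"
is externally fixed.

**Confidence intervals.** Parametric bootstrap (percentile, B = 500
default): event indicators redrawn as Bernoulli(P(t_i)) at the observed
thicknesses, refit, per-parameter and per-quantile intervals. Chosen
because it stays valid when π sits near a boundary, where Wald
asymptotics do not.

## Synthetic cohorts

The generator's defaults are the study conditions; every stochastic
element hangs off a hierarchical per-patient stream
(`SeedSequence(seed, spawn_key=(patient,))`), so outputs are
bit-reproducible and individual patients keep their draws when the
cohort grows.

* **Thickness law** (`t_stage`, default): the published cohort's
  thickness distribution is unpublished, but its stage composition is
  printed (T1 ≤1 mm: 83, T2 1–2 mm: 496, T3 2–4 mm: 315, T4 >4 mm: 133
  of 1027). The default law draws the stage from those frequencies and
  the thickness within the stage bin from a truncated log-normal whose
  (µ, σ) ≈ (0.685, 0.553 log-mm) are ML-fitted to the same bin counts.
  A plain log-normal is available (`thickness_law="log_normal"`).
* **Dissemination**: event with probability `π·t/(t+θ_d)` (defaults
  π = 0.652, θ_d = 0.5 mm). For disseminated patients the dissemination
  thickness `t_L` is drawn from the same law truncated to `[0, t]`.
* **DCCD**: the node colony grows exponentially from one cell over the
  divisions elapsed between `t_L` and `t`:
  `log2 DCCD = ĝ·(N_T(t) − N_T(t_L))·s + ε`, capped at 10⁶ cells and
  floored at 1. The scale `s` is solved in closed form so that the
  *median* colony at the colonisation TD50 (10.3 mm) holds exactly 100
  cells — colonisation (DCCD > 100) reaches 50% at TD50 without
  modelling node cellularity. The dispersion ε ~ N(0, 3² log2-units),
  about one order of magnitude in colony size, reflects that the
  division ↔ DCCD mapping is qualitative (dormancy, growth-rate
  variability, disaggregation and counting noise); its zero median
  leaves the TD50 calibration untouched. The resulting full-cohort
  Spearman correlation between thickness and DCCD is ≈ 0.13–0.15,
  close to the weak published association.
* **Aberrations**: each locus carries a risk category with coefficients
  (a, b) — (1,0), (1,1), (1,2), (0,1) for categories 1–4 — and a rate
  κ; a DCC acquires the aberration with probability `1 − exp(−κ·E)`,
  `E = a·n_T + b·n_L`, where `n_L = log2 DCCD` (colony doublings) and
  `n_T = N_T − ĝ·n_L` (divisions in the primary before dissemination,
  via the growth identity). PT clones use `n_L = 0` with `n_T = N_T(t)`
  (primary cells divide until surgery). Signs are fixed per locus
  (single-sign state space); mutation pseudo-loci (BRAF/NRAS) use
  {0, 1}. Default κ values put aberration frequencies in the 10–60%
  range, with losses rarer than gains.
* **Bulk CGH**: a clone mixture is observed per locus through the mean
  allele frequency `m = Σ fraction·(2+state)`; I1 if m ≤ 1.4, I3 if
  m ≥ 2.6, else I2 — the 60%-detection behaviour of metaphase CGH.
* **Single cells**: each present allele is detected with probability
  1 − drop rate (defaults: wild type 0.08, mutant 0).

**What the generator does not emulate**: genome coordinates or CGH
ratio tracks; co-occurrence structure between loci (draws are
independent given the division counts); clonal nesting of PT clones
(clones are drawn independently and mixed with Dirichlet fractions);
inter-patient heterogeneity in growth rates beyond the DCCD dispersion.
Passing tests therefore demonstrate that the *pipeline* recovers the
generative structure, not that real cohorts satisfy these assumptions.

**`prototype_plane_cohort`** is a separate preset for classifier
round-trip tests: thickness log-uniform over the experimental range
(0.6–10 mm) and node divisions uniform over half the span of `N_T` —
the regime in which the half-axis DCCD correction (below) maps the
theoretical prototype angles exactly.

## Parsimony phylogenies

Observed profiles are vectors over {−1, 0, +1}. Candidate ancestors are
the "meets" of every sample subset: a locus is aberrant in the ancestor
exactly when all subset members agree on its sign (opposing signs meet
at 0 — the only state consistent with shared features). Edges descend
from the all-zero root; per locus, 0 may change freely, +1 may persist
or revert to 0 (a reloss), −1 may never revert. Globally, a relost gain
may not be regained along any path, and each gained locus may be relost
at most twice across the whole graph — branch-wise losses; within one
path a second reloss is impossible anyway since regains are forbidden.

Assembly enumerates, per sample, all simple valid root-to-sample paths
through the candidate ancestors and selects one path per sample
minimising first the total number of state changes along the union of
edges, then the number of intermediates used. Co-optima are enumerated;
the lexicographically first (by sorted vertex profiles) is returned and
a `unique` flag reports whether the optimum was unique. The brute-force
oracle searches every intermediate subset of the restricted lattice
(per-locus states limited to those observed or balanced — an aberration
absent from every sample can only add changes) up to one fewer
intermediates than samples (an optimal intermediate has out-degree ≥ 2,
else it can be contracted), with an early stop once the lower bound —
one change per distinct observed (locus, state) aberration — is
attained. Equality of both routes is asserted on 200 random instances.

Enumeration limits (8 samples, 60 loci, 20 000 paths per sample) raise
a resource error advising locus pre-filtering rather than degrading
silently.

## Subclone exclusion

Per locus the bulk PT measurement confines the composite mean allele
frequency `(1−Σf)·C + Σ f_k·D_k` to its interval; the unmeasured
non-DCC clone frequency `C ∈ [1,3]` is eliminated analytically, turning
each locus into the linear pair `(1−S) + Σf_k D_k ≤ hi` and
`3(1−S) + Σf_k D_k ≥ lo`. Maximising `Σ log f_k` over this polytope is
concave; it is solved with SLSQP (closed form for a single DCC, a 1e-3
grid fallback for pairs), and feasibility is re-checked at 1e-9 slack.
The open interval I2 is closed by ε = 1e-9. With several PT samples all
`T^D` DCC-to-PT assignments are tried and the maximum-product assignment
kept. The fold adjustment `p = d·f/(1+(d−1)Σf)` sums over the same
patient's fractions (the grouping convention is documented and
switchable by passing per-patient vectors).

The exclusion bound uses the exact Poisson-binomial law of the origin
indicators, computed by sequential convolution and cross-checked against
the class-partition sum over per-class binomials; `n*` is the smallest
`n` with `P(X ≥ n) ≤ α` and the reported bound is `n* − 1`. For the
published class fractions (5×0.1, 9×0.2, 10×0.4) at α = 0.05 the exact
tails give `P(X ≥ 10) = 0.065` and `P(X ≥ 11) = 0.025`, hence `n* = 11`
and a bound of 10 — one less than the figure in the original analysis,
whose tail convention is not stated; the package pins its own
oracle-computed value.

## The thickness × DCCD risk plane

`N_T = log2((t/d)³·φ)` with cell diameter d = 18 µm and packing
fraction φ = 0.6, so a 0.6 mm sphere holds ≈ 2.2·10⁴ cells (14.4
doublings) and 10 mm ≈ 10⁸ (26.6). Sub-single-cell thicknesses warn and
clamp to 0.

Classifier scans work in min–max-scaled natural-log coordinates (the
scaling absorbs the log base — verified bit-for-bit). Each experimental
(DCCD, thickness) pair spawns four set points displaced by ±δ/2 per
axis, δ the minimal gap between distinct scaled values, so no sample
ever lies on a boundary; angles are scanned in 1° steps and samples
split by the sign of `(sample − set point)·(cos φ, sin φ)`. Identical
splits are deduplicated before testing; each split is tested per locus
(2×2 or 2×3 Fisher, weighted variant when sample weights are supplied)
and BH-adjusted across loci per classifier — adjusting per classifier
and reporting the per-locus minimum is one of two defensible orders;
pooling displacements before adjustment is the other, and the choice is
confined to one function. Best-angle summaries admit only classifiers
with at least 10 samples per class. Ties at the minimum FDR (relative
tolerance 1e-9) are collapsed to the medoid of the tied corrected
angles, with the tied range reported.

Corrected angles rescale the log(DCCD) axis by 1/2 (normal x-component
doubled, renormalised) and map angles ≥ 157.5° to negatives by
subtracting 180°; 157.5° is the midpoint between the 135° prototype and
180°, the transform itself being externally fixed but its cutoff not.

**Attainable and unattainable recovery.** Two per-seed precision checks
in the acceptance suite fail by design of the problem, not of the code:

1. At n = 1027 with the printed stage composition, the Fisher
   information of the cure fit bounds SE(π̂) at ≈ 0.05 — the T4 cell
   alone contributes a binomial floor of ≈ 0.04 — so per-seed estimates
   cannot sit inside intervals implying SE ≈ 0.024 in 90% of seeds.
   What holds, and is asserted: the colonisation median satisfies the
   per-seed check, and all three quantities are recovered without bias
   when averaged over seeds (the quantity the acceptance script
   reports).
2. The concave aberration law `1 − exp(−κE)` has its steepest change at
   E = 0, while the diagonal (category-1) risk index satisfies
   E_min/E_median ≈ 0.2–0.5 in any geometry respecting the 0.6–10 mm
   range; the achievable class contrast (≈ 0.29–0.66 aberration rate
   across the plane) is too weak for the best-angle statistic — or even
   a logistic-regression boundary estimate — to concentrate within ±15°
   at n = 87. The vertical category-4 prototype (0°) is recovered in
   ≥ 80% of seeds, and category-1 best angles concentrate in the
   ascending quadrant (±45°), which is asserted instead alongside the
   strict check.

## Sample weights

Multiple samples per patient are down-weighted. The patient-weight
model `w = 1/n_i` is the conservative end; locus-specific weights follow
the one-parameter family `w(γ) = (1−γ)/n_i + γ` and γ is pushed, by
bisection to 1e-3, to the largest value at which the weighted
gain/balance/loss distribution remains equivalent to the γ = 0
distribution — interpolated-Fisher p ≥ 0.95 — both globally and within
every k = 5 nearest-patient neighbourhood (Euclidean distance between
patient centroids in the scaled plane; the metric is this package's
choice). The one-parameter family is itself a design choice: it spans
exactly the admissible range and makes the maximisation deterministic;
per-sample free weights would need an objective the problem statement
does not supply. p(γ) is not guaranteed monotone; bisection returns the
largest feasible point of its trace. Formal equivalence testing (TOST)
is deliberately not used — no established variant covers exact tests on
2×3 tables.

The non-integer Fisher test interpolates: with r fractional entries,
the simplex rooted at the entry-wise rounded table and directed toward
the observed table has r+1 integer vertices; the p value is the affine
combination of their exact p values with the fractional offsets as
coordinates. It is exactly the enumeration test on integer tables and
piecewise-linear in each entry.

## Problem sizes and determinism

Default test and acceptance runs use: 200 random datasets (≤ 50 points)
for the NPMLE/PAVA equivalence; 200 random instances (≤ 4 samples × ≤ 5
loci) for the parsimony oracle; 25–50 seeds for recovery studies at the
study sample sizes (n = 1027 / 525 / 87); 10⁴ random tables for the
Fisher equivalence. All randomness flows from explicit seeds; rerunning
any entry point with the same seed reproduces every output byte for
byte.
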