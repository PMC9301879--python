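# Methods

## Task geometry and response coding

Four speaker/LED positions sit at −15°, −5°, +5°, +15° azimuth; responses
are one of 12 buttons spanning the same width as the speaker array. The
physical button-to-degree mapping is not uniquely determined by the
apparatus description, so the package adopts one consistent convention:
12 uniformly spaced button centers at (i − 6.5) · (10/3)°, i = 1..12. This
puts buttons 2, 5, 8 and 11 exactly on the four speakers, leaves one
flanking button beyond each outer speaker, and makes one response unit equal
10/3°. Continuous model estimates are binned with half-open intervals
[center − spacing/2, center + spacing/2) — an exact edge belongs to the
right-hand button — and the outer buttons absorb everything beyond the
array. All model arithmetic is in degrees; button space appears only at the
final binning step and in the behavioral error coding.

## Trial sequences

Block 1: 160 audiovisual trials covering each of the 16 location pairs 10
times (discrepancies ±30°: 10 each, ±20°: 20 each, ±10°: 30 each, 0°: 40),
plus 40 auditory and 40 visual trials (10 per location), under two ordering
constraints: each unimodal trial's nearest preceding audiovisual trial
(skipping interjacent unimodal trials) has discrepancy in
{−20°, −10°, 0°, +10°, +20°}, exactly 8 trials per modality per category;
and no unimodal trial directly follows a ±30° audiovisual trial. Generation
is constructive rather than rejection-based: the audiovisual trials are
shuffled to form a backbone, and the unimodal trials are placed into the
gaps after eligible audiovisual trials so the quota holds by construction
(a retry budget guards internal validation, which has never failed in
practice). Block 2 is a plain shuffle: 160 audiovisual trials from the three
+10°-discrepancy pairs (53/54/53) plus 40+40 unimodal trials. Both
generators are pure functions of their seed. Inter-trial timing is not
modelled; response order (A-first/V-first) is carried as metadata and
ignored by every analysis, mirroring its counterbalancing-only role.

## Observer models

Seven families share the same front end: internal samples
x_A ~ N(s_A + Δ_A, σ_A), x_V ~ N(s_V + Δ_V, σ_V), a Gaussian location prior
N(μ_P, σ_P) shared across modalities, and a causal prior Pc. The joint
sample likelihoods under a common cause and under independent causes have
Gaussian closed forms (verified against trapezoid quadrature of the defining
integrals to ~1e-14 relative error); Bayes' rule on these with Pc gives the
per-trial causal posterior. Fused estimates precision-weight both samples
and the prior mean; segregated estimates shrink each sample toward the prior
alone. The decision stage distinguishes the CI families:

* CI-MA averages the fused and segregated estimates with posterior weights;
* CI-PM picks the fused branch when the posterior exceeds a uniform draw ξ,
  with **one ξ shared by the A and V responses of a trial**, so the selected
  causal structure is consistent within a trial (the two per-modality
  selection rules reference the same draw; the shared reading is the design
  choice adopted here);
* CI-MS picks the fused branch when the posterior exceeds 0.5.

Posteriors exactly at the threshold resolve to segregation in both PM and
MS, following the "≤" direction of the printed selection rules. FF/SG fix
the causal structure (fusion/segregation with the prior); FFnp/SGnp drop the
prior, reducing to reliability-weighted averaging and identity reporting.
No motor or response noise is added beyond binning: the continuous estimate
is binned directly.

Predicted response distributions are Monte-Carlo: 10,000 simulated trials
per stimulus pair by default, binned into two 12-bin proportion histograms
(A and V). The simulation seed is part of every call's contract.

## Fitting conventions

**Step 1.** (Δ_m, σ_m) per modality and block by discretized-Gaussian MLE:
a response's probability is the Normal(s + Δ, σ) mass on its button's
interval, outer buttons integrating to ±∞, errors pooled across the four
stimulus locations. A coarse grid (41 bias × 25 log-spaced SD values) seeds
an L-BFGS-B polish; bounds Δ ∈ [−20, 20]°, σ ∈ [0.25, 30]°. Degenerate data
(all errors identical) return the common error and the σ lower bound with a
warning flag. Note a deliberate asymmetry inherited from the procedure being
replicated: Step 1 fits unimodal responses as unshrunk Gaussians even though
the prior-aware observers predict prior-shrunk unimodal responses.

**Step 2.** With Step-1 likelihoods fixed, the free prior parameters (CI:
Pc, μ_P, σ_P; FF/SG: μ_P, σ_P; FFnp/SGnp: none) are fitted to the Block 1
audiovisual trials by maximizing Σ_i n_i ln p_i over all pairs and both
modalities, with p_i the Monte-Carlo predicted proportions; the multinomial
coefficient is a model-independent constant and is dropped. Monte-Carlo
zeros are floored at 1/(2·n_sim) without renormalization. Bounds (the
printed procedure does not state them): μ_P ∈ [−20, 20]°, σ_P ∈ [1, 60]°,
Pc ∈ [0, 1], each divided into 10 even portions (11 grid values; 1,331
candidates for CI models, 121 for FF/SG). The best grid point seeds a
bounded L-BFGS-B refinement. The objective is made deterministic by common
random numbers: one simulation seed per fit fixes the sensory noise and the
ξ draws for every parameter evaluation — the draws do not depend on the free
parameters, so the same noise realization underlies every candidate. The
objective is still piecewise constant through the binning, so the gradient
search often terminates immediately at the grid optimum; any refinement that
does not fall below the grid optimum is accepted.

**BIC.** BIC = −2·LL + k·ln N with k the number of prior parameters fitted
in Step 2 (CI: 3, FF/SG: 2, FFnp/SGnp: 0) — the Step-1 likelihood
parameters are shared by all families and cancel in comparisons — and N the
number of localization responses entering the likelihood (Block 1: 160
trials × 2 = 320). Both conventions are recorded in the fit result. Ties go
to the model with fewer parameters, then to a fixed family order. BIC
differences are categorized 0–2 weak, 2–6 positive, 6–10 strong, ≥10 very
strong.

**Step 3.** The per-participant Block 1 winner is refit to Block 2 with the
Block 2 likelihood parameters; no model comparison.

## Behavioral statistics

Responses (1..12) are baseline-coded: the mean response over the 10 Block 1
unimodal trials per modality and location is subtracted from every response
of both blocks; errors convert to degrees via the button spacing. VE and
VAEi are right-minus-left contrasts (on the trial's own discrepancy and on
the nearest preceding audiovisual discrepancy, respectively); 0°-discrepancy
trials are excluded from both contrasts since they are neither rightward nor
leftward, and trials pool with equal weight rather than weighting
discrepancy magnitudes. VAEc is the plain mean error over Block 2 unimodal
trials. Precision is the SD of Block 1 unimodal errors (location-centered,
pooled across locations). A consequence worth noting: reflecting all stimuli
and responses about 0° flips VAEc but leaves the VE/VAEi contrasts
invariant, because the discrepancy labels flip together with the errors.

Group comparisons use Welch's heteroscedastic ANOVA and Games-Howell
post-hoc tests (two-sided), one-tailed one-sample t-tests against zero with
Holm correction applied within each effect type (the six tests across two
modalities and three groups form one family; the family membership is a
configurable choice since the original correction family is not stated), and
Spearman rank correlations between effect pairs per modality, overall and
within group.

## Synthetic cohorts

The generator emulates the full two-block design with known ground truth.
Archetypes (defaults, all overridable): every group is a CI-PM observer with
σ_A = 6°, μ_P = 0, σ_P = 25°, Pc = 0.5; visual noise separates the groups
(σ_V = 2° SC, 2.5° DC, 3.5° CC); Block 2 plants the cumulative aftereffect
as likelihood-bias shifts, Δ_A +3° (SC, CC) or +2° (DC) and additionally
Δ_V −2° in CC only — the minimal parameter change consistent with treating
the recalibration as a shift of the sensory mapping, and the only
configuration in which the visual aftereffect is negative. Scale parameters
are jittered 15% (relative, Gaussian) across participants; response order is
counterbalanced within group; group sizes default to 11 CC / 10 DC / 10 SC.

A static ideal observer has no trial memory and therefore cannot produce an
immediate aftereffect. The generator adds an explicit trial-history term to
the unimodal response means — gain_m × d × decay^g degrees, with d the
nearest preceding audiovisual discrepancy and g the number of interjacent
unimodal trials (defaults gain_A = 0.15, gain_V = 0.05, decay = 1) — as a
deliberate extension beyond the static observer families, enabled by default
so that archetype cohorts show the complete VE/VAEi/VAEc pattern; setting
the gains to zero recovers the pure static observer. The recovery
experiments do exactly that.

What passing tests on these cohorts show: that the analysis chain recovers
effects and parameters that hold by construction under the model's own
assumptions. What they do not show: anything about deviations real data
exhibit — lapses, attention drift, motor errors, learning within block,
or recalibration dynamics richer than a constant history gain.

## Validation experiments and their conditions

* Quadrature cross-check: 100 random parameter/sample draws, trapezoid rule
  on [−200°, 200°] at 0.01° steps; observed relative error ~1e-14.
* Flat-prior limit at σ_P = 1e4: fused estimates agree with
  reliability-weighted averaging to <1e-3°.
* Pc recovery: CI-PM truth (Pc = 0.8, σ_A = 6°, σ_V = 2°, σ_P = 25°), 160
  audiovisual trials per replicate, 20 replicates at the reduced preset
  (n_sim = 2,000, 5 grid points/parameter); median |P̂c − Pc| ≈ 0.07.
* Model recovery: 20 replicates per generating family at the reduced
  preset. Generating parameters are fixed a priori: CI families at Pc = 0.5
  and σ_P = 25° (mid-range, so neither fixed-structure limit mimics them);
  FF/SG at σ_P = 8° (narrow enough for the prior to be identifiable against
  the no-prior twins). Recovery is scored as causal-structure recovery: CI
  strategies must match exactly, while fusion (segregation) generators are
  also recovered by a CI winner whose fitted Pc is ≥ 0.9 (≤ 0.1) — the
  Pc-limit equivalences — or by their priored/no-prior twin. Reduced-preset
  sizes keep the full experiment within a few minutes; rates are 0.8–1.0
  per family.

## Known limitations

* The multinomial objective is a step function of the parameters; gradient
  refinement mostly polishes the grid optimum, so parameter resolution is
  bounded by the grid unless n_sim is raised.
* μ_P is weakly identified when σ_P is large (its likelihood contribution
  scales with σ_P⁻²); fitted μ_P values should not be over-interpreted.
* With 320 responses, two extra free parameters can occasionally win a BIC
  comparison against their own restriction by fitting multinomial noise
  (seen as FF beating FFnp on FFnp-generated data in a minority of
  replicates); the structure-level scoring above is robust to this.
* Δ_A, Δ_V, σ_A, σ_V are never fitted jointly with the prior parameters on
  audiovisual data, and no hierarchical (group-level) fitting or
  cross-validation-based comparison is provided.
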