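# Methods

## Problem and scope

`lumbarcpr` implements the derivation stage of a clinical prediction rule
(CPR) for treatment success after a lumbar stabilization exercise program.
The input is a baseline cohort — demographics, candidate clinical tests and
questionnaire scores — together with disability outcomes (Oswestry
Disability Index, ODI) at the end of treatment (week 8, "T8") and at
six-month follow-up (week 34, "T34").  The output is a small set of
dichotomous clinical tests combined by counting positives, with the
diagnostic performance and post-test probability of success at every count
threshold.  Validation and impact stages of CPR development, instrument
scoring, and sample-size planning are out of scope.

## Response classification

Response is judged on ODI only.  With ΔODI = ODI_T0 − ODI_Tx and
ΔODI% = ΔODI/ODI_T0 × 100:

* **success**: ΔODI% ≥ 50;
* **clinically significant improvement**: ΔODI% < 50 but ΔODI ≥ 10 points
  (the conventional minimal clinically important difference, treated as a
  fixed constant);
* **failure**: otherwise.

Both boundaries are inclusive exactly as written (Δ% = 50 is a success).
The improvement class is excluded from every success-vs-failure contrast
(screening, modeling, rule 2×2 tables) but is included in the Bayes prior
by default (see below).  Pre-to-post effect sizes are Cohen's d with the
pooled pre/post standard deviation, d = (M_post − M_pre)/√((SD_pre² +
SD_post²)/2); this is the only variant that reproduces all four published
whole-sample values (−1.24, −1.70, −1.24, −1.32) from the printed means and
SDs, which we verified numerically before freezing it.  (The source's
discussion section quotes slightly different values, −1.20/−1.30; the
tables and results section are taken as authoritative.)

## Cut-point selection

Candidate thresholds are midpoints between consecutive distinct observed
values plus ±∞ sentinels, so results depend only on ranks and any
printable threshold is representable.  Six criteria are computed per
variable (seven selections — the Kullback–Leibler divergence is directional):
closest-to-(1,1) on the ROC curve, pooled median, maximum Youden J,
minimum |Se − Sp|, maximum LR+ (requiring ≥ 1 false positive so the ratio
is finite), and maximal D(f‖g) / D(g‖f) between the Bernoulli
test-positive distributions of the success and failure groups, with
0·ln 0 = 0 and infinite divergences inadmissible.  Ties break toward the
larger Youden J, then the smaller cut.  When LRmax/KL have no admissible
cut the Youden optimum is returned with a fallback flag.  Which criterion
supplies the working threshold is a reported choice (`DerivationConfig.cut_method`,
default Youden), never an inference: the audit table always carries all
criteria, mirroring the fact that the original analysis chose thresholds
by joint clinical judgment that software should not fake.

When a variable's direction hint is unknown (including binary tests), both
orientations are scanned and the one whose optimum points toward success
(LR+ > 1, Youden J as arbiter) is used — this is what allows a "test
negative" finding to act as a positive rule component.

## Screening and hierarchical modeling

Each dichotomous test is screened univariately against success vs failure
with a Pearson chi-square (df = 1, no continuity correction — the screen is
deliberately liberal and the Yates correction would only make it more
conservative; a config switch restores it).  A test is accepted when
p < 0.20 **or** LR+ ≥ 2; zero-cell LR+ uses the Haldane–Anscombe 0.5
correction, flagged.

Accepted tests enter a three-step hierarchical backward-stepwise logistic
regression: step 1 considers class-A variables (treatment-specific,
instability-related) plus the demographic covariates age, sex and BMI;
step 2 adds class-B (adherence-related) candidates to the step-1
survivors; step 3 adds class-C (treatment-nonspecific).  Elimination drops
the removable term with the largest Wald p until all are below
`alpha_retain` (default 0.05; the source only requires "all significant"
without a number).  Wald tests drive elimination because the reported
per-term intervals are Wald intervals; covariates are removable by default
because none appear in the published final models (`force_confounders`
restores forcing).

The fitter is iteratively reweighted least squares with step-halving;
convergence at max |score| < 1e-8 or relative deviance change < 1e-10.
Quasi-separation (|log-odds| > 15) is flagged and halts elimination for
that pool rather than being silently penalized; Firth-type penalization is
deliberately not offered at the derivation stage.  Rank-deficient designs
raise an error naming the collinear columns.

Model diagnostics: Nagelkerke R² = [1 − exp((D − D₀)/n)]/[1 − exp(−D₀/n)];
Hosmer–Lemeshow over deciles of predicted risk with ties kept together,
zero-expected bins merged (df = bins − 2), and the test skipped with a flag
when fewer than three distinct risks exist (the usual situation for a
model of 3–4 binary tests — how the original analysis binned such models is
unstated, so the strategy here is documented as our decision); ROC area as
rank concordance of the predicted risks; and per-term *adequacy* =
(D₀ − D_single)/(D₀ − D_full), the share of the full model's deviance
reduction achieved by each predictor alone, ranked with ties sharing a
rank.  The adequacy footnote in the source admits a second reading (a raw
−2LL ratio); the normalized form is used because it is scale-free and
bounded, and the choice is switch-visible in the code rather than claimed
to be the authors' exact variant.

## Rule evaluation

The chosen step's final tests (default: the class-A-only model, as in both
published rules) become the CPR; for k = 1..|tests| the "k or more
positive" 2×2 table against success/failure is built.  Intervals: Wald
normal approximation on the proportion scale for Se/Sp/PV (truncated to
[0, 1]); the log (Simel) method for likelihood ratios with
SE(ln LR+) = √(1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn)) and the mirrored form
for LR−.  These two conventions were fixed by reverse-engineering the
published intervals (e.g. 22.64 (11.37–33.9) from 12/53 and 8.15
(1.11–59.9) from tp = 12, fp = 1) and are locked by unit tests.  The
recommended threshold is the k with the largest finite LR+.

Post-test probability is Bayes' rule on the odds scale (the algebraic
Fagan nomogram).  The default prior is the prevalence among **all**
completers (54/110 = 49% at T8, 53/100 = 53% at T34), improvement class
included, even though the 2×2 excludes it — matching the published
convention; the analysis-subset prior is available.  With the table's own
prevalence, posttest(prev, LR+) = PV+ identically, which is asserted as a
property test.  Thresholds whose failure column holds ≤ 1 patient leave
LR+ undefined; on explicit request a lower threshold's failure split can
be substituted (flagged `approximated`, reported as illustrative only) —
the published approximated rows themselves do not reproduce exactly under
this substitution, so no exact reproduction is claimed.

## Synthetic cohorts

The generator emulates the study design so the whole pipeline is testable
without patient data.  Defaults are the study's marginals: 134 enrolled;
baseline ODI normal 26.8 (10) truncated at the eligibility floor of 12
(the mean/SD are midpoints of the published male 25.6 (9.0) and female
27.8 (10.6) marginals); NPRS 5.0 (1.3); BMI 26.5 (4.7); age 43.5 (12),
55% female; 18% in-program attrition and exactly 10 further follow-up
losses; success prevalence 0.49 at T8 and 0.53 at T34.

Four class-A tests are planted with odds ratio 6 each (the published
coefficients, B ≈ 1.4–1.8, correspond to per-test odds ratios of roughly
4–6): a continuous loaded-reach ratio (normal 0.70 (0.10), positive
≥ 0.75), two binary provocation/movement tests (positive rates 0.35 and
0.40), and a 0–9 ordinal laxity score positive *below* 5, generated as a
discretized truncated normal with a sex shift (males 0.5 (1.4), females
2.2 (2.6)).  Class-B/C noise variables have no outcome association.
Predictors are independent by default; no joint correlation structure is
asserted because the source provides none.

Success at T8 is drawn from a logistic model on the planted-test count,
the intercept solved by root-finding so the cohort-average success
probability equals the target prevalence (an unreachable target raises a
configuration error).  Follow-up success uses the planted effects scaled
by 0.8 plus a +1.0 log-odds persistence bonus for T8 successes, with its
own solved intercept — a package design choice, since only the follow-up
prevalence is documented.  Among non-successes, a configurable fraction
(default 0.2, chosen so that ≈ 11 of 110 completers land in the class, as
published) becomes "improvement" where the baseline ODI permits ΔODI ≥ 10
with ΔODI% < 50.  Follow-up ODI and pain scores are then drawn
*conditional on* the assigned class, so classification of the written file
reproduces the generated labels exactly; attrition is applied afterwards
and only hides measurements.

What the simulator does **not** model: adherence dynamics, item-level
questionnaire responses, measurement error correlated across tests,
outcome-dependent attrition (available as a switch but off by default),
and predictor correlation.  Passing pipeline-recovery tests on these
cohorts therefore demonstrates the statistical machinery under a known
mechanism, not the clinical validity of any rule derived from real data.

## Problem sizes and numerical choices

Tests run the derivation at n = 134–500 and the replicate-based checks
(prevalence calibration, planted-test recovery at n = 400 × 100
replicates, screening type-I enumeration at 30 + 30) at sizes where
Monte-Carlo error is a small fraction of the asserted tolerance; oracle
comparisons (exhaustive cut-point scans, grid-search likelihood, pairwise
concordance) are run at n ≤ 200 where brute force is exact and fast.
Floating-point policy: internal probabilities clipped at 1e-10 inside
IRLS weights only; candidate-cut ties compared at 1e-12; adequacy ties at
1e-9.  File round-trips write `repr` floats so read∘write is the identity.

## Known limitations

* Backward elimination explores a single path; the 9/16 candidate models
  of the original supplementary analysis arise from human choices the
  package intentionally reports rather than automates.
* Wald inference is poor near separation; the package flags and halts
  instead of switching estimators.
* The Hosmer–Lemeshow binning for coarse risk distributions is one of
  several defensible conventions.
* Published T8 per-threshold tables are internally inconsistent (the
  failure count at "2 or more" implies a specificity that contradicts the
  printed one); only internally consistent cells are used as fixtures and
  no attempt is made to decide which printed number is the typo.
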