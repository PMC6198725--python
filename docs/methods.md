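# Methods

## Model

All simulations operate on bivariate standard-normal populations of a
behavioral measure x and a brain measure y with a controlled **observable**
Pearson correlation r_o. Three generators are provided:

* **direct**: x ~ N(0,1), e ~ N(0,1) independent,
  y = r_o·x + √(1−r_o²)·e. Both marginals are standard normal and
  corr(x, y) = r_o by construction. A draw is accepted only if the realized
  correlation is within a tolerance (default 0.01) of the target, otherwise
  it is regenerated (at the default population size of 10^6 the realized
  correlation is essentially always within ~0.003, so the rejection loop is
  a safeguard rather than an active filter; it aborts with an error after
  100 attempts).
* **latent**: latent traits (t_x, t_y) bivariate normal with correlation
  r_h; observed scores mix trait and independent error,
  x = √rel_behav·t_x + √(1−rel_behav)·ε_x (and analogously for y), so that
  corr(x, y) = r_h·√(rel_brain·rel_behav) — Spearman's attenuation formula.
  This decomposition lets one verify that downstream power depends on the
  observable correlation only, not on how it splits into true effect and
  reliability.
* **heteroscedastic**: latent mode in which the behavioral error standard
  deviation is scaled by 1 + γ·Φ(t_x) (Φ the standard normal CDF), i.e.
  error grows with the latent trait's rank. The scale is renormalized by
  √(1 + γ + γ²/3) = √E[(1 + γU)²], U ~ Uniform(0,1), so the
  population-average error variance — and therefore the overall reliability
  and r_o — is unchanged. This isolates heteroscedasticity from reliability.
  The functional form is this package's own choice; any monotone,
  variance-renormalized scale would serve the same purpose.

One master seed (a numpy `SeedSequence`) spawns independent substreams for
every random component, so populations and simulation cells are exactly
reproducible and order-independent.

## Sampling schemes

A study sample of scanned size n is drawn from the population with
replacement. Under prescreening, n·f indices are drawn first (f the
prescreening factor) and the scanned subsample is selected **on x only** —
y values never influence retention, which is why the false-positive rate at
r_o = 0 stays at the nominal α under every scheme.

* **random**: the n draws are the sample (f = 1).
* **extreme**: the n/2 lowest and n/2 highest x in the pool are retained
  (n must be even; ties broken by index order). With anticipated dropout,
  `invited_per_tail` > n/2 most extreme participants are invited per tail
  and a uniformly random subset of n/2 is scanned — acceptance is assumed
  independent of the trait value. When only a dropout rate is given,
  invited = round(n/2 · (1 + rate)), e.g. 18 invited / 15 scanned per tail
  at a 20% rate.
* **even**: n target points equally spaced from the pool minimum to the
  pool maximum; each target, in order, is greedily assigned the nearest
  not-yet-selected observation (ties toward the lower value). The pool
  minimum and maximum are always retained. The greedy rule is this
  package's reconstruction of "cover the range as evenly as possible"; it
  is deterministic and O(pool size) per target.

## Power engine

Per replication a sample is drawn and tested with the exact t-based
two-sided Pearson test (t = r√((n−2)/(1−r²)), n−2 df). Power is the
fraction of replications with p < α (default 0.05, 10,000 replications).
The engine also reports the signed mean of the correlation estimates among
the *significant* replications — the effect size a file-drawer-biased
literature would see. Signed averaging is essential: at the null the
significant correlations are symmetric around zero and their signed mean
stays ~0 even though each is large in magnitude. An absolute-value variant
is available behind a flag.

All replications are vectorized (index matrices, row-wise argsort/argpartition
selection, batch correlation), so a 10,000-replication cell costs ~0.3 s on
one CPU; the acceptance script and acceptance tests therefore run the full
10,000 replications, while ordinary unit tests use 2,000–4,000 with
tolerances widened to ~3 binomial standard errors.

## Closed-form analytics

Sample-size planning uses the Fisher-z normal approximation with the +3
correction: n = ⌈((z_{1−α/2} + z_{power}) / atanh|r_o|)² + 3⌉. With
two-sided α = 0.05 and power 0.85 this gives n = 97 at r_o = 0.3 and
n = 201 at r_o = 0.21 — the convention adopted throughout (the α/power pair
is the package's inference; it reproduces both endpoints exactly and agrees
with the Monte-Carlo engine within 0.03 across the grid). Confidence
intervals are Fisher-z: tanh(atanh r ± z_{(1+level)/2}/√(n−3)); the width
shrinks only with √n, e.g. still >0.1 for r = 0.3 at n = 1000. Prose
statements of a single "reliability of 0.7" are interpreted as the combined
geometric-mean reliability √(rel_brain·rel_behav) = 0.7, consistent with
the attenuation formula and the 0.43/0.21 endpoints.

## Model discrimination

Two generating forms: y_h = x (linear) and y_h = (x+3)² (quadratic, monotone
over x > −3 and hence over virtually all of a standard-normal x). For each
replication a pool of n·f pairs is generated with
y = r_o·z(y_h) + √(1−r_o²)·e, where z(·) standardizes y_h **at the pool
level** — this makes r_o mean the same signal strength for both forms, and
it is the pool-level mixing that lets even-coverage selection enrich the
in-sample signal (standardizing after selection would define the noise
relative to the selected sample and erase the benefit). 1st- and 2nd-order
polynomials are fit by least squares and compared by
AIC = n·ln(RSS/n) + 2k with k = degree + 2 (coefficients, intercept, error
variance). RSS is floored at machine epsilon times the response variance so
noise-free inputs yield a finite AIC; exact AIC ties resolve to the simpler
(linear) model and the tie rate is recorded. AICc is available behind a
flag-off default (plain AIC is the package convention). Accuracy is pooled
over both forms with half the replications each, so chance is 0.5.

## Cost model

total = n_behavioral·(behav_hours·participant_fee)
      + n_scanned·(behav_hours·participant_fee
                   + scan_booking_hours·(participant_fee + scanner_fee)).

Defaults: 1 h behavioral session, 2 h scanner booking, 8 €/h participant
reimbursement, 150 €/h scanner fee. Staff costs are excluded; currency is a
label only. The formula is linear and monotone in every count and rate.

## Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| population size | 10^6 | participants | large enough that the rejection tolerance never binds and sampling-with-replacement overlap is negligible; 10× larger changes no result at reported precision |
| correlation tolerance | 0.01 | correlation | acceptance margin for the realized population correlation |
| replications | 10,000 | samples | binomial SE ≤ 0.005 on any power estimate |
| α | 0.05 | probability | two-sided; one-sided behind a flag |
| target power | 0.85 | proportion | planning default |
| prescreening factor | 6 | ratio | the canonical design point (n = 30 × 6 = 180 prescreened) |
| dropout invited/retained | 18 / 15 per tail | participants | 20% anticipated dropout at n = 30 |

## What the generator does and does not emulate

The synthetic populations are bivariate normal with exactly linear (or
exactly polynomial) relationships and, except in the heteroscedastic
variant, homoscedastic Gaussian measurement error. Real behavioral and
neural measures have skewed marginals, floor/ceiling effects, outliers,
non-stationary reliability and confounds that correlate with the trait.
Passing tests therefore demonstrate the statistical mechanics of
prescreening — variance enrichment, preserved type-I error, inflation of
significant effect sizes, reliability attenuation — not robustness of any
particular empirical study to all of these departures. Dropout is modelled
as independent of the trait; trait-correlated dropout would bias the
retained tails and is out of scope.

## Numerical choices and known limitations

* Monte-Carlo tolerances in tests are set at ~3 binomial standard errors of
  the replication count used; monotonicity checks allow a 0.02 violation.
* The dropout step (scan a uniformly random 15 of the 18 most extreme
  invitees per tail) costs about 0.028 power at the r_o = 0.3, n = 30,
  factor-6 design (measured at 200,000 paired replications) while leaving
  the ~0.36 boost over random sampling at the same n essentially intact.
  It is a real, if small, cost — designs that must guarantee ≥85% power
  under dropout should invite more than 20% extra or raise the factor.
* `mean_sig_r` is undefined (NaN, with a warning) when no replication is
  significant, which occurs only at tiny effect sizes and sample sizes.
* Sampling is with replacement; at the default population size duplicate
  draws are vanishingly rare, but tiny populations (< ~100× the pool) are
  rejected to avoid overlap artifacts.
* The even-coverage greedy rule is order-dependent by construction (targets
  processed left to right); it is deterministic and always includes both
  pool extremes, but it is not guaranteed to minimize any global coverage
  criterion.
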