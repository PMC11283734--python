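# Methods

## The model

`liversim` is a discrete-event simulation of a small national liver-transplant
waiting list (Norwegian scale: roughly 103 listings and 115 donor livers per
year) built to answer one policy question: what happens to the patients
already on the list — and to total population health — if eligibility is
extended to patients with nonresectable colorectal liver-only metastases
(CRLM), for whom transplantation is curative-intent but who otherwise receive
palliative chemotherapy?

Two strategies are compared. Under strategy 1 only the currently eligible
("Status Quo") indications are listed and CRLM patients follow the palliative
pathway off-list. Under strategy 2 an average of *n* CRLM patients per year
(n = 0..10) join the list and follow the same transplantation pathway as
everyone else. Outcomes are counted for the cohort listed during a 10-year
enrollment window, followed for their remaining lifetime.

The simulation advances an event calendar over six processes:

1. **Status Quo arrivals** — Poisson, mean interarrival 3.55 days. Each
   arrival draws a diagnosis (HCC 13.7%, PBC 6.7%, PSC 18%, ALF 8.3%,
   AC 10.1%, Others 43.2%), a blood type (A 49%, B 8%, AB 4%, 0 39%), and a
   static age (HCC 61 y; PBC/AC/Others 57 y; PSC/ALF 43 y). ALF patients are
   prioritised.
2. **CRLM arrivals** — Poisson with mean interarrival 365/n days; age 57 y,
   no priority.
3. **Pretransplant natural history** — at listing, each patient draws three
   competing exit clocks: disease-specific death and dropout (registry
   strata, exponential defaults) and an administrative withdrawal (see
   below). The earliest exit removes the patient if it precedes a
   transplant.
4. **Liver arrivals** — Poisson, mean interarrival 3.18 days (≈114.8/year);
   each liver draws a blood type from a calibrated donor mix.
5. **Matching** — an arriving liver goes to the longest-waiting
   ABO-compatible patient (donor 0 → anyone, A → A/AB, B → B/AB, AB → AB),
   with priority patients (ALF, retransplant listings) served first. A liver
   with no eligible recipient is exported immediately (the model never banks
   organs), which makes each blood-group queue a double-ended ("taxi-stand")
   queue rather than M/M/1 — waits are substantially longer than the M/M/1
   formulas suggest, because a patient arriving at an empty queue must still
   wait for the next organ. An identical-type matching rule is available
   behind `abo_rule="identical"`; it cannot reproduce the national
   type-specific waits (reaching the AB median of 21 days under identical
   matching would require ~16 AB livers/year against 4.2 AB listings/year,
   and ~133 livers/year in total against the 114.8 available), which is why
   compatible matching is the default.
6. **Post-transplant survival** — a transplant fails and leads to an
   immediate retransplant listing with probability 13.4%; of those listed,
   74.9% qualify (non-qualifiers are removed and die at removal). Successful
   recipients draw a disease-specific survival time by inverse-transform
   sampling. Beyond 10 years post-transplant the disease-specific curve is
   replaced by age-specific background mortality from a national-style life
   table (no excess transplant mortality assumed). One retransplant at most;
   retransplant recipients draw survival from their original diagnosis
   stratum.

Life expectancy is measured from listing — the only time origin shared by
the transplant and palliative arms. Patients removed from the list accrue
life-years only to removal; this slightly understates absolute life-years,
symmetrically across strategies.

### Withdrawal

The withdrawal input ("6% per year") is implemented in two modes:

* `fraction` (default): 6% of listings withdraw, at an exponentially
  distributed time with a 30-day mean, independent of queue state. This
  matches the registry observation that withdrawals track *listings*
  (≈6 per year against 103 listings) rather than waiting time, and it is
  required to reproduce the observed queue slack: under the hazard reading
  below, only ~1.8 patients/year withdraw and every median wait inflates by
  roughly 40%.
* `hazard`: an exponential clock with annual probability 6%
  (rate −ln(0.94)/365 per day) while listed.

### Randomness and common random numbers

A master seed feeds seven named RNG streams (Status Quo arrivals, CRLM
arrivals, livers, attributes, pretransplant, posttransplant, palliative),
each re-derived per replication. Every patient pre-draws all uniforms its
pathway could ever use at creation, in arrival order. Two scenarios run
from the same seed therefore see the *same* patients with the same latent
fates, and differ only through queue interaction. This is essential: the
incremental outcomes of interest (a 0.05-year life-expectancy change) are
far below between-replication noise. Each CRLM patient also carries a
palliative counterfactual draw and both eligibility-criteria survival
draws, so one sweep yields matched SECA I and SECA II surfaces and matched
palliative baselines.

Replication design: 1,900-day burn-in (the queue starts empty and
stabilises), 3,650-day enrollment window, arrivals continuing afterwards so
late-window patients face realistic competition, and a run-out until every
tracked patient has left the list. Default replications: 500 for the
shipped analyses, chosen so a full 0–10 sweep runs in minutes on one CPU;
the published setting of 7,000 is a flag away (`--replications 7000`).
Estimates of aggregate net life-years carry a Monte-Carlo standard error of
roughly ±10–15 life-years at 500 replications (queue-path divergence is
chaotic, so common random numbers only partially control the loss term);
structural conclusions are insensitive to this, point estimates of net
life-years are not.

## Survival machinery

Five parametric families (exponential, Weibull, log-logistic, log-normal,
Gompertz) with closed-form survival, density, CDF and quantile functions.
Gompertz uses the (shape *b*, rate *a*) convention with hazard
a·exp(b·t), b > 0. Right-censored maximum likelihood is optimised with
Nelder-Mead on log coordinates (closed form for the exponential), and
AIC/BIC selection breaks ties by parsimony then a fixed family order. The
fitting stack exists so that survival inputs digitised from published
curves can be re-estimated; in this package it is exercised end-to-end on
synthetic cohorts drawn from known families.

Life-table sampling: one uniform selects the death year from the
conditional survival ladder, with uniform placement within the year (annual
probabilities do not identify sub-year timing). The shipped life table is
*synthetic*: a Gompertz–Makeham hazard μ(x) = A + B·e^(θx)
(A = 5·10⁻⁵, B = 1.7553·10⁻⁶, θ = 0.1285) chosen to mimic a recent
Norwegian period table (e₀ ≈ 82.5 y, e₆₇ ≈ 17.5 y). Any CSV with columns
`age,qx` (closed by qx = 1) can replace it.

## Calibration (what is fitted to what)

The fitted survival coefficients behind the original analysis are not
published; the registry is therefore *calibrated*, not transcribed:

* **Scales** — each treatment stratum's scale parameter is solved exactly so
  its 75%-survival time (0.25 quantile) matches the published value
  (HCC 2.20 y, PBC 7.25, PSC 8.94, ALF 2.23, AC 5.43, Others 5.05,
  palliative 1.18, CRLM SECA I 2.64, SECA II 5.06). Base-case family:
  log-logistic.
* **Shapes** — not identified by one quantile. They are solved so the
  *implied life expectancy* (E[min(T,10)] + S(10)·e(age+10), the analytic
  form of the 10-year switch) reproduces the published group-level
  anchors: Status Quo mixture 15.28 y (one shared shape across the six
  diagnoses, solved on the diagnosis mixture), palliative 2.48 y, SECA I
  8.19 y, SECA II 13.16 y. Anchors measured from listing are first
  converted to post-transplant targets using three queue constants
  (survival-path fraction 0.90, mean wait 0.17 y, mean time-to-removal
  0.12 y) read off base-case queue behaviour. This is a calibration, not a
  derivation; every entry is overridable from a YAML registry file.
* **Waiting-list death/dropout** — the underlying cumulative-incidence
  coefficients are unpublished; defaults are exponential clocks (mean
  4,300 days per competing cause, identical across diagnoses, CRLM
  aliasing HCC) calibrated so the strategy-1 annual Status Quo
  death/dropout count is ≈3.3/year.
* **Donor blood-type mix** — starts from the population mix and is adjusted
  by a seeded greedy pairwise-transfer search (each candidate moves
  probability mass between two types, scored by short simulations against
  the type-specific median-wait targets, steps bounded to ±10 points).
  The shipped default {A 0.46, B 0.08, AB 0.025, 0 0.435} was calibrated
  once against the published model's wait column (A 32, B 53, AB 21,
  0 106 days) and frozen. The calibration uses its own RNG seed and never
  touches experiment streams.

Weibull uncertainty variants re-anchor the named strata to the Weibull
passing through the base curve's 25th and 50th percentiles — same
near-term survival, lighter tail, hence poorer long-term survival — since
the original Weibull coefficients are likewise unpublished. Liver
availability variants rescale the liver interarrival mean to 365/121
(best case) and 365/103 (worst case) days.

## Synthetic data: what it does and does not show

`generate_cohort` draws individual-level event times from a known family
with optional administrative right-censoring. It stands in for the
digitised Kaplan-Meier coordinates of the source trials, and makes the
fitting/selection machinery testable end-to-end (parameter recovery within
10% at n = 2,000; the true family wins ≥70/100 AIC contests at that size).
Passing these tests shows the estimation machinery is correct; it says
nothing about how well any parametric family fits *real* transplant
survival, which is exactly the information the published 75%-quantiles and
life-expectancy anchors inject through calibration.

## Numerical choices

* Quantiles are closed-form for all five families; cross-checked against
  the independent scipy parameterisations to 1e-9 in tests.
* Simultaneous events break ties by insertion order; liver arrivals are
  inserted after same-instant listings, so a same-day listing can receive a
  same-day organ (unobservable at daily resolution, maximises matching
  consistency).
* Exit events are lazily invalidated (a stale spell index is skipped), so
  transplanting a patient silently cancels their pending exit.
* Degenerate inputs fail loudly: empty ledgers, all-censored cohorts,
  non-summing mixes, out-of-range ages and probabilities raise typed
  errors.

## Known limitations

* Matching ignores body size, disease severity and organ quality; the model
  consequently matches organs more easily than clinicians do (exports run
  ~1 liver/year below the observed count, first transplants above it).
* Queue-level accounting conserves patients and livers exactly; the
  published validation table it is compared against does not (its listed
  inflow exceeds its counted outflows by ~13 patients/year), so the
  first-transplant count of a conserving model necessarily sits above the
  published 80.8/year.
* Ages are static; no aging on the list (waits are weeks to months).
* One retransplant maximum; no retransplant-specific survival curve.
* QALY weighting and costs are out of scope.
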