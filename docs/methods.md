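# Methods

## Counting model

The counting unit is a message (forum) or a report (reference source). A
unit attests a drug–event pair at most once; a unit mentioning *k* drugs
and *m* adverse-event preferred terms contributes *k·m* distinct pairs
(the convention of spontaneous-report systems, and the choice that loses no
information when the unit is ambiguous). Margins of the pair-count table
are sums over its entries, so for every pair the 2×2 decomposition

    a = n(drug, event)        b = drug margin − a
    c = event margin − a      d = grand total − a − b − c

holds exactly, with the "other drugs" stratum being the study drugs and
the background comparator group pooled. The event universe of a source is
the set of preferred terms observed in that source. Cross-source matching
of pairs is exact on (drug id, preferred-term code): no fuzzy matching, so
nearly-synonymous preferred terms ("weight" vs "overweight") stay
distinct, as they do in real terminologies.

All dates are truncated to calendar months, the time unit throughout.

## Disproportionality statistics

With `N = a+b+c+d` and expected count `E = (a+b)(a+c)/N`:

* **PRR** `= [a/(a+b)]/[c/(c+d)]`, with
  `PRR025 = exp(ln PRR − 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))` and
  Pearson's χ² without continuity correction (a Yates-corrected variant is
  not provided; the Haldane–Anscombe +0.5 option below covers sparse
  tables).
* **ROR** `= ad/bc`, `ROR025 = exp(ln ROR − 1.96·√(1/a+1/b+1/c+1/d))`.
* **RFET**: one-sided upper-tail Fisher exact `P = P(X ≥ a)` under the
  hypergeometric law with the table's margins (scipy's `hypergeom.sf`;
  validated against exhaustive enumeration over all tables with N ≤ 40).
* **IC** `= log2((n+0.5)/(E+0.5))` with the closed-form credibility bound
  `IC025 = IC − 3.3(n+0.5)^−1/2 − 2(n+0.5)^−3/2`. This is the shrunk
  observed/expected form; a full-Bayes alternative would be an extension
  point.
* **EBGM / EB05**: the MGPS empirical-Bayes shrinker. The relative
  reporting ratio λ has a two-component gamma mixture prior
  `p·Γ(α₁,β₁) + (1−p)·Γ(α₂,β₂)` whose five hyperparameters are fitted by
  maximum marginal likelihood over all pairs of the source (the marginal
  of each count is a two-component negative-binomial mixture). The
  posterior for a pair is again a two-gamma mixture with shapes `αₖ+n`,
  rates `βₖ+E`, and weights proportional to prior weight × component
  marginal mass. EBGM is the posterior geometric mean
  `2^E[log2 λ | n]`; EB05 is the posterior 5th percentile. EB05 is a
  one-sided quantity; it corresponds to the lower endpoint of a 90%
  equal-tailed interval and is the conventional MGPS threshold statistic.

**Zero cells.** Metrics whose formulas are undefined on a zero cell (PRR
with a=0 or c=0, ROR with any zero cell, the CIs) return NaN, and NaN
never flags a signal. An optional Haldane–Anscombe +0.5 correction to all
four cells exists but is off by default. Independently, no definition may
flag a pair with n = 0: a signal of disproportionate *reporting* requires
at least one report. (This only matters when a degenerate prior would
otherwise let EBGM flag unobserved pairs; see the fitting note below.)

**Signal definitions** (inclusive thresholds except IC): EBGM ≥ 2,
EBGM ≥ 4, EB05 ≥ 2, (PRR ≥ 2 & n ≥ 3 & χ² ≥ 4), PRR025 ≥ 1, ROR025 ≥ 1,
IC025 > 0 (strict, threshold configurable), RFET P ≤ .05. The IC rule is
strict rather than `≥ 0` because a pair with exactly zero lower bound
carries no evidence of excess.

## Fitting the MGPS prior

The five parameters are optimized on an unconstrained scale (logit weight,
log shapes and rates) with L-BFGS-B from five fixed, documented starting
points (the first being the classical MGPS default prior
p = 1/3, α₁ = 0.2, β₁ = 0.1, α₂ = 2, β₂ = 4); the best optimum wins and
components are reported high-prior-mean first, so fits are reproducible
and comparable. If no start converges, the error carries the best
incumbent and per-start diagnostics.

Two practical points matter more than the optimizer:

* **Zero cells belong in the fit.** In the monthly surveillance scan the
  prior is fitted on the full drug × event grid with positive margins as
  of that month, zero-count cells included. Fitting on observed pairs only
  is badly biased when the database is young — nearly every observed count
  is 1, the likelihood concentrates the prior far from 1, and every pair
  (including unobserved ones) looks like a signal. The zero cells anchor
  the null component, which is the standard MGPS formulation.
* **Refit cadence.** `detection_dates` refits the prior at every as-of
  month by default (the surveillance-faithful choice); `prior_mode="final"`
  fits once on the full window and reuses it, a good approximation once
  the database is large and several times faster.

EB05 (and mixture quantiles generally) are computed by bisection on the
mixture CDF between the two component quantiles, 200 halvings, which is
exact to well below 1e-10 — cheaper and more robust than general
root-finders when vectorized over thousands of pairs.

## Evaluation

Forum flags are compared to reference flags over an evaluation universe —
by default the pairs attested in both sources, with a minimum per-source
count of 1 (or 2 for the stricter universe); against synthetic ground
truth the universe is the full scored pair set. The five indicators are
`sensitivity = tp/(tp+fn)`, `specificity = tn/(fp+tn)`, `PPV = tp/(tp+fp)`,
`NPV = tn/(fn+tn)`, `accuracy = (tp+tn)/N`; a zero denominator yields an
undefined (NaN) indicator, never 0. ROC curves sweep the distinct values
of a continuous forum metric (default EBGM) against binary reference
labels (default the reference EBGM ≥ 4 flags); ties share one threshold
point, NaN scores rank below all defined scores, and AUC is the
trapezoidal integral, which equals the Mann–Whitney ordering probability
(asserted to 1e-10 in the tests).

## Time analysis

Detection date = the first month the definition holds on cumulative
counts; no persistence is required, so a transient crossing counts. Δtime
is tabulated per definition over the pairs detected in both sources for
that definition, which is why the per-definition totals differ.

## The synthetic generator

`generate_streams` draws, for every (source, drug, event, month),
an independent Poisson count with mean

    baseline_rate × drug_multiplier × [relative_rate if planted and
    month ≥ that source's onset] × [messages_per_report_ratio if forum]

The Poisson law is chosen because disproportionality analysis is an
observed/expected framework; it makes planted relative rates directly
interpretable as asymptotic observed/expected ratios. The forum onset of a
planted pair is the reference onset plus `forum_lead_months` (negative
when the forum leads). Defaults mirror the comparative study design: 3
study drugs plus 327 background drugs, 150 event terms, monthly reporting
2005–2015, baseline giving ~3 units per pair over the window. The optional
per-drug multipliers emulate the strong skew of real reporting volume
toward a few heavily-discussed drugs; they scale rows only, so drug–event
independence — and a true relative rate of 1 for unplanted pairs — is
preserved.

Forum occurrences can be rendered as text: one positive message per
occurrence from slot-filler templates (drug surface form — substance,
brand, or a dropped-letter misspelling — plus a first-person intake phrase
and an event variant term), and decoy messages in a configurable
proportion cycling through four labelled classes: indication mentions,
questions about an unexperienced effect, posts without an intake phrase,
and symptoms predating the intake. The vocabulary is coined letter-only
words, so template prose can never collide with a drug or event term.

What the generator does **not** emulate: realistic prose (slot fillers
only), multilinguality, user-level correlation (every unit is
independent), reporting-rate drift over calendar time, terminology
mismatch across sources (both sources use one terminology), and
event–event correlation within a message. Passing tests therefore show
that the statistical machinery is correct under the generative model, not
that the annotation heuristics would reach any particular recall on real
forum text — the rule-based adverse-event classifier in particular is
validated only against the decoy classes it was designed for, standing in
for a trainable classifier behind the same interface.

## Validation problem sizes

The test suite validates, at these scales (chosen to give the statistics
room to converge while keeping a laptop-friendly runtime):

* Fisher exact vs exhaustive enumeration: all 135,751 tables with N ≤ 40.
* MGPS closed forms: single-component priors over a (n, E) grid, 1e-8.
* Prior recovery: 50,000 pairs from a known two-gamma mixture, all five
  hyperparameters within 15%; marginal masses vs quadrature to 1e-6.
* Null calibration: 330 drugs × 40 events over 132 months, five drugs at
  100× propensity (giving ~200 pairs with E ≥ 100 where the information
  component's small-count bias, of order 1/(2E·ln 2), is negligible
  against its sampling error).
* Operating characteristics: 2,000 pairs with 50 planted at relative rate
  10 (expected planted count 30), all eight definitions at sensitivity and
  specificity ≥ 0.9, AUC ≥ 0.95.
* Time scan: 43 drugs × 25 events over 48 months, 8 planted pairs at
  relative rate 25 with a −6 month forum lead (~2 expected units per
  month post-onset); a deterministic fixture cross-checks the scan against
  brute-force month-by-month re-evaluation for all definitions.

## Known limitations

* The rule-based AE classifier judges the whole message, which is adequate
  for short single-clause posts (and the synthetic templates) but not for
  multi-concept messages where one concept is an indication and another a
  reaction.
* Expected counts are raw margins-based; no stratification (age, sex,
  year) and no multiple-comparison adjustment across pairs.
* The intake flag does not distinguish the author from a relative.
* Porter stemming is language-specific; non-English corpora need a
  different normalizer behind the same interface.
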