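# Methods

## The problem

Spontaneous adverse-event report databases (FAERS-style) collect unsolicited
reports from consumers, clinicians and manufacturers. There is no exposure
denominator, so incidence cannot be estimated; instead, *disproportionality
analysis* asks whether a drug–event pair is reported more often than the
database's own reporting patterns predict. `pvsignal` implements that
analysis as a pipeline: ingestion of the three delimited report tables,
staged duplicate removal, report-level drug × event-term counting with
composite endpoints, empirical-Bayes gamma-Poisson shrinkage (MGPS) of the
relative reporting ratio, and screening at EB05 ≥ 2.

## The statistical core

For a cell (drug Y, event term X) let N be the number of distinct reports
mentioning both, and

    E = (reports with X) · (reports with Y) / (total reports)

the count expected if drug and event were reported independently. The raw
disproportionality measure is the relative reporting ratio RRR = N/E. Raw
ratios explode for rare events (N = 1, E = 0.01 gives RRR = 100 with no
evidential weight), which is the motivation for shrinkage.

The model: N | λ ~ Poisson(λE), with the cell's true reporting ratio λ
drawn from a two-component gamma mixture prior

    λ ~ w·Gamma(α₁, β₁) + (1−w)·Gamma(α₂, β₂)      (rate parameterization)

Marginally N is a two-component negative-binomial mixture with component k
having size αₖ and success probability βₖ/(βₖ+E). The five hyperparameters
are estimated once per database by maximizing the summed log marginal
likelihood over all scorable cells (empirical Bayes). Conjugacy then gives
each cell's posterior in closed form:

    λ | N ~ Q·Gamma(α₁+N, β₁+E) + (1−Q)·Gamma(α₂+N, β₂+E)

with Q the posterior component weight (Bayes rule on the two NB masses,
computed in log space). Reported scores:

* **EBGM** = exp(E[log λ | N]), evaluated with the digamma function —
  the shrunken "empirical Bayes geometric mean" of the reporting ratio;
* **EB05, EB95** — the posterior 5th and 95th percentiles (a 90% interval),
  obtained by bracketed root-finding on the posterior mixture CDF;
* a pair is screened as a potential signal when EB05 ≥ 2 (inclusive): the
  pair is reported at least twice as often as expected with 95% posterior
  confidence. The threshold is a screening rule, not a causal claim.

## Numerical choices

* Likelihood and posterior weights are computed entirely in log space
  (`gammaln`, `logaddexp`); the marginal is stable for N up to 10⁵ and
  extreme hyperparameters.
* The fit runs L-BFGS-B on log-transformed shapes/rates and the
  logit-transformed weight, parameters bounded to [10⁻⁶, 10⁶] (weight to
  [10⁻⁶, 1−10⁻⁶]), convergence at relative likelihood change < 10⁻¹⁰ and
  projected gradient < 10⁻⁶, best of `n_restarts` seeded jittered starts
  (first start is the classical α=(0.2, 2.0), β=(0.1, 4.0), w=1/3 point).
  Label switching is resolved by ordering components by prior mean. A
  result at a box bound sets an `at_bounds` flag. The fit warns below ~100
  cells and requires an explicit seed; identical seed and cells give an
  identical result.
* Posterior quantiles: the mixture quantile is bracketed by the two
  component quantiles and solved by Brent's method *in log space* (relative
  tolerance ~10⁻¹²); log space matters because a degenerate fitted prior
  (a near-zero-shape component, which the optimizer can produce on
  null-only data) puts quantiles dozens of decades below the bracket top.
  Quantiles or EBGM values beneath 10⁻³⁰⁰ saturate at that floor — they are
  operationally zero and can never flag. A bracket failure raises; an
  endpoint is never silently returned.
* Zero-N cells are retained for fitting and scoring (the model is defined
  at N = 0; dropping them biases the hyperparameter fit). Cells with a
  zero margin have no defined E and are excluded from scoring, with a count
  logged.
* The expected-count denominator is the total number of reports in the
  deduplicated database, including reports mentioning none of the studied
  drugs or terms. An optional stratified variant sums per-stratum expected
  counts E = Σₛ Eₛ (e.g. age band × gender); the default is unstratified.

## Duplicate detection

Matching is deterministic and staged: each stage requires a set of
demographic fields (gender, age within a tolerance, death date) and record
fields (manufacturer, drug set, event set, drug/event start dates) to
agree; duplicate groups are connected components of the stage's match
relation among reports not claimed by an earlier stage; one representative
per group survives (latest receipt date by default).

Semantics: missing values never satisfy a required match — a report lacking
a required field (including an empty drug or event set) is ineligible for
that stage. The one exception is the death date: absent from both reports
passes, present on exactly one fails. "Nearby age" defaults to ±1 year and
is configurable; within a block of otherwise-identical reports, sorted ages
are chained whenever consecutive gaps are within tolerance, which is
exactly the connected components of the pairwise |Δage| ≤ tol graph.

The default ladder (strict → loose) anchors every stage on drug
information including start dates: (1) full demographics + manufacturer +
drug set + event set + drug start dates for spontaneous reports, with the
manufacturer requirement dropped for literature/study reports (those often
arrive without a meaningful sender); (2) the same without manufacturer and
death date. A loose event-only rung (gender + age + event set + event onset
dates) is available behind `include_event_only_stage` for databases whose
drug records may be missing entirely; it is off by default because when
drug records are complete it almost exclusively merges distinct cases that
happen to share one event and demography — on generated data it costs
pairwise precision (≈0.87) while adding nothing to recall. Proprietary
production systems do not disclose their stage ladders; this one is an
explicit, configurable stand-in that follows the same published matching
criteria (demographics, manufacturer/drug/event information, start dates,
source-dependent adjustment).

## The synthetic generator

`synthetic.simulate_database` generates databases embodying exactly the
structure the model assumes, so recovery tests are well-posed:

* One λ per (drug, PT) pair, drawn once from a background two-gamma
  mixture and fixed — the gamma-Poisson assumption. Planted signal pairs
  get a fixed elevated λ. The default background is 90% Gamma(2,2)
  (mean 1, concentrated near the null) + 10% Gamma(2,1) (mean 2), an
  elevated minority at rates that keep event probabilities far from the
  cap. A degenerate λ ≡ 1 background (`true_hyper=None`) gives exact-null
  databases.
* Per report, drug exposures are independent Bernoulli draws from the
  vocabulary's marginal probabilities (defaults: 20 drugs spread over
  exposure 0.01–0.09; 15 PTs spread over base rate 0.002–0.02). Each PT
  occurs with probability base_rate × λ, taking the largest λ over the
  report's drugs; probabilities above 0.5 raise a validation error rather
  than being silently capped, keeping the Poisson approximation honest.
* Every report carries ≥1 drug and ≥1 event: when no studied entry is
  drawn, a filler from a small out-of-vocabulary background list is used
  (a report exists because a drug–event experience was reported). Fillers
  are never counted, so realized studied margins stay calibrated at
  n_reports × probability.
* Demographics: gender 50/50, age ~ round(Normal(48, 15)) truncated to
  [18, 90], death date present with probability 0.03; sources 90%
  spontaneous / 5% literature / 5% study; five manufacturers; complete
  drug start and event onset dates.
* Duplicates: a configurable fraction of reports (default 5%) is cloned
  under a new ID with age jittered within ±1 year and the manufacturer
  occasionally dropped (5%); ground truth records the clusters.
* Everything is driven by one `numpy` Generator; identical config ⇒
  identical database.

What the generator does **not** emulate: real term frequencies and their
heavy tails, drug co-prescription structure, reporting dynamics over time
(notoriety effects), free-text name misspellings, or duplicates submitted
with conflicting drug/event content. Passing recovery tests therefore
demonstrates correctness of the pipeline under the model's own assumptions,
not performance on real regulatory data.

## Study conditions used by the test suite

Problem sizes were chosen as the smallest at which each property is
statistically unambiguous: hyperparameter recovery uses 5·10⁴ cells with
E log-uniform on [0.1, 100]; posterior-quantile checks use 10⁶ Monte-Carlo
draws; oracle-equivalence checks 100 random (hyperparameter, N, E)
instances against adaptive quadrature; planted-signal detection runs the
full pipeline on 50 seeded databases of 2·10⁴ reports with one λ = 10 pair
at 5% exposure and 1% base rate over a λ ≡ 1 background, with a matched
50-seed null batch for false-positive control; duplicate recovery uses one
2·10⁴-report database at 5% duplication.

## Design decisions that were genuinely open

* The published MGPS outputs (EBGM, EB05, EB95) do not pin down the prior
  form; this implementation follows the standard two-gamma mixture /
  negative-binomial-marginal formulation of the gamma-Poisson shrinker.
  No higher-order (multi-drug interaction) terms and no covariate-adjusted
  variant are modelled: pairs only.
* The fit universe is all cells with E > 0 over the configured drug/term
  sets, including N = 0 cells; shrinking toward an entire multi-million-
  report database is a production-scale choice exposed as configuration,
  not a default.
* Drug roles (suspect vs concomitant) are retained but not filtered by
  default; `suspect_only` enables suspect-only exposure counting.
* PT matching is case-insensitive exact string match against a flat
  configured vocabulary; no hierarchy or standardized-query expansion is
  modelled (the licensed dictionary is out of scope).
* Combination products expand to their components at name normalization
  (the efavirenz/emtricitabine/tenofovir disoproxil fumarate product is the
  shipped default), so combo exposure counts as exposure to each component.
  Salt-suffix stripping is available but off unless configured.

## Known limitations

* EB05 ≥ 2 is a screening rule on reporting disproportionality; it cannot
  establish causation, quantify risk, or (when not crossed) establish
  absence of association. Under-reporting, channelling and notoriety
  biases all pass through untouched.
* The deduplication ladder is a documented stand-in for undisclosed
  proprietary matching; its precision/recall guarantees are demonstrated
  only under the generator's duplication model.
* The fit can legitimately terminate at a parameter bound on degenerate
  inputs (e.g. all-null databases); `at_bounds` marks this and scores
  remain well-defined, but hyperparameter values themselves should not be
  interpreted there.
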