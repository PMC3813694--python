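# Methods

This note documents the model, the estimators and the numerical choices
behind `robfish`, in the spirit of a model-description appendix: what is
computed, under which assumptions, with which defaults, and what the
built-in fixtures can and cannot show.

## Population and fleet dynamics

The simulator is a deliberately reduced, single-zone representation of a
mixed flatfish fishery, using the survival and catch equations standard in
stock-assessment practice rather than any platform-specific formulation.

* **State.** Per population, abundance-at-age N(a) from the recruit age to a
  plus group.  Time steps monthly; all rates (F, natural death rate M) are
  annual and a month applies rate/12.
* **Survival / catch.** With Z(a) = F(a) + M, one month gives
  N' = N·e^(−Z/12), catch C = (F/Z)(1 − e^(−Z/12))·N and natural deaths
  D = (M/Z)(1 − e^(−Z/12))·N.  The identity N = N' + C + D holds to machine
  precision and is asserted on every step of every run (tolerance 1e−9
  relative, observed ~1e−16).
* **Fishing mortality.** F(a) = q · Σₘ TFₘ · selₘ(L(a)) · Eₘ: linear in
  each métier effort, with length-based selectivity (logistic (L50, slope),
  knife-edge available) on von Bertalanffy length
  L(a) = L∞(1 − e^(−K(a−t₀))).  Effort units and the catchability scale are
  conventional; only their products are identified, which is why the
  catchability axis is explored as a relative window.
* **Ageing and recruitment.** Ageing happens on 1 January: ages shift, the
  plus group accumulates, and the recruit-age slot is set from the schedule
  (forced values for the first three simulated years, then a constant).
  Spawning biomass SSB = Σ N(a)·mat(a)·w(a) and total biomass are evaluated
  at the same instant.  The recruitment axis (RE) multiplies the
  post-forcing constant only: the forced years are treated as data, not as
  an uncertainty.
* **Effort allocation.** Once per year each fleet distributes its monthly
  effort over métiers with attractivity
  habit·(historical share) + (1 − habit)·(revenue share), revenue shares
  being last year's per-métier landed value normalized to one; the first
  year, and whenever all revenues are zero, habit shares are used alone.
* **Quota closures and discarding.** Landings count against the TAC; when a
  population's quota is exhausted, métiers targeting it stop for the rest of
  the year, their effort moving to the highest-attractivity métier of the
  same fleet and gear whose target is still open (else it is lost), while
  continuing métiers discard that species entirely as bycatch.  Undersized
  fish (below the minimum landing size) are always discarded.  A fraction
  `discard_survival` of discarded fish is returned to its year class; the
  rest die.  Closures are checked at month ends, so landings may overshoot
  the TAC by at most one month's catch.
* **Realized annual F.** Reported F-at-age is catch-consistent: the annual
  Baranov equation C = F/(F+M)·(1 − e^(−F−M))·N_Jan is inverted per cohort
  (Brent's method on [0, 50]; closed form when M = 0; zero-catch cohorts get
  F = 0).  The headline F is the mean over ages ≥ 2 (configurable).  The sum
  of monthly rates is kept as a fallback for cohorts whose inversion is
  degenerate (possible when returned discards inflate a cohort mid-year).

## Harvest control rule

After the three forced-TAC years, each population's TAC comes from the
MSY-transition rule: blend weight w = min(1, y/T) in transition year y of a
T-year transition, target F = min(F_pa, (1 − w)·F_pre + w·F_msy), scaled by
SSB/B_trigger when SSB sits below the trigger.  Design choices where the
rule leaves room:

* **F_pre is measured inside the simulation** as the realized mean F of the
  last forced year, not supplied externally, so the transition starts from
  whatever the simulated fishery actually did.
* **F → TAC** by a deterministic one-year Baranov forecast from the current
  January abundance, spreading the scalar target over ages with last year's
  realized F-at-age pattern (normalized to mean one over the F-bar ages).
  This is the simplest monotone, testable choice: TAC(0) = 0 and TAC is
  non-decreasing in the target.
* **The ±15% year-to-year bound** is applied last (after the F_pa cap and
  the trigger scaling) and is anchored, in the first rule year, on the last
  fixed TAC.  The F_pa comparison is non-strict.
* **Below-trigger behaviour** defaults to the linear advice-rule reduction;
  a hard floor (target F = 0 below the trigger) sits behind
  `btrigger_mode="hard_floor"`.

## The uncertainty space

Every explored parameter is a `ParameterAxis` with a reference value and an
affine transform onto [0, 1].  Axes without explicit bounds get
[ref·(1 − w), ref·(1 + w)] with w = 0.5 — the default ±50% window, wide by
sensitivity-analysis standards but appropriate where stock parameters carry
confidence intervals of that order — so the reference maps to 0.5 exactly.
Axes with an asymmetric natural range (the discard-survival rate, explored
on [0, 0.5] because the reference model returns none of its discards)
carry explicit bounds.  Negative references (t₀) sort their window
endpoints.  Management axes form Q, biological + technical axes form U.

Designs are Latin Hypercubes (scipy's `qmc.LatinHypercube`): per axis,
exactly one point per equal-width stratum, placed uniformly at random within
the stratum, reproducible by seed.  Campaign records are plain DataFrames —
run id, normalized coordinates, outputs, success flags — and round-trip
through CSV.

Success is evaluated on the final simulated year (the default 10-year
horizon leaves 7 HCR years); a `from_year` option adds minimum-SSB columns
for goals phrased as "every year from … on".  Success is non-strict
(output ≥ threshold counts).

## The demonstration fixture

The demo scenario is a two-population (sole 7D, plaice 7D), three-métier
(netting, beam trawl, an aggregate of lesser métiers), two-fleet reduction
of the Eastern Channel flatfish fishery.  Published quantities — recruitment
forcing and post-forcing values, fixed 2008–2010 TACs, F_msy / F_pa /
B_trigger reference points, the 15% TAC bound, the 5-year transition, the
24/27 cm minimum landing sizes, the [0, 0.5] discard-survival window — are
carried verbatim.  Everything else (weight- and maturity-at-age, growth
parameters, selectivities, efforts, catchabilities, initial abundances,
prices) is a **synthetic placeholder**, flagged `synthetic` in the YAML and
in the axis registry, chosen once so that the demo reproduces the stocks'
qualitative situation: sole hovering just above its 8000 t goal
(equilibrium SSB ≈ 8.4 kt at the reference), plaice overexploited and
mostly failing it.  Consequences:

* Tests passing on the demo validate the *machinery* (conservation,
  monotonicity, rule constants, pipeline behaviour), not any calibrated
  prediction for the real Channel stocks.
* Campaign-level results (sensitivity rankings, tree split values) are
  properties of the fixture, not of the published fishery model; the
  published variance fractions and split values would require the full
  calibrated database, which is out of scope here.

Toy fixtures with closed-form behaviour complete the test bed: a
single-cohort scenario (M = 0, full selectivity) whose annual catch is
(1 − e^(−F))·B₀ exactly; a "box-recovery" analytic stand-in whose success
region is the known box q₁ < 0.4 ∧ u₁ > 0.3; and a null fixture whose
labels are independent of every axis.  "1% label noise" in the box fixture
means each record's label is replaced, with probability 0.01, by a fair coin
flip (so ≈ 0.5% of labels actually flip); this keeps the true success rate
inside the box at 99.5%, strictly above the 99% robustness threshold, which
a symmetric 1%-flip definition would straddle exactly.

## Sensitivity estimators

The primary estimator is the binned correlation ratio, computed directly on
the LHS campaign: partition Xᵢ into equal-count bins (default
max(10, n/100)), then Sᵢ = Σ_b (n_b/n)(ȳ_b − ȳ)²/Var(Y), clipped to [0, 1].
It needs no paired design, so a single campaign feeds both the ranking and
the trees; its known upward bias is ≈ (bins − 1)/n per axis, negligible at
the default bin rule and irrelevant for ranking.  Interactions use the
analogous 2-D grid (default ⌈√(n/20)⌉ bins per dimension), with the
marginal terms computed on the same partition so Sᵢⱼ is exactly zero for
bin-additive responses.  A pick-freeze backend (Jansen estimator,
Sᵢ = 1 − mean((y_A − y_ABᵢ)²)/2V, n·(d + 2) model calls) serves as an
independent cross-check on analytic models.

Axis selection for the subtree stage: sort indices, cut at the largest
relative gap ("elbow"), ignoring gaps whose upper index is below 5% of the
top index — relative gaps between two near-zero indices are pure noise.
`top_k` and absolute-threshold policies are available; all-equal indices
select everything with a warning.

## Conditional trees

At each node, every candidate axis is tested for association with the
binary response via the absolute centred cross-product statistic
|Σ (xᵢⱼ − x̄ⱼ)(yᵢ − ȳ)|, standardized by its conditional null scale (i.e.
the absolute correlation).  P-values come from Monte-Carlo permutation of
the response (default 9999 draws, computed in chunked matrix products;
p = (1 + exceedances)/(1 + draws)) or from the asymptotic normal
approximation z = |r|·√(n−1) for large campaigns, and are Bonferroni
multiplied by the number of candidate axes.  The node becomes a leaf when
the smallest adjusted p-value exceeds α (default 0.05), when it is pure,
or when no split can give both children `min_leaf` (default 50) records.

The split point on the winning axis maximizes the standardized two-sample
statistic |Σ_left y − n_left·ȳ| / √(n_left(1 − n_left/n)) over midpoints
between consecutive distinct values; ties (within 1e−12) break toward the
cut closest to the axis median, then toward the smaller value — fully
deterministic.  Fitting is reproducible given the config seed (which drives
only the permutation draws).

**Robust leaves.**  A leaf is robust iff its success proportion is
≥ `success_threshold` (default 0.99 — strict purity is unrealistic because
box boundaries are estimated from finite samples) **and** its share of the
root's records is ≥ `min_weight` (default 5% — a "high-weight" requirement;
leaves failing only this are flagged "low weight").  Both thresholds are
configurable.

**Two stages.**  The main tree uses management axes only.  Each non-robust
main leaf whose records still allow a split gets a subtree on the sensitive
natural axes; robust subtree leaves, conjoined with their main-leaf
management box, become `RobustRegion`s.  Margins per natural axis are the
distance from the reference coordinate 0.5 to the nearest binding bound
(0.5 when unconstrained, 0 when the box excludes the reference), and are
also expressed as a percentage of the reference value through the axis
window: pct = distance · (upper − lower)/|reference| · 100, so a normalized
margin of 0.24 on a ±50% axis reads "24% of the reference value".
A region `contains_reference` iff 0.5 lies inside every natural-axis bound.

**Stability.**  `stability_analysis` refits the tree on B (default 500)
uniform subsets of ⌈frac·n⌉ records (default 95%), fingerprints each fit by
its depth-tagged breadth-first split-axis sequence (split values ignored;
leaves marked), reports the frequency table, and for the modal fingerprint
(ties broken lexicographically) the per-node mean split value and standard
deviation.

**Robustness horizon.**  α̂ = the Chebyshev distance (on natural axes, to
the reference 0.5) of the nearest failing record after restricting to an
optional management box; 0.5 — the full half-window — when no failure is
observed.  This equals the exhaustive definition (largest α such that every
record in the α-box succeeds) exactly on any finite record set, and is
tested against an independent brute-force scan.

## Numerical choices and degenerate inputs

* Balance checks use relative residuals against max(N, 1) to avoid
  0/0 on empty cohorts; any non-finite abundance aborts the run with a
  diagnostic naming population, year and month.
* Constant response or constant covariate columns get association p = 1
  (never selected); a constant output raises a "degenerate output" error in
  the sensitivity estimators (minimum 50 records enforced).
* The Baranov inversion brackets F in [0, 50] and returns the bracket top
  when returned-survivor inflation makes the observed catch unreachable.
* Zero-revenue years fall back to habit shares; zero-effort months simply
  apply natural mortality.
* Axis normalization round-trips to 1e−12; region bounds are clipped to the
  unit interval through the node boxes by construction.

## Problem sizes

The shipped test-bed sizes were chosen to make the statistical checks sharp
at desk scale: campaigns of 600–5000 records for pipeline and box-recovery
checks, n = 10⁴ for the additive-model oracle and LHS stratification,
n = 2×10⁴ for the Ishigami benchmark, 500 replicates for the null
calibration of the stopping rule and for the stability analysis (the
stability runs use the asymptotic association test; the permutation and
asymptotic backends agree on the separable fixtures).  The demonstration
campaign default is n = 5000.

## Known limitations

* One homogeneous zone per population: no spatial structure, migration or
  spatial management measures.
* Two explicit species; "other" species enter only through an aggregate
  métier, not as dynamic populations.
* Recruitment is a schedule (forced years + constant with a multiplier
  axis): no stock–recruitment feedback and no within-year variability.
* Economics is a single price per population; no costs, so the gravity
  model weighs revenue, not profit.
* The demo's life-history values are synthetic placeholders; absolute
  outputs of the demo are illustrative only.
* Trees are univariate and single-response; conflicting goals on several
  outputs must be analysed per output and intersected manually.
* Subtrees are grown from the single full-data main tree, not from a
  consensus tree over resampling replicates.
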