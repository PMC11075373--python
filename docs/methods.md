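# Methods

## Scope and model

`narcoscreen` screens dispensing records of three controlled drug
classes — appetite suppressants, zolpidem, propofol — for
overprescription signals by analyzing the bipartite structure of who
prescribes to whom. The pipeline is: safe-use exceedance filtering →
two-mode (hospital–patient) network → one-mode (hospital–hospital)
projection → centrality / community metrics → screening statistics
(top-1% list overlap, Narcotics Safety Index, prescription-pattern
quadrants, size/region strata). Exceeding a safe-use limit is treated
strictly as a *screening* signal: clinicians may exceed the standards
legitimately, which is precisely why the method looks at network
structure rather than violation counts alone.

## Safe-use rules and flagging semantics

Default rule set (all user-overridable):

| drug | dose cap | episode cap | cumulative cap | frequency cap |
|---|---|---|---|---|
| appetite suppressant | — | 28 d | 90 d / rolling 90 d | — |
| zolpidem | 10 mg/day | 28 d | — | — |
| propofol | — | — | — | 1 event / rolling 30 d |

Interpretation choices (the regulatory text is phrased in weeks/months):
"four weeks" = 28 days, "three months" = 90 days, "once a month" = one
event per rolling 30-day window. Rolling windows avoid calendar-month
length artifacts and are closed on the left, open on the right,
`[t, t+30)`.

* **DOSE** is per prescription: `daily_dose_mg > cap`. Whether
  concurrent prescriptions should be dose-aggregated per day is an open
  modelling question; we flag per prescription and expose the records so
  an aggregated re-analysis is possible downstream.
* **EPISODE** chains a patient–drug pair's prescriptions into treatment
  episodes with the standard persistence-window convention: a
  prescription continues the episode if it starts no more than
  `episode_gap_days` (default 7, configurable) after the episode's
  running coverage end (`date + days_supplied`). Every record of an
  episode whose total days supplied exceeds the cap is flagged.
* **CUMULATIVE** flags all records inside any anchored window
  `[dateᵢ, dateᵢ+90)` whose summed days supplied exceeds the cap.
* **FREQUENCY** flags a record that is the (k+1)-th or later event of
  its pair within a 30-day window starting at an earlier event.

The analysis subset keeps the **whole history** of every flagged
patient–drug pair (configurable to violating records only). Rationale:
the networks should reflect a flagged patient's complete visiting
pattern across hospitals, not only the violating visits; whether the
original extraction kept whole histories is not documented, so both
behaviours exist behind a switch.

Per-drug exceedance summaries use the population SD (sample SD is a
switch); at study scale the difference is negligible.

## Networks

The two-mode network is undirected and bipartite with edge weight =
prescription count of the (patient, hospital) pair. Patient and
hospital identifiers must live in disjoint namespaces (canonical files
use `P-`/`H-` prefixes); a collision aborts construction.

The one-mode projection is computed by sparse incidence-matrix
multiplication: weight(i,j) = `(BᵀB)ᵢⱼ` with `B` binary — the number of
*distinct shared patients* — and the diagonal discarded. This is the
standard reading of "projection by matrix multiplication"; a
prescription-weighted variant (`NᵀN` over the count matrix, summing
count products over shared patients) is available for sensitivity
analysis but is not the default. Hospitals sharing no patients remain
as isolated nodes so per-hospital reports stay complete.

## Metric conventions

* **Degree / weighted degree**: incident edge count and incident weight
  sum. Screening (the top-1% lists, quadrants, NSI) operates on the
  two-mode network restricted to hospital rows, where these equal
  distinct-patient and total-prescription counts.
* **Betweenness**: unnormalized, over unweighted (hop-count) shortest
  paths, each unordered pair counted once. Prescription counts are
  connection strengths, not distances, so they play no role in path
  finding.
* **Eigenvector**: dominant eigenvector of the weighted adjacency,
  computed per connected component and globally rescaled so the maximum
  over all nodes is exactly 1; isolated nodes score 0. Numerics: plain
  power iteration oscillates on bipartite components (spectra are
  symmetric ±λ), and an identity shift contracts at `(λ₁−1)/(λ₁+1)` —
  hopeless for heavily weighted components. Each component therefore
  runs a short `A²` burst whose Rayleigh quotient gives `λ̂₁` (exact on
  the mixed ± iterate), followed by power iteration of `A + λ̂₁I`
  (annihilating the −λ₁ branch) applied twice per sweep; convergence is
  declared at successive change < tol/100 (default tol 1e-8, max 1000
  sweeps). Screening networks occasionally contain components whose two
  leading eigenvalues agree to ~5·10⁻⁴ relative (two near-identical
  heavy hospital stars sharing one patient); no power scheme separates
  these in any reasonable budget, so such components are finished by a
  deterministic Lanczos solve (fixed start vector; dense below n = 6).
  `fallback=None` restores an explicit convergence error. Agreement
  with dense eigendecomposition is verified to 1e-8 in the test suite.
* **Communities**: Louvain (seeded, weighted, resolution 1.0 by
  default) via networkx. Modularity Q is evaluated by our own
  implementation of `Q = Σ_c [W_c/m − (d_c/2m)²]` and cross-checked in
  tests against both an elementwise double-sum and networkx's
  implementation; on ≤8-node planted-partition graphs Louvain is
  verified against exhaustive enumeration of all set partitions.
* **Diameter / average path length**: hop-count BFS over *connected
  node pairs only* — the screening networks are highly fragmented, so
  all-pairs statistics would be infinite; the connected-pair fraction
  is reported alongside for transparency.

## Screening layer

* Top-k% sets use `n_top = ceil(k/100 · n_hospitals)` (ceiling
  guarantees nonemptiness) with fully deterministic tie-breaking:
  primary metric descending, the other metric descending, then id.
  The overlap denominator is `n_top` ("x% of the two equal-size lists
  coincide").
* Quadrant labels (Low/High degree × Low/High weighted degree) reuse
  exactly the top-k% sets of the overlap statistic, keeping the two
  reports consistent. `LOW_D_HIGH_W` marks suspected overprescribers;
  `HIGH_D_HIGH_W` marks hubs that are high on both signals.
* NSI = weighted degree / degree = mean prescriptions per connected
  patient. Multiplying one hospital's edge weights by c multiplies its
  NSI by c and leaves its degree unchanged (tested). Degree-0 hospitals
  (only possible for injected isolated nodes) are excluded with a
  warning.
* Stratification reports per-category node shares, within-category edge
  counts and weighted-degree shares over the 10 hospital size codes or
  16 region codes (plus `UNKNOWN` for hospitals missing from the
  attribute sidecar — attributes are a reporting layer, never a
  filter). The cross-region edge fraction of the one-mode network is a
  doctor-shopping signal.

## Synthetic data generator

The real national data is not publicly available, so the generator
emulates its statistical structure; it is first-class, tested code.

* **Counts.** A patient receives 1 prescription with probability
  `single_rx_frac`, else `2 + NegBin(mean − 2, r)`; negative-binomial
  dispersion accommodates SD ≫ mean (propofol), which a Poisson model
  cannot. A per-patient budget (`max_rx_per_patient`, including
  overprescriber extras) tames the extreme tail, whose unbounded
  version made the SD of flagged-patient counts fluctuate several-fold
  across seeds.
* **Hospital choice.** With probability `hub_concentration` a visit
  goes to a fixed hub set (the first `n_hubs` ids — fixed rather than
  preferential attachment so hub identity is known to tests); otherwise
  it stays in the patient's home region with probability
  `region_locality`; otherwise any hospital. Shoppers draw a fresh
  hospital every prescription; other patients reuse a personal set of
  1–2 hospitals.
* **Overprescribers.** The last `frac_overprescriber_hospitals` of the
  id range (disjoint from hubs); each visit there spawns
  `Poisson(overprescriber_boost)` extra prescriptions — few patients,
  many prescriptions each, which decouples the weighted-degree ranking
  from the degree ranking.
* **Dates.** Uniform over the study window (2019-07-01..2021-06-30 by
  default). For frequency-capped drugs, dates instead follow a gap
  chain — each inter-event gap is 1–14 days with probability
  `frequency_violation_rate`, else ≥ 30 days — because perturbing and
  re-sorting uniform draws measurably distorted the realized rate
  (0.72 for a 0.8 target). Dose and duration violations are per-record
  Bernoulli draws above the respective caps.
* **Determinism.** All draws come from `numpy.random.Generator`
  seeded via `SeedSequence([seed, stream])`; identical profiles give
  identical datasets across runs and platforms.

### Presets and calibration

One archetype per drug class, with the count marginals targeted at the
reported flagged-patient summaries (mean/SD 5.6/6.3, 3.8/8.3, 7.9/27.2)
and the structural dials calibrated — by running the full pipeline at
n = 2,000 patients, 600 hospitals, multi-seed medians — until the
cross-drug orderings hold:

| | appetite_like | zolpidem_like | propofol_like |
|---|---|---|---|
| hub_concentration | 0.50 | 0.25 | 0.20 |
| region_locality | 0.40 | 0.90 | 0.85 |
| frac_shopper_patients | 0.35 | 0.05 | 0.10 |
| frac_overprescribers / boost | 0.005 / 4 | 0.002 / 4 | 0.02 / 25 |
| single_rx_frac | 0.30 | 0.45 | 0.50 |
| rx_count_mean / dispersion | 5.6 / 0.36 | 3.8 / 0.048 | 5.2 / 0.10 |
| violation rates (dose/dur/freq) | 0 / 0.45 / 0 | 0.3 / 0.2 / 0 | 0 / 0 / 0.8 |

Calibration notes: zolpidem needs a modest hub share (0.25) to show a
high top-1% overlap *and* high modularity simultaneously — with no hubs
the heavy-count tail alone tops the weighted-degree list and the
overlap collapses, which does not match the reported structure.
Propofol's preset lowers the multi-visit mean to 5.2 and caps records
at 500/patient because flagging selects against single-visit patients
and overprescriber inflation adds records, both of which raise the
realized flagged mean above the raw marginal.

Resulting 20-seed medians at n = 2,000: modularity 0.74 / 0.96 / 0.95
(zolpidem > propofol > appetite), top-1% overlap 0.83 / 0.67 / 0.20
(propofol far below both), average weighted degree 7.6 / 4.7 / 10.2
(propofol > appetite > zolpidem), propofol flagged SD/mean ≈ 2.9.

### What the generator does and does not emulate

It reproduces network *shapes and orderings* — hub concentration,
regional communities, overprescriber decoupling, overdispersed counts —
at thousands of patients, not the tens of millions of records of the
real system; absolute centrality magnitudes (e.g. betweenness of order
10⁹ in the real networks) are out of reach at this scale and are not
targets. Real per-drug dose/duration marginals beyond the count
summaries are unpublished; the generator's dose menus and duration
ranges are documented free parameters. Passing tests therefore show
the *method* behaves correctly and the qualitative cross-drug contrasts
are recoverable, not that any specific real hospital ranking would be
reproduced.

## Pipeline and reproducibility

`run_pipeline` executes filter → build → analyze → screen per drug,
logs entering/leaving counts per stage, and stamps every artifact with
the seed and a SHA-256 hash of the configuration. All stages are pure
functions of (inputs, config, seed) — Louvain is the only seeded
stochastic stage — so re-running with an identical configuration is
byte-identical (tested). Usage tables round prescriptions-per-patient
half-up to 2 decimals; where a source's prose and table differ in the
last digit (e.g. 4.71 vs 4.72), the arithmetic of the printed totals is
followed.

`scripts/acceptance.py` re-derives the headline quantities at n = 2,000
patients and 10 seeds per archetype (medians), a size chosen so the
whole script runs in seconds while the medians are stable; the test
suite's ordering checks use 20 seeds at the same n.

## Known limitations

* Episode/window semantics are one defensible reading of regulation
  phrased in weeks/months; the conventions are explicit and
  configurable but not the only possible ones.
* Betweenness and eigenvector conventions of the original desktop SNA
  tools are not fully documented; our conventions (unnormalized,
  hop-count paths; per-component max-normalized eigenvector) are stated
  instead and validated against first-principles oracles.
* The generator's violation processes are independent per record;
  real prescribing has temporal and clinician-level correlation the
  model does not attempt.
* Quadrant labels apply to hospitals within one drug network; the
  method does not place drugs themselves into quadrants.
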