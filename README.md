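# narcoscreen

Network-based screening for overprescription of medical narcotics in
national dispensing records.

Regulators who monitor controlled substances (e.g. through Korea's
Narcotics Information Management System, the US PDMPs, or similar
reporting systems) face a needle-in-a-haystack problem: raw prescription
counts flag large legitimate prescribers alongside genuinely problematic
ones. `narcoscreen` implements a social-network screening methodology
for three drug classes with distinct misuse profiles — appetite
suppressants, zolpidem and propofol — aimed at analysts and
pharmacoepidemiologists working with dispensing claims.

## Method

1. **Exceedance filtering.** Records are screened against the Standards
   for Safe Use of Medical Narcotics (SSUN): appetite suppressants
   limited to 28-day episodes and 90 cumulative days per rolling 90-day
   window; zolpidem to 10 mg/day and 28-day episodes; propofol to one
   administration per rolling 30-day window. The whole prescription
   history of every flagged patient–drug pair forms the analysis subset.
2. **Two-mode network.** An undirected bipartite graph joins patients
   and hospitals; edge weight = number of prescriptions of the pair.
   For a hospital, degree = distinct patients, weighted degree = total
   prescriptions issued.
3. **One-mode projection.** With `B` the binary patient×hospital
   incidence matrix, hospitals are joined with weight
   `(BᵀB)_{ij}` — the number of shared patients (diagonal discarded).
4. **Network metrics.** Degree / weighted degree, unnormalized
   betweenness and max-normalized eigenvector centrality, seeded Louvain
   communities with modularity `Q = Σ_c [W_c/m − (d_c/2m)²]`, and
   diameter / average path length over connected pairs.
5. **Screening statistics.** The overlap of the top-1% hospital lists by
   degree vs weighted degree separates "many patients" hubs from "many
   prescriptions per patient" outliers; each hospital gets a
   prescription-pattern quadrant and a **Narcotics Safety Index**

   NSI = weighted degree / degree

   — the mean number of prescriptions per connected patient — which
   ranks hospitals for inspection priority.

Because the real national data is legally restricted, the package ships
a seeded synthetic generator with one calibrated archetype per drug
class (`appetite_like`, `zolpidem_like`, `propofol_like`) reproducing
the qualitative cross-drug structure: fragmented regional communities
for zolpidem, centralized dispersed networks for appetite suppressants,
and heavy-tailed overprescriber-driven networks for propofol.

## Worked example

```bash
narcoscreen simulate --preset propofol_like --n-patients 2000 --seed 7 \
    --out rx.csv --hospitals hosp.csv
cat > demo.yaml <<EOF
records: rx.csv
attributes: hosp.csv
outdir: demo
seed: 7
EOF
narcoscreen run --config demo.yaml
```

This writes 7,476 synthetic propofol records, flags the SSUN
exceedances, builds both networks and produces `demo/summary.json`
containing (seed 7):

* 878 flagged patients, 7.05 prescriptions each on average with SD
  14.26 — the heavy-tailed count distribution typical of propofol;
* two-mode modularity 0.960 over 205 communities;
* top-1% degree/weighted-degree overlap 0.0 (n_top = 5): the hospitals
  collecting the most patients are *not* the ones issuing the most
  prescriptions — the propofol signature that motivates screening both
  lists;
* the top NSI hospital `H-0589` with degree 2 but weighted degree 166
  (NSI = 83): two patients receiving 166 prescriptions between them,
  exactly the "few patients, many prescriptions" pattern inspectors
  look for, labelled `LOW_D_HIGH_W` in the quadrant table.

The same stages are available individually (`simulate`, `filter`,
`build`, `analyze`, `screen`, `usage-table`) and as library functions:

```python
import narcoscreen as ns

records, population = ns.generate_dataset(ns.preset("zolpidem_like", seed=1))
flags = ns.flag_exceedances(records, ns.default_ssun_rules())
subset = ns.flagged_subset(records, flags)
G = ns.build_two_mode(subset)
print(ns.communities_louvain(G, seed=1).modularity)   # 0.954...
```

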