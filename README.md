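# tribscreen

Risk-based screening of pharmaceutical contaminants in surface waters.

Hundreds of pharmaceuticals are routinely detectable in streams, yet most
have no established water-quality criteria. `tribscreen` implements the
screening workflow used to triage such monitoring data: curate
left-censored concentration measurements, derive screening-level
benchmarks from in vivo ecotoxicity endpoints, compare measured
concentrations against high-throughput in vitro bioactivity data, and
rank chemicals and sites by their potential for biological effects. It is
aimed at water-quality scientists and ecotoxicologists who run multi-site
monitoring studies and need a reproducible, auditable path from raw
concentration tables to a prioritized chemical list.

## The method

**Censored-data curation.** Each measured concentration is judged against
its method detection limit (MDL) and method reporting limit (MRL):
values below the MDL become nondetects (carried as 0), values between
MDL and MRL are estimate-qualified, and severe analytical interference
voids the value. Detection frequencies are expressed as percentages of
*sites monitored* for each chemical, because analytical panel coverage
differs between sites.

**ECOTOX-style benchmarks.** In vivo endpoint records are classified
into three subsets — *No Effect* (NOEC/NOEL, ECx/LCx with x ≤ 10),
*Low Effect* (LOEC/LOEL, 10 < x < 50) and *Acute Effect* (EC50/LC50) —
and each non-empty subset yields a benchmark

```
benchmark = min subset concentration (µg/L) / (AF_Endpoint × AF_Species × AF_Persistence)
```

with AF_Endpoint = 10 (no/low effect) or 100 (acute), AF_Species = 1 for
subsets well characterized by test species (≥3 fish, ≥3 invertebrate,
≥1 plant species) and 2 otherwise, and AF_Persistence = 5 for chemicals
with a biodegradation half-life ≥ 8 weeks (never applied to the acute
subset). Admissible overall factors are exactly {10, 20, 50, 100, 200}.
The chemical-level benchmark is the minimum over its subsets.

**Hazard quotients.** For every sample,

```
EAR = concentration (µM) / ACC (µM)        per chemical–assay pair
EAR_Chem = Σ EAR                            over the chemical's included assays
TQ  = concentration (µg/L) / benchmark (µg/L)
```

where the ACC (activity concentration at cutoff) comes from a curated
in vitro assay table. A chemical exceeds at a site when the maximum
across that site's samples is strictly above the threshold
(EAR_Chem > 10⁻³, TQ > 0.1); it is **high priority** when either
exceedance occurs at ≥ 10 % of the sites monitored for its presence.
Chemicals with no screening value of either kind are reported in a gap
report — they can never be prioritized, which is itself a finding.

**Hydrology.** Summed per-sample concentrations are normalized by the
site mean, split into low-/increased-flow groups by the site median
discharge, and compared with a Welch two-sample t test; per-site median
sums are regressed on the wastewater-effluent fraction of streamflow
(Pearson).

A seeded synthetic-data generator (`tribscreen.synthetic`) produces
study-shaped bundles — 44 sites, two sampling tiers, three analytical
panels with unequal coverage, lognormal concentrations tied to effluent
fraction, left-censoring, sparse screening-value coverage — with known
ground truth for every downstream stage.

## Worked example

```sh
tribscreen simulate --seed 11 --out data
# wrote bundle to data: 44 sites, 266 chemicals, 124 samples, 116 detected

cat > run.yaml <<EOF
input_dir: data
out_dir: reports
log_level: WARNING
EOF
tribscreen run --config run.yaml
# pipeline complete: 6 priority chemicals, 55 chemicals without screening values; reports in reports
```

`reports/priority.csv` then holds the per-chemical exceedance tallies
(the high-priority rows shown):

```
cas          name       class                ear_exceed_sites  tq_exceed_sites  sites_monitored  priority
100000-10-0  pharm_000  Stimulant            24                24               44               True
100001-11-1  pharm_001  Antibiotic           21                21               44               True
100002-12-2  pharm_002  Antidepressant       27                27               44               True
100003-13-3  pharm_003  Analgesic            17                17               44               True
100004-14-4  pharm_004  Anticonvulsant       20                20               44               True
100005-15-5  pharm_005  Cardiovascular care  19                19               44               True
```

Each row counts the sites at which the chemical's maximum EAR_Chem or TQ
exceeded its threshold; 24 of 44 sites is 55 % ≥ 10 %, so the chemical is
priority. These six are exactly the chemicals the generator planted
(`data/truth.json`), and the run manifest records the hydrologic
statistics computed along the way — the low-flow group's normalized
median was 51 % above the increased-flow group (Welch t = 9.64,
p = 1.7 × 10⁻¹⁶) and per-site median sums correlated with effluent
fraction at r = 0.91 (p = 3.9 × 10⁻¹⁸), matching the generator's planted
1.5× low-flow multiplier and positive effluent slope.

The same stages are available as library calls (`generate_bundle`,
`derive_benchmark_table`, `compute_ear_table`, `sum_ear_chem`,
`compute_tq_table`, `site_flags`, `prioritize`, `hydro_summary`) and as
finer CLI commands (`tribscreen validate | benchmark | ear | prioritize |
sites | hydro`).

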