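# Methods

## Scope and data model

`tribscreen` operates on four tabular inputs (chemical catalog, site
metadata, sample metadata, per-sample measurements) plus two
screening-value tables (in vitro ACCs per chemical–assay pair; in vivo
ecotoxicity endpoint records). All joins are on CAS identifiers; names
are display-only. Units are fixed per table: ng/L in measurement files,
µg/L in endpoint and benchmark files, µM in ACC files.

## Curation of censored concentrations

A raw value below the method detection limit (MDL) is a nondetect and is
carried as 0; between the MDL and the method reporting limit (MRL) it is
kept but estimate-qualified; severe analytical interference voids the
value entirely, and minor interference downgrades a detect to an
estimate. The zeros are censoring markers, not observations: summary
statistics and sums use curated values, where nondetects contribute
nothing, and detection counts include estimate-qualified results.
Estimates count as detections throughout — including in hazard-quotient
computation — because a sub-MRL quantitation still carries concentration
information, and a minimum-based screening framework should not discard
it.

Quality-control samples never enter screening: blanks feed a diagnostic
report (chemical, number of blank detections, maximum value vs MRL) that
deliberately makes no adjustment to regular-sample data, and duplicates
exist for relative-percent-difference checks only. The monitored-chemical
set of a site is the union of analytical panels run on its regular
samples; detection and exceedance frequencies always use this
chemical-specific site count as the denominator, because panel coverage
is deliberately unequal across sites and a global denominator would bias
against chemicals on the narrower panels.

## Benchmark derivation

Endpoint records are classified by endpoint code: NOEC/NOEL and ECx/LCx
with x ≤ 10 form the No Effect subset; LOEC/LOEL and 10 < x < 50 the Low
Effect subset; x = 50 the Acute Effect subset. Records with x > 50 and
unrecognized endpoint codes are excluded rather than guessed — for a
minimum-based benchmark, exclusion is the conservative choice. A
record-level `excluded` flag supports manual relevance filtering
(media, exposure route, literature verification) without touching the
derivation logic.

Each non-empty subset yields `min_conc / (AF_Endpoint × AF_Species ×
AF_Persistence)`. Numerical conventions at the boundaries:

* Species counting uses distinct species names, not records.
* A half-life of exactly 8 weeks counts as persistent (non-persistence
  is defined as *shorter than* 8 weeks).
* A missing half-life defaults to the persistent factor (5) for
  non-acute subsets — conservative, and overridable
  (`missing_half_life_af`).
* The acute subset never receives a persistence factor, so the
  admissible overall factors are exactly {10, 20, 50, 100, 200}.

The chemical-level benchmark is the minimum over subset benchmarks,
which maximizes the resulting toxicity quotient. A chemical with no
qualifying endpoint has *no* benchmark — never 0 or infinity — and
surfaces in the gap report instead.

One property worth stating because it surprises: benchmarks are not
monotone in the endpoint set. Adding a record that completes the
3-fish/3-invertebrate/1-plant species criterion halves the overall AF
and therefore *raises* the benchmark. With the species-characterization
status held fixed, adding endpoints can only lower it; the test suite
asserts both facts.

## Hazard quotients and prioritization

Concentrations convert to µM as `ng/L / (1000 × MW)`. EARs divide the
molar concentration by each included assay ACC; per-chemical EAR_Chem
sums the EARs over included assays, recording the assay count for
coverage-bias diagnostics. Assay curation is consumed as an `included`
flag — which assays are appropriate is a judgment encoded upstream, not
a computation this package can repeat. TQs divide the µg/L concentration
by the chemical's minimum benchmark.

Site-level exceedance takes the maximum across the site's regular
samples (per-sample counting would inflate with unequal sample counts),
compared strictly (`>`) against the thresholds (EAR_Chem 10⁻³, TQ 0.1,
both configurable). A chemical is high priority when either exceedance
fraction is ≥ 10 % of its monitored sites (inclusive — "a minimum of
10 %"). A missing screening value renders as NA, distinct from 0: it can
never produce an exceedance, and a chemical lacking both value types can
never be prioritized — the gap report lists such detected chemicals
sorted by detection frequency, since they represent untestable risk.

Site summaries band each exceeding chemical by its maximum quotient into
(t, 10t], (10t, 100t] and (100t, ∞) tiers — the bands partition the
exceeding set — and report a site-level summed maximum EAR, computed as
max over samples per chemical–assay pair, then summed over pairs. The
per-chemical alternative (sum of maxima of EAR_Chem) is exposed as an
option (`per_chemical=True`).

## Hydrologic analyses

Only the panel run on every sample (M1) enters cross-site concentration
comparisons. Per-sample summed pharmaceutical concentrations are
normalized by the site mean (so each site's normalized values average
exactly 1), samples are classed low/increased flow by the site median of
mean daily discharge (for two-sample sites, lowest vs highest), and the
two pooled groups are compared with a Welch two-sample t test plus the
percent difference of group medians. Sites lacking discharge data, a
second sample, or any nonzero sum are omitted with a log entry.
Separately, per-site *median* summed concentrations are regressed on the
wastewater-effluent fraction of streamflow; Pearson r, its two-sided
p-value and the linear fit are reported.

**Known limitation — the Welch test is anti-conservative here.**
Normalizing by the site mean makes each site's low- and increased-flow
values sum to a fixed total, so the two groups are exactly negatively
correlated within site. The unpaired Welch variance estimate ignores
this, inflating the statistic by √(m/(m−1)) for m samples per site (√2
at two-sample sites); under a null generator the nominal 5 % test
rejects at roughly 11–12 % with the default two-tier design. This is a
property of the procedure itself, reproduced faithfully; the acceptance
suite documents it as a failing calibration check rather than hiding
it. The test's *power* to detect a planted 1.5× low-flow elevation
exceeds 0.97 at 40 sites. A paired test on per-site differences would be
calibrated, but it is not the procedure this package implements.

## Synthetic data generator

The generator emulates a two-tier, 44-site tributary monitoring study:
16 tier-1 sites with four quarterly samples, 28 tier-2 sites with one
low-flow and one increased-flow sample; 257 pharmaceuticals plus 9
contextual nonpharmaceuticals across three method panels (all sites run
M1; nested site subsets add the two M2 panels); wastewater-effluent
fractions uniform on [0, 0.45]; and a small number of field blanks and
duplicates.

Concentrations are lognormal — strictly positive and right-skewed, as
environmental concentration data are — with

```
log10 C = chemical offset + slope × wwtp_fraction + log10(multiplier)·[low flow] + noise
```

Defaults, with rationale:

| parameter | default | meaning |
|---|---|---|
| `log_conc_base` | 0.3 ng/L | median chemical's median concentration; calibrated so ~110 of 257 pharmaceuticals are detected, the study-shaped availability pattern |
| `chem_spread_decades` | 2.0 | spread of per-chemical occurrence levels; most chemicals sit below reporting limits, a few reach µg/L |
| `sample_sigma_decades` | 0.3 | ≈2× between-visit swing of summed concentrations at a site |
| `wwtp_slope` | 2.0 log10/unit fraction | ~1 decade of concentration across the observed effluent range |
| `low_flow_multiplier` | 1.5 | low-flow elevation; yields ~+50 % site-normalized medians |
| `acc_coverage`, `endpoint_coverage`, `benchmark_overlap` | 0.45 / 0.25 / 0.65 | sparse screening-value coverage: roughly half of detected chemicals end with no screening value of either kind |

MDLs are lognormal with quartiles near 13–80 ng/L (clipped to 2–270)
and MRLs sit 1.5–3× above. Censoring at the MDL is on by default and can
be disabled for calibration studies. Each table draws from its own
seeded substream (`default_rng([seed, table_key])`), so adding a table
never perturbs earlier draws and a fixed seed reproduces the bundle
byte-for-byte.

**Planted ground truth.** Endpoint records are generated by inverting
the benchmark arithmetic (minimum endpoint = target × overall AF, with
decoy subsets, an out-of-range EC90 and an excluded record sitting
where they must be ignored), so derived benchmarks equal their targets
to machine precision. ACC tables pin the minimum included assay at the
target with the remaining assays orders of magnitude higher, so the
assay sum stays dominated by the most sensitive assay. For chemicals in
`planted_priority`, the targets are computed from the *realized*
site-maximum concentrations such that the chemical exceeds both
thresholds by a 2× margin at ≥ 25 % of monitored sites; every other
covered chemical is constructed to stay a 2× margin *below* threshold
everywhere. Downstream prioritization must therefore recover exactly the
planted set — the acceptance suite verifies this across 50 seeds.
Infeasible plants (a planted chemical detected at too few sites, or no
screening-value coverage at all) raise a configuration error rather than
degrade silently.

**What the generator does not emulate.** Spatial correlation between
sites, seasonality beyond the two flow classes, correlated occurrence
across chemicals (real co-occurrence is driven by shared sources),
matrix effects on detection limits, and real chemical identities.
Passing tests on synthetic bundles therefore demonstrate the
correctness of the screening arithmetic and decision rules under known
truth — not that any particular real-world chemical ranking is
reproduced.

## Problem sizes in the test suite

Priority-recovery runs use the full 44-site default design over 50
seeds. The hydrologic operating-characteristic simulations (2000 null
bundles, 500 powered bundles) use a reduced 12-chemical, M1-only
generator profile — the hydrologic statistics depend only on the M1
summed concentrations, so the reduction changes nothing but runtime —
with the site/sample design and all hydrology parameters at study scale.
Oracle-equivalence checks run 200 random fixtures of up to 10 sites ×
10 chemicals × 20 assays/endpoints against brute-force loop
implementations.

## Limitations

* Assay curation, endpoint relevance filtering and half-life estimation
  are inputs, not computations; the package trusts their flags.
* The ≥10 %-of-sites rule is sensitive to the monitored-site denominator
  for chemicals on narrow panels (a chemical monitored at 10 sites needs
  a single exceedance).
* TQ values are not summed across chemicals (benchmark heterogeneity
  makes per-chemical minima incomparable), so mixture effects are out of
  scope.
* The Welch flow comparison is anti-conservative by construction, as
  described above.
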