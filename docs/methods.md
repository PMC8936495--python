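# Methods

## The index

`lakefi` measures *dynamic order* of a multivariate system state with the
discrete Fisher Information index. Observations (stations × variables) inside
a moving window are partitioned into states by an indistinguishability rule:
observation *i* joins the first previously founded state whose **founding
observation** is within the size-of-states tolerance on every variable
(|x_k(i) − x_k(ref)| ≤ sost_k for all k); otherwise it founds a new state.
Membership is tested against the founding observation — not a running centroid
and not all members — because it is the simplest deterministic reading of
"two points within sost are the same state", it makes assignments independent
of arrival order *within* a state, and ties (a point matching several states)
resolve to the earliest-founded state. The alternatives (centroid or
complete-linkage membership) change assignments only for chains of borderline
points and none is canonical; the greedy founding-point rule is frozen here.

From state probabilities p(s) (counts/window size) and amplitudes
q(s) = √p(s), taken in state first-appearance order and padded with a single
zero amplitude at each end,

    FI = 4 Σ_{s=0..m} (q(s) − q(s+1))².

The zero padding fixes the otherwise undefined sequence ends and gives the
conventional range [0, 8]: one state → (0,1,0) → FI = 8; m equiprobable states
→ FI = 8/m (only the edge differences are non-zero). FI is reported per window
and anchored at the window's first (nearest-to-reference) station; the anchor
choice is a plotting convention with no effect on any statistic computed from
the series.

## Spatial ordering

The windowed statistic needs a 1-D route through the landscape. Stations are
sorted by Haversine distance (sphere radius 6371.0 km) from the coordinate-wise
minimum (min latitude, min longitude) of the station set — a synthetic
south-west corner, normally not itself a station. Distance ties break by
lexicographic station id, so the ordering is a deterministic permutation,
invariant to input row order. When two datasets share the station network the
ordering is computed once and reused, so window *k* covers the same lakes in
both; the reference corner is computed once for all years (the station set is
fixed).

## Size of states (sost)

If measurement uncertainties are unknown, sost is estimated from a stable
reference period: the ordered rows are cut into consecutive **disjoint**
windows of the analysis window size; each window's per-variable sample sd is
rescaled by that variable's overall sd (so no large-magnitude variable
dominates; a raw-mean mode is available); the window minimising the mean
rescaled sd is "least variable", and sost = multiplier × that window's
(unscaled) per-variable sds. The multiplier defaults to 2.0, the common
stable-period convention. A variable constant everywhere gets tolerance 0
(identical values still co-bin) with a warning. Disjoint rather than sliding
estimation windows keep the candidate sds independent; with sliding windows
the minimum is nearly unchanged but costs |rows| times more sd evaluations.

By default the pipeline estimates sost once per dataset from the **first
survey year** and holds it fixed. Holding the tolerance fixed is what makes
temporal change in spatial variance visible: re-estimating sost each year
rescales the tolerance with the noise and normalises the trend away. A pooled
mode (all years) and an explicit reference year are available.

Missing data: a station-year row with any missing variable is dropped from
that year's ordered sequence (listwise per year) with a logged count; years
left with fewer rows than the window are skipped with a warning.

## Summary statistics and tests

Per year and dataset: μFI (mean), σFI (sample sd, n−1), cvFI = σFI/μFI
(reported missing when μFI = 0). A year is **stable** when all three hold
strictly: μFI above the study-period mean of μFI, σFI below the mean σFI, and
cvFI below the mean cvFI. (The three-way conjunction uses "below" for cvFI —
lower dispersion means more stable — consistent with every use of cvFI as a
variability measure here.)

Kendall tau-b with tie correction in both margins serves two roles: per-year
congruence between two datasets' paired window FI series, and monotone trend
tests of yearly scalars (typically cvFI) against calendar year. P-values use
the tie-corrected normal approximation of the concordance statistic
(`scipy.stats.kendalltau`, `variant="b"`, `method="asymptotic"`); at the
study's n (≥ 23) the approximation is standard. A margin that is entirely tied
leaves tau undefined and is signalled with a warning and NaN. Significance
defaults to α = 0.05 and is reported, never silently filtered.

The boundary partition splits stations by region label (or a latitude
threshold) and re-runs the full pipeline independently on each side — fresh
ordering, windowed FI, summaries, trends — reusing the global sost by default
so the two regimes are binned on a common scale (per-regime re-estimation is a
flag). The per-regime window is min(configured, side size − 1) — the −1 keeps
at least two windows per year so σFI stays defined — with a warning when it
shrinks; a side with fewer than 3 stations is skipped.

`boundary_window_zones` classifies windows for ecotone contrasts: *boundary*
if the anchor is within one decay length of the boundary latitude, *interior*
if **every** member is farther than that, else *shoulder*. Excluding shoulder
windows from the interior class matters: windows anchored just outside the
zone still contain inflated-noise members and would otherwise contaminate the
interior baseline.

## Synthetic landscape

The generator emulates the statistical structure of a two-regime boreal lake
monitoring network; all draws flow from one integer seed (same seed →
byte-identical tables).

* **Stations** — 31 uniform in a northern box (60.1–66.5°N) and 54 in a
  southern box (56.0–59.9°N), separated by a hard ecotone boundary at 60°N;
  longitudes 12.5–18.5°E. Counts, boxes and boundary are configurable.
* **Abiotic field** — 10 physicochemical variables on plausible natural
  scales, driven by 2 latent spatial factors plus idiosyncratic noise
  (sd 0.2), a shared year×regime intercept (sd 0.3), and an alternating-sign
  north–south mean offset (1.0 factor-sd). Noise is an episodic Gaussian
  mixture (8% of draws 4× larger) — environmental fluctuations are spiky, and
  the spikes let the tolerance sit above the quiet fluctuation scale.
* **Boundary variance** — every noise scale is multiplied by
  1 + 0.7·exp(−|lat − 60|/0.75°): elevated variability in the transition zone.
* **Temporal trend** — all noise scales shrink by ×0.93 per year: declining
  spatial variance over 1996–2018.
* **Community** — 200 taxa. 40 cosmopolitan taxa have log-normal biovolumes
  whose log10 abundance tracks one abiotic latent factor with a response
  coefficient that interpolates linearly from 0.8 (1996) to 0.1 (2018) — the
  decoupling — plus an independent community-wide factor and taxon noise.
  160 specialists are range-limited to one regime with range edges jittered
  ±0.1° around the boundary and a fixed detection-level biovolume where
  present; their structural zeros supply the matrix's sparsity (~40% zeros).

Defaults were frozen after a one-time power calibration so the three planted
patterns are recovered with high power at the design scale (85 stations ×
23 years, window 10): over 50 seeds the cvFI decline is detected (negative
tau, p < 0.05) in ≥95% of runs with correct nominal level when the trend is
off; the abiotic–biotic tau series trends negative in ≥95%; and
boundary-anchored windows show lower mean FI and higher within-year FI spread
than interior windows on seed average.

What the generator does **not** emulate — and what passing tests therefore do
not establish about real data: real chemical ranges beyond order-of-magnitude
plausibility; seasonality (single August-style survey per year); observation-
level random absences in the community (zeros are structural range limits —
random per-station zeros interact degenerately with the all-variables
co-binning rule when a taxon's tolerance is estimated as 0); gradual range
edges (specialist abundance is constant where present); and spatial
autocorrelation beyond the boundary kernel. Conclusions about real monitoring
data require the real tables.

## Numerical choices and degenerate inputs

* Comparisons use exact `≤` against sost; no epsilon. Affine invariance
  (rescaling a variable together with its tolerance) holds exactly up to
  floating-point rounding of the products.
* p(s) must sum to 1 within 1e-9 or the FI evaluation raises.
* Window/step/size misconfigurations raise sizing errors naming the numbers;
  missing values surviving the listwise policy raise data errors.
* All-identical windows give FI = 8 by construction; FI = 8 ⇔ one state.
* Pipeline outputs are deterministic given config + inputs + seed; every CSV
  starts with a `# columns:` schema comment; the manifest records config and
  package version.

## Known limitations

* The sost estimator's minimum-over-windows is biased low (≈0.8× the quiet
  sd at the default window count), which caps attainable co-binning; with the
  2.0 multiplier interior windows of a stationary Gaussian field sit in a
  partial-order regime rather than at FI = 8. The trend and boundary analyses
  operate through this regime; absolute FI levels should not be compared
  across window sizes or multipliers.
* Greedy founding-point binning is order-dependent for borderline chains;
  alternative membership rules would shift absolute FI slightly.
* Kendall p-values are asymptotic; for very short series (< 10 windows/years)
  exact enumeration would be preferable.
* The per-regime re-run inherits the global sost by default; regimes with very
  different measurement scales may warrant per-regime re-estimation.
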