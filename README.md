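# lakefi

Fisher Information (FI) analysis of spatial order and variability in lake
monitoring landscapes.

Long-term monitoring networks sample many waterbodies across a landscape, each
characterised by multivariate observations (water chemistry, plankton community
composition). A recurring question in resilience analysis is whether the
landscape behaves as one coherent regime or several, whether variability is
elevated near regime boundaries (ecotones), and whether spatial variability is
rising or falling over time — a potential early-warning signal for regime
shifts. `lakefi` answers these questions with the discrete Fisher Information
index of dynamic order, computed in a moving spatial window along a
distance-ordered station sequence, for analysts of spatially replicated
environmental monitoring data.

## Method

1. **Spatial ordering.** Stations are ordered by great-circle (Haversine)
   distance from a reference corner — the dataset's minimum latitude and
   longitude:

   d = 2r·arcsin √( sin²(Δφ/2) + cos φ₁ · cos φ₂ · sin²(Δλ/2) ),  r = 6371 km.

2. **State binning.** Within a window of consecutive stations, observations
   are grouped into discrete *states*: two observations are indistinguishable
   (one state) when they differ by at most a per-variable tolerance — the
   *size of states* (sost) — on **every** variable. The sost is estimated as a
   multiplier (default 2.0) times the per-variable standard deviations of the
   least-variable window of a stable reference period.

3. **Fisher Information.** With state probabilities p(s) and amplitudes
   q(s) = √p(s) in state first-appearance order, padded with one zero at each
   end,

   FI = 4 Σₛ (q(s) − q(s+1))²  ∈ [0, 8],

   FI = 8 exactly when all window members share one state (perfect order);
   dispersal over many states drives FI toward its disordered floor.

4. **Summaries and trends.** Per year and dataset, the windowed FI series is
   reduced to μFI, σFI and cvFI = σFI/μFI. A year is *stable* when μFI is above
   and σFI and cvFI below their study-period means. Kendall tau-b (tie
   corrected) quantifies the congruence between two datasets' window FI series
   within each year, and monotone trends of cvFI against calendar year; the
   pipeline repeats everything on the two sides of a regime boundary.

A fully parameterised synthetic lake-landscape generator
(`lakefi.simulate`) provides reproducible two-regime test data with boundary
noise inflation, a declining spatial-variance trend and abiotic–biotic
coupling that weakens over years.

## Worked example

```bash
lakefi simulate --out-dir demo --seed 1
lakefi run --abiotic demo/abiotic.csv --community demo/community.csv \
           --stations demo/stations.csv --out-dir demo/out
```

or equivalently in Python:

```python
import lakefi as lf

abiotic, community, stations = lf.generate_landscape(lf.SyntheticConfig(seed=1))
res = lf.analyze_landscape({"PC": abiotic, "PHYTO": community}, stations)

print(res.summaries.query("dataset == 'PC' and year == 1996")
      [["mean_fi", "sd_fi", "cv_fi"]].round(3).to_string(index=False))
print("PC-PHYTO tau (1996):", round(res.cross_tau.set_index("year").loc[1996, "tau"], 3))
print("PC cvFI trend tau:",
      round(res.trends.query("dataset=='PC' and scope=='all'")["tau"].iloc[0], 3))
```

prints

```
 mean_fi  sd_fi  cv_fi
    2.94  1.049  0.357
PC-PHYTO tau (1996): 0.331
PC cvFI trend tau: -0.763
```

In 1996 the physicochemical windows average FI ≈ 2.9 with σFI ≈ 1.05 —
substantial spatial disorder and heterogeneity across the landscape. The
window FI series of the two datasets agree moderately (τ ≈ 0.33): where the
chemistry is disordered the plankton community tends to be as well. Over
1996–2018 the spatial coefficient of variation declines strongly
(τ ≈ −0.76, p < 0.05): the landscape becomes more orderly and homogeneous,
while per-window maps (`fi_map_*.png`) show persistently lower FI in the
ecotone zone between the two regimes.

The `run` pipeline writes the station ordering, per-window FI tables, yearly
summaries with stability flags, tau tables (between-dataset congruence per
year; cvFI-vs-year trends overall and per regime), plots, and a JSON manifest.

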