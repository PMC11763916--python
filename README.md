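# ratioflux

Analysis toolkit for the **daily RATIO** — the ratio of daytime
(photosynthetic-period) to whole-day latent-heat flux (vapor flux,
evapotranspiration) measured by eddy-covariance (EC) towers:

```
RATIO = Σ LE(daytime half-hours) / Σ LE(all 48 half-hours)   ∈ (0, 1)
```

Energy, water and carbon exchange are produced by the same coupled
biophysical and biogeochemical processes, so this single dimensionless
statistic of a tower's day is tightly coupled with the magnitudes of the EC
variables themselves. Two empirical properties follow and drive everything
in this package:

1. **Coupling.** Binned over the RATIO axis, 15 EC variables (LE, NEE and its
   day/night parts, RECO day/night, GPP-day, inherent water-use efficiency
   WUEi-GPP = GPP-day × VPD / LE-day, Ta-day/Ta-night, Rn, VPD, P, CO2, SWC)
   follow tight curves: flux and energy variables rise to a peak at RATIO
   ≈ 0.93–0.95 and fall beyond it; matter variables (P, CO2, SWC) decline
   roughly linearly.
2. **Transferability.** At equal RATIO the same variable has nearly the same
   magnitude in any two ecosystems, so coupling curves fitted in one region
   predict daily values elsewhere from nothing but the target's RATIOs.

On top of these the package estimates per-RATIO-bin **temporal trends**: in
each of 50 sub-intervals, bootstrap samples of 4000 site-day records (each
containing at least 10 distinct sites) are regressed against year, and the
signed coefficient r = sign(slope)·√R² is accumulated; |r| > 0.47 marks a
significant trend over 18 years at α = 0.05. The Ta-day trend curve changes
sign at RATIO ≈ 0.55 and peaks at ≈ 0.90, which yields a simple rule for the
surface-temperature effect of vegetation change (greening raises the RATIO):

| mean daily RATIO | greening effect        |
|------------------|------------------------|
| < 0.75           | strong warming         |
| 0.75 – 0.90      | weak warming (minimal) |
| > 0.90           | strong cooling         |

Browning flips the sign. A random-forest screen ranks nine environmental
contributors to the RATIO (day length, LAI, ΔT, P, SWC, CO2, P/PET, VPD, WS).

Because the full FLUXNET2015 archive cannot be redistributed, the package
ships a first-class synthetic flux-network generator
(`ratioflux.synthetic`): multi-site, multi-year 30-min records in the
FLUXNET2015 FULLSET dialect with latitude-driven day length, prescribed
coupling curves, per-RATIO temporal trends, an LAI→RATIO link, site effects
and an engineered share of out-of-(0,1) days — with a machine-readable truth
record, so every stage of the pipeline is testable offline against known
ground truth.

## Worked example

```python
from ratioflux import SyntheticConfig, filter_ratio, coupling
from ratioflux.pipeline import simulate_summaries

summaries, sites, truth = simulate_summaries(SyntheticConfig(seed=1))
kept, discarded = filter_ratio(summaries)
print(f"site-days: {len(summaries)}  discarded: {100*discarded:.1f}%")

binned = coupling.bin_by_ratio(kept, "gpp_day", n_bins=200)["all"]
model = coupling.fit_coupling_curve(binned)
peak, _ = coupling.peak_location(model)
print(f"GPP-day coupling R^2 = {model.goodness:.3f}, peak at RATIO = {peak:.3f}")
```

prints

```
site-days: 197220  discarded: 23.5%
GPP-day coupling R^2 = 1.000, peak at RATIO = 0.938
```

197220 site-days come from 30 sites over 1997–2014; 23.5% of computed daily
ratios fall outside (0, 1) (negative night-time LE under condensation, polar
night/day) and are discarded — the generator's default operating point. The
daytime-GPP coupling curve fitted on 200 RATIO bins recovers the network's
prescribed peak (0.94) to within one bin.

The same stages are available from the shell:

```bash
ratioflux simulate --n-sites 30 --seed 1 --out raw/
ratioflux compute-ratio --input raw/ --out summaries.csv
ratioflux fit-coupling --summaries summaries.csv --variable gpp_day --out model.json
ratioflux trends --summaries summaries.csv --variable ta_day --out trend.csv
ratioflux classify --mean-ratio 0.94 --change greening
```

The last command prints

```json
{
 "mean_ratio": 0.94,
 "change_sign": "greening",
 "effect": "strong cooling",
 "rationale": "gradually accelerating cooling above 0.90",
 "flagged": false
}
```

— a tropical-zone mean RATIO of 0.94 sits on the falling limb of the Ta-day
trend curve, so vegetation increase there cools the land surface.

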