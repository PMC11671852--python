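# firerecov

Post-fire vegetation **greenness recovery** analysis for fire-prone
Mediterranean-type ecosystems, built around satellite vegetation-index
time-series (MODIS-like 16-day EVI composites, 2001–2022) and monthly
burned-area maps. The package estimates, per pixel and per fire event, how
fast burned vegetation returns to its ideal seasonal state, and analyses how
that speed is modulated by fire severity, pre-fire vegetation condition and
post-fire climate anomalies — with a first-class synthetic-scene generator
that provides known ground truth for every stage.

It is aimed at fire ecologists and remote-sensing scientists who want a
tested, reusable implementation of the time-series (rather than
space-for-time) approach to recovery estimation.

## The model

For each pixel, the *Gorgeous Year* `GY(m)` is the maximum monthly EVI
observed at calendar month `m` over the record — the pixel's ideal annual
cycle. The loss of greenness is the departure from it,

```
y(t) = EVI(t) − GY(month(t)),        y ∈ [−1, 0].
```

Assuming the recovery rate of greenness is proportional to the remaining
loss, `dy/dt = −b·y`, the post-fire deficit decays exponentially,

```
y(t) = a·e^(−b·t),
```

where `a` (the minimum of `y` at/after the fire) measures **fire severity**
and `b` (month⁻¹) is the **recovery rate**. `b` is estimated as minus the
slope of an OLS regression of `ln(−y)` on months-since-minimum, fitted over
candidate windows of 2–5 years; the window with the best adjusted r² wins,
and fits with adjusted r² < 0.25 are screened out. Derived quantities:

- characteristic recovery time `1/b` — e.g. `b = 0.10 month⁻¹` → 10 months;
- relative severity `a_REL = |a| / GY_MEAN` (0 = no severity, unbounded above);
- per-pixel event contrast `b_DIFF = b₂ − b₁` for pixels burned twice
  (≥ 4 years apart, in-season, burn-date uncertainty ≤ 7 days), tested with a
  Wilcoxon signed-rank test and stratified by land-cover category
  (BL/NL/MF/Shb/TW/Gs/Cp/Oth aggregated from the 37-class UN-LCCS coding);
- quantile regression (τ = 0.01, 0.99) of `b` on `a_REL` for the
  severity–recovery envelopes, and seasonal standardized climate anomalies
  (z-scores of 3-month precipitation totals and temperature means) over the
  four post-fire quarters.

## Worked example

```python
from firerecov import RunConfig, SimConfig, run_pipeline

cfg = RunConfig(
    sim=SimConfig(grid_rows=10, grid_cols=10, b_true_range=(0.04, 0.10), seed=42),
    out_dir="run", seed=42,
)
res = run_pipeline(cfg)

valid = res.fits[res.fits["valid"]]
print(f"valid fits: {len(valid)} / {len(res.fits)}")
print(f"median recovery rate b: {valid['b'].median():.3f} month^-1")
print(f"median characteristic time 1/b: {valid['t_char'].median():.1f} months")
print(f"median relative severity a_REL: {valid['a_rel'].median():.2f}")
w = res.wilcoxon[res.wilcoxon.landcover == "ALL"].iloc[0]
print(f"paired contrast: median b_DIFF = {w['median_b_diff']:+.4f}, "
      f"Wilcoxon p = {w['p_value']:.3f} (n = {int(w['n'])})")
```

prints

```
valid fits: 200 / 200
median recovery rate b: 0.065 month^-1
median characteristic time 1/b: 15.4 months
median relative severity a_REL: 0.52
paired contrast: median b_DIFF = -0.0061, Wilcoxon p = 0.016 (n = 100)
```

All 100 twice-burned pixels of this 10×10 scene yield valid fits for both
events. The median fitted rate, 0.065 month⁻¹, sits mid-range of the
generative truth (`b_true ~ U(0.04, 0.10)`), i.e. a characteristic recovery
time of about 15 months. The paired contrast is a property of this
particular truth draw (rates are drawn independently per event), and the
Wilcoxon test flags its nonzero median. Every intermediate product (scene,
monthly cube, fit table, pair groups, climate profiles, run report) is
written under `out_dir`.

The same stages are available from the shell:

```
firerecov simulate --out scene/ --seed 7
firerecov preprocess --in scene/evi.nc --out monthly.nc
firerecov detect-fires --burns scene/burns.nc --season mediterranean \
    --out pairs.csv --start-year 2001
firerecov fit-recovery --evi monthly.nc --pairs pairs.csv \
    --landcover scene/landcover.nc --out fits.csv
firerecov analyze-modulation --fits fits.csv --out mod/
firerecov analyze-climate --climate scene/climate.nc --pairs mod/groups.csv \
    --out clim/ --start-year 2001
firerecov run --out run/ --seed 7     # everything at once
```

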