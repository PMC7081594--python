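# mycometry

Community metrology for wood-degrading fungi: quantify colony radial
extension rates from daily leading-edge traces, normalize them to
**Relative Extension Units (REU)** against a same-lab reference condition,
and analyze interlaboratory variability and substrate correlations. A
first-class synthetic-data generator emulates multi-lab trace studies and
traced-plate photographs with ground truth, so the whole pipeline is
testable end to end without any experimental data.

## The problem

Plate-based radial extension assays are the workhorse performance measure
for wood-degrading fungi (*Ganoderma lucidum*, *Trametes versicolor*,
*Phanerochaete chrysosporium*, *Schizophyllum commune*, ...): a colony is
started from a 5 mm inoculation plug on a 9 cm dish, its leading edge is
traced with a marker every 24 h for ~5 days, and the traces are measured
along three equally spaced axes. The **radial extension rate** `v`
(mm/day) is the slope of one ordinary least-squares regression

```
r(t) = v·t + b + ε,
```

pooling all axes' daily radii of a plate into a single fit. Rates below
2 mm/day are flagged as being at the limit of quantification of the
technique (flagged, never dropped).

Absolute rates are strongly affected by lab-specific extrinsic factors
(humidity, media preparation, tracing technique) that act roughly
multiplicatively. The REU statistic cancels them: each plate's rate is
divided by the same lab's mean rate for a reference condition —
*G. lucidum* on the locally-sourced reference substrate —

```
REU = v_plate / mean(v_reference plates, same lab),
```

so a lab-wide multiplier drops out of the ratio. Interlab agreement is
scored by the coefficient of variation (CV, sample SD / mean) across labs
of per-lab means, and by the percent CV reduction
`100·(1 − CV_REU / CV_raw)`.

## Worked example

```python
from mycometry import (demo_interlab_config, simulate_interlab_study,
                       fit_all_plates, compute_reu, interlab_variability)

config = demo_interlab_config(seed=3)          # 5 labs x 4 fungi x 2 sources
traces, truth = simulate_interlab_study(config)
rates = fit_all_plates(traces)                 # pooled 3-axis OLS per plate
local = rates[rates["substrate_source"] == "local"]
reu = compute_reu(local, "G_lucidum", "local")
print(interlab_variability(reu, by="organism", source="local").round(3))
```

prints

```
          organism  n_labs  cv_raw  cv_reu  cv_reduction_percent
0        G_lucidum       5   0.156   0.000               100.000
1  P_chrysosporium       5   0.181   0.062                66.024
2        S_commune       5   0.185   0.050                72.980
3     T_versicolor       5   0.184   0.057                69.155
```

Raw across-lab CVs of 16–19 % collapse to ≤ 6 % after REU normalization:
the simulated lab effects are multiplicative, which is exactly the
structure the ratio removes. The reference organism's REU is 1 per lab by
construction, so its across-lab REU CV is 0.

The same workflow runs from the shell:

```
mycometry simulate --seed 3 --out sim/
mycometry quantify --traces sim/traces.csv --out rates.csv --summary-by organism
mycometry reu --rates rates.csv --out reu_out/
mycometry report --mode interlab --seed 3 --out report/
```

Plate photographs are handled by `mycometry render` (synthetic traced
plates with ground truth) and `mycometry measure-image`, which calibrates
the pixel scale from the detected dish rim (9 cm diameter), casts three
rays from the plug edge, and reads each day's trace crossing to sub-pixel
precision.

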