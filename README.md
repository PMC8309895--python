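# thermoskin

Contact skin-temperature (T<sub>sk</sub>) sensors change the temperature of
the surface they measure: a taped-on sensor insulates the skin beneath it,
while a bare metal-bodied logger acts as a fin and cools it. `thermoskin`
quantifies both effects on a benchtop *skin simulant* — a silicone slab with
skin-like thermal properties, heated from below by a temperature-stepped
plate — and compares sensor families against each other at matched surface
temperatures. It is aimed at thermal physiologists and wearable-sensor
engineers who need to characterize measurement error without running human
trials for every sensor iteration.

Because no physical rig is required, the package ships a physics-based
generator (a two-column, one-dimensional thermal-resistance network plus
first-order transients, sensor noise and logger quantization) that emulates
the full experimental design — six surface-coverage conditions × five
replicates × two air velocities, each run stepping the plate through five
30-minute temperature steps — together with a rest/cycling human-trial
generator with a sweat-onset step in skin humidity.

## The quantities at the core

With T<sub>sen</sub> the sensor reading, T<sub>d</sub> the *disturbed*
surface temperature directly beneath the sensor/tape, and T<sub>u</sub> the
matched *undisturbed* (bare) surface temperature:

```
disturbance   = T_d  − T_u
bias from T_d = T_sen − T_d
bias from T_u = T_sen − T_u        (= bias from T_d + disturbance, exactly)
```

Both references are measured just below the surface and extrapolated to the
surface by Fourier's law using a second embedded sensor,
`T_surface = T_z1 + (T_z1 − T_z2)·z1/(z2 − z1)`. Disturbance and bias grow
linearly with the surface-to-air temperature gradient, so condition
summaries are produced at a fixed 31 °C sensor reading by fitting each
replicate's bias against T<sub>sen</sub> and evaluating the line there
(mean across replicates, unadjusted 95 % t-interval).

Inter-sensor comparisons use inverse prediction: each sensor is regressed
on the undisturbed reference (`Y′ = b0 + b1·X`), seven anchor temperatures
matching the human trial's summary periods are computed from the
custom-thermistor fits, and each sensor's reading at every anchor is
recovered as `X′ = (Y′ − b0)/b1`.

## Worked example

```python
import thermoskin as tk

bundle = tk.run_rig_suite(master_seed=1)   # full 60-run design, ~2 s
t1 = bundle.table1
print(t1[t1.form != "disturbance"].round(2).to_string(index=False))
```

```
    coverage  air_velocity         form  evaluated_at  mean  ci_low  ci_high  n
 custom+tape           0.2 bias_from_Td          31.0 -0.26   -0.26    -0.26  5
 custom+tape           0.2 bias_from_Tu          31.0 -0.14   -0.14    -0.14  5
  grant+tape           0.5 bias_from_Td          31.0 -2.05   -2.05    -2.05  5
ibutton+tape           0.5 bias_from_Tu          31.0 -1.58   -1.59    -1.58  5
ibutton_only           0.5 bias_from_Td          31.0 -2.28   -2.29    -2.28  5
ibutton_only           0.5 bias_from_Tu          31.0 -3.16   -3.17    -3.16  5
```

(abridged; 16 rows in total). Read: at a sensor reading of 31 °C the
un-taped iButton at 0.5 m·s⁻¹ air velocity reads 2.28 °C cooler than the
surface beneath it and 3.16 °C cooler than the same surface left
undisturbed, while the silicone-encapsulated custom thermistor stays within
a few tenths of a degree of both references. The `disturbance` rows of the
same table carry the local warming/cooling each coverage causes, and
`bundle.comparison` holds the model-vs-human inter-sensor difference table.

The same pipeline is scriptable from the shell:

```sh
thermoskin analyze-rig --seed 1 --out-dir results/
thermoskin analyze-trial --seed 1 --participants 14 --out-dir results/
```

## Layout

| module | contents |
| --- | --- |
| `thermoskin.network` | thermal-resistance network, material/coverage/sensor/rig types |
| `thermoskin.synthetic` | rig-run and human-trial generators |
| `thermoskin.calibration` | steady-window detection, linear sensor corrections |
| `thermoskin.steady_state` | minutes-21–29 step means, Fourier surface correction |
| `thermoskin.disturbance` | disturbance/bias, gradient fits, fixed-point summaries |
| `thermoskin.comparison` | inverse-prediction inter-sensor comparison |
| `thermoskin.trial` | weighted-mean T<sub>sk</sub>, vapor pressure, sweat onset |
| `thermoskin.pipeline`, `thermoskin.cli` | orchestration, CSV/manifest I/O, CLI |

See `docs/methods.md` for the model, its assumptions, and parameter
choices.
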