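# dropmetry

Automated metrology for bioprinted sessile droplets, plus a regression
harness that predicts droplet volume from bioprinting parameters.

Droplet-based bioprinting dispenses cell-laden hydrogel (bioink) droplets
onto a hydrophobic substrate; downstream applications such as organoid
culture demand tight control of droplet volume. `dropmetry` addresses both
halves of that control loop:

1. **Measurement** — a side-view photograph of a sessile droplet is reduced
   to a circle (the droplet profile) and a horizontal substrate line
   *y = a*. From the two intersection points the base diameter *D* and the
   contact angle *θ* follow, and the volume is the spherical-cap closed
   form

   V = (π D³ / 24) · (2 − 3 cos θ + cos³ θ) / sin³ θ

   with *D* in mm and *V* in µL. Pixel measurements are converted to mm
   through a calibration object of known length (by default a 10 mm
   micro-ruler spanning 1028 px, i.e. 0.009728 mm/px).

2. **Prediction** — five regression models (decision tree, random forest,
   polynomial regression, multilayer perceptron, LSTM) map the five print
   parameters (bioink viscosity, nozzle inner diameter, dispensing time,
   pressure, cell concentration) to droplet volume, with a 70/30 split,
   10-fold cross-validation, grid-search hyperparameter tuning, the four
   standard metrics (MAE, MSE, RMSE, R²) and normalized random-forest
   feature importances.

Because no droplet photographs or print logs ship with the package, a
synthetic module renders droplet images with exact analytic ground truth
and samples parameter→volume datasets from a documented power-law
surrogate, so every stage is testable end to end.

## Worked example

```python
from dropmetry import calibrate, measure_droplet
from dropmetry.synthetic import RenderSpec, render_droplet

cal = calibrate(10, 1028)            # 10 mm == 1028 px
spec = RenderSpec(diameter_mm=2.0, theta_deg=90.0, noise=0.0)
image, truth, _, _ = render_droplet(spec)
m = measure_droplet(image, cal).measurement
print(f"D = {m.diameter_mm:.4g} mm, theta = {m.theta_deg:.2f} deg, "
      f"V = {m.volume_uL:.4g} uL (true {truth.volume_uL:.4g})")
```

prints

```
D = 1.994 mm, theta = 90.28 deg, V = 2.091 uL (true 2.094)
```

— a hemispherical 2 mm droplet measured to within 0.2 % of its analytic
volume π·2³/12 ≈ 2.0944 µL.

On the prediction side:

```
dropmetry simulate --n 1758 --seed 42 --out dataset.csv
dropmetry train --dataset dataset.csv --seed 42 --out-dir models --repeats 3
dropmetry predict --models-dir models --viscosity 10.03 --nozzle 0.26 \
    --time 0.1 --pressure 2 --cells 9.33e5
```

`train` prints a five-row comparison table (mean ± sd of MAE/RMSE/R² and
train/test times per algorithm); `predict` prints one row per trained
model with its predicted volume in µL and its held-out R² as the accuracy
column. On the default synthetic dataset every model reaches R² ≥ 0.99,
with tree models training in milliseconds and the neural models in
seconds.

A `measure` command batch-processes real photographs
(`dropmetry measure *.png --known-length-mm 10 --span-px 1028 --out out.csv`),
and `render`, `tune` and `importance` cover synthetic image generation,
grid-search curves and feature-importance tables. See `dropmetry --help`.

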