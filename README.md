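# pbsqa — spot-position-sensitive daily QA for PBS proton therapy

`pbsqa` implements the analysis chain behind a daily quality-assurance
programme for pencil-beam-scanning (PBS) proton therapy built on a
commercial multi-detector array: output constancy, range constancy, spot
positioning accuracy and imaging/proton-beam isocenter coincidence, all
from one short irradiation. It is aimed at proton-therapy medical
physicists who want the threshold-derivation mathematics, the calibration
campaign bookkeeping and the daily trend evaluation as reusable,
scriptable code rather than a vendor GUI.

## The model

A single proton spot has an approximately Gaussian lateral fluence at the
detector plane. The normalized signal of a detector with a circular
sensitive area of radius R, when the spot is offset by (Δx, Δy), is

    S(Δx, Δy) = N ∬_R G(x, y; Δx, Δy, σ) dx dy,     S(0) = 1,

which by axisymmetry depends only on the radial offset r = √(Δx²+Δy²) and
decreases strictly with it. With σ ≈ 4.8 mm at the 13.8 mm central
chamber and σ ≈ 2.2 mm at the 0.8 mm positioning diodes, S(1.5 mm) is
97.2 % and 79.5 % respectively — the anchor values for a 1.5 mm
positioning/centering tolerance.

Because the spot never lands exactly on a detector, the daily offset is
estimated from five irradiations (aligned, ±1.5 mm left–right, ±1.5 mm
sup–inf) via the signal asymmetries

    Ax = (D(+1.5 LR) − D(−1.5 LR)) / D0,   Ay likewise,

each an odd, monotone function of the corresponding offset component that
is inverted by bracketed root finding (valid for |Δx|, |Δy| < 3 mm).
Over an N-day campaign the per-day offsets (Δx,i, Δy,i) are summarized by
ν (mean radial distance) and σxy (larger per-axis standard deviation);
assuming bivariate-normal setup errors the radial offset is
Rice-distributed with mean

    Δ̄ = σxy √(π/2) · L_{1/2}(−ν² / 2σxy²),

and the absolute daily signal threshold for a tolerance `tol` is

    th = D̄0 · S(tol) / S(Δ̄),

with a 1σ advisory band from Δ̄ ± the Rice standard deviation. Range
constancy is checked through distal-edge/plateau chamber signal ratios
against bounds measured with 0 and 2 mm of added plastic water (a ±1 mm
band around the 1 mm reference), and output constancy through a ±3 % band
on the plateau-chamber campaign means.

## Worked example

```python
import pbsqa as qa

# 20-day calibration campaign with a systematic 0.5/0.2 mm setup offset
truth = qa.SetupErrorModel(mu_x=0.5, mu_y=0.2, sigma_setup=0.25, seed=42)
signals, ground_truth = qa.generate_campaign(truth, n_days=20)

model = qa.SpotPositionCalibration.from_signals(signals)
results = model.fit()
print(results.summary())

th = results.thresholds()[qa.DetectorId.T2]["config1"]
print(f"\nT2 config1: D0_bar={th.d0_bar:.1f} counts, "
      f"threshold={th.threshold:.1f} "
      f"(band {th.threshold_lo:.1f}-{th.threshold_hi:.1f})")
```

prints

```
Spot position calibration (Rice model)
========================================================================
  det  days   nu/mm  sxy/mm  mean/mm  1s-lo  1s-hi   drop%
   B2    20   0.577   0.218    0.620  0.412  0.828    3.87
  CAX    20   0.572   0.260    0.636  0.394  0.878    0.50
   L2    20   0.565   0.216    0.609  0.402  0.815    3.72
   R2    20   0.569   0.216    0.612  0.405  0.818    3.76
   T2    20   0.572   0.218    0.616  0.408  0.824    3.81

T2 config1: D0_bar=961.7 counts, threshold=794.0 (band 776.8-818.8)
```

Each row is one detector's fitted campaign: `nu` the mean radial
spot–detector distance, `sxy` the larger per-axis spread, `mean` the Rice
mean offset Δ̄ with its 1σ bounds, and `drop%` the baseline signal loss
1−S(Δ̄) that the threshold formula compensates. The generator's true
radial offset magnitude here is 0.54 mm with 0.25 mm daily spread — the
fitted means sit on top of the corresponding Rice mean, and the T2
threshold of 794 counts is D̄0 · S(1.5)/S(Δ̄) = 961.7 · 0.794/0.962.

The same chain is available from the shell:

```sh
pbsqa simulate campaign -o data --seed 42
pbsqa calibrate data/campaign_signals.csv -o cal.json
pbsqa simulate exports -o data --seed 7 --n-days 5
pbsqa simulate range-sweep -o data
pbsqa evaluate data/daily_exports.csv --calibration cal.json \
      --range-calibration data/range_calibration.csv \
      --output-baselines data/output_baselines.yaml --trend trend.csv
pbsqa trend trend.csv --plot trend.png
```

`evaluate` exits nonzero if any QA item fails.

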