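# odcal

Calibration of plate-reader optical density (OD₆₀₀) readings to microbial
cell concentrations.

OD measurements are turbidity measurements: what a spectrophotometer
records is light scattered out of the beam, not absorbed by it. The
Beer–Lambert proportionality OD ∝ C holds only at low density (OD₆₀₀ ≲
0.2, the single-scattering regime); plate readers routinely operate far
above it, where OD acquires a parabolic dependence on concentration, and
the proportionality "constant" itself depends strongly on cell size and
on the refractive-index contrast between cells and medium. `odcal`
implements the physics and the calibration procedures needed to convert
OD to cell concentration quantitatively, for microbiologists running
growth curves in microplate readers.

## What it computes

**Single-particle optics** (`odcal.scattering`): exact Mie extinction and
scattering efficiencies Q(x, m) of a homogeneous sphere (size parameter
x = πD·n_m/λ, relative index m = n_p/n_m), the Rayleigh limit
Q_sca = (8/3)x⁴|(m²−1)/(m²+2)|², the anomalous-diffraction (van de Hulst)
form for soft particles, and the small-phase-shift (Jöbst) cross-section
σ = (ρ²/2)πr² with ρ = 2x(m−1), which scales exactly as r⁴ — the reason
OD per cell grows with cell volume to the power 4/3. A detector-acceptance
correction accounts for near-forward scattered light that a real
instrument wrongly counts as transmitted.

**Forward model** (`odcal.forward_model`): decadic turbidity
τ = σCL/ln 10 and the multiple-scattering parabola OD = τ − qτ², valid on
the monotone branch τ ≤ 1/(2q); mixtures; fill-volume path corrections;
scattering-regime classification.

**Calibration** (`odcal.calibration`): saturation trimming, robust
quadratic fits OD(C) = p₀ + p₁C + p₂C² by Tukey-bisquare IRLS (tuning
constant 4.685, MAD scale), sequential-F-test degree selection, exact
inversion on the monotone branch with saturated/below-blank diagnostics,
concentration-vs-diameter tables, cross-instrument proportional
calibration, and least-squares alignment of OD traces with microscope
counts.

**Growth analysis** (`odcal.growth`): OD→concentration conversion with
per-point validity flags, sliding-window log-linear specific growth
rates (hr⁻¹), maximum rate, tangent-construction lag time, yield, and
OD-based vs count-based rate comparison.

**Synthetic data** (`odcal.synthetic`): dilution series of the reference
polystyrene bead set (0.51, 0.96, 3.00, 10.0, 15.7 µm, n_p = 1.59),
growth curves with constant, shrinking, or filamenting cell-size
trajectories, 5-read plate noise, and Poisson field-of-view microscope
counting (55.6 × 55.6 × 100 µm volumes) — all with stored ground truth
and full seed determinism.

## Worked example

Simulate a 0.96 µm bead dilution series with 2% readout noise, fit a
calibration curve, and invert an OD reading:

```sh
$ odcal --seed 1 simulate beads --diameter 0.96 --replicates 5 --out-dir demo
wrote demo/beads.csv
$ odcal fit --series demo/beads.csv --out demo/curve.json
wrote demo/curve.json (trimmed 0 saturated points, rmse 0.01713)
$ odcal invert --curve demo/curve.json --od 0.5
64628664.95
```

The fitted artifact stores the quadratic OD(C) = p₀ + p₁C + p₂C²:

```
"coefficients": [-0.0008135675, 8.181808820e-09, -6.695408613e-18]
"od_valid_range": [0.0502, 2.3942]
```

p₁ ≈ 8.2·10⁻⁹ OD·ml is the single-scattering slope (extinction
cross-section × path length / ln 10 per bead), the negative p₂ is the
multiple-scattering curvature, and the near-zero intercept confirms a
clean blank. Inverting OD = 0.5 gives ≈ 6.46·10⁷ beads ml⁻¹, on the
rising branch of the parabola. The same workflow applies to cell
cultures; `odcal convert` and `odcal metrics` then turn OD growth CSVs
into concentration curves and growth metrics.

From Python, the same steps are
`make_bead_series → trim_saturated → fit_calibration → invert_calibration`.

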