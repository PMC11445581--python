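# fccskit

Quantitative analysis of protein–protein binding and degradation in
living mitotic cells, built around two measurement families:

1. **Fluorescence (cross-)correlation spectroscopy (FCS/FCCS).** Photon
   count fluctuations in a femtolitre confocal volume report absolute
   concentrations, diffusion coefficients and — with two spectrally
   separated labels — the co-diffusing (bound) fraction of a protein
   pair, and hence an *in-cell dissociation constant* K_D. The
   motivating application is the binding between a green-labelled
   substrate (Cyclin B1-mEmerald) and a red-labelled subunit of its
   ubiquitin ligase (APC8-mScarlet) in different subcellular
   compartments.
2. **Single-cell degradation kinetics.** Anaphase-aligned fluorescence
   trajectories are normalised, corrected for photobleaching, and
   scanned with sliding linear fits to extract the degradation onset
   frame, the initial degradation speed and the maximum degradation
   speed; thick-line intensity profiles between the two centrosomes
   quantify spatial enrichment.

Because the raw microscopy data behind such studies are rarely
re-analysable at desk scale, the package ships a first-class
**synthetic-data generator**: Brownian dynamics of point emitters
through a 3-D Gaussian observation volume with Poisson photon
statistics (including a co-diffusing bound complex at mass-action
equilibrium), plus parametric degradation traces and line-profile
images — all with recorded ground truth, so every stage of the analysis
is verifiable end to end.

## The core quantities

For a 3-D Gaussian observation volume with lateral 1/e² radius `w_xy`
and structure parameter `κ = w_z/w_xy`, a freely diffusing species gives
the autocorrelation

```
G(τ) = (1/N) · (1 + τ/τ_D)⁻¹ · (1 + τ/(κ²τ_D))⁻½,
```

with `N = C·N_A·V_eff` the mean molecule number in
`V_eff = π^{3/2} w_xy² w_z` and `τ_D = w_xy²/(4D)`. Dual-colour
amplitudes invert to absolute concentrations,

```
C_complex = G_x(0) / (s·G_g(0)·G_r(0)),      s = N_A·V_eff,
C_free    = 1/(s·G_auto(0)) − C_complex,
K_D       = C_gfree · C_rfree / C_complex,
```

and the cross-correlation quotient `q` (the larger of the two bound
fractions `G_x(0)/G_r(0)`, `G_x(0)/G_g(0)`) reports the bound fraction
of the limiting species. The degradation-onset detector declares onset
at the first frame of the first sliding five-point window whose
least-squares slope falls strictly below −0.05 normalised units per
frame, after four-point trailing smoothing.

## Worked example

```sh
fccskit run-demo --seed 1 --out demo_out
```

simulates one 10-s dual-colour FCCS measurement of a binding pair
(100 nM of each partner, ground-truth K_D = 80 nM, V_eff ≈ 0.22 fL) and
one degradation trace, runs the full analysis on each, and prints:

```json
{
  "fccs": {
    "kd_true_nM": 80.0,
    "kd_est_nM": 63.749665935679246,
    "q": 0.46068952698068005,
    "c_complex_nM": 45.72081234488288
  },
  "degradation": {
    "onset_true_frame": 0,
    "onset_est_frame": 0,
    "initial_speed_per_frame": -0.054043238782714866,
    "max_speed_per_frame": -0.07124994170532929
  }
}
```

A single 10-s measurement recovers the dissociation constant to within
~20% (here 64 vs 80 nM — per-measurement scatter of this size is
expected; medians over ≥20 measurements land within a few percent, see
below) and a bound fraction q ≈ 0.46. The degradation onset is found at
the true frame, with an initial speed of −0.054/frame (just past the
−0.05 trigger threshold) and a maximum speed of −0.071/frame.

Step-by-step equivalents of the demo:

```sh
fccskit simulate fcs --seed 1 --kd-nm 80 --out run/
fccskit correlate --green run/green.csv --red run/red.csv --max-lag 0.014 --out run/
fccskit fit --curve run/auto_g.csv --out run/fit_g.json
fccskit kd --auto-green run/auto_g.csv --auto-red run/auto_r.csv \
           --cross run/cross.csv --out run/kd.json
fccskit simulate degradation --seed 1 --out deg/
fccskit kinetics --trace deg/trace.csv --bleach control \
                 --control deg/control.csv --out deg/kinetics.json
```

## Layout

| module | contents |
| --- | --- |
| `fccskit.synthgen` | photon-trace, model-curve, degradation-trace and image generators |
| `fccskit.correlator` | brute-force and multi-tau correlation estimators |
| `fccskit.fcsfit` | diffusion models, curve fitting, calibration, unit conversions |
| `fccskit.interaction` | equilibrium solver, amplitude → concentration → q, K_D |
| `fccskit.kinetics` | trace normalisation, bleach correction, onset/speed detection, line profiles |
| `fccskit.io` / `fccskit.cli` / `fccskit.pipelines` | formats, config, provenance, CLI, composite experiments |

See `docs/methods.md` for the models, parameter choices and known
limitations.
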