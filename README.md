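# angioflow

Synthetic angiographic velocimetry: can machine-learning models correct the
systematic errors of optical-flow velocity estimation on projective contrast
images?

In X-ray angiography (DSA), a contrast agent flowing with the blood is imaged
as a 2D projection of a 3D flow field. Intensity-based optical flow applied to
consecutive frames yields a dense velocity estimate, but one that is badly
biased: the projection integrates the whole depth of the vessel, the pattern
displacement between frames routinely exceeds one pixel, and steady contrast
columns carry almost no temporal signal. `angioflow` reproduces this situation
end to end on fully synthetic data, where the true velocity field is known
exactly, and trains multi-output regression models that map the raw
optical-flow features to the true centre-plane velocity.

The pipeline has five stages:

1. **Scene generation** (`angioflow.flow_scene`) — laminar flow in a
   1 × 1-inch square duct (the classical Fourier-series solution of the fully
   developed rectangular-duct profile, no-slip walls, centreline/bulk ratio
   ≈ 2.096) carries a centred dye jet (inlet speed 0.005 m/s, dye diffusivity
   10⁻⁹ m²/s). Four injection patterns are simulated: a constant jet whose
   radius ramps 0.37 → 2.0 mm, an intermittent jet (0.1 s on / 0.25 s off), an
   intermittent jet with radial cosine concentration φ(r) = φ₀cos(ωr)
   (ω = 500 rad/m), and a continuous jet with temporal cosine concentration
   φ(t) = cos(4π/3·t) clipped at zero. The scalar transport equation
   ρ∂φ/∂t + ρ∂(uᵢφ)/∂xᵢ = ρD∇²φ is integrated with a quasi-monotone
   semi-Lagrangian scheme.
2. **Projection** (`angioflow.projector`) — parallel light along z attenuated
   by the Beer-Lambert law, I_j = I_{j-1}·exp(−μ_j Δz), with μ proportional to
   dye concentration; quantized to 8-bit 161 × 306-pixel grayscale images.
3. **Optical flow** (`angioflow.ofm`) — dense velocity from each image pair
   (Δt = 0.02 s) by minimizing the squared residual of the brightness-transport
   constraint Q_t + V·∇Q + Q∇·V = D∇²Q plus a Horn-Schunck smoothness term,
   solved as an SPD sparse system by preconditioned conjugate gradients.
4. **Dataset** (`angioflow.dataset`) — pixels with gray ≤ 80 are dye-dominant
   samples; each record joins the four features (u_ofm, v_ofm, Ix, Iy) to the
   centre-plane ground truth (u, v). Coordinates observed at several time
   instances contribute one random record to the test set, the rest to
   training (the duplicate-coordinate split).
5. **Models & evaluation** (`angioflow.regressors`, `angioflow.evaluation`) —
   LASSO (baseline), an MLP (one ReLU hidden layer of 10, dropout 0.02), a 1D
   CNN, and an LSTM, each trained with both MAE and MSE losses under
   10-fold × 3-repeat cross-validation with Adam; evaluated by MAE/MSE and by
   station-wise percentage error of the v-component against ground truth.

## Worked example

```python
from angioflow import pipeline as pl

result = pl.run_pipeline(pl.default_config(seed=1))
r = result.report
print(f"raw OFM average v-error:   {r['avg_v_error_ofm_pct']:.1f} %")
print(f"MLP-corrected v-error:     {r['avg_v_error_mlp_pct']:.3f} %")
print(f"held-out MAE, raw OFM:     {r['test_mae_ofm_raw']:.2e} m/s")
print(f"held-out MAE, MLP:         {r['test_mae_mlp_mae']:.2e} m/s")
```

On the default desk-scale configuration (quarter-domain 32 × 128 × 32 grid,
53 image pairs, ≈ 42 000 samples) this prints:

```
raw OFM average v-error:   52.0 %
MLP-corrected v-error:     0.056 %
held-out MAE, raw OFM:     2.24e-03 m/s
held-out MAE, MLP:         3.05e-06 m/s
```

Raw optical flow underestimates the streamwise velocity by about half on
average — steady dye columns look motionless, and 2-pixel frame-to-frame
displacements violate the sub-pixel assumption — while the learned correction
reduces the station-averaged error by more than two orders of magnitude.

The same run is available from a shell:

```bash
angioflow all --seed 1 --outdir out/
```

which writes scene volumes, PNG projections, per-pair optical-flow tables, the
sample CSV, fitted models with CV scores, and the evaluation report, each with
a JSON provenance sidecar.

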