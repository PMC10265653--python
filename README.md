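# vifstretch

Quantitative image analysis of membrane-bound vimentin intermediate
filament (VIF) networks under uniaxial substrate stretch.

When an elastomer sheet carrying a lipid bilayer and membrane-coupled
filaments is stretched along one axis, the substrate elongates
longitudinally (Cauchy strain ε_yy = ΔL/L > 0) and contracts laterally
(ε_xx < 0, Poisson ratio ν = −ε_xx/ε_yy). This package implements the full
measurement chain that turns raw image stacks into the mechanical
quantities of interest:

- **Substrate strain fields** — fiducial beads are detected, tracked
  across motor positions, and converted into per-step Cauchy strains, a
  least-squares affine transform, ν, and the zero-strain direction α₀
  (where the deformed ellipse meets the unit circle, the direction along
  which material lines keep their length).
- **Tilt correction** — free-standing sheets tilt; z-stacks are collapsed
  onto a best-in-focus surface built from Laplacian sharpness and a fitted
  second-order polynomial z(x, y).
- **Filament strain** — filaments are traced as sub-pixel polylines
  (Hessian ridge filter → skeleton → spline → ridge refinement), their
  contour length L_C measured per motor position, and the filament strain
  ε_VIF = (L_C,mp − L_C,0)/L_C,0 regressed against the substrate strain;
  the slope measures how much substrate stretch is transmitted into
  filament elongation.
- **Angular segmentation** — traces are cut wherever the tangent drifts
  more than 5° from the segment's starting tangent, giving polar
  statistics of segment orientation and length, plus an apparent
  persistence length from the tangent-correlation decay
  ⟨cos θ(s)⟩ = exp(−s/2L_p).
- **AFM tube filter** — height maps are filtered with a Hessian
  eigenvalue (|λ₂|, scale-normalized) ridge detector; masked, background-
  corrected pixel heights pool into a height distribution whose mode is
  the single-filament height.
- **Orientation fields** — dense networks get per-pixel structure-tensor
  orientations, coherence, and polar histograms.
- **FRAP** — recovery curves are fitted with the Soumpasis uniform-disk
  diffusion model f_S(t) = e^(−2τ_D/t)[I₀(2τ_D/t) + I₁(2τ_D/t)], giving
  D = w²/(4τ_D) and the mobile fraction.
- **Photometry** — degree of labeling from UV–vis absorbances.

Because raw experimental images are not redistributable, a first-class
synthetic-data generator (`vifstretch.synthetic`) produces every input the
pipeline consumes with exact ground truth: beads carried by the stretcher's
affine map, worm-like-chain filaments that elongate by a tunable fraction
κ of the substrate strain, entangled AFM height maps with 10 nm tubes and
additive overlap, Soumpasis-shaped recovery curves, and tilted z-stacks.
See `docs/methods.md` for the models and their assumptions.

## Worked example

Run the full synthetic pipeline (simulate → track → trace → fit):

```python
from vifstretch.pipeline import RunConfig, run_stretch_analysis

summary = run_stretch_analysis(RunConfig(outdir="run", seed=42))
```

which writes per-stage TIFF/CSV outputs plus `run/summary.json`:

```json
{
  "strain":    {"eps_yy_final": 0.3306, "eps_xx_final": -0.1200,
                "poisson_ratio": 0.363, "zero_strain_angle_deg": 50.71},
  "filaments": {"slope": 0.155, "slope_ci95": [0.136, 0.175],
                "eps_vif_at_max_percent": 5.07},
  "afm":       {"height_mode_nm": 9.0},
  "frap":      {"tau_D_s": 0.699, "D_um2_s": 1.430, "mobile_fraction": 0.915}
}
```

Reading: the bead tracker recovers the stretcher's calibration strains
(+33% / −12%, ν ≈ 0.36, zero-strain direction ≈ 51° from the stretch
axis); the trace→strain→fit chain recovers the generator's strain-transfer
coefficient κ = 0.16 within its confidence band, i.e. the filaments take
up ~16% of the substrate strain (≈ 5% elongation at full stretch); the
tube-filtered height maps pool to a mode within a bin of the 10 nm
single-filament height; and the FRAP fit returns the lipid diffusion
coefficient (1.4 μm²/s) and mobile fraction (0.91) the curve was
generated with.

The same stages are available as CLI subcommands on files
(`vifstretch simulate | tiltcorrect | strain | filaments | tubefilter |
orient | frap | dol | run`).

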