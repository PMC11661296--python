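# mtq — quantitative imaging pipelines for membrane-tension proxies

Peripheral membrane proteins such as the cPla₂ C2 domain and ALPS
(amphipathic lipid packing sensor) motifs adsorb to lipid bilayers when
stretch exposes packing defects between phospholipid headgroups.  Their
fluorescence on a membrane is therefore a practical, genetically encodable
proxy for membrane tension.  `mtq` implements the quantitative image
analyses this readout needs, for three experimental geometries:

1. **GUV equilibrium binding** — protein recruitment to giant unilamellar
   vesicle membranes: semi-automatic cropping from a user seed line,
   per-slice marker-controlled watershed, middle-section selection, and the
   median rim intensity along a 3-pixel contour, normalised across protein
   purification batches.
2. **Nuclear-membrane (NM) binding** — fully automatic 3D nucleus
   segmentation (masked-object thresholding + marker-controlled watershed),
   nearest-neighbour tracking (≤ 50 µm/step), and per-nucleus time series of

   `ratio(t) = median(membrane contour) / median(nucleoplasm contour)`,

   normalised to t = 0, with an optional lamin-ratiometric control.
3. **ER morphology** — endoplasmic reticulum segmentation from luminal or
   membrane markers (watershed or Hessian filament filter) and per-FOV
   medians of object area and circularity `4πA/P²`, whose fold changes
   report ER fragmentation (vesiculation: area ↓, circularity ↑).

Around these sit the corresponding models and statistics — the Langmuir
adsorption isotherm with Hill expansion

    B_bound = Bmax · [Domain]^H / ([Domain]^H + Kd'^H)

fitted by nonlinear least squares with 95% CIs, OLS binding rates on the
linear part of ratio time courses, the Welch unequal-variance t-test with
star categories, FOV-to-nucleus correlation joins, and hypoosmotic dilution
arithmetic — plus a synthetic phantom generator (GUV shells, rim+interior
nuclei, tubular/vesiculated ER, noisy binding curves) that provides ground
truth for every pipeline.

The audience is microscopists and mechanobiology labs quantifying
organelle membrane tension by probe adsorption rather than by absolute
physical-unit tension measurements.

## Worked example

```bash
mtq demo --seed 0 --out demo_out
```

generates all three synthetic scenes plus a noisy binding curve, runs every
pipeline, and writes `demo_out/report.md`:

```
## Scenes
1. GUV shell phantom -> rim median 105.64 (middle slice 4)
2. Nucleus ramp phantom -> final binding ratio_norm 2.938 (rate 0.2189/min on frames (5, 8))
3. ER tubular-to-vesiculated phantom -> final fold_circularity 31.360, fold_area 0.025

## Hill fit
Kd' = 105.01 nM (true 100), Bmax = 1.0378 (true 1), H = 1.914 (true 2)
```

Reading the numbers: the GUV phantom's rim was rendered at amplitude 120
and is read back as ≈ 106 after PSF blur and noise; the nucleus phantom's
rim/nucleoplasm ratio ramps 1 → 3 and the measured normalised ratio ends at
2.94; converting the tubular ER network into vesicles multiplies the median
object circularity ~31-fold while the median area collapses to 2.5% —
the fragmentation signature.  The Hill fit recovers all three parameters of
the simulated isotherm within a few percent at 2% measurement noise.

The same stages run on real TIFF/OME-TIFF stacks:

```bash
mtq guv     --stack guv.tif --line 64,64,64,84 --reference 950 --out guv.csv
mtq nuclear --stack cells.ome.tif --probe-channel 1 --lamin-channel 0 --out nm.csv
mtq er      --stack er.tif --label-type luminal --out er.csv
mtq fit-hill --curve binding_curve.csv --out fit.json
mtq rate    --series nm.csv --out rates.csv
mtq run     --config run.yaml          # end-to-end from one config
```

In Python, the model-fitting layer follows the statsmodels pattern:

```python
import mtq
curve = mtq.simulate_binding_curve(bmax=1, kd=100, h=2,
                                   concentrations=[0, 10, 25, 50, 100, 200, 350, 500],
                                   noise_sd=0.02, seed=0)
res = mtq.HillBindingModel.from_dataframe(curve).fit()
print(res.summary())
print(res.conf_int())
```

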