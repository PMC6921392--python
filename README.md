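# xravessel

Vessel enhancement and segmentation for coronary X-ray angiographic (XRA)
image sequences.

In an angiogram the contrast-filled coronary tree appears as thin dark
curves superimposed on vertebrae, ribs, the diaphragm and a catheter, all
of which move with breathing while the vessels pulse with the heart.
`xravessel` separates those layers and segments the vessels, frame by
frame and online (each frame is processed once, without re-optimising on
the past), which makes the method usable on streaming fluoroscopy.  It is
aimed at researchers working on angiographic image analysis who need a
tested, scriptable reference pipeline plus a synthetic phantom with exact
ground truth.

## Method

Given a sequence `I` of grayscale frames (vessels dark), four stages run
in order:

1. **Morphological top-hat.**  A grayscale closing with a flat disk of
   diameter `d = 8.5/(2p)` pixels (`p` = pixel spacing in mm) fills
   structures thinner than the disk.  The difference `DI = close(I) − I`
   turns dark thin structures (vessels, catheter) into a positive signal
   and cancels the large smooth respiratory layer.

2. **Inter-frame constrained decomposition.**  Each frame vector is split
   into a quasi-static part `B = Lr·Ceᵀ` and a sparse vascular part `E`
   by minimising, per frame,

       ½‖DIᵢ − Lr·Ceᵢ − Eᵢ‖² + (λ₁/2)‖Ceᵢ‖² + λ₂‖Eᵢ‖₁

   with a single basis `Lr ∈ R^(D×r)` that evolves across frames from
   accumulated sufficient statistics (the inter-frame constraint).
   Defaults: `r = 5`, `λ₁ = λ₂ = 2.1/max(M1, M2)`.

3. **Intra-frame constrained pass.**  After a second top-hat removes
   broad residual artefacts, each frame is decomposed independently
   against a fixed all-ones basis; the "low-rank" term is then a
   spatially constant offset and the sparse residual `V` is the enhanced
   vascular frame over a flattened background.

4. **Multi-feature segmentation.**  At scales σ ∈ {1, 1.5, 2, 3, 4} px the
   σ²-normalised Hessian eigenvalues (|λ₁| ≤ |λ₂|) feed two tube
   descriptors — a log response `F1 = ln(λ₂²+1)` gated at `λ₂ < −√(2π)σ`,
   and a bounded uniform response `F2` built from the regularised
   eigenvalue `λr` — fused as `F = max_σ(α₁F1 + α₂F2)` with
   `α₁ = α₂ = 0.5`; a per-frame Otsu threshold yields the binary mask
   `SI`.

Evaluation uses the contrast-to-noise ratio `CNR = |μ_F − μ_B|/σ_B`
against a global (whole non-vessel area) or local (7-pixel ring around
the vessel boundary) background, and pixelwise precision / sensitivity /
F1.

Because clinical angiograms cannot be redistributed, the package ships a
phantom generator (`xravessel.synthetic`) that composes a static anatomy
layer, a breathing diaphragm, a pulsing Bezier-tube coronary tree with
progressive contrast inflow, and Gaussian noise — with the exact layer
decomposition and vessel masks as ground truth.

## Worked example

```python
import xravessel as xv

seq, gt = xv.generate_sequence(xv.PhantomConfig())          # 30 frames, 128x128
model = xv.VesselSegmentationModel(seq, truth_masks=gt.vessel_mask)
res = model.fit()
print(res.summary())
```

prints (abridged):

```
Vessel segmentation results
================================================================
frames: 30  size: 128x128  pixel spacing: 0.3 mm
rank bound r=5, r'=5; seed=0
feature scales: [1.0, 1.5, 2.0, 3.0, 4.0]  weights: (0.5, 0.5)

Stage diagnostics:
             min    max   mean  nonzero_frac
stage
original  0.0000 1.0000 0.7838        1.0000
DI        0.0000 0.7963 0.0469        0.8868
...
V         0.0000 0.7247 0.0208        0.1642

Per-frame metrics (last rows aggregate mean/std):
       cnr_global  cnr_local  precision  sensitivity     f1
frame
28         5.5034     4.7888     0.7354       0.8577 0.7919
29         5.4265     4.6126     0.7348       0.8651 0.7946
mean       4.7241     4.0830     0.6688       0.7598 0.7098
```

Reading the output: the sparse component `V` is nonzero on 16% of pixels
(the vessels plus residual noise), the enhanced CNR of ~4.7 global / 4.1
local compares with ~2.3 / 2.2 on the original frames, and per-frame
pixel F1 reaches ~0.79 once contrast has fully flowed in (the aggregate
row includes the early inflow frames, where vessels are barely present).
`res.enhanced`, `res.segmentation`, `res.metrics`,
`res.simulate_low_dose(f)` and `res.plot_frame(i)` expose the fitted
components; `res.intermediates` carries every stage (`DI`, `B`, `E`,
`DI'`, `V`, `F`, `SI`).

The same pipeline is available from the shell:

```bash
xravessel simulate --out phantom --frames 30
xravessel segment phantom/frames.tif --truth-masks phantom/masks --out run
xravessel lowdose phantom/frames.tif run/V.tif --dose-fraction 0.3 --out low.tif
```

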