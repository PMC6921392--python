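# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `xravessel`, and what the synthetic phantom does and
does not establish about clinical data.

## Layer model and stage order

A coronary angiogram frame is modelled as a superposition of

* a *static* absorption layer (vertebrae, ribs, catheter),
* a *respiratory* layer — large, smooth, slowly translating (diaphragm,
  lung borders),
* a *vascular* layer — thin dark tubes moving with the cardiac cycle and
  filling in as contrast agent flows,
* additive noise.

The stages attack these in order of spatial scale: morphology removes
what is *broad* (respiration), the inter-frame decomposition removes what
is *temporally persistent* (static residuals), the intra-frame pass
removes what is *spatially constant per frame* (illumination offsets),
and the Hessian descriptors keep what is *tubular*.

## Morphological preprocessing

* Disk diameter `d = 8.5/(2p)` px (≈ 4.25 mm) — wider than any coronary
  lumen, narrower than the diaphragm silhouette.  The raw value is
  rounded to the nearest odd integer and clamped to ≥ 3 so the flat disk
  has a well-defined centre; reflect padding avoids bright border
  artefacts in the top-hat.
* **Subtraction direction.**  Subtracting the closed (respiratory)
  estimate literally from the input leaves vessels negative.  We define
  the difference sequence as the black top-hat `close(I) − I` instead, so
  that the sparse component downstream is a non-negative vessel signal;
  `subtract_direction="frame_minus_close"` restores the literal order
  (outputs flip sign, the segmentation is unchanged).
* **Second top-hat input.**  The stage that removes broad artefacts
  around the catheter is applied to the sparse component `E` (flag
  `second_close_input` also accepts `DI`).  Since `E` carries vessels
  *positive*, the pipeline applies the closing to `−E`, which equals an
  opening-based white top-hat on `E` — the same thin-structure
  extraction in the opposite polarity.  On a clean sparse `E` (nothing
  broad) this stage is a provable no-op.

## Online decomposition

* Per frame both passes minimise
  `½‖x − Lr·Ce − E‖² + (λ₁/2)‖Ce‖² + λ₂‖E‖₁`
  by exact alternation (ridge solve, soft threshold), which makes the
  objective non-increasing; iteration stops at relative change < 1e-6 or
  100 iterations.  The basis update is one pass of exact block-coordinate
  descent on the ridge-regularised quadratic surrogate accumulated from
  all frames seen; the surrogate never increases.  One solve + one basis
  update per frame; frames are visited once (online contract).
* Basis initialisation: i.i.d. `N(0, 1/D)` entries, seeded — the
  convention for factorised online robust PCA; all outputs are bit-exact
  under a fixed seed.
* The intra pass fixes the basis to an all-ones `D×r'` matrix.  The Gram
  matrix is rank one; the ridge `λ₁'` keeps the normal equations
  well-posed and the fitted "low-rank" term is a constant offset per
  frame.
* `rank_r = r' = 5`, `λ₁ = λ₂ = λ₁' = λ₂' = 2.1/max(M1, M2)` by default.
* **Processing gray scale.**  Frames are globally normalised to [0, 1]
  per sequence, then the decomposition operates on `processing_scale`
  (default 255) gray-level equivalents.  The two intensity-dependent
  rules of the method — the regulariser `2.1/max(M1, M2)` and the F1
  gate `λ₂ < −√(2π)σ` — are only mutually consistent on an 8-bit-like
  scale: on [0, 1] data the F1 gate can never fire and the same λ would
  shrink the sparse component by ~15 % of a typical vessel depth per
  pass.  On the 0–255 scale λ acts as a small denoising floor and the
  recovered vessel amplitude is nearly unbiased, which is what the
  low-dose subtraction requires.  Emitted sequences are mapped back to
  the input's [0, 1] scale.
* The sparse components are not sign-constrained by the objective; the
  pipeline clips them at zero afterwards (`clip_negative`, default on)
  because vessels are positive in the top-hat convention.

## Feature fusion and segmentation

* Scales {1, 1.5, 2, 3, 4} px cover tube profile widths of roughly 1–6 px
  (the phantom's and, after 4× downsampling, typical coronary calibres).
* **Polarity reconciliation.**  F1 fires on negative λ₂ (bright tubes);
  F2/λr use the positive convention (dark tubes).  The pipeline orients
  the frame so vessels are bright and feeds λ₂ to F1 and −λ₂ to F2/λr,
  so both descriptors respond to the same structures.
* **F1 normalisation.**  F1 is unbounded while F2 ∈ [0, 1]; with equal
  weights the sum would be meaningless, so F1 is min–max normalised over
  the full per-frame scale stack before fusion.
* λr uses the per-frame, per-scale maximum of the positive eigenvalue;
  `tau` (default 1, the literal definition) optionally scales the cutoff.
  Eigenvalue magnitudes below 1e-8 are floored to zero so float-level
  noise in flat regions cannot saturate F2's ratio branches.
* Gaussian-derivative kernels are sampled at truncation 4σ with reflect
  boundaries; the second-derivative kernel is re-centred to exact zero
  sum so constant images have an exactly zero Hessian.
* Threshold: per-frame Otsu over the *nonzero* fused responses (the zero
  background would otherwise dominate the histogram); a scalar threshold
  can be supplied.

## Evaluation conventions

* CNR uses the sample (n−1) standard deviation of the background.
* The local background is the ring `dilate(mask, disk r=width) \ mask`
  with `width = 7` px by default (the alternative "total width 7"
  reading is available through the parameter).
* Precision/sensitivity/F1 with empty denominators return 0 with a
  warning.  Sequence tables report per-frame rows plus mean ± std
  aggregates.
* End-to-end phantom metrics are aggregated over frames after a 10-frame
  burn-in, which covers the contrast-inflow ramp (8 frames by default —
  vessels are genuinely absent or faint before that) and the streaming
  warm-up of the basis.

## Phantom design

The generator emulates what the pipeline's assumptions rely on:
vessels as smooth Gaussian-profile Bezier tubes (FWHM 2–4 px, absorption
depth 0.35) so the Hessian model applies; a breathing layer as a
translated anisotropic Gaussian dimming, removable by the closing; static
high-contrast structures (vertebra blocks, rib bands, a 2.5 px catheter
curve) that the inter-frame pass must absorb; additive Gaussian noise
(σ = 0.01).  Motion amplitudes are scaled from clinical magnitudes at the
default 128-px frame (~1.2 mm effective pixel): 6 px (~7 mm) cardiac
excursion along a fixed oblique axis and 8 px (~10 mm) diaphragm
translation, of which the coronary tree inherits half — superposing the
two incommensurate phases keeps the tree from revisiting pixel-identical
positions, as in real sequences.  Contrast inflow ramps linearly over 8
frames (`min(1, i/n_inflow)`, so frame 0 is vessel-free).

Not emulated: washout, beam hardening and scatter, non-rigid vessel
deformation, table panning, ECG-correlated motion profiles.  Passing the
phantom regression therefore shows the pipeline implements the intended
mechanics under its own assumptions — not clinical-grade performance;
clinical CNR/F1 values depend on data that cannot be redistributed.

Ground truth stores every layer plus the realised noise, so the emitted
sequence is exactly recomposable; the vessel mask is exactly the support
of the absorption layer (profiles truncated at 2σ, shifted to reach zero
continuously at the support boundary).

## Problem sizes

Default phantom runs use 30 frames of 128×128 (a 4× linear downsampling
of the clinical 512×512 format); solver-oracle checks use D ≤ 100,
r ≤ 5; planted-recovery streams use 50 frames of 64×64.  These sizes keep
the full test suite and the acceptance script in the minutes range on a
single CPU while exercising every code path at realistic aspect ratios.

## Known limitations

* The online basis partially absorbs the motion-averaged vessel envelope
  (pixels the moving tree covers in many frames), biasing the recovered
  amplitude low; the effect shrinks as motion grows relative to vessel
  width.
* A strictly periodic phantom with small motion is the worst case for
  the low-rank/sparse split; results on such configurations understate
  clinical behaviour.
* The segmentation threshold is per-frame; flickering of faint distal
  branches across frames is possible and no temporal regularisation is
  applied.
* Eigenvectors of the Hessian are computed and exported but unused by
  the segmentation (no centerline tracking).
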