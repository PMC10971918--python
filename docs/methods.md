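# Methods

This note documents the models, numerical choices and known limitations of
the `cceit` package: a fully synthetic pipeline for capacitively coupled
electrical impedance tomography (CCEIT) of brain stroke, from parametric
head phantoms through a complex-capacitance forward solver to linear and
adversarial-network image reconstruction.

## 1. Head phantom model

The phantom is a 2D axial cross-section representing the average of a 3 cm
slab at electrode height. Regions are built from tilted ellipses combined
with boolean algebra:

* **Head outline** — fixed ellipse, semiaxes 77 x 105 mm (circumference
  575 mm, an average adult male head). Origin at the belt centre, x right,
  y up, millimetres.
* **Skin + skull shell** — a concentric shell: 3 mm skin plus a sampled
  skull thickness of 7.5 ± 1.5 mm. The shell encloses the cranial cavity.
  The constraint tables we work from carry a skull ellipse of 91 x 99 mm
  with a centre offset, which cannot be contained inside the 77 x 105 mm
  outline under any reading of the sizes (as semiaxes it pokes outside the
  head; as full axes it is smaller than the brain-bounding ellipse). The
  concentric-shell model replaces it; the 10.5 mm mean total thickness was
  chosen so that the skin+skull region occupies ~13.5 % of the image at
  the mean geometry, the population value the phantom family is required
  to respect.
* **Inner (brain-bounding) ellipse** — head semiaxes plus sampled offsets
  (−14 ± 5 mm each), sampled centre and tilt; if a draw pokes outside the
  cavity it is uniformly shrunk to fit (containment repair).
* **Hemispheres** — each hemisphere is the intersection of Inner with the
  union of an upper and a lower ellipse, cut by a near-vertical dividing
  line (shifted −3 ± 6 mm in x, −8.5 ± 10.5 mm in y, tilted 1 ± 10°).
  Ellipse centres are offsets in Inner's tilted frame; sizes are additive
  offsets to Inner's *sampled* semiaxes; tilts compose additively.
* **CSF** — everything inside the cavity that is not brain, plus five
  explicit ellipses (a tall central one and four lobes placed on its
  boundary at sampled axis angles, shifted outward along the normal) that
  carve into the hemispheres. CSF overrides brain where they overlap.

### Sampling law and rejection windows

Each table parameter is drawn within mean ± half-range; the default law is
a truncated normal with sd = half-range/2 truncated at ± half-range
(uniform available via `law="uniform"`). Candidates are rejected until all
enforced windows hold:

| window | range |
|---|---|
| Inner circumference | 487.5 ± 53.5 mm |
| Inner axes ratio (b/a) | 1.3 ± 0.2 |
| central-CSF circumference / Inner circumference | 0.3 ± 0.1 |
| central-CSF axes ratio | 4.4 ± 2.9 |
| CSF lobe circumferences | 93.5 ± 24.5 / 94 ± 22 / 57 ± 21 / 70 ± 23 mm |
| brain area (% of image) | 23 ± 6 |
| CSF area (% of image) | 23 ± 6 |
| skin+skull area (% of image) | 13.5 ± 5.5 |
| left/right hemisphere area ratio (%) | 98.5 ± 7.5 |

The constraint tables also carry circumference-ratio and axes-ratio rows
for the hemisphere ellipses; those are numerically incompatible with the
hemisphere sizes under every size reading we tested (for example the
left-lower ellipse's perimeter ratio evaluates to 0.52 at the table means
against a 0.7 ± 0.1 window) and are not enforced. Enforcing them would
reject every candidate.

Area fractions are measured on a 128 x 128 raster of the 208 mm square
image window. The extent is a model constant: 208 mm makes the mean
geometry satisfy all three area windows simultaneously with the brain and
skin+skull fractions close to their window centres. At these settings the
acceptance rate of the rejection sampler is roughly 20 %, ~7 ms per
accepted phantom.

A second generation mode perturbs a frozen set of 50 base geometries
(themselves accepted draws, standing in for manually fitted reference
models) with independent Gaussian noise of sd = `relative_sd` x (full
table range), default `relative_sd = 0.05`, re-validated against the same
windows.

### Dielectric properties

Region values at 64 MHz are Gaussian draws (means ± sd):
skin+skull ε_r 14.79 ± 1.77, σ 102 ± 29 mS/m; brain ε_r 46.46 ± 3.44,
σ 378 ± 59 mS/m; CSF ε_r 61.26 ± 4.40, σ 788 ± 207 mS/m. The two
hemispheres are drawn independently from the brain prior. Draws are
rejected until CSF > brain > skin+skull holds for both quantities.
Individual-tissue values (white/grey matter, bone, fat, skin) are kept in
`TissueTable` for reference; the model itself uses the averaged region
values. Air outside the head is ε_r = 1, σ = 0.

### Stroke model

Six artery rays leave a common anchor — the midpoint between the Inner
centre and Inner's topmost point on its vertical axis — at 12, 80, 135,
−12, −80, −135 degrees from the vertical, fanning *downward* through the
brain mass (an upward fan misses brain tissue on ~3 % of phantoms because
the near-vertical rays can exit through central CSF; the downward fan hits
brain on all of 200 validation phantoms). A random artery is chosen; the
admissible lesion radius is uniform in [15 mm, gap], where the gap is the
ray distance from its last CSF crossing to the brain boundary; arteries
with gap < 15 mm are skipped and the insertion fails after all six.

* **Hemorrhagic**: circle centre uniform on the in-brain ray segment;
  lesion pixels get blood values σ = 1230 mS/m, ε_r = 76.
* **Ischemic**: circle centre on the ray *beyond* the brain edge (offset
  0.1–0.9 radii); lesion σ is uniform in 60–70 % ("65 ± 5 %") of the host
  hemisphere's σ; ε_r unchanged.

The lesion is always intersected with the host hemisphere's brain mask, so
it cannot cross the midline or enter CSF. Stroke descriptors are sampled
once per phantom and rasterised identically on the image and solver grids.

## 2. Forward model

Measurements are single-frequency phasors at 64 MHz. The complex relative
permittivity is ε = ε′ − jσ/(ωε₀); at these tissue values the imaginary
part is comparable to the real part (brain: 46 − 106j), so the measured
inter-electrode quantities are genuinely complex capacitances.

The 16 electrodes are arcs on the head outline, each spanning 80 % of its
22.5° sector in the elliptic parameter angle, numbered clockwise from the
top; a grounded elliptical screen sits 20 mm outside the electrode ring.
The quasi-static equation ∇·(ε∇V) = 0 is discretised by a cell-centred
finite-volume scheme on a regular Cartesian grid (264 mm square domain)
with harmonic-mean face permittivities; electrode and screen cells are
Dirichlet unknowns kept in the system as identity rows, so one sparse LU
factorisation serves all 16 excitations. Faces between a conductor cell
and a free cell take the free side's permittivity — a conductor has no
dielectric of its own, and using its placeholder value would insert a
spurious half-cell film whose thickness changes with resolution.

Each ordered pair's capacitance is the Gauss-law flux through the faces
one cell off the measuring electrode, divided by the excitation potential
(1 V), in farads per metre of depth. Reciprocity C(i,j) = C(j,i) holds to
solver precision by construction (symmetric operator + consistent flux
functional).

**Coupling capacitance.** The electrode insulation (default 0.5 mm,
ε_r = 4) is treated through the equivalent circuit rather than as
rasterised cells: each electrode's C_c = ε₀ ε_ins · arc/t is combined in
series with the field capacitance, C_m = (1/C_c,i + 1/C_x + 1/C_c,j)⁻¹.
A 0.5 mm film cannot be resolved on any practical grid, and rasterising
it makes capacitances grid-dependent at the tens-of-percent level; the
lumped form is exact in the thin-layer limit, keeps C_c large compared to
the measured admittance (as the measurement principle requires), and makes
"thicker insulation ⇒ smaller |C|" an exact monotone property.
`gauss_capacitance` itself returns the raw flux integral, which is exactly
linear in ε.

**Accuracy.** Against the closed-form cylindrical capacitor the solver is
within 1.6 % at 256². For the belt sensor, staircase rasterisation of the
electrode arcs limits pointwise grid convergence: frames at 128² vs 256²
agree to ~5 % (median over pairs). This is an inherent property of
staircase boundaries with edge-field singularities, not a bug; datasets
are generated on a single fixed grid, so the network and the linear
baselines always see self-consistent physics. The default dataset grid is
64² (4 mm cells), chosen so a full 240-pair frame costs ~30 ms.

**Noise.** Measurement noise is i.i.d. Gaussian on real and imaginary
parts with sd = max|C| / 10^(SNR/20) — peak-referenced, matching the
"peak SNR in dB" convention.

## 3. Linearised model and baselines

The sensitivity matrix (Jacobian dC/dε per image pixel) is assembled from
the 16 per-electrode field solutions via the discrete adjoint identity
dC_ij/dε_face = −ε₀ Δ_f v_i Δ_f v_j, chained through the harmonic-mean
face coefficients onto cells and aggregated onto image pixels. It matches
finite-difference perturbation to <1 % with the expected O(‖Δε‖²)
remainder. The reference field is the homogeneous brain-averaged head
(ε_r 46.46, σ 378 mS/m). Conductivity images use the imaginary part of the
capacitance change: with ε = ε′ − jσ/(ωε₀), Im(ΔC) = −Re(dC/dε)·Δσ/(ωε₀).

Linear back projection divides the transposed-sensitivity image by the
per-pixel total |S| mass (zero-sensitivity pixels are set to 0 with a
warning). The pseudoinverse baseline is a truncated SVD; the default rank
keeps singular values above 10⁻² of the largest — a simple elbow
heuristic, overridable with an integer.

## 4. Dataset construction

A sample is (input, target, label): the input is the raw 2 x 240 re/im
capacitance stack, the target the 64 x 64 conductivity map min-max
normalised to [0, 1] over the head support (background 0), the label a
uniform draw over healthy / hemorrhagic / ischemic. Half the samples are
constraint-sampled, half perturbation-based. Every sample is regenerable
bit-exactly from its (root seed, index, retry) record; per-sample failures
are retried with a bumped retry counter and tallied in the manifest.

The dataset stores clean frames by default; noise enters as per-batch
augmentation during training (and per-level at evaluation), re-drawn each
epoch on the raw scale before standardisation. Standardisation is
per-channel z-scoring fitted on the training split only; "raw" training
without standardisation is possible but the 480 channels span two orders
of magnitude, which needlessly burdens a dense first layer.

Desk-scale defaults: 2000 + 2000 training samples with a 75:25
train/test split; the full-scale configuration (100k + 100k and a 50k
validation set) is the same code with larger `n_constraint`/`n_perturb`.

## 5. Adversarial reconstruction network

The networks are written directly in numpy (dense layers, batch
normalisation, leaky ReLU α = 0.2, sigmoid output, Adam with β₁ = 0.5),
with hand-derived backward passes verified against finite differences.
The design is deliberately fully connected rather than convolutional: at
64 x 64 output the whole generator is three matrix products, a tensor
framework adds nothing, and the arithmetic stays bit-reproducible under a
fixed seed.

* **Generator**: 480 → 512 → 1024 → 4096, batch norm + leaky ReLU between
  layers, sigmoid to [0, 1], reshaped to 64 x 64. Only the entry layer's
  weight count depends on the measurement vector length (a 32-electrode
  system changes 480 → 1984 and nothing else).
* **Discriminator**: concat(image 4096, measurement 480) → 256 → 64 → 1,
  sigmoid. Conditioning by concatenation of the flattened measurement
  vector.
* **Losses**: BCE adversarial (labels 1 = ground truth, 0 = reconstruction)
  plus λ·L1 reconstruction with λ = 100; BCE is computed on logits in the
  numerically stable softplus form.
* **Learning rates**: generator 10⁻³, discriminator 10⁻⁸ (constant). The
  tiny discriminator rate is the stabilisation mechanism: the
  discriminator stays near its initialisation (loss ≈ ln 2), cannot
  collapse to zero loss, and the generator is effectively guided by the
  L1 term with a weak adversarial signal. A collapse warning fires if the
  discriminator loss stays below 10⁻⁴ for three consecutive epochs.
* **Logging**: per-epoch generator/discriminator losses and the test-split
  mean relative image error IE = ‖ŷ − y‖₂/‖y‖₂ (L2 norms).

## 6. Quality metrics

RMSE, Pearson 2D correlation, PSNR and a single global (windowless) SSIM,
computed on [0, 1]-normalised images over the full 64 x 64 frame. PSNR
follows this pipeline's convention 10·log₁₀(N·max(ŷ)/Σ(y−ŷ)²) — note the
non-squared peak and the explicit N — with the textbook definition
available via `conventional=True`; the two differ by a constant for
fixed N and peak, so trends agree but absolute values are not comparable
across conventions. SSIM uses the standard stabilisers c₁ = (0.01 L)²,
c₂ = (0.03 L)² with L = 1. Aggregation reports mean ± sd per noise level
with per-sample CSVs and histogram counts; samples on which a metric is
undefined (constant images) are excluded and counted.

## 7. What the synthetic study does and does not show

The generator emulates inter-individual anatomical variability (ellipse
geometry within published windows), tissue-property variability (Gaussian
region values with physical ordering), lesion variability (artery
territories, size range, both stroke types) and instrument noise (peak-SNR
Gaussian). It does not emulate: real cranial anatomy beyond four averaged
regions (no grey/white substructure, no ventricles beyond the stylised
CSF set), 3D current spreading, electrode placement/contact variability,
drift or correlated hardware noise, or patient motion. Training and test
data come from the same generative family, so reconstruction quality here
is an upper bound on what identical methods would achieve on physical
measurements; the package's claims are therefore about the *pipeline*
(solver correctness, learnability, relative ranking of methods, trend
under noise), not about clinical performance.

## 8. Numerical choices and degenerate inputs

* Rejection budgets: 10,000 attempts (geometry), 10,000 (property
  ordering), 6 artery retries; errors name the violated constraint.
* Ellipse perimeters via the complete elliptic integral (scipy `ellipe`),
  exact to machine precision.
* Rasterisation is pixel-centre sampling; boundary points count as inside.
* The linear solver rejects solutions with relative residual above 1e−8
  (direct LU; typical residuals are at machine precision).
* Degenerate rasters (empty hemisphere or CSF at the target resolution)
  raise instead of silently producing broken targets; the dataset builder
  retries them under a fresh seed record.
* Sampled semiaxes derived from offsets are floored at 2 mm so that the
  unconstrained sampling law stays unbiased; degenerate candidates are
  eliminated by the rejection windows rather than by silent resampling.

## 9. Reported problem sizes

The shipped tests and the acceptance script use: 500 phantoms for
population statistics; 200,000 condition draws; solver grids of 64²–256²
(256² for the closed-form capacitor check); and a desk-scale training
study of 4000 samples / 20 epochs on the 64² solver grid. These are the
package's default study sizes; all of them scale up by changing one
argument.
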