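# Methods

`mirsim` is a behavioral simulator of an analog in-memory Fourier-transform
engine: a memristor crossbar whose conductances store a DFT matrix, so that a
vector-matrix multiply (Ohm's law for the products, Kirchhoff's current law
for the sums) performs an N-point transform in one analog step.  The package
models the mapping and programming of the matrix, the device non-idealities
that perturb operation, and two end-to-end medical-imaging pipelines (MRI
K-space inversion and CT reconstruction via the Fourier central slice
theorem) whose image quality and segmentation agreement quantify the impact
of those non-idealities.

## Transform conventions

The unitary DFT matrix is `W[j,k] = exp(-2*pi*i*j*k/N)/sqrt(N)`.  The forward
transform applies a further `1/sqrt(N)` (total scale `1/N`); the inverse uses
`sqrt(N) * conj(W)` (total scale 1), so forward/inverse compose to the
identity without renormalization.  2D transforms are executed exactly as the
hardware dataflow prescribes: the matrix is split into column vectors, each
column is 1D-transformed, the intermediate is transposed, and a second
column pass follows — `M + N` 1D transforms for an `M x N` input (128 for
64 x 64), with the transpose free.  No FFT factorization is used anywhere:
the point of the architecture is an O(1) dense analog product, and the
software mirrors it with dense matrix products.  Spectra are DC-first;
centered (fftshift-style) ordering appears only where the CT gridding needs
it, behind explicit re-orderings.

A complex operator is realized on a single real array through the block form
`[[Re(W), -Im(W)], [Im(W), Re(W)]]` acting on stacked `[Re(x); Im(x)]`
vectors; the inverse direction only flips the sign of the imaginary blocks
(it is the same block form of `conj(W)`).

## Crossbar model

Signed block-matrix entries become differential pairs of nonnegative
conductances; the matrix is scaled linearly so its largest magnitude maps to
`g_full_scale` (default 100 uS — the physical range is not a published
figure, and every accuracy property is scale-invariant because outputs are
de-scaled by the recorded factor).  Inputs are idealized analog voltages
(`read_voltage` 0.2 V per signal unit, negatives allowed; converter
quantization is not modeled).  Wire resistance is not modeled: at the
0.13 um node it is a sub-dominant effect.

Programming schemes:

* **QAM (quasi-analog mapping)** — write-verify iterates until the cell is
  within `mapping_margin` (default 0.25 uS) of the continuous target.  The
  residual is modeled as independent uniform error on `[-margin, +margin]`,
  clipped at 0 uS.  The uniform shape is a modeling choice (only the margin
  is a published figure); its variance `margin^2/3 ~ 0.0208 uS^2` matches
  the ~0.02 uS^2 error statistic the scheme is known for.  Cells whose
  target is exactly zero clip half their error distribution, which pulls
  the array-wide MSE slightly below the uniform bound (~0.015 uS^2 for the
  64-point mapping, still 0.02 at two decimals).
* **QM (quantized mapping)** — targets snap to the nearest of `n_levels`
  uniform levels on `[0, g_full_scale]` (default 25 for the 64-point
  matrix; how levels are counted in hardware is not published, so this is a
  parameter), ties rounding toward the higher conductance, then the same
  margin error applies.  Its error therefore carries an extra quantization
  term and stochastically dominates QAM's.

Operation non-idealities: per-read Gaussian current noise per cell
(std 50–600 nA studied; the typical device value is 50–100 nA), and
stuck-at faults — each cell fails independently with the configured rate,
pinned to 0 uS by default ("off"; the failed state is not published, "on"
and "mixed" policies exist).  Because only column sums of the per-cell noise
are observable, the implementation draws one `N(0, sigma*sqrt(rows))`
variate per column and plane per read — distributionally identical to
cell-by-cell draws and much faster.  All randomness flows from seeded
generators; an engine seeded identically reproduces programming, faults and
read noise bit-for-bit.

## MRI pipeline

Images are tiled into 64 x 64 patches (zero-padded if needed), each patch is
taken to K-space by a lossless exact forward 2D DFT (this emulates the
scanner acquisition and is deliberately noise-free), and reconstruction is a
per-tile 2D IDFT on the configured engine.  The imaginary residue of a noisy
inverse is discarded by taking the real part (magnitude is available behind
a flag).  Volumes are processed slice by slice; no 3D transform.  The exact
path is an identity to < 1e-6, so all reconstruction error is attributable
to the crossbar model.

## CT pipeline

Each 36 x 36 patch is embedded centered in a 64-bin field of view and
parallel-beam projected from 180 uniform angles in [0, 180)
(`skimage.transform.radon`, linear interpolation).  Every projection is
1D-DFT'd on the engine and its 64 radial samples are filled along the
projection's frequency line through the center of a 64 x 64 grid by
nearest-neighbour gridding with hit averaging and zero fill; a 2D IDFT on
the engine, a real-part extraction, and a central 36 x 36 crop complete the
patch — three transform stages in total.  Full images are covered by
overlapping patches (stride 18, half a patch) averaged with uniform weights;
stride 36 degenerates to plain tiling.  Uniform averaging keeps the
assembly linear.

**Phase convention (a deliberate design choice).**  The gridded spectrum is
referenced to the detector's central bin (the rotation axis), i.e. the grid
holds the spectrum of the field of view circularly rolled so the axis sits
at index (0, 0), and the inverse image is rolled back before cropping.
Against a corner-referenced grid every sample would carry a
`(-1)^(k+l)` checkerboard factor (the spectral signature of center
placement), and nearest-neighbour rounding of sample positions then
scrambles signs: reconstruction correlation collapses to ~0.55–0.8.  With
center referencing the gridded spectrum varies smoothly, the identical NN
rule yields correlations of ~0.985–0.995 and ~26 dB PSNR on smooth
phantoms, and the on-axis central-slice identity is exact.  Bilinear
sample-spreading (without density compensation) was measured to be worse
than NN and is not offered.

The central slice theorem holds exactly at 0°/90° (image rotation is exact
there) on every grid cell the radial lines reach; the single unpaired
Nyquist cell of a line can fall outside the grid at some angles and stays
zero.  Oblique angles are limited by rotation interpolation and frequency
rounding.  More angles can only add coverage, so quality is non-decreasing
in the angle count.

## Metrics

MSE, `PSNR = 20*log10(MAX_I/sqrt(MSE))` and
`SNR = 10*log10(sum I^2 / sum (I-K)^2)` with `MAX_I` the reference image's
own maximum (an override exists for fixed 8-bit comparisons); identical
images report `+inf`, serialized as `"inf"`.  DICE is
`2|X & Y|/(|X|+|Y|)`; two empty masks score 1, empty vs nonempty 0.
Volumes are scored per slice and averaged.

## Synthetic data and segmentation stand-in

Phantoms are deterministic ellipse compositions: dim background ellipses
(15–45% of the organ intensity) painted first, one full-intensity organ
ellipse painted last, whose raster footprint is the ground-truth mask.
`mri` mode spans [0, 255], `ct` mode a soft-tissue-like [0, 400] stored
scale.  The generator reproduces the geometry and dynamic range that the
pipelines care about, but not real anatomy, partial-volume edges, scanner
noise statistics or full Hounsfield dynamic range — passing tests show the
*transform and device models* behave, not that clinical images would score
identically.  Segmentation is a global threshold (half the organ intensity)
plus largest-connected-component selection, applied identically to
reference and reconstruction, so relative DICE isolates the effect of
reconstruction noise; neural segmenters are out of scope, and externally
produced masks can be compared with the same DICE routine.

## Sweeps and operation counts

Robustness sweeps rerun a full pipeline over a read-noise grid (default ten
values spanning 50–600 nA) or a fault-rate grid (default seven log-spaced
values spanning 0.1–2%), ten trials per value.  The chip is programmed once
per sweep (fixed programming seed derived from the base seed) and only the
operating noise/fault streams vary across trials, modeling repeated
scenarios on one physical array; faults are resampled per trial.  Mean PSNR
is then non-increasing in either non-ideality by construction of the error
budget.  Test and acceptance runs use a 64 x 64 MRI phantom and a 72 x 72
CT phantom (3 x 3 overlapping patches), sizes chosen so the full suite runs
in seconds while still exercising tiling, overlap and every transform size
the hardware demonstration used.

Operation counting follows the block-form convention: one N-point transform
is a `(2N)^2`-cell VMM counted as one multiply and one add per cell
(`8 N^2` operations), and a 2D task of `M x N` costs `M + N` transforms.
The benchmark tasks use the full-size convention (a 320 x 320 MRI raw
matrix: 640 320-point IDFTs, 524,288,000 operations; a 768-bin/180-angle CT
task: 180 + 1536 768-point transforms, 8,097,103,872 operations) even
though the hardware demonstration tiled to 64-point transforms — transform
size is an explicit parameter so both views are expressible.  Energy,
latency and die-area figures are hardware-derived and out of scope.

## Known limitations

- No SPICE-level device physics: no SET/RESET dynamics, retention/drift,
  ADC transfer curves, or IR drop.
- The conductance range, read voltage and stuck state are declared
  defaults, not measured values; absolute current levels are therefore
  nominal even though signal-domain accuracy is scale-invariant.
- CT gridding uses no interpolation kernel; reconstruction accuracy is
  gridding-limited (~26 dB on smooth phantoms) rather than noise-limited
  at typical device noise.
- No filtered back-projection, fan/cone beams, coil combination or
  iterative/learned reconstruction.
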