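# mirsim

A behavioral simulator of analog in-memory Fourier transforms on memristor
crossbars, driving end-to-end MRI and CT image reconstruction.

In computing-in-memory, an `N`-point DFT becomes a single analog
vector-matrix multiply: the DFT matrix is stored as conductances, inputs
arrive as voltages, and Ohm's/Kirchhoff's laws produce the output currents
in one step.  Because the matrix is complex, it is mapped through the real
block form

    [X_re]   [ Re(W)  -Im(W) ] [x_re]
    [X_im] = [ Im(W)   Re(W) ] [x_im]     (inverse: flip the Im signs)

with `W[j,k] = exp(-2*pi*i*j*k/N)/sqrt(N)`, and signed entries become
differential pairs of nonnegative conductances.  `mirsim` models this
mapping, two programming schemes (quasi-analog write-verify within a
±0.25 µS margin, and quantized mapping onto a finite level grid), read
noise and stuck-at faults, and measures how those non-idealities propagate
through two reconstruction pipelines:

* **MRI** — tile the image into 64 × 64 patches, synthesize K-space with a
  lossless forward 2D DFT, reconstruct with a (noisy) 2D IDFT on the
  simulated crossbar, reassemble.
* **CT** — parallel-beam Radon projections from 180 angles, per-angle 1D
  DFT, central-slice filling of a 64 × 64 Fourier grid, 2D IDFT, 36 × 36
  crop, with overlapping patches averaged.

Quality is scored with MSE/PSNR/SNR and, after threshold segmentation,
DICE overlap against ground-truth organ masks from the built-in ellipse
phantom generator — no external data needed.  The intended audience is
anyone studying analog CIM accelerators for signal processing: the
simulator answers "how much image and segmentation quality survives a
given device error budget?"

See `docs/methods.md` for the model details and conventions.

## Worked example

```python
import numpy as np
from mirsim import (
    CrossbarConfig, CrossbarEngine, NoiseSpec,
    make_phantom, mri_pipeline, image_metrics, dice_score, threshold_segment,
    mapping_error_stats,
)
from mirsim.crossbar import build_dft_crossbar

# program a 64-point DFT crossbar with quasi-analog write-verify mapping
arr = build_dft_crossbar(64, "forward", CrossbarConfig(), seed=0)
stats = mapping_error_stats(arr)
print(f"mapping MSE: {stats['mse']:.4f} uS^2, max |error|: {stats['max_abs_error']:.4f} uS")

# reconstruct a synthetic MRI phantom through a noisy crossbar
ph = make_phantom(64, seed=2, mode="mri")
engine = CrossbarEngine(CrossbarConfig(), NoiseSpec(read_noise_std=100.0), seed=1)
recon = mri_pipeline(ph.image, engine=engine)
m = image_metrics(ph.image, recon)
print(f"PSNR: {m.psnr_db:.2f} dB, SNR: {m.snr_db:.2f} dB")

mask = threshold_segment(recon, ph.segmentation_threshold)
print(f"DICE vs ground truth: {dice_score(mask, ph.organ_mask):.3f}")
```

Output:

```
mapping MSE: 0.0150 uS^2, max |error|: 0.2500 uS
PSNR: 51.50 dB, SNR: 42.87 dB
DICE vs ground truth: 1.000
```

The mapping error is bounded by the 0.25 µS write-verify margin and its MSE
sits at the uniform-error level (≈0.02 µS² at two decimals).  At a typical
100 nA read-noise level the reconstruction stays above 50 dB PSNR — far
beyond the ~30 dB threshold of visually lossless — and segmentation of the
organ is unaffected.

A command-line interface mirrors the library:

```bash
mir phantom --size 320 --mode mri --seed 7 --out phantom.png --mask mask.png
mir mri-sim --input phantom.png --tile 64 --engine crossbar --out recon.png --report metrics.json
mir ct-sim  --input phantom.png --angles 180 --bins 64 --patch 36 --stride 18 --engine crossbar --out ct.png
mir sweep-noise --task mri --stds 50,100,200,300,400,500,600 --trials 10 --seed 1 --out sweep.csv
mir opcount --task ct --bins 768 --angles 180
```

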