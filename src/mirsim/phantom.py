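"""Ellipse-based synthetic phantoms, test signals and a simple segmenter.

The phantom generator emulates the geometry of organ slices (one bright
"organ" ellipse over dimmer anatomical background ellipses) so that every
reconstruction pipeline can be exercised and scored, including
segmentation agreement, without any external dataset.  ``mri`` mode maps
intensities to an 8-bit-like [0, 255] range; ``ct`` mode uses a soft-tissue
Hounsfield-like [0, 400] range (stored values, no display windowing).

The segmenter is deliberately simple -- global threshold followed by
largest-connected-component selection.  It is applied identically to the
reference and the reconstructed image, so *relative* DICE between the two
paths measures how much reconstruction noise perturbs segmentation, which
is the quantity the pipelines report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["Ellipse", "Phantom", "make_phantom", "make_test_signal", "threshold_segment"]

#: documented sinusoid-mix components: (frequency resolver, amplitude)
SINUSOID_MIX_AMPLITUDES = (1.0, 0.5)


@dataclass(frozen=True)
class Ellipse:
    """One phantom ellipse: center (row, col), semi-axes, rotation, value."""

    center: tuple[float, float]
    axes: tuple[float, float]
    rotation_deg: float
    intensity: float
    organ: bool = False


@dataclass
class Phantom:
    image: np.ndarray
    organ_mask: np.ndarray
    ellipses: list[Ellipse] = field(default_factory=list)
    mode: str = "mri"
    seed: int | None = None

    @property
    def organ_intensity(self) -> float:
        return max(e.intensity for e in self.ellipses if e.organ)

    @property
    def segmentation_threshold(self) -> float:
        """Half the organ intensity -- separates organ from background."""
        return self.organ_intensity / 2.0


def _raster_ellipse(e: Ellipse, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - e.center[0]
    dc = cc - e.center[1]
    th = np.deg2rad(e.rotation_deg)
    u = dr * np.cos(th) + dc * np.sin(th)
    v = -dr * np.sin(th) + dc * np.cos(th)
    return (u / e.axes[0]) ** 2 + (v / e.axes[1]) ** 2 <= 1.0


def make_phantom(
    size: int, n_ellipses: int = 4, seed: int | None = 0, mode: str = "mri"
) -> Phantom:
    """Deterministic random phantom with a ground-truth organ mask.

    Background ellipses are painted first at 15-45% of the organ
    intensity; the single organ ellipse is painted last at full intensity,
    so its raster footprint *is* the ground-truth mask and a threshold at
    half the organ intensity separates it cleanly in the noise-free image.
    """
    if size < 16:
        raise ValueError("size must be >= 16")
    if n_ellipses < 1:
        raise ValueError("n_ellipses must be >= 1")
    if mode not in ("mri", "ct"):
        raise ValueError(f"mode must be 'mri' or 'ct', got {mode!r}")
    rng = np.random.default_rng(seed)
    organ_intensity = 255.0 if mode == "mri" else 400.0

    ellipses: list[Ellipse] = []
    for _ in range(n_ellipses - 1):
        ellipses.append(
            Ellipse(
                center=tuple(rng.uniform(0.25 * size, 0.75 * size, 2)),
                axes=tuple(rng.uniform(size / 10, size / 4, 2)),
                rotation_deg=float(rng.uniform(0, 180)),
                intensity=float(rng.uniform(0.15, 0.45) * organ_intensity),
            )
        )
    ellipses.append(
        Ellipse(
            center=tuple(rng.uniform(0.4 * size, 0.6 * size, 2)),
            axes=tuple(rng.uniform(size / 6, size / 4, 2)),
            rotation_deg=float(rng.uniform(0, 180)),
            intensity=organ_intensity,
            organ=True,
        )
    )

    image = np.zeros((size, size))
    for e in ellipses:  # painted in order; organ last overwrites overlaps
        image[_raster_ellipse(e, image.shape)] = e.intensity
    organ_mask = _raster_ellipse(ellipses[-1], image.shape)
    return Phantom(image=image, organ_mask=organ_mask, ellipses=ellipses, mode=mode, seed=seed)


def sinusoid_mix_frequencies(n: int) -> tuple[int, int]:
    """Component frequencies (bins) of the ``sinusoid_mix`` test signal."""
    return max(1, n // 8), max(2, n // 4)


def make_test_signal(n: int, kind: str, seed: int | None = 0) -> np.ndarray:
    """Deterministic complex test vectors for exercising the transforms.

    ``sinusoid_mix`` is ``cos(2*pi*f1*t/n) + 0.5*sin(2*pi*f2*t/n)`` with
    ``(f1, f2)`` from :func:`sinusoid_mix_frequencies`, so its exact
    spectrum peaks at those bins and their mirror images.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "impulse":
        x = np.zeros(n, dtype=complex)
        x[0] = 1.0
        return x
    if kind == "constant":
        return np.ones(n, dtype=complex)
    if kind == "sinusoid_mix":
        t = np.arange(n)
        f1, f2 = sinusoid_mix_frequencies(n)
        a1, a2 = SINUSOID_MIX_AMPLITUDES
        return (
            a1 * np.cos(2 * np.pi * f1 * t / n) + a2 * np.sin(2 * np.pi * f2 * t / n)
        ).astype(complex)
    if kind == "random_complex":
        rng = np.random.default_rng(seed)
        return rng.normal(size=n) + 1j * rng.normal(size=n)
    raise ValueError(f"unknown signal kind {kind!r}")


def threshold_segment(img: np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask: pixels >= threshold, largest connected component only."""
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    mask = img >= threshold
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)
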