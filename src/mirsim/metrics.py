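"""Image-fidelity and segmentation-agreement metrics.

MSE is the mean squared pixel difference; PSNR is
``20*log10(MAX_I / sqrt(MSE))`` in dB, where ``MAX_I`` is the maximum
pixel value of the *reference* image (overridable for fixed bit-depth
comparisons); SNR is ``10*log10(sum(I^2) / sum((I-K)^2))`` in dB.  DICE is
``2|X & Y| / (|X| + |Y|)`` between binary masks.  Identical images yield
``+inf`` PSNR/SNR, serialized as the string ``"inf"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "image_metrics", "dice_score", "pearson_correlation"]


@dataclass(frozen=True)
class MetricsReport:
    mse: float
    psnr_db: float
    snr_db: float
    max_ref: float

    def to_dict(self) -> dict:
        def enc(v: float):
            return "inf" if math.isinf(v) else v

        return {
            "mse": self.mse,
            "psnr_db": enc(self.psnr_db),
            "snr_db": enc(self.snr_db),
            "max_ref": self.max_ref,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def image_metrics(
    ref: np.ndarray, test: np.ndarray, max_value: float | None = None
) -> MetricsReport:
    """MSE, PSNR and SNR of ``test`` against the reference image."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    diff = ref - test
    mse = float(np.mean(diff**2))
    max_ref = float(np.max(ref)) if max_value is None else float(max_value)
    if mse == 0.0:
        psnr = snr = math.inf
    else:
        psnr = 20.0 * math.log10(max_ref / math.sqrt(mse))
        energy = float(np.sum(ref**2))
        snr = 10.0 * math.log10(energy / float(np.sum(diff**2)))
    return MetricsReport(mse=mse, psnr_db=psnr, snr_db=snr, max_ref=max_ref)


def dice_score(x: np.ndarray, y: np.ndarray) -> float:
    """Overlap agreement ``2|X & Y| / (|X| + |Y|)`` of two binary masks.

    Two empty masks agree perfectly (1.0); empty vs nonempty is 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    for m in (x, y):
        if m.dtype != bool and not np.isin(m, (0, 1)).all():
            raise ValueError("masks must be binary")
    x = x.astype(bool)
    y = y.astype(bool)
    total = int(x.sum()) + int(y.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / total


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two arrays, flattened."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("arrays must have the same size")
    return float(np.corrcoef(a, b)[0, 1])
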