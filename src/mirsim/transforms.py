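"""Exact discrete Fourier transforms and their real block-matrix form.

This module is the noise-free mathematical core of the simulator.  It
constructs the unitary DFT matrix, assembles it into the real block form
used to map a complex operator onto a single analog crossbar
(``[[Re, -Im], [Im, Re]]`` for the forward transform), and executes 1D/2D
transforms through a pluggable *engine* so that the same pipeline code can
run either on exact arithmetic or on the analog crossbar model.

Scaling convention
------------------
The forward N-point transform carries a total scale of ``1/N``::

    X_k = (1/N) * sum_n x_n * exp(-2*pi*i*k*n/N)

i.e. an extra ``1/sqrt(N)`` applied to the unitary DFT matrix.  The inverse
transform carries a total scale of 1 (an extra ``sqrt(N)`` applied to the
conjugate of the unitary matrix), so ``inverse(forward(x)) == x``.  The 2D
transforms inherit ``1/(M*N)`` forward and 1 inverse by running two
column-wise 1D passes with a transpose in between -- exactly the dataflow
of the hardware, where a ``M x N`` 2D transform costs ``N + M`` 1D
transforms and no extra arithmetic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dft_matrix",
    "cmt_block",
    "stack_reim",
    "unstack_reim",
    "ExactEngine",
    "transform_1d",
    "transform_2d",
    "transform_columns",
    "intensity_phase",
]

_DIRECTIONS = ("forward", "inverse")


def _check_direction(direction: str) -> None:
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")


def dft_matrix(n_points: int) -> np.ndarray:
    """Unitary N-point DFT matrix ``W[j, k] = exp(-2*pi*i*j*k/N) / sqrt(N)``.

    Parameters
    ----------
    n_points : int
        Transform length N, at least 1.

    Returns
    -------
    numpy.ndarray
        Complex ``(N, N)`` matrix, unitary to floating-point precision.
    """
    n = int(n_points)
    if n < 1:
        raise ValueError(f"n_points must be >= 1, got {n_points}")
    idx = np.arange(n)
    phase = np.outer(idx, idx) * (-2j * np.pi / n)
    return np.exp(phase) / np.sqrt(n)


def cmt_block(w: np.ndarray, direction: str = "forward") -> np.ndarray:
    """Assemble a complex matrix into its 2N x 2N real block form.

    The complex product ``y = w @ x`` becomes a single real vector-matrix
    multiplication on the stacked vector ``[Re(x); Im(x)]``::

        forward : [[Re(w), -Im(w)], [Im(w),  Re(w)]]
        inverse : [[Re(w),  Im(w)], [-Im(w), Re(w)]]

    The inverse arrangement is the forward form of ``conj(w)``; for the
    symmetric unitary DFT matrix this realizes the inverse transform with
    only a sign change on the imaginary blocks.
    """
    _check_direction(direction)
    w = np.asarray(w, dtype=complex)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"w must be a square matrix, got shape {w.shape}")
    re, im = w.real, w.imag
    if direction == "forward":
        return np.block([[re, -im], [im, re]])
    return np.block([[re, im], [-im, re]])


def stack_reim(z: np.ndarray) -> np.ndarray:
    """Stack a complex vector into the real vector ``[Re(z); Im(z)]``."""
    z = np.asarray(z, dtype=complex)
    return np.concatenate([z.real, z.imag])


def unstack_reim(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`stack_reim`: rebuild the complex vector."""
    v = np.asarray(v, dtype=float)
    if v.size % 2:
        raise ValueError("stacked vector must have even length")
    n = v.size // 2
    return v[:n] + 1j * v[n:]


class ExactEngine:
    """Noise-free transform engine computing dense matrix-vector products.

    Serves as the golden reference for the crossbar engine.  Operators are
    cached per ``(n_points, direction)``.  ``n_transforms`` counts the 1D
    transforms executed; ``pass_log`` records one entry per column-wise
    pass, which the pipelines use to report their transform-stage counts.
    """

    def __init__(self) -> None:
        self._operators: dict[tuple[int, str], np.ndarray] = {}
        self.n_transforms = 0
        self.pass_log: list[tuple[str, int, int]] = []

    def _operator(self, n: int, direction: str) -> np.ndarray:
        key = (n, direction)
        if key not in self._operators:
            w = dft_matrix(n)
            if direction == "forward":
                op = w / np.sqrt(n)
            else:
                op = np.conj(w) * np.sqrt(n)
            self._operators[key] = op
        return self._operators[key]

    def transform(self, x: np.ndarray, direction: str) -> np.ndarray:
        _check_direction(direction)
        x = np.asarray(x, dtype=complex)
        if x.ndim != 1:
            raise ValueError("engine input must be a 1D vector")
        self.n_transforms += 1
        return self._operator(x.size, direction) @ x


def transform_1d(x: np.ndarray, direction: str, engine=None) -> np.ndarray:
    """1D DFT (total scale 1/N) or IDFT (total scale 1) of a complex vector."""
    if engine is None:
        engine = ExactEngine()
    x = np.asarray(x, dtype=complex)
    if x.ndim != 1:
        raise ValueError(f"expected a 1D vector, got shape {x.shape}")
    return engine.transform(x, direction)


def transform_columns(a: np.ndarray, direction: str, engine) -> np.ndarray:
    """Apply the engine's 1D transform to every column of ``a``.

    One call is one dataflow *pass*: the matrix is split into column
    vectors, each fed through the engine, and the pass is appended to
    ``engine.pass_log`` as ``(direction, n_points, n_vectors)``.
    """
    a = np.asarray(a, dtype=complex)
    if a.ndim != 2:
        raise ValueError(f"expected a 2D matrix, got shape {a.shape}")
    out = np.empty_like(a)
    for c in range(a.shape[1]):
        out[:, c] = engine.transform(a[:, c], direction)
    engine.pass_log.append((direction, a.shape[0], a.shape[1]))
    return out


def transform_2d(a: np.ndarray, direction: str, engine=None) -> np.ndarray:
    """2D DFT/IDFT of an ``M x N`` matrix via two column-wise 1D passes.

    Forward total scale is ``1/(M*N)``, inverse is 1.  The implementation
    follows the hardware dataflow literally: transform all N columns,
    transpose, transform all M columns of the intermediate, transpose back
    (``N + M`` 1D transforms in total, 128 for a 64 x 64 input).
    """
    _check_direction(direction)
    if engine is None:
        engine = ExactEngine()
    a = np.asarray(a, dtype=complex)
    if a.ndim != 2:
        raise ValueError(f"expected a 2D matrix, got shape {a.shape}")
    first = transform_columns(a, direction, engine)
    second = transform_columns(first.T.copy(), direction, engine)
    return second.T.copy()


def intensity_phase(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split complex spectra into magnitude and phase (phase of 0 is 0)."""
    z = np.asarray(z, dtype=complex)
    mag = np.abs(z)
    phase = np.where(mag == 0, 0.0, np.angle(z))
    return mag, phase
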