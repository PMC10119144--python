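"""Analog memristor-crossbar model for the block-form DFT.

Signed matrix entries are stored as *differential pairs* of nonnegative
conductances (a positive and a negative column per logical output); the
real block matrix of a complex transform is scaled so its largest entry
maps to ``g_full_scale`` (in microsiemens) and programmed with one of two
schemes:

* quasi-analog mapping (QAM): write-verify until the cell is within a
  fixed ``mapping_margin`` of the continuous target.  Modeled as additive
  uniform error on ``[-margin, +margin]``, clipped at zero conductance.
* quantized mapping (QM): the target is first snapped to one of
  ``n_levels`` uniformly spaced conductance levels, then programmed with
  the same margin model, so its error carries an extra quantization term.

A vector-matrix multiply obeys Ohm's and Kirchhoff's laws: inputs are
voltages on the rows, each column output is the sum of ``g * v`` over its
cells plus an independent Gaussian read-noise current per cell per read,
and the differential pair is subtracted to recover the signed product.
Stuck-at faults pin individual cells to a device state (0 uS by default).

Units: conductance in uS, voltage in V, current in uA, read noise in nA.

Array layout note: conductance planes are stored ``(rows=inputs,
cols=outputs)``, i.e. the transpose of the mathematical operator, matching
the bit-line (input) / source-line (output) orientation of the hardware.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .transforms import (
    cmt_block,
    dft_matrix,
    stack_reim,
    unstack_reim,
    _check_direction,
)

__all__ = [
    "CrossbarConfig",
    "NoiseSpec",
    "CrossbarArray",
    "differential_decompose",
    "scale_to_conductance",
    "program_qam",
    "program_qm",
    "inject_stuck_faults",
    "vmm",
    "mapping_error_stats",
    "build_dft_crossbar",
    "qam_mapping_mse",
    "CrossbarEngine",
    "SUBMATRIX_LABELS",
]

#: Differential-pair submatrix labels: real/imaginary part, positive/negative.
SUBMATRIX_LABELS = ("R.P.", "R.N.", "I.P.", "I.N.")

_POS, _NEG = 0, 1


@dataclass(frozen=True)
class CrossbarConfig:
    """Programming configuration of one crossbar array.

    Parameters
    ----------
    g_full_scale : float
        Conductance (uS) assigned to the largest ``|entry|`` of the mapped
        matrix.  The hardware range is not a published figure; accuracy is
        scale-invariant because outputs are de-scaled by the recorded
        factor.
    mapping_margin : float
        Write-verify acceptance band (uS); programming stops once the cell
        is within this margin of the target.
    n_levels : int or None
        Number of uniformly spaced conductance levels for the QM scheme
        (None for QAM, which uses no level grid).
    read_voltage : float
        Volts per unit of input signal amplitude.
    scheme : str
        ``"qam"`` or ``"qm"``.
    """

    g_full_scale: float = 100.0
    mapping_margin: float = 0.25
    n_levels: int | None = None
    read_voltage: float = 0.2
    scheme: str = "qam"

    def __post_init__(self) -> None:
        if self.g_full_scale <= 0:
            raise ValueError("g_full_scale must be > 0")
        if self.mapping_margin < 0:
            raise ValueError("mapping_margin must be >= 0")
        if self.scheme not in ("qam", "qm"):
            raise ValueError(f"scheme must be 'qam' or 'qm', got {self.scheme!r}")
        if self.scheme == "qm" and (self.n_levels is None or self.n_levels < 2):
            raise ValueError("QM requires n_levels >= 2")


@dataclass(frozen=True)
class NoiseSpec:
    """Device non-idealities applied during operation.

    ``read_noise_std`` is the standard deviation (nA) of the Gaussian
    current fluctuation of a single cell during one read; it is resampled
    on every VMM.  ``stuck_rate`` is the per-cell probability of a
    stuck-at fault; faulted cells are pinned according to
    ``stuck_value_policy`` (``"off"`` -> 0 uS, ``"on"`` -> full scale,
    ``"mixed"`` -> either, at random).
    """

    read_noise_std: float = 0.0
    stuck_rate: float = 0.0
    stuck_value_policy: str = "off"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.read_noise_std < 0:
            raise ValueError("read_noise_std must be >= 0")
        if not 0.0 <= self.stuck_rate <= 1.0:
            raise ValueError("stuck_rate must be in [0, 1]")
        if self.stuck_value_policy not in ("off", "on", "mixed"):
            raise ValueError("stuck_value_policy must be 'off', 'on' or 'mixed'")


@dataclass
class CrossbarArray:
    """A programmed differential crossbar.

    ``g_target`` and ``g_programmed`` have shape ``(2, rows, cols)``: plane
    0 holds the positive cells, plane 1 the negative cells of each
    differential pair.  ``g_target`` is the ideal continuous target
    (before any quantization); mapping-error statistics are taken against
    it.  ``fault_mask`` marks stuck cells.  ``scale_factor`` is the uS per
    unit matrix entry used at mapping time, recorded so output currents
    can be de-scaled exactly.
    """

    g_target: np.ndarray
    g_programmed: np.ndarray
    fault_mask: np.ndarray
    scale_factor: float
    config: CrossbarConfig
    n_points: int | None = None
    direction: str | None = None

    @property
    def n_inputs(self) -> int:
        return self.g_target.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.g_target.shape[2]

    @property
    def n_cells(self) -> int:
        return self.g_target.size

    def signed_matrix(self) -> np.ndarray:
        """Effective signed operator (outputs x inputs) in matrix units."""
        g = self.g_programmed[_POS] - self.g_programmed[_NEG]
        return g.T / self.scale_factor

    def submatrix_masks(self) -> dict[str, np.ndarray]:
        """Boolean cell masks of the four differential submatrices.

        Only defined for arrays mapped from a 2N x 2N complex block form
        (``n_points`` set): the diagonal quadrants hold the real part, the
        off-diagonal quadrants the imaginary part.
        """
        if self.n_points is None:
            raise ValueError("submatrix masks require a block-form array")
        n = self.n_points
        quad = np.zeros((2 * n, 2 * n), dtype=bool)
        real = quad.copy()
        real[:n, :n] = True
        real[n:, n:] = True
        imag = ~real
        full = np.zeros_like(self.g_target, dtype=bool)
        masks = {}
        for label, region, plane in (
            ("R.P.", real, _POS),
            ("R.N.", real, _NEG),
            ("I.P.", imag, _POS),
            ("I.N.", imag, _NEG),
        ):
            m = full.copy()
            m[plane] = region
            masks[label] = m
        return masks


def differential_decompose(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a signed matrix into nonnegative positive/negative parts.

    ``pos - neg == m``, both parts nonnegative, and at most one of the two
    is nonzero per cell (``pos * neg == 0``).
    """
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix entries must be finite")
    pos = np.where(m > 0, m, 0.0)
    neg = np.where(m < 0, -m, 0.0)
    return pos, neg


def scale_to_conductance(
    m: np.ndarray, g_full_scale: float, strict: bool = False
) -> tuple[np.ndarray, float]:
    """Map a signed operator to differential conductance targets (uS).

    The operator ``m`` (outputs x inputs) is linearly scaled so that
    ``max|entry| -> g_full_scale`` and laid out in array orientation
    (inputs x outputs).  Returns ``(targets, scale_factor)`` where
    ``targets`` has shape ``(2, n_inputs, n_outputs)`` and
    ``scale_factor`` (uS per matrix unit) de-scales output currents.
    """
    m = np.asarray(m, dtype=float)
    peak = float(np.max(np.abs(m))) if m.size else 0.0
    if peak == 0.0:
        if strict:
            raise ValueError("cannot scale an all-zero matrix")
        targets = np.zeros((2,) + m.T.shape)
        return targets, 1.0
    scale_factor = g_full_scale / peak
    pos, neg = differential_decompose(m.T * scale_factor)
    return np.stack([pos, neg]), scale_factor


def _as_targets(targets: np.ndarray) -> np.ndarray:
    targets = np.asarray(targets, dtype=float)
    if np.any(targets < 0):
        raise ValueError("conductance targets must be nonnegative")
    return targets


def program_qam(
    targets: np.ndarray,
    config: CrossbarConfig,
    seed: int | np.random.SeedSequence | None = None,
    *,
    scale_factor: float = 1.0,
    n_points: int | None = None,
    direction: str | None = None,
) -> CrossbarArray:
    """Program targets with the quasi-analog write-verify model.

    Each cell receives an independent uniform error on
    ``[-mapping_margin, +mapping_margin]`` uS (the write-verify acceptance
    band), clipped at 0 uS.  Deterministic given ``seed``.
    """
    targets = _as_targets(targets)
    rng = np.random.default_rng(seed)
    err = rng.uniform(-config.mapping_margin, config.mapping_margin, targets.shape)
    g = np.clip(targets + err, 0.0, None)
    return CrossbarArray(
        g_target=targets,
        g_programmed=g,
        fault_mask=np.zeros(targets.shape, dtype=bool),
        scale_factor=scale_factor,
        config=config,
        n_points=n_points,
        direction=direction,
    )


def program_qm(
    targets: np.ndarray,
    config: CrossbarConfig,
    seed: int | np.random.SeedSequence | None = None,
    *,
    scale_factor: float = 1.0,
    n_points: int | None = None,
    direction: str | None = None,
) -> CrossbarArray:
    """Program targets with the quantized-mapping model.

    Targets are snapped to the nearest of ``n_levels`` uniform levels on
    ``[0, g_full_scale]`` (ties round toward the higher conductance), then
    the QAM margin error is added on top.  ``g_target`` keeps the ideal
    continuous values so error statistics include the quantization term.
    """
    if config.n_levels is None or config.n_levels < 2:
        raise ValueError("QM programming requires n_levels >= 2")
    targets = _as_targets(targets)
    step = config.g_full_scale / (config.n_levels - 1)
    levels = np.floor(targets / step + 0.5)  # half-way ties go up
    quantized = np.clip(levels, 0, config.n_levels - 1) * step
    arr = program_qam(
        quantized,
        config,
        seed,
        scale_factor=scale_factor,
        n_points=n_points,
        direction=direction,
    )
    arr.g_target = targets
    return arr


def inject_stuck_faults(
    arr: CrossbarArray,
    noise: NoiseSpec,
    rng: np.random.Generator | int | None = None,
) -> CrossbarArray:
    """Return a copy of the array with stuck-at faults applied.

    Each cell fails independently with probability ``noise.stuck_rate``;
    failed cells are pinned to the policy value and recorded in
    ``fault_mask``.  Deterministic given the generator/seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(noise.seed if rng is None else rng)
    shape = arr.g_programmed.shape
    mask = rng.random(shape) < noise.stuck_rate
    g = arr.g_programmed.copy()
    if noise.stuck_value_policy == "off":
        stuck = np.zeros(shape)
    elif noise.stuck_value_policy == "on":
        stuck = np.full(shape, arr.config.g_full_scale)
    else:  # mixed: device fails high or low with equal probability
        stuck = rng.choice([0.0, arr.config.g_full_scale], size=shape)
    g[mask] = stuck[mask]
    return dataclasses.replace(
        arr, g_programmed=g, fault_mask=arr.fault_mask | mask
    )


def vmm(
    arr: CrossbarArray,
    v: np.ndarray,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Analog vector-matrix multiply: voltages in, signed currents out.

    Each column current is ``sum_rows(g * v)`` plus one Gaussian read-noise
    draw per cell (std ``noise.read_noise_std`` nA), resampled on every
    call; the positive and negative columns of each differential pair are
    subtracted to yield the signed output in uA.  The per-cell draws on a
    column are summed, so they are sampled directly as one normal with std
    ``sigma * sqrt(rows)`` per column and plane -- distributionally
    identical to cell-by-cell sampling.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size != arr.n_inputs:
        raise ValueError(
            f"voltage vector length {v.shape} does not match {arr.n_inputs} rows"
        )
    gp, gn = arr.g_programmed
    i_pos = gp.T @ v
    i_neg = gn.T @ v
    if noise is not None and noise.read_noise_std > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(noise.seed if rng is None else rng)
        sigma_ua = noise.read_noise_std * 1e-3  # nA -> uA
        col_sigma = sigma_ua * np.sqrt(arr.n_inputs)
        eps = rng.normal(0.0, col_sigma, size=(2, arr.n_outputs))
        i_pos = i_pos + eps[0]
        i_neg = i_neg + eps[1]
    return i_pos - i_neg


def mapping_error_stats(arr: CrossbarArray) -> dict:
    """Programming-error report against the ideal (pre-quantization) target.

    Returns overall MSE (uS^2) and max absolute error (uS), plus a
    per-submatrix breakdown (R.P./R.N./I.P./I.N.) for block-form arrays.
    """
    err = arr.g_programmed - arr.g_target
    report = {
        "mse": float(np.mean(err**2)),
        "max_abs_error": float(np.max(np.abs(err))) if err.size else 0.0,
        "n_cells": int(err.size),
        "n_faults": int(arr.fault_mask.sum()),
    }
    if arr.n_points is not None:
        sub = {}
        for label, mask in arr.submatrix_masks().items():
            e = err[mask]
            sub[label] = {
                "mse": float(np.mean(e**2)),
                "max_abs_error": float(np.max(np.abs(e))),
            }
        report["submatrices"] = sub
    return report


def build_dft_crossbar(
    n_points: int,
    direction: str,
    config: CrossbarConfig | None = None,
    noise: NoiseSpec | None = None,
    seed: int | np.random.SeedSequence | None = None,
    fault_rng: np.random.Generator | None = None,
) -> CrossbarArray:
    """Map, program and (optionally) fault a DFT/IDFT block-form crossbar."""
    _check_direction(direction)
    config = config or CrossbarConfig()
    block = cmt_block(dft_matrix(n_points), direction)
    targets, scale_factor = scale_to_conductance(block, config.g_full_scale)
    program = program_qm if config.scheme == "qm" else program_qam
    arr = program(
        targets,
        config,
        seed,
        scale_factor=scale_factor,
        n_points=n_points,
        direction=direction,
    )
    if noise is not None and noise.stuck_rate > 0:
        arr = inject_stuck_faults(arr, noise, fault_rng)
    return arr


def qam_mapping_mse(
    n_points: int = 64,
    config: CrossbarConfig | None = None,
    min_cells: int = 100_000,
    seed: int | None = 0,
) -> float:
    """Mean squared programming error (uS^2) of the QAM scheme.

    The block-form DFT matrix is programmed repeatedly (fresh error draws)
    until at least ``min_cells`` cells have been accumulated, and the MSE
    of ``programmed - target`` over all of them is returned.
    """
    config = config or CrossbarConfig()
    ss = np.random.SeedSequence(seed)
    total_sq = 0.0
    n_cells = 0
    while n_cells < min_cells:
        arr = build_dft_crossbar(n_points, "forward", config, seed=ss.spawn(1)[0])
        err = arr.g_programmed - arr.g_target
        total_sq += float(np.sum(err**2))
        n_cells += err.size
    return total_sq / n_cells


class CrossbarEngine:
    """Transform engine backed by programmed crossbar arrays.

    One array is programmed lazily per ``(n_points, direction)`` and
    reused for every subsequent transform of that shape -- the software
    analogue of mapping a chip once and streaming inputs through it.
    Complex inputs are stacked into ``[Re; Im]``, scaled by the read
    voltage, pushed through :func:`vmm`, de-scaled by the recorded
    conductance factor and the transform's scalar (``1/sqrt(N)`` forward,
    ``sqrt(N)`` inverse).

    Seeding: ``seed`` drives three independent streams (programming,
    faults, read noise).  ``program_seed`` optionally pins the programming
    stream separately so sweeps can model a fixed chip under varying
    operating noise.
    """

    def __init__(
        self,
        config: CrossbarConfig | None = None,
        noise: NoiseSpec | None = None,
        seed: int = 0,
        program_seed: int | None = None,
        sizes: tuple[int, ...] | None = None,
    ) -> None:
        self.config = config or CrossbarConfig()
        self.noise = noise or NoiseSpec()
        ss = np.random.SeedSequence(seed)
        read_ss, fault_ss, prog_default = ss.spawn(3)
        self._prog_ss = (
            np.random.SeedSequence(program_seed)
            if program_seed is not None
            else prog_default
        )
        self._read_rng = np.random.default_rng(read_ss)
        self._fault_rng = np.random.default_rng(fault_ss)
        self.sizes = tuple(sizes) if sizes is not None else None
        self._arrays: dict[tuple[int, str], CrossbarArray] = {}
        self.n_transforms = 0
        self.pass_log: list[tuple[str, int, int]] = []

    def array_for(self, n_points: int, direction: str) -> CrossbarArray:
        key = (n_points, direction)
        if key not in self._arrays:
            self._arrays[key] = build_dft_crossbar(
                n_points,
                direction,
                self.config,
                self.noise,
                seed=self._prog_ss.spawn(1)[0],
                fault_rng=self._fault_rng,
            )
        return self._arrays[key]

    def transform(self, x: np.ndarray, direction: str) -> np.ndarray:
        _check_direction(direction)
        x = np.asarray(x, dtype=complex)
        if x.ndim != 1:
            raise ValueError("engine input must be a 1D vector")
        n = x.size
        if self.sizes is not None and n not in self.sizes:
            raise ValueError(
                f"{n}-point transform not supported by this engine "
                f"(configured sizes: {self.sizes})"
            )
        arr = self.array_for(n, direction)
        volts = stack_reim(x) * self.config.read_voltage
        currents = vmm(arr, volts, self.noise, rng=self._read_rng)
        y = unstack_reim(
            currents / (arr.scale_factor * self.config.read_voltage)
        )
        self.n_transforms += 1
        if direction == "forward":
            return y / np.sqrt(n)
        return y * np.sqrt(n)
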