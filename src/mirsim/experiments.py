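"""Device-nonideality sweeps and operation-count accounting.

The sweeps mirror the robustness analyses run on the hardware: the full
reconstruction pipeline (MRI or CT) is repeated over a grid of read-noise
standard deviations (50-600 nA) or stuck-at fault rates (0.1%-2%), ten
trials per grid value, and the per-trial PSNR/SNR and segmentation DICE
are aggregated.  The chip is programmed once per sweep (a fixed
``program_seed``) and only the operating-noise/fault streams vary across
trials, modeling repeated reads of one physical array.

Operation counting follows the block-form convention: one N-point complex
transform is a ``2N x 2N`` real VMM, counted as ``(2N)^2`` multiplies plus
``(2N)^2`` additions = ``8 N^2`` operations, and an ``M x N`` 2D transform
costs ``M + N`` 1D transforms (the transpose between passes is free).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crossbar import CrossbarConfig, CrossbarEngine, NoiseSpec
from .ct import reconstruct_ct_image, reconstruct_ct_patch
from .metrics import dice_score, image_metrics
from .mri import mri_pipeline
from .phantom import Phantom, threshold_segment

__all__ = [
    "SweepResult",
    "sweep_read_noise",
    "sweep_stuck_faults",
    "count_transforms",
    "TransformStage",
    "OpCountReport",
    "count_operations",
    "mri_task_stages",
    "ct_task_stages",
    "DEFAULT_READ_NOISE_GRID_NA",
    "DEFAULT_STUCK_RATE_GRID",
]

#: ten read-noise scenarios spanning the studied 50-600 nA range
DEFAULT_READ_NOISE_GRID_NA = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0, 350.0, 400.0, 500.0, 600.0)

#: seven stuck-at-fault scenarios spanning 0.1%-2% (log-spaced)
DEFAULT_STUCK_RATE_GRID = tuple(np.geomspace(0.001, 0.02, 7).round(6))


@dataclass
class SweepResult:
    """Per-trial and aggregated metrics of one parameter sweep."""

    parameter: str
    task: str
    values: np.ndarray
    psnr_db: np.ndarray  # (n_values, n_trials)
    snr_db: np.ndarray
    dice: np.ndarray
    seeds: np.ndarray
    trials: int = field(init=False)

    def __post_init__(self) -> None:
        self.trials = self.psnr_db.shape[1]

    @property
    def mean_psnr_db(self) -> np.ndarray:
        return self.psnr_db.mean(axis=1)

    @property
    def mean_dice(self) -> np.ndarray:
        return self.dice.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, v in enumerate(self.values):
            for t in range(self.trials):
                rows.append(
                    {
                        "param": v,
                        "trial": t,
                        "seed": int(self.seeds[i, t]),
                        "psnr_db": self.psnr_db[i, t],
                        "snr_db": self.snr_db[i, t],
                        "dice": self.dice[i, t],
                    }
                )
        return pd.DataFrame(rows)


def _run_task(task: str, phantom: Phantom, engine, task_kwargs: dict) -> np.ndarray:
    if task == "mri":
        kw = {"tile_size": 64, "pad": True}
        kw.update(task_kwargs)
        return mri_pipeline(phantom.image, engine=engine, **kw)
    if task == "ct":
        return reconstruct_ct_image(phantom.image, engine=engine, **task_kwargs)
    if task == "ct-patch":
        from .ct import radon_project

        sino = radon_project(phantom.image, **task_kwargs)
        return reconstruct_ct_patch(sino, engine)
    raise ValueError(f"unknown task {task!r}")


def _sweep(
    task: str,
    phantom: Phantom,
    parameter: str,
    values,
    noise_for,
    trials: int,
    base_seed: int,
    config: CrossbarConfig | None,
    threshold: float | None,
    task_kwargs: dict | None,
) -> SweepResult:
    config = config or CrossbarConfig()
    task_kwargs = task_kwargs or {}
    values = np.asarray(list(values), dtype=float)
    threshold = phantom.segmentation_threshold if threshold is None else threshold
    ref_mask = threshold_segment(phantom.image, threshold)

    ss = np.random.SeedSequence(base_seed)
    program_seed = int(ss.generate_state(1)[0] % (2**31))
    trial_seeds = ss.generate_state(values.size * trials + 1)[1:] % (2**31)
    trial_seeds = trial_seeds.reshape(values.size, trials)

    shape = (values.size, trials)
    psnr = np.empty(shape)
    snr = np.empty(shape)
    dice = np.empty(shape)
    for i, v in enumerate(values):
        for t in range(trials):
            engine = CrossbarEngine(
                config,
                noise_for(float(v)),
                seed=int(trial_seeds[i, t]),
                program_seed=program_seed,
            )
            recon = _run_task(task, phantom, engine, task_kwargs)
            m = image_metrics(phantom.image, recon)
            psnr[i, t] = m.psnr_db
            snr[i, t] = m.snr_db
            dice[i, t] = dice_score(ref_mask, threshold_segment(recon, threshold))
    return SweepResult(
        parameter=parameter,
        task=task,
        values=values,
        psnr_db=psnr,
        snr_db=snr,
        dice=dice,
        seeds=trial_seeds,
    )


def sweep_read_noise(
    task: str,
    phantom: Phantom,
    stds=DEFAULT_READ_NOISE_GRID_NA,
    trials: int = 10,
    base_seed: int = 0,
    config: CrossbarConfig | None = None,
    threshold: float | None = None,
    task_kwargs: dict | None = None,
) -> SweepResult:
    """Run the pipeline over a grid of read-noise STDs (nA)."""
    if any(s < 0 for s in stds):
        raise ValueError("read-noise STDs must be >= 0")
    return _sweep(
        task,
        phantom,
        "read_noise_std_nA",
        stds,
        lambda v: NoiseSpec(read_noise_std=v),
        trials,
        base_seed,
        config,
        threshold,
        task_kwargs,
    )


def sweep_stuck_faults(
    task: str,
    phantom: Phantom,
    rates=DEFAULT_STUCK_RATE_GRID,
    trials: int = 10,
    base_seed: int = 0,
    config: CrossbarConfig | None = None,
    threshold: float | None = None,
    task_kwargs: dict | None = None,
    stuck_value_policy: str = "off",
) -> SweepResult:
    """Run the pipeline over a grid of stuck-at fault rates (fractions)."""
    if any(not 0 <= r <= 1 for r in rates):
        raise ValueError("fault rates must be in [0, 1]")
    return _sweep(
        task,
        phantom,
        "stuck_rate",
        rates,
        lambda v: NoiseSpec(stuck_rate=v, stuck_value_policy=stuck_value_policy),
        trials,
        base_seed,
        config,
        threshold,
        task_kwargs,
    )


def count_transforms(rows: int, cols: int) -> int:
    """1D transforms needed for a ``rows x cols`` 2D transform.

    One per column in each of the two passes: ``cols`` length-``rows``
    transforms, then ``rows`` length-``cols`` transforms after the
    transpose -- 128 for 64 x 64, 640 for 320 x 320.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    return rows + cols


@dataclass(frozen=True)
class TransformStage:
    """A batch of same-size 1D transforms within a task."""

    name: str
    n_points: int
    n_transforms: int

    @property
    def operations(self) -> int:
        # (2N)^2 multiplies + (2N)^2 additions per block-form transform
        return self.n_transforms * 8 * self.n_points**2


@dataclass
class OpCountReport:
    stages: list[TransformStage]

    @property
    def total_operations(self) -> int:
        return sum(s.operations for s in self.stages)

    @property
    def total_transforms(self) -> int:
        return sum(s.n_transforms for s in self.stages)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "n_points": s.n_points,
                    "n_transforms": s.n_transforms,
                    "operations": s.operations,
                }
                for s in self.stages
            ],
            "total_transforms": self.total_transforms,
            "total_operations": self.total_operations,
        }


def count_operations(stages: list[TransformStage]) -> OpCountReport:
    """Total multiply+add count of a task described by transform stages."""
    for s in stages:
        if s.n_points < 1 or s.n_transforms < 0:
            raise ValueError(f"invalid stage {s}")
    return OpCountReport(stages=list(stages))


def mri_task_stages(size: int = 320) -> list[TransformStage]:
    """MRI reconstruction of a ``size x size`` raw-data matrix: one 2D IDFT."""
    return [TransformStage("2d_idft", size, count_transforms(size, size))]


def ct_task_stages(n_bins: int = 768, n_angles: int = 180) -> list[TransformStage]:
    """CT reconstruction: per-angle 1D DFTs, then one ``n_bins``-square 2D IDFT."""
    return [
        TransformStage("projection_dft", n_bins, n_angles),
        TransformStage("2d_idft", n_bins, count_transforms(n_bins, n_bins)),
    ]
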