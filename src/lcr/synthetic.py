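"""Synthetic radius-time datasets with the acquisition structure of
time-resolved single-exposure photography.

One bubble event is photographed per laser shot, so a cycle is sampled
by repeating shots at camera delays stepped in 1 µs increments with at
least five replicates per delay.  The generator simulates one forward
cycle, samples it at the protocol delays, applies per-replicate
multiplicative radius noise, and omits delays at which no bubble exists
(before inception / after collapse) — exactly what the camera would
record.

The default protocol mirrors that acquisition: 1 µs delay step over
0-30 µs, 5 replicates per delay, and 3 % multiplicative radius noise (a
level chosen so that fit scatter across synthetic replicates is of the
same order as the sample-to-sample spread reported for real hydrogels;
measurement noise itself is not reported for the instrument and remains
a free knob).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .constitutive import AmbientConditions, Material
from .dynamics import simulate_cycle
from .imaging import Frame, render_synthetic_frame
from .inversion import FitParameters, RadiusTimeDataset

__all__ = ["AcquisitionProtocol", "generate_dataset", "generate_frame_stack"]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Statistical structure of the synthetic acquisition."""

    delay_step: float = 1.0e-6  # s
    delay_start: float = 0.0
    delay_stop: float = 30.0e-6
    replicates_per_delay: int = 5
    radius_noise_sigma: float = 0.03  # multiplicative
    additive_noise_floor: float = 0.0  # m
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delay_step <= 0:
            raise ValueError("delay_step must be positive")
        if self.delay_stop < self.delay_start:
            raise ValueError("empty delay range")
        if self.replicates_per_delay < 1:
            raise ValueError("need at least one replicate per delay")
        if self.radius_noise_sigma < 0 or self.additive_noise_floor < 0:
            raise ValueError("noise levels must be >= 0")

    def delays(self) -> np.ndarray:
        n = int(np.floor((self.delay_stop - self.delay_start) / self.delay_step + 0.5))
        return self.delay_start + self.delay_step * np.arange(n + 1)


def generate_dataset(
    true_params: FitParameters,
    material: Material = Material(),
    ambient: AmbientConditions = AmbientConditions(),
    protocol: AcquisitionProtocol = AcquisitionProtocol(),
    sample_id: str = "synthetic",
    mode: str = "failure",
    rtol: float = 1e-8,
) -> RadiusTimeDataset:
    """Sample a simulated cycle at the protocol delays with noise.

    eta and eps_f_rr of ``material`` are overridden by ``true_params``;
    delays falling outside the cycle window (no bubble present) are
    omitted.  Deterministic for a fixed ``protocol.seed``.
    """
    mat = true_params.as_material(material)
    traj = simulate_cycle(true_params.r_max, mat, ambient, mode=mode, rtol=rtol)
    if traj.cycle_time < protocol.delay_step:
        raise ValueError(
            f"cycle ({traj.cycle_time:.2e} s) shorter than one delay step "
            f"({protocol.delay_step:.2e} s): degenerate protocol"
        )
    delays = protocol.delays()
    model_t = delays - true_params.t0
    in_cycle = (model_t >= 0.0) & (model_t <= traj.cycle_time)
    delays = delays[in_cycle]
    clean = traj.radius_at(model_t[in_cycle])

    rng = np.random.default_rng(protocol.seed)
    rows = []
    for d, r in zip(delays, clean):
        for rep in range(protocol.replicates_per_delay):
            noisy = r * (1.0 + protocol.radius_noise_sigma * rng.standard_normal())
            if protocol.additive_noise_floor > 0:
                noisy += protocol.additive_noise_floor * rng.standard_normal()
            rows.append((d, max(noisy, 0.0), rep))
    points = pd.DataFrame(rows, columns=["time_s", "radius_m", "replicate_id"])
    return RadiusTimeDataset(
        sample_id=sample_id,
        points=points,
        metadata={
            "generator": "lcr.synthetic.generate_dataset",
            "true_r_max_um": true_params.r_max * 1e6,
            "true_eta_kpa": true_params.eta * 1e-3,
            "true_eps_f_rr": true_params.eps_f_rr,
            "true_t0_us": true_params.t0 * 1e6,
            "noise_sigma": protocol.radius_noise_sigma,
            "seed": protocol.seed,
        },
    )


def generate_frame_stack(
    true_params: FitParameters,
    material: Material = Material(),
    ambient: AmbientConditions = AmbientConditions(),
    protocol: AcquisitionProtocol = AcquisitionProtocol(),
    scale_um_per_px: float = 1.0,
    shape: tuple[int, int] = (256, 256),
    blur_px: float = 1.5,
    noise_sigma: float = 0.03,
    sample_id: str = "synthetic",
    mode: str = "failure",
) -> tuple[list[Frame], pd.DataFrame]:
    """Render one synthetic photograph per (delay, replicate).

    The rendered radii are the noise-free model radii — measurement
    noise enters through the renderer's pixel noise, as it would on the
    instrument.  Returns the frames and a manifest table matching the
    imaging module's input schema (``path`` left blank until frames are
    written to disk).
    """
    noiseless = replace(
        protocol,
        radius_noise_sigma=0.0,
        additive_noise_floor=0.0,
        replicates_per_delay=1,
    )
    clean = generate_dataset(
        true_params, material, ambient, noiseless, sample_id=sample_id, mode=mode
    )
    base = pd.DataFrame(
        {
            "delay_s": clean.points["time_s"],
            "radius_m": clean.points["radius_m"],
        }
    )
    frames: list[Frame] = []
    manifest_rows = []
    rng_seed = np.random.SeedSequence(protocol.seed)
    seeds = rng_seed.generate_state(len(base) * protocol.replicates_per_delay)
    i = 0
    for _, row in base.iterrows():
        for rep in range(protocol.replicates_per_delay):
            frame = render_synthetic_frame(
                radius=row["radius_m"],
                scale_um_per_px=scale_um_per_px,
                shape=shape,
                blur_px=blur_px,
                noise_sigma=noise_sigma,
                seed=int(seeds[i]),
                delay=row["delay_s"],
                replicate_id=rep,
                sample_id=sample_id,
            )
            frames.append(frame)
            manifest_rows.append(
                {
                    "path": "",
                    "delay_us": row["delay_s"] * 1e6,
                    "replicate_id": rep,
                    "sample_id": sample_id,
                    "um_per_px": scale_um_per_px,
                }
            )
            i += 1
    return frames, pd.DataFrame(manifest_rows)
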