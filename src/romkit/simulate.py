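"""Synthetic landmark trajectories and multi-subject ROM studies.

No public dataset of paired webcam / optical-mocap ROM trajectories
exists, so every pipeline stage is exercised against simulated movements
with known ground truth.  A trial is a slow, deliberate single excursion:
one segment endpoint stays fixed (the proximal joint) while the other
rotates about a fixed axis from 0 degrees up to the trial's true ROM and
back, following a minimum-jerk (default) or sinusoidal angular profile.
Sampling is ~15 FPS for the webcam dialect and 120 FPS for mocap; the
frame grid always contains the apex frame, so a noiseless trial's maximum
sampled angle equals the true ROM exactly.

Degradations mirror what real capture produces: isotropic Gaussian
landmark noise, spike outliers from tracking inconsistency (injected in
landmark space so the residual-based detector is exercised end to end),
and low-visibility dropouts (webcam dialect only).  A study draws each
subject's true ROM from a between-subject normal distribution and each
trial's realization from a within-subject normal around it, optionally
clipping the webcam's apex (emulating reduced sensitivity to joint
location at the movement apex) and biasing the mocap device.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a
fixed seed reproduces trials byte for byte across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .registry import MovementSpec
from .trajectory_io import TrialTrajectory, landmark_vocabulary

_UP = np.array([0.0, 1.0, 0.0])
_PIVOT = np.array([0.0, 1.2, 0.0])
_MIDPOINT_HALF_SPAN = 0.07  # meters between a midpoint's constituent markers / 2


@dataclass
class KinematicScenario:
    """One movement performance: what rotates, how far, how fast."""

    movement: MovementSpec
    true_rom: float = 60.0        # degrees, in (0, 180]
    duration: float = 6.0         # seconds for the full out-and-back excursion
    fps: float = 15.0             # 15 (webcam) or 120 (mocap) by default
    rise_profile: str = "minimum_jerk"   # or "sinusoidal"
    segment_length: float = 0.4   # meters

    def __post_init__(self) -> None:
        if not 0 < self.true_rom <= 180:
            raise ValueError(f"true_rom must be in (0, 180], got {self.true_rom}")
        if self.rise_profile not in ("minimum_jerk", "sinusoidal"):
            raise ValueError(f"unknown rise profile {self.rise_profile!r}")
        if self.duration <= 0 or self.fps <= 0 or self.segment_length <= 0:
            raise ValueError("duration, fps and segment_length must be positive")


@dataclass
class NoiseModel:
    """Capture degradations, all off by default."""

    landmark_sigma: float = 0.0     # meters, isotropic Gaussian per landmark
    outlier_rate: float = 0.0       # per-frame spike probability
    outlier_scale: float = 0.15     # meters, spike magnitude
    dropout_rate: float = 0.0       # per-frame low-visibility probability
    dropout_visibility: float = 0.3  # assigned visibility, below the 0.5 cut
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("outlier_rate", "dropout_rate"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not self.dropout_visibility < 0.5:
            raise ValueError("dropout_visibility must fall below the 0.5 threshold")


@dataclass
class StudyDesign:
    """A repeated-measures reliability study layout.

    Defaults mirror a 25-subject study with three consecutive trials per
    movement per device.  ``apex_saturation`` clips the webcam dialect's
    true apex at a ceiling; ``device_bias`` / ``device_extra_sd`` perturb
    the mocap dialect's realized ROM.
    """

    n_subjects: int = 25
    n_trials: int = 3
    population_mean_rom: float = 60.0
    between_subject_sd: float = 10.0
    within_subject_sd: float = 3.0
    device_bias: float = 0.0
    device_extra_sd: float = 0.0
    apex_saturation: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_trials < 2:
            raise ValueError("need >= 2 subjects and >= 2 trials")
        for name in ("between_subject_sd", "within_subject_sd", "device_extra_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def _minimum_jerk(u: np.ndarray) -> np.ndarray:
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def angle_profile(t: np.ndarray, scenario: KinematicScenario) -> np.ndarray:
    """Movement angle (degrees) at each time: 0 -> true_rom -> 0."""
    tau = np.clip(np.asarray(t, float) / scenario.duration, 0.0, 1.0)
    if scenario.rise_profile == "sinusoidal":
        shape = 0.5 * (1.0 - np.cos(2.0 * np.pi * tau))
    else:
        up = np.clip(2.0 * tau, 0.0, 1.0)
        down = np.clip(2.0 * (1.0 - tau), 0.0, 1.0)
        shape = np.where(tau <= 0.5, _minimum_jerk(up), _minimum_jerk(down))
    return scenario.true_rom * shape


def _time_grid(scenario: KinematicScenario) -> np.ndarray:
    """Uniform frame times covering [0, duration] with the apex sampled.

    An even number of frame intervals guarantees t = duration/2 (where the
    profile attains the true ROM) is itself a frame.
    """
    n_intervals = 2 * max(1, int(round(scenario.duration * scenario.fps / 2)))
    return np.arange(n_intervals + 1) / (n_intervals / scenario.duration)


@lru_cache(maxsize=8)
def _filler_layout(dialect: str) -> dict[str, np.ndarray]:
    """Fixed, anatomically plausible static positions for filler landmarks."""
    rng = np.random.default_rng(20230923)
    layout = {}
    for name in landmark_vocabulary(dialect):
        layout[name] = np.array(
            [rng.uniform(-0.3, 0.3), rng.uniform(0.0, 1.8), rng.uniform(-0.2, 0.2)]
        )
    return layout


def simulate_trial(
    scenario: KinematicScenario,
    noise: NoiseModel | None = None,
    dialect: str = "pose33",
    subject: str = "S01",
    trial: int = 1,
) -> TrialTrajectory:
    """Synthesize one schema-complete trial trajectory.

    The movement's two endpoints (and the constituent markers of any
    midpoint endpoint, placed symmetrically about the endpoint so the
    midpoint is exact) are animated; every other landmark of the dialect
    is emitted as static filler so files are schema-complete.  Noise,
    spikes and dropouts are applied per the noise model; a fixed seed
    yields byte-identical output.
    """
    noise = noise or NoiseModel()
    spec = scenario.movement
    ep1, ep2 = spec.endpoint_pair(dialect)
    t = _time_grid(scenario)
    n_frames = len(t)
    theta = np.radians(angle_profile(t, scenario))

    axis = (
        np.array([1.0, 0.0, 0.0])
        if spec.orientation == "lateral_sagittal"
        else np.array([0.0, 0.0, 1.0])
    )
    # u0 is orthogonal to the rotation axis, so Rodrigues reduces to
    # u = cos(theta) u0 + sin(theta) (axis x u0)
    u = (
        np.cos(theta)[:, None] * _UP
        + np.sin(theta)[:, None] * np.cross(axis, _UP)
    )
    pivot = np.broadcast_to(_PIVOT, (n_frames, 3))
    moving = pivot + scenario.segment_length * u

    offset = _MIDPOINT_HALF_SPAN * axis
    positions: dict[str, np.ndarray] = {}
    for ep, point in ((ep1, pivot), (ep2, moving)):
        if ep.rule == "single":
            positions[ep.markers[0]] = np.array(point, float)
        else:
            positions[ep.markers[0]] = point + offset
            positions[ep.markers[1]] = point - offset

    vocab = landmark_vocabulary(dialect)
    layout = _filler_layout(dialect)
    for name in vocab:
        if name not in positions:
            positions[name] = np.broadcast_to(layout[name], (n_frames, 3)).copy()

    # stack in vocabulary order: (n_landmarks, n_frames, 3)
    stack = np.stack([np.array(positions[name], float) for name in vocab])

    rng = np.random.default_rng(noise.seed)
    if noise.landmark_sigma > 0:
        stack = stack + rng.normal(0.0, noise.landmark_sigma, stack.shape)

    moving_idx = [vocab.index(m) for m in ep2.markers]
    # spikes model transient tracking glitches mid-movement; frame 0 is
    # exempt because corrupting the reference frame is a different failure
    # mode (it biases every angle, and no residual test can see it)
    spike_draws = rng.random(n_frames)
    spike_draws[0] = 1.0
    spike_frames = np.flatnonzero(spike_draws < noise.outlier_rate)
    for frame in spike_frames:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for idx in moving_idx:
            stack[idx, frame] += noise.outlier_scale * direction

    visibility = None
    dropout_frames = np.array([], int)
    if dialect == "pose33":
        visibility = np.ones((len(vocab), n_frames))
        relevant_idx = [vocab.index(m) for m in (*ep1.markers, *ep2.markers)]
        dropout_frames = np.flatnonzero(rng.random(n_frames) < noise.dropout_rate)
        for frame in dropout_frames:
            idx = relevant_idx[rng.integers(len(relevant_idx))]
            visibility[idx, frame] = noise.dropout_visibility

    n_marks = len(vocab)
    data = {
        "t": np.repeat(t, n_marks),
        "landmark": np.tile(np.array(vocab, object), n_frames),
        "x": stack[:, :, 0].T.ravel(),
        "y": stack[:, :, 1].T.ravel(),
        "z": stack[:, :, 2].T.ravel(),
    }
    if visibility is not None:
        data["visibility"] = visibility.T.ravel()
    traj = TrialTrajectory(
        subject=subject,
        movement=spec.label,
        device=dialect,
        trial=trial,
        fps=scenario.fps,
        df=pd.DataFrame(data),
        provenance={
            "true_rom": scenario.true_rom,
            "outlier_frames": spike_frames.tolist(),
            "dropout_frames": dropout_frames.tolist(),
        },
    )
    return traj


# ---------------------------------------------------------------------------
# multi-subject studies
# ---------------------------------------------------------------------------

_DEVICE_FPS = {"pose33": 15.0, "mocap39": 120.0}


def simulate_study(
    design: StudyDesign,
    scenario: KinematicScenario,
    noise: NoiseModel | None = None,
    dialects: Sequence[str] = ("pose33", "mocap39"),
) -> tuple[list[TrialTrajectory], pd.DataFrame]:
    """Generate a full repeated-measures study with its ground truth.

    Latent structure: subject i's true ROM ~ N(population_mean_rom,
    between_subject_sd^2); trial j's realization ~ N(subject ROM,
    within_subject_sd^2) — shared between devices, since both record the
    same physical performance.  The webcam dialect's apex is then
    optionally clipped at ``apex_saturation``; the mocap dialect's ROM is
    shifted by ``device_bias`` plus N(0, device_extra_sd^2).  Realized
    ROMs are clipped into (0, 180).  The ground-truth table records every
    latent and emitted value plus each trial's derived noise seed.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(design.seed)
    trials: list[TrialTrajectory] = []
    truth_rows = []
    width = len(str(design.n_subjects))
    for i in range(design.n_subjects):
        subject = f"S{i + 1:0{width}d}"
        subject_rom = rng.normal(design.population_mean_rom, design.between_subject_sd)
        for j in range(1, design.n_trials + 1):
            latent = rng.normal(subject_rom, design.within_subject_sd)
            for dialect in dialects:
                emitted = latent
                if dialect == "pose33" and design.apex_saturation is not None:
                    emitted = min(emitted, design.apex_saturation)
                if dialect == "mocap39":
                    emitted = emitted + design.device_bias
                    if design.device_extra_sd > 0:
                        emitted = emitted + rng.normal(0.0, design.device_extra_sd)
                emitted = float(np.clip(emitted, 0.5, 179.5))
                trial_seed = int(rng.integers(2**31))
                trial_scenario = replace(
                    scenario, true_rom=emitted, fps=_DEVICE_FPS.get(dialect, scenario.fps)
                )
                trial_noise = replace(noise, seed=trial_seed)
                trials.append(
                    simulate_trial(
                        trial_scenario, trial_noise, dialect=dialect,
                        subject=subject, trial=j,
                    )
                )
                truth_rows.append(
                    {
                        "subject": subject,
                        "movement": scenario.movement.label,
                        "device": dialect,
                        "trial": j,
                        "subject_rom": subject_rom,
                        "latent_rom": latent,
                        "true_rom": emitted,
                        "noise_seed": trial_seed,
                    }
                )
    return trials, pd.DataFrame(truth_rows)


def study_rom_table(
    trials: Iterable[TrialTrajectory],
    cfg=None,
    registry: Iterable[MovementSpec] | None = None,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Run the ROM pipeline over simulated trials into a long ROM table."""
    from .registry import lookup
    from .rom_engine import compute_trial_rom

    registry = list(registry) if registry is not None else None
    rows = []
    for traj in trials:
        spec = lookup(traj.movement, registry=registry)
        result = compute_trial_rom(traj, spec, cfg, **pipeline_kwargs)
        rows.append(result.__dict__)
    return pd.DataFrame(rows)
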