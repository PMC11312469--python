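"""Synthetic steering tasks and the closed-loop plant.

Emulates a primate steering experiment in which a joystick controls the
angular velocity of travel through a virtual world.  Two target-motion
contexts are generated:

* **step** — the target holds still for a truncated-exponential interval
  (1000 ms minimum, 2000 ms mean) then jumps by 5–25 deg, smaller jumps
  more probable;
* **drift** — the target moves at a piecewise-constant random velocity
  (zero-mean Gaussian, sd 0.1 deg/s, redrawn every 259–494 ms), with
  display noise added to the shown target (sd 0.1 deg) and shown heading
  (sd 2.5 deg), both held for 94 ms blocks.

The plant closes the loop at the display frame rate (85 Hz): the displayed
error x = T_displayed - H_displayed drives the kernel, the response r sets
the heading rate, and heading is integrated frame by frame:

    x[i] = T_disp[i] - H_disp[i]
    r[i] = dt * sum_{j>=1} k[j] (x[i-j] + n[i-j])
    H[i+1] = H[i] + joystick_gain * r[i] * dt

with n i.i.d. Gaussian "multiplicative" sensory noise added to the error
before the kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kernels import FRAME_RATE, Kernel

__all__ = [
    "TaskConfig",
    "PlantConfig",
    "TargetTrajectory",
    "TrialRecord",
    "generate_step_target",
    "generate_drift_target",
    "apply_display_noise",
    "simulate_trial",
    "make_dataset",
    "tune_noise_sd",
]


@dataclass
class TaskConfig:
    """Target-motion and display statistics for one experimental context.

    Times are in ms where noted; angles in deg; rates in deg/s.
    """

    context: str = "drift"
    frame_rate: float = FRAME_RATE
    trial_duration: float = 15.0  # s; step context draws 15-30 s per trial
    step_min_interval: float = 1000.0  # ms
    step_mean_interval: float = 2000.0  # ms
    step_amplitudes: tuple = (5.0, 10.0, 15.0, 20.0, 25.0)
    step_amplitude_weights: tuple | None = None  # default ~ 1/amplitude
    step_duration_range: tuple = (15.0, 30.0)  # s
    drift_velocity_sd: float = 0.1  # deg/s
    drift_update_range: tuple = (259.0, 494.0)  # ms
    target_jitter_sd: float = 0.1  # deg
    heading_noise_sd: float = 2.5  # deg
    display_noise_period: float = 94.0  # ms
    initial_offset: float = 4.0  # deg, drift context
    pre_steer_hold: float = 500.0  # ms

    def __post_init__(self) -> None:
        if self.context not in ("step", "drift"):
            raise ValueError(f"unknown context {self.context!r}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.step_min_interval > self.step_mean_interval:
            raise ValueError("minimum inter-step interval exceeds the mean")
        if len(self.step_amplitudes) == 0:
            raise ValueError("need at least one step amplitude")
        if self.step_amplitude_weights is None:
            w = np.array([1.0 / a for a in self.step_amplitudes])
            self.step_amplitude_weights = tuple(w / w.sum())
        w = np.asarray(self.step_amplitude_weights, dtype=float)
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("amplitude weights must be nonnegative and sum to 1")
        if self.drift_update_range[0] > self.drift_update_range[1]:
            raise ValueError("drift_update_range must be ordered")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


@dataclass
class PlantConfig:
    """Joystick-to-heading plant.

    joystick_gain maps the response (deg/s per unit r) into heading rate;
    noise_sd is the SD (deg) of the Gaussian noise added to the error
    before the kernel.
    """

    joystick_gain: float = 1.0
    response_clip: float | None = None
    noise_sd: float = 0.0
    dt: float = 1.0 / FRAME_RATE

    def __post_init__(self) -> None:
        if self.joystick_gain <= 0:
            raise ValueError("joystick_gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class TargetTrajectory:
    """Target direction over one trial, on the frame grid.

    T_world is the noiseless target direction; T_displayed includes display
    jitter (equal to T_world in the step context).  Step events are recorded
    as (time, signed amplitude) lists in the step context.
    """

    t: np.ndarray
    T_world: np.ndarray
    T_displayed: np.ndarray
    step_times: np.ndarray | None = None
    step_amplitudes: np.ndarray | None = None
    context: str = "drift"

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class TrialRecord:
    """One simulated steering trial: all series share the frame grid.

    x is the displayed steering error actually presented to the controller,
    x[i] = T_displayed[i] - H_displayed[i]; r is the steering response.
    """

    t: np.ndarray
    T_world: np.ndarray
    T_displayed: np.ndarray
    H_world: np.ndarray
    H_displayed: np.ndarray
    x: np.ndarray
    r: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)

    @property
    def heading_offsets(self) -> np.ndarray:
        """Display-noise offsets on the heading, H_displayed - H_world."""
        return self.H_displayed - self.H_world

    @property
    def step_times(self):
        return self.meta.get("step_times")

    @property
    def step_amplitudes(self):
        return self.meta.get("step_amplitudes")


def draw_step_intervals(cfg: TaskConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inter-step intervals (ms): shifted exponential, min + Exp(mean - min)."""
    return cfg.step_min_interval + rng.exponential(
        cfg.step_mean_interval - cfg.step_min_interval, size=n
    )


def draw_step_amplitudes(cfg: TaskConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Signed step amplitudes: magnitude weighted per config, sign equiprobable."""
    mags = rng.choice(np.asarray(cfg.step_amplitudes, dtype=float), size=n,
                      p=np.asarray(cfg.step_amplitude_weights, dtype=float))
    signs = rng.choice([-1.0, 1.0], size=n)
    return mags * signs


def generate_step_target(
    cfg: TaskConfig, duration: float, rng: np.random.Generator
) -> TargetTrajectory:
    """Piecewise-constant target with random jumps.

    The first jump occurs at the end of the pre-steer hold; subsequent
    jumps are separated by truncated-exponential intervals.  Each jump
    displaces the target relative to its previous position by a signed
    amplitude drawn from the configured set.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt = cfg.dt
    n = int(round(duration / dt))
    t = dt * np.arange(n)

    event_times = [cfg.pre_steer_hold / 1000.0]
    while True:
        gap = draw_step_intervals(cfg, 1, rng)[0] / 1000.0
        nxt = event_times[-1] + gap
        if nxt >= duration:
            break
        event_times.append(nxt)
    amps = draw_step_amplitudes(cfg, len(event_times), rng)

    T = np.zeros(n)
    level = 0.0
    kept_times, kept_amps = [], []
    for et, amp in zip(event_times, amps):
        idx = int(round(et / dt))
        if idx >= n:
            continue
        level += amp
        T[idx:] = level
        kept_times.append(idx * dt)
        kept_amps.append(amp)
    return TargetTrajectory(
        t=t, T_world=T, T_displayed=T.copy(),
        step_times=np.array(kept_times), step_amplitudes=np.array(kept_amps),
        context="step",
    )


def generate_drift_target(
    cfg: TaskConfig, duration: float, rng: np.random.Generator
) -> TargetTrajectory:
    """Random-drift target: piecewise-constant Gaussian velocity.

    After the pre-steer hold the target jumps +/- initial_offset deg, then
    moves at a velocity redrawn from N(0, drift_velocity_sd^2) every
    259-494 ms (uniform, rounded to whole frames), integrated on the frame
    grid.  Display jitter is added separately (see apply_display_noise).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt = cfg.dt
    n = int(round(duration / dt))
    t = dt * np.arange(n)
    hold_frames = int(round(cfg.pre_steer_hold / 1000.0 / dt))

    offset = cfg.initial_offset * rng.choice([-1.0, 1.0])
    v = np.zeros(n)
    lo = max(1, int(round(cfg.drift_update_range[0] / 1000.0 / dt)))
    hi = max(lo, int(round(cfg.drift_update_range[1] / 1000.0 / dt)))
    i = hold_frames
    while i < n:
        seg = int(rng.integers(lo, hi + 1))
        v[i : i + seg] = rng.normal(0.0, cfg.drift_velocity_sd)
        i += seg

    T = np.zeros(n)
    if hold_frames < n:
        # position at the offset frame is the offset itself; drift accrues
        # from the following frame
        T[hold_frames:] = offset
        T[hold_frames + 1 :] += np.cumsum(v[hold_frames:-1]) * dt
    jitter = _block_noise(n, cfg.target_jitter_sd, cfg, rng)
    return TargetTrajectory(
        t=t, T_world=T, T_displayed=T + jitter, context="drift",
    )


def _block_noise(
    n: int, sd: float, cfg: TaskConfig, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean Gaussian offsets held constant over display-noise blocks."""
    period = max(1, int(round(cfg.display_noise_period / 1000.0 / cfg.dt)))
    n_blocks = -(-n // period)
    draws = rng.normal(0.0, sd, size=n_blocks) if sd > 0 else np.zeros(n_blocks)
    return np.repeat(draws, period)[:n]


def apply_display_noise(
    target: TargetTrajectory,
    heading: np.ndarray,
    cfg: TaskConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Add block-held display noise to the target and heading series.

    In the step context this is the identity (no display noise was used).
    Offsets are independent zero-mean Gaussians redrawn every
    display_noise_period (94 ms -> 8 frames at 85 Hz).
    """
    heading = np.asarray(heading, dtype=float)
    if len(heading) != len(target):
        raise ValueError("heading and target series lengths differ")
    if cfg.context == "step":
        return target.T_world.copy(), heading.copy()
    T_disp = target.T_world + _block_noise(len(target), cfg.target_jitter_sd, cfg, rng)
    H_disp = heading + _block_noise(len(target), cfg.heading_noise_sd, cfg, rng)
    return T_disp, H_disp


def _run_loop(
    T_disp: np.ndarray,
    h_off: np.ndarray,
    err_noise: np.ndarray,
    kernel: Kernel,
    gain: float,
    dt: float,
    H0: float,
    clip: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frame-by-frame closed loop; returns (x, r, H_world).

    x[i] = T_disp[i] - (H[i] + h_off[i]);
    r[i] = dt * sum_{j=1..L} k[j] (x[i-j] + n[i-j]);
    H[i+1] = H[i] + gain * r[i] * dt.
    """
    n = len(T_disp)
    L = len(kernel.k)
    krev = kernel.k[::-1] * dt  # krev[L-1-j] = k at lag (j+1)*dt, scaled
    e = np.zeros(n)
    x = np.empty(n)
    r = np.zeros(n)
    H = np.empty(n)
    H[0] = H0
    for i in range(n):
        x[i] = T_disp[i] - (H[i] + h_off[i])
        e[i] = x[i] + err_noise[i]
        m = min(i, L)
        if m:
            r[i] = krev[L - m :] @ e[i - m : i]
            if clip is not None:
                r[i] = max(-clip, min(clip, r[i]))
        if i + 1 < n:
            H[i + 1] = H[i] + gain * r[i] * dt
    return x, r, H


def simulate_trial(
    target: TargetTrajectory,
    kernel: Kernel,
    plant: PlantConfig,
    cfg: TaskConfig,
    rng: np.random.Generator,
    heading_offsets: np.ndarray | None = None,
    error_noise: np.ndarray | None = None,
) -> TrialRecord:
    """Simulate one closed-loop trial from a known ground-truth kernel.

    The displayed target stored on ``target`` is used as the loop input;
    heading display offsets and per-frame error noise are drawn here unless
    supplied (supplying them enables paired-noise simulations).
    """
    n = len(target)
    if n < 2:
        raise ValueError("target must have at least two samples")
    if abs(kernel.dt - plant.dt) > 1e-9 * plant.dt:
        raise ValueError("kernel lag grid spacing does not match plant dt")
    if not np.all(np.isfinite(target.T_world)):
        raise ValueError("NaN/inf in target trajectory")

    if heading_offsets is None:
        sd = cfg.heading_noise_sd if cfg.context == "drift" else 0.0
        heading_offsets = _block_noise(n, sd, cfg, rng)
    if error_noise is None:
        error_noise = (
            rng.normal(0.0, plant.noise_sd, size=n)
            if plant.noise_sd > 0
            else np.zeros(n)
        )

    x, r, H = _run_loop(
        target.T_displayed, heading_offsets, error_noise, kernel,
        plant.joystick_gain, plant.dt, H0=0.0, clip=plant.response_clip,
    )
    meta = {"context": cfg.context}
    if target.step_times is not None:
        meta["step_times"] = target.step_times
        meta["step_amplitudes"] = target.step_amplitudes
    return TrialRecord(
        t=target.t.copy(),
        T_world=target.T_world.copy(),
        T_displayed=target.T_displayed.copy(),
        H_world=H,
        H_displayed=H + heading_offsets,
        x=x,
        r=r,
        meta=meta,
    )


def generate_target(cfg: TaskConfig, duration: float, rng: np.random.Generator) -> TargetTrajectory:
    """Dispatch to the step or drift generator per cfg.context."""
    if cfg.context == "step":
        return generate_step_target(cfg, duration, rng)
    return generate_drift_target(cfg, duration, rng)


def make_dataset(
    cfg: TaskConfig,
    plant: PlantConfig,
    kernel: Kernel,
    n_trials: int,
    seed: int,
) -> list[TrialRecord]:
    """n_trials independent trials with per-trial derived seeds.

    Deterministic given (seed, configs).  Step-context trial durations are
    drawn uniformly from cfg.step_duration_range; drift trials use
    cfg.trial_duration.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    children = np.random.SeedSequence(seed).spawn(n_trials)
    trials = []
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        if cfg.context == "step":
            duration = rng.uniform(*cfg.step_duration_range)
        else:
            duration = cfg.trial_duration
        target = generate_target(cfg, duration, rng)
        trial = simulate_trial(target, kernel, plant, cfg, rng)
        trial.meta.update({"trial_id": i, "seed": seed})
        trials.append(trial)
    return trials


def tune_noise_sd(
    kernel: Kernel,
    cfg: TaskConfig,
    plant: PlantConfig,
    target_r2: float = 0.6,
    n_pilot: int = 30,
    seed: int = 12345,
) -> float:
    """Calibrate the error-noise SD to a desired validation r^2 regime.

    Runs a paired pilot simulation at unit noise SD, splits each observed
    response into its deterministic part s (paired noiseless run) and its
    noise-driven part q (difference), and solves

        r^2(sigma) = Var(s) / (Var(s) + sigma^2 Var(q_1))

    for the requested target r^2.  The loop is linear, so the noise-driven
    variance scales exactly as sigma^2.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    children = np.random.SeedSequence(seed).spawn(n_pilot)
    clean_parts, resid_parts = [], []
    for ss in children:
        rng = np.random.default_rng(ss)
        target = generate_target(cfg, cfg.trial_duration, rng)
        sd = cfg.heading_noise_sd if cfg.context == "drift" else 0.0
        h_off = _block_noise(len(target), sd, cfg, rng)
        noise = rng.normal(0.0, 1.0, size=len(target))
        zeros = np.zeros(len(target))
        _, r_noisy, _ = _run_loop(target.T_displayed, h_off, noise, kernel,
                                  plant.joystick_gain, plant.dt, 0.0)
        _, r_clean, _ = _run_loop(target.T_displayed, h_off, zeros, kernel,
                                  plant.joystick_gain, plant.dt, 0.0)
        clean_parts.append(r_clean)
        resid_parts.append(r_noisy - r_clean)
    # pooled variances: validation r^2 pools samples across trials, so
    # between-trial variance of the deterministic part counts as signal
    var_s = float(np.var(np.concatenate(clean_parts)))
    var_q = float(np.var(np.concatenate(resid_parts)))
    sigma2 = (var_s / var_q) * (1.0 / target_r2 - 1.0)
    return float(np.sqrt(sigma2))
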