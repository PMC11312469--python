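"""Remnant (residual) analysis and the multiplicative-noise model.

The part of the response the deterministic linear model cannot explain,
q(t) = r(t) - r_hat(t), is modeled as sensory noise added to the steering
error before the kernel.  Because the loop is linear, the target and the
injected noise pass through the same closed-loop transfer, so the noise
spectrum can be recovered from measurable spectra:

    Phi_nn = Phi_qq * Phi_TT / Phi_rr_hat

bin by bin, where Phi_TT is the spectrum of the effective loop input and
Phi_rr_hat the spectrum of the deterministic (free-running) prediction.

In the drift context the displayed heading noise enters the summing
junction exactly like target motion, so the effective input is
T_displayed - (H_displayed - H_world); in the step context it is simply
the target itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .identify import predict_trial
from .kernels import Kernel
from .tasks import (
    PlantConfig,
    TargetTrajectory,
    TaskConfig,
    TrialRecord,
    _block_noise,
    _run_loop,
)

__all__ = [
    "Spectrum",
    "ResidualSet",
    "compute_residuals",
    "power_spectrum",
    "simulate_multiplicative",
    "perturbation_response",
    "estimate_noise_spectrum",
    "effective_input",
    "noise_spectrum_from_trials",
]


@dataclass
class Spectrum:
    """One-sided power spectrum averaged across trials.

    normalization: 'none' (raw squared DFT magnitudes), 'unit_total_power'
    (sums to 1), or 'error_variance' (divided by the steering-error
    variance of the task).
    """

    frequencies: np.ndarray
    power: np.ndarray
    normalization: str = "none"
    n_trials: int = 0
    trial_length: int = 0
    valid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class ResidualSet:
    """Per-trial residual series q(t) = r(t) - r_hat(t)."""

    residuals: list
    dt: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.residuals)


def _series(obj) -> np.ndarray:
    return obj.r if isinstance(obj, TrialRecord) else np.asarray(obj, dtype=float)


def compute_residuals(observed: list, predictions: list) -> ResidualSet:
    """Pointwise observed - predicted response, per matched trial pair."""
    if len(observed) != len(predictions):
        raise ValueError("observed and predicted trial counts differ")
    out = []
    for obs, pred in zip(observed, predictions):
        o, p = _series(obs), _series(pred)
        if len(o) != len(p):
            raise ValueError("trial length mismatch between observed and predicted")
        out.append(o - p)
    dt = observed[0].dt if isinstance(observed[0], TrialRecord) else float("nan")
    return ResidualSet(residuals=out, dt=dt)


def power_spectrum(
    series: list,
    dt: float,
    normalization: str = "none",
    remove_mean: bool = True,
) -> Spectrum:
    """Trial-averaged one-sided power spectrum.

    Each series is truncated to the common minimum length, mean-removed
    (by default), transformed with a single FFT, and the squared DFT
    magnitudes are averaged across trials.
    """
    arrs = [np.asarray(s, dtype=float) for s in series]
    if not arrs:
        raise ValueError("no series supplied")
    n = min(len(a) for a in arrs)
    X = np.stack([a[:n] for a in arrs])
    if remove_mean:
        X = X - X.mean(axis=1, keepdims=True)
    P = np.abs(np.fft.rfft(X, axis=1)) ** 2
    power = P.mean(axis=0)
    freqs = np.fft.rfftfreq(n, dt)
    if normalization == "unit_total_power":
        total = power.sum()
        if total == 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        power = power / total
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    return Spectrum(
        frequencies=freqs, power=power, normalization=normalization,
        n_trials=len(arrs), trial_length=n,
    )


def simulate_multiplicative(
    kernel: Kernel,
    targets: list[TargetTrajectory],
    plant: PlantConfig,
    cfg: TaskConfig,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
    return_pairs: bool = False,
):
    """Closed-loop simulation with noise injected into the error signal.

    For each target the loop runs twice on identical display-noise streams:
    once with Gaussian error noise of SD ``noise_sd`` and once without.
    The difference isolates the noise-driven response (by superposition in
    the linear loop), and its trial-averaged spectrum, normalized to unit
    total power, is returned alongside the noisy trials.
    """
    if np.all(kernel.k == 0):
        raise ValueError("zero kernel: residual spectrum undefined")
    rng = np.random.default_rng() if rng is None else rng
    noisy_trials: list[TrialRecord] = []
    clean_preds: list[TrialRecord] = []
    for target in targets:
        n = len(target)
        sd_h = cfg.heading_noise_sd if cfg.context == "drift" else 0.0
        h_off = _block_noise(n, sd_h, cfg, rng)
        noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
        x1, r1, H1 = _run_loop(target.T_displayed, h_off, noise, kernel,
                               plant.joystick_gain, plant.dt, 0.0)
        x0, r0, H0 = _run_loop(target.T_displayed, h_off, np.zeros(n), kernel,
                               plant.joystick_gain, plant.dt, 0.0)
        meta = {"context": cfg.context, "noise_sd": noise_sd}
        noisy_trials.append(TrialRecord(
            t=target.t.copy(), T_world=target.T_world.copy(),
            T_displayed=target.T_displayed.copy(), H_world=H1,
            H_displayed=H1 + h_off, x=x1, r=r1, meta=meta,
        ))
        clean_preds.append(TrialRecord(
            t=target.t.copy(), T_world=target.T_world.copy(),
            T_displayed=target.T_displayed.copy(), H_world=H0,
            H_displayed=H0 + h_off, x=x0, r=r0, meta={"predicted": True},
        ))
    res = compute_residuals(noisy_trials, clean_preds)
    if all(np.allclose(q, 0) for q in res.residuals):
        raise ValueError("residuals are identically zero; cannot normalize spectrum")
    spec = power_spectrum(res.residuals, plant.dt, normalization="unit_total_power")
    if return_pairs:
        return noisy_trials, clean_preds, spec
    return noisy_trials, spec


def perturbation_response(
    kernel: Kernel,
    base_target: TargetTrajectory,
    plant: PlantConfig,
    pulse_time: float,
    pulse_amp: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-loop impulse response to a one-frame error perturbation.

    Two noiseless simulations differ only by an error pulse of
    ``pulse_amp`` deg applied for one frame at ``pulse_time``; returns
    (t, response difference).  By closed-loop linearity the trace is
    independent of the base target.
    """
    n = len(base_target)
    idx = int(round(pulse_time / base_target.dt))
    if not 0 <= idx < n:
        raise ValueError("pulse_time falls outside the trial")
    zeros = np.zeros(n)
    pulse = np.zeros(n)
    pulse[idx] = pulse_amp
    h_off = np.zeros(n)
    _, r0, _ = _run_loop(base_target.T_displayed, h_off, zeros, kernel,
                         plant.joystick_gain, plant.dt, 0.0)
    _, r1, _ = _run_loop(base_target.T_displayed, h_off, pulse, kernel,
                         plant.joystick_gain, plant.dt, 0.0)
    return base_target.t.copy(), r1 - r0


def estimate_noise_spectrum(
    Sqq: Spectrum,
    Srr_hat: Spectrum,
    Stt: Spectrum,
    error_variance: float | None = None,
    floor: float = 1e-6,
) -> Spectrum:
    """Closed-loop noise-spectrum estimator Phi_nn = Phi_qq Phi_TT / Phi_rr_hat.

    All three inputs must be un-normalized spectra on one frequency grid.
    Bins where the predicted-response power falls below ``floor`` times its
    maximum are masked (``valid`` False, power NaN) instead of producing
    unstable ratios.  If ``error_variance`` is given, the result is divided
    by it ('error_variance' normalization).
    """
    for s in (Srr_hat, Stt):
        if len(s.frequencies) != len(Sqq.frequencies) or not np.allclose(
            s.frequencies, Sqq.frequencies
        ):
            raise ValueError("spectra are not on a common frequency grid")
    for s in (Sqq, Srr_hat, Stt):
        if s.normalization != "none":
            raise ValueError("estimator requires un-normalized spectra")
    denom = Srr_hat.power
    valid = denom > floor * denom.max()
    if not valid.any():
        raise ValueError("all bins masked: predicted-response spectrum too small")
    power = np.full_like(denom, np.nan)
    power[valid] = Sqq.power[valid] * Stt.power[valid] / denom[valid]
    norm = "none"
    if error_variance is not None:
        if error_variance <= 0:
            raise ValueError("error_variance must be positive")
        power = power / error_variance
        norm = "error_variance"
    return Spectrum(
        frequencies=Sqq.frequencies.copy(), power=power, normalization=norm,
        n_trials=Sqq.n_trials, trial_length=Sqq.trial_length, valid=valid,
    )


def effective_input(trial: TrialRecord) -> np.ndarray:
    """The exogenous series actually driving the loop.

    Displayed heading noise enters the error exactly like target motion
    (x = T_disp - H - h_off), so the effective input is
    T_displayed - (H_displayed - H_world).  In the step context (no display
    noise) this reduces to the target itself.
    """
    return trial.T_displayed - (trial.H_displayed - trial.H_world)


def noise_spectrum_from_trials(
    trials: list[TrialRecord],
    kernel: Kernel,
    plant: PlantConfig,
    normalize_by_error_variance: bool = False,
    floor: float = 1e-6,
) -> Spectrum:
    """End-to-end noise-spectrum estimate from recorded trials.

    Predicts each trial free-running with the supplied kernel, forms the
    residuals, and applies the closed-loop estimator with the effective
    input spectrum.
    """
    preds = [predict_trial(kernel, tr, plant) for tr in trials]
    res = compute_residuals(trials, preds)
    dt = trials[0].dt
    Sqq = power_spectrum(res.residuals, dt)
    Srr = power_spectrum([p.r for p in preds], dt)
    Stt = power_spectrum([effective_input(tr) for tr in trials], dt)
    err_var = None
    if normalize_by_error_variance:
        err_var = float(np.var(np.concatenate([tr.x for tr in trials])))
    return estimate_noise_spectrum(Sqq, Srr, Stt, error_variance=err_var, floor=floor)
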