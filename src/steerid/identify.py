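"""Nonparametric identification of the steering kernel.

The kernel weights are fit by ordinary least squares on lagged observed
errors: each basis function is convolved with a trial's displayed-error
series to form a design column, and the weights minimize the squared
difference between the weighted column sum and the observed response.
Because the basis spans only causal lags, the fit is immune to the
acausal artifacts that plain lagged regression produces on the strongly
autocorrelated errors of a closed loop.

Validation is free-running: the fitted kernel is run in closed loop given
only the initial heading and the (displayed) target trajectory, and the
squared Pearson correlation between predicted and observed responses,
pooled over time and trials, is reported as variance explained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .kernels import BasisSet, Kernel, kernel_from_weights
from .tasks import PlantConfig, TargetTrajectory, TrialRecord, _run_loop

__all__ = [
    "RegressionProblem",
    "FitResult",
    "split_train_validation",
    "build_design",
    "fit_kernel_weights",
    "predict_closed_loop",
    "predict_trial",
    "variance_explained",
    "fit_kernel",
    "mean_step_response",
    "conditional_response",
]


@dataclass
class RegressionProblem:
    """Stacked least-squares problem for the basis weights.

    Row i of ``design`` holds the convolution of each basis function with
    the displayed-error series of some trial, evaluated at one retained
    time sample; ``y`` holds the observed response at that sample;
    ``row_index`` maps rows back to (trial position, frame).
    """

    design: np.ndarray
    y: np.ndarray
    row_index: np.ndarray  # shape (rows, 2): (trial index, frame index)


@dataclass
class FitResult:
    weights: np.ndarray
    kernel: Kernel
    train_ids: list
    validation_ids: list
    variance_explained: float | None = None
    extras: dict = field(default_factory=dict)


def split_train_validation(
    trials: list[TrialRecord], n_train: int = 100, rng: np.random.Generator | None = None
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Uniform without-replacement split into train and validation sets."""
    if n_train > len(trials):
        raise ValueError(f"n_train={n_train} exceeds {len(trials)} available trials")
    rng = np.random.default_rng() if rng is None else rng
    order = rng.permutation(len(trials))
    train = [trials[i] for i in sorted(order[:n_train])]
    valid = [trials[i] for i in sorted(order[n_train:])]
    return train, valid


def _basis_columns(x: np.ndarray, basis: BasisSet, dt: float) -> np.ndarray:
    """Convolve every basis function with x: column j at row i is
    sum_m B[m, j] x[i - 1 - m] dt (causal, zero-padded history)."""
    n = len(x)
    full = sp_signal.fftconvolve(x[:, None], basis.B, axes=0) * dt
    cols = np.zeros((n, basis.N))
    cols[1:] = full[: n - 1]
    return cols


def build_design(
    trials: list[TrialRecord],
    basis: BasisSet,
    dt: float | None = None,
    drop_initial: float = 500.0,
    drop_incomplete_history: bool = False,
) -> RegressionProblem:
    """Stack the lagged-error regressors of every trial.

    drop_initial (ms) removes the stationary-hold rows at the start of
    each trial.  By default earlier samples keep a zero-padded lag history
    (matching the free-running prediction convention); set
    ``drop_incomplete_history`` to drop the first kernel-length of rows
    instead.
    """
    if not trials:
        raise ValueError("no trials supplied")
    if dt is None:
        dt = trials[0].dt
    for tr in trials:
        if abs(tr.dt - dt) > 1e-9 * dt:
            raise ValueError("trials do not share a common dt")
    first = int(round(drop_initial / 1000.0 / dt))
    if drop_incomplete_history:
        first = max(first, basis.B.shape[0])
    blocks, ys, idx = [], [], []
    for ti, tr in enumerate(trials):
        cols = _basis_columns(tr.x, basis, dt)
        keep = np.arange(first, len(tr))
        blocks.append(cols[keep])
        ys.append(tr.r[keep])
        idx.append(np.column_stack([np.full(len(keep), ti), keep]))
    return RegressionProblem(
        design=np.vstack(blocks), y=np.concatenate(ys), row_index=np.vstack(idx)
    )


def fit_kernel_weights(problem: RegressionProblem) -> np.ndarray:
    """Ordinary least squares; minimum-norm solution with a warning if
    the design is rank-deficient."""
    A, y = problem.design, problem.y
    if A.shape[0] < A.shape[1]:
        raise ValueError(
            f"underdetermined problem: {A.shape[0]} rows < {A.shape[1]} columns"
        )
    w, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {A.shape[1]}); "
            "returning the minimum-norm solution",
            stacklevel=2,
        )
    return w


def predict_closed_loop(
    kernel: Kernel,
    target: TargetTrajectory,
    H0: float,
    plant: PlantConfig,
    heading_offsets: np.ndarray | None = None,
) -> TrialRecord:
    """Free-running deterministic prediction of a whole trial.

    Runs the same closed-loop recursion as the simulator with zero error
    noise, given only the initial heading and the target trajectory.  The
    stored displayed target (and, when supplied, the recorded heading
    display offsets) are replayed so that on a noiseless plant the
    prediction reproduces a simulated trial sample for sample.
    """
    if abs(kernel.dt - plant.dt) > 1e-9 * plant.dt:
        raise ValueError("kernel lag grid spacing does not match plant dt")
    n = len(target)
    h_off = np.zeros(n) if heading_offsets is None else np.asarray(heading_offsets)
    if len(h_off) != n:
        raise ValueError("heading_offsets length mismatch")
    x, r, H = _run_loop(
        target.T_displayed, h_off, np.zeros(n), kernel,
        plant.joystick_gain, plant.dt, H0=H0, clip=plant.response_clip,
    )
    return TrialRecord(
        t=target.t.copy(), T_world=target.T_world.copy(),
        T_displayed=target.T_displayed.copy(),
        H_world=H, H_displayed=H + h_off, x=x, r=r,
        meta={"predicted": True},
    )


def predict_trial(kernel: Kernel, trial: TrialRecord, plant: PlantConfig) -> TrialRecord:
    """Free-running prediction of a recorded trial, replaying the displayed
    target and the recorded heading display-noise offsets."""
    target = TargetTrajectory(
        t=trial.t, T_world=trial.T_world, T_displayed=trial.T_displayed,
        step_times=trial.step_times, step_amplitudes=trial.step_amplitudes,
        context=trial.meta.get("context", "drift"),
    )
    return predict_closed_loop(
        kernel, target, H0=trial.H_world[0], plant=plant,
        heading_offsets=trial.heading_offsets,
    )


def variance_explained(predicted, observed) -> float:
    """Squared Pearson correlation pooled over all (trial, frame) samples."""
    p = np.concatenate([np.ravel(a) for a in _as_series_list(predicted)])
    o = np.concatenate([np.ravel(a) for a in _as_series_list(observed)])
    if p.shape != o.shape:
        raise ValueError("pooled predicted and observed lengths differ")
    if np.std(p) == 0 or np.std(o) == 0:
        raise ValueError("zero-variance input to variance_explained")
    r = np.corrcoef(p, o)[0, 1]
    return float(r**2)


def _as_series_list(obj) -> list[np.ndarray]:
    if isinstance(obj, TrialRecord):
        return [obj.r]
    if isinstance(obj, np.ndarray):
        return [obj]
    return [tr.r if isinstance(tr, TrialRecord) else np.asarray(tr) for tr in obj]


def fit_kernel(
    trials: list[TrialRecord],
    basis: BasisSet,
    plant: PlantConfig,
    n_train: int = 100,
    rng: np.random.Generator | None = None,
    drop_initial: float = 500.0,
) -> FitResult:
    """End-to-end pipeline: split, regress, assemble, validate.

    Variance explained is the pooled squared correlation between the
    free-running closed-loop prediction and the observed responses on the
    held-out validation trials; 1 - SSE/SStot is stored in ``extras``.
    """
    n_train = min(n_train, len(trials))
    train, valid = split_train_validation(trials, n_train, rng)
    problem = build_design(train, basis, drop_initial=drop_initial)
    w = fit_kernel_weights(problem)
    kernel = kernel_from_weights(w, basis)
    result = FitResult(
        weights=w, kernel=kernel,
        train_ids=[tr.meta.get("trial_id") for tr in train],
        validation_ids=[tr.meta.get("trial_id") for tr in valid],
    )
    eval_set = valid if valid else train
    preds = [predict_trial(kernel, tr, plant) for tr in eval_set]
    result.variance_explained = variance_explained(preds, eval_set)
    p = np.concatenate([pr.r for pr in preds])
    o = np.concatenate([tr.r for tr in eval_set])
    sse = np.sum((o - p) ** 2)
    sstot = np.sum((o - o.mean()) ** 2)
    result.extras["r2_sse"] = float(1.0 - sse / sstot)
    result.extras["validated_on_train"] = not valid
    return result


def mean_step_response(
    trials: list[TrialRecord],
    window: tuple[float, float] = (-0.5, 3.0),
    amplitudes: list[float] | None = None,
) -> dict:
    """Sign-aligned mean response traces around target steps.

    For every step event the response is extracted in ``window`` seconds
    around the step frame, negated for leftward steps, grouped by step
    magnitude, and averaged pointwise.  Returns
    ``{amplitude: {"t": offsets, "mean": trace, "n": count}}``; index 0 of
    each trace is the step frame.
    """
    dt = trials[0].dt
    pre = int(round(-window[0] / dt))
    post = int(round(window[1] / dt))
    groups: dict[float, list[np.ndarray]] = {}
    for tr in trials:
        if tr.step_times is None:
            continue
        for st, amp in zip(tr.step_times, tr.step_amplitudes):
            i0 = int(round(st / dt))
            if i0 - pre < 0 or i0 + post >= len(tr):
                continue
            seg = tr.r[i0 - pre : i0 + post + 1] * np.sign(amp)
            groups.setdefault(abs(float(amp)), []).append(seg)
    if amplitudes is not None:
        missing = [a for a in amplitudes if a not in groups]
        if missing:
            raise ValueError(f"no steps of amplitude(s) {missing} in the data")
        groups = {a: groups[a] for a in amplitudes}
    offsets = dt * np.arange(-pre, post + 1)
    return {
        amp: {"t": offsets, "mean": np.mean(segs, axis=0), "n": len(segs)}
        for amp, segs in sorted(groups.items())
    }


DEFAULT_CONDITIONAL_LAGS = (0.0, 0.21, 0.42, 0.85, 1.69, 3.39)


def conditional_response(
    trials: list[TrialRecord],
    lags: tuple[float, ...] = DEFAULT_CONDITIONAL_LAGS,
    error_halfwidth: float = 1.0,
    bin_centers: np.ndarray | None = None,
) -> dict:
    """Error-conditioned response means at a set of time lags.

    For each lag dt_lag and error-bin center c, the mean and SEM of
    r(t + dt_lag) over all (trial, t) with |x(t) - c| <= error_halfwidth.
    Bins with fewer than two observations get SEM = NaN and are flagged.
    Also reports the pooled lag-0 Pearson correlation between x and r.
    """
    dt = trials[0].dt
    x_all = np.concatenate([tr.x for tr in trials])
    if bin_centers is None:
        hi = np.percentile(np.abs(x_all), 99)
        bin_centers = np.arange(-np.ceil(hi), np.ceil(hi) + 0.5, 1.0)
    rows = []
    for lag in lags:
        shift = int(round(lag / dt))
        xs, rs = [], []
        for tr in trials:
            n = len(tr)
            if shift >= n:
                continue
            xs.append(tr.x[: n - shift])
            rs.append(tr.r[shift:])
        xp = np.concatenate(xs)
        rp = np.concatenate(rs)
        for c in bin_centers:
            sel = np.abs(xp - c) <= error_halfwidth
            cnt = int(sel.sum())
            if cnt == 0:
                rows.append((lag, c, 0, np.nan, np.nan, True))
                continue
            vals = rp[sel]
            sem = float(vals.std(ddof=1) / np.sqrt(cnt)) if cnt > 1 else np.nan
            rows.append((lag, c, cnt, float(vals.mean()), sem, cnt < 2))
    x0 = np.concatenate([tr.x for tr in trials])
    r0 = np.concatenate([tr.r for tr in trials])
    corr0 = float(np.corrcoef(x0, r0)[0, 1])
    import pandas as pd

    table = pd.DataFrame(
        rows, columns=["lag_s", "bin_center_deg", "n", "mean", "sem", "flagged"]
    )
    return {"table": table, "lag0_correlation": corr0}
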