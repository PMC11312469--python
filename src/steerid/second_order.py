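"""Second-order control-model fits and context comparison.

Classic manual-control models treat the hand driving the joystick as a
damped mass-spring system driven by the time-delayed steering error:

    r''(t) = g x(t - delay) - 2 zeta wn r'(t) - wn^2 r(t)

whose impulse response is the delayed damped sinusoid implemented in
``kernels.second_order_kernel``.  Here the four parameters
(zeta, wn, g, delay) are fit by nonlinear least squares: the predicted
response is the convolution of the parameterized kernel with each trial's
observed displayed-error series (the same open-loop protocol used to train
the nonparametric kernel), and the objective is the summed squared response
residual across trials.

Bootstrap resampling of trials yields parameter distributions; contexts
are compared by the percent change of each parameter mean and a t statistic
(mean difference over the root summed bootstrap variances).  Because the
test is applied to bootstrap distributions it is anti-conservative; see
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .kernels import SecondOrderParams, default_lag_grid, second_order_kernel
from .tasks import TrialRecord

__all__ = [
    "BootstrapResult",
    "ContextComparison",
    "fit_second_order",
    "bootstrap_second_order",
    "compare_contexts",
]

PARAM_NAMES = ("zeta", "omega_n", "g", "delay")

#: Multi-start grid: delays (s) and natural frequencies (rad/s) covering
#: the plausible sensorimotor range.
_START_DELAYS = (0.1, 0.2, 0.35)
_START_OMEGAS = (6.0, 10.0, 16.0)


@dataclass
class BootstrapResult:
    """Bootstrap distribution of second-order parameter fits.

    CI halfwidths are 1.96 times the SD of the retained fits (i.e. a
    normal-approximation 95% interval).
    """

    samples: dict  # name -> array of retained fits
    means: dict
    sds: dict
    ci_halfwidths: dict
    n_boot: int
    n_per_boot: int
    outlier_sd: float
    outlier_fraction: float
    extras: dict = field(default_factory=dict)

    @property
    def params(self) -> SecondOrderParams:
        return SecondOrderParams(
            zeta=self.means["zeta"], omega_n=self.means["omega_n"],
            g=self.means["g"], delay=self.means["delay"],
        )


@dataclass
class ContextComparison:
    """Per-parameter change between contexts (test relative to reference)."""

    percent_change: dict
    t_stat: dict
    p_value: dict
    df: int


class _Predictor:
    """Batched open-loop prediction: conv of a trial-shared kernel with each
    trial's error series, evaluated via one cached rFFT per dataset."""

    def __init__(self, trials: list[TrialRecord], lag_grid: np.ndarray):
        self.dt = trials[0].dt
        self.lag_grid = lag_grid
        L = len(lag_grid)
        self.lengths = [len(tr) for tr in trials]
        nmax = max(self.lengths)
        self.nfft = int(2 ** np.ceil(np.log2(nmax + L)))
        X = np.zeros((len(trials), nmax))
        for i, tr in enumerate(trials):
            X[i, : self.lengths[i]] = tr.x
        self.Xf = np.fft.rfft(X, n=self.nfft, axis=1)
        self.y = np.concatenate([tr.r for tr in trials])

    def predict(self, theta: np.ndarray) -> np.ndarray:
        params = SecondOrderParams(*theta)
        k = second_order_kernel(params, self.lag_grid).k
        kf = np.fft.rfft(np.concatenate([[0.0], k]), n=self.nfft)
        conv = np.fft.irfft(self.Xf * kf[None, :], n=self.nfft, axis=1) * self.dt
        return np.concatenate([conv[i, :n] for i, n in enumerate(self.lengths)])

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        return self.predict(theta) - self.y


_DEFAULT_BOUNDS = ((0.0, 0.999), (0.5, 60.0), (1e-8, 1e4), (0.0, 1.0))


def fit_second_order(
    trials: list[TrialRecord],
    init: SecondOrderParams | None = None,
    bounds: tuple = _DEFAULT_BOUNDS,
    lag_grid: np.ndarray | None = None,
    n_starts: int = 5,
    rng: np.random.Generator | None = None,
) -> SecondOrderParams:
    """Nonlinear least-squares fit of (zeta, wn, g, delay).

    If no explicit initialization is given, ``n_starts`` starts are taken
    from a coarse (delay, wn) grid with multiplicative jitter, and the fit
    with the lowest final objective is kept.  Raises if no start converges.
    """
    if not trials:
        raise ValueError("no trials supplied")
    if lag_grid is None:
        lag_grid = default_lag_grid(dt=trials[0].dt)
    pred = _Predictor(trials, lag_grid)
    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])

    if init is not None:
        theta0 = np.array([init.zeta, init.omega_n, init.g, init.delay])
        if np.any(theta0 < lb) or np.any(theta0 > ub):
            raise ValueError("initialization outside bounds")
        starts = [theta0]
    else:
        rng = np.random.default_rng(0) if rng is None else rng
        grid = [(d, w) for d in _START_DELAYS for w in _START_OMEGAS]
        picks = [grid[i % len(grid)] for i in range(n_starts)]
        starts = []
        for d, w in picks:
            jd = d * rng.uniform(0.8, 1.2)
            jw = w * rng.uniform(0.8, 1.2)
            starts.append(np.clip(np.array([0.3, jw, 1.0, jd]), lb, ub))

    best = None
    for theta0 in starts:
        sol = optimize.least_squares(
            pred.residuals, theta0, bounds=(lb, ub),
            x_scale=[0.1, 5.0, 1.0, 0.05], xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.status <= 0:
        raise RuntimeError(
            f"second-order fit did not converge (final objective {best.cost if best else 'n/a'})"
        )
    return SecondOrderParams(*best.x)


def bootstrap_second_order(
    trials: list[TrialRecord],
    n_boot: int = 100,
    n_per_boot: int = 200,
    outlier_sd: float = 2.5,
    rng: np.random.Generator | None = None,
    **fit_kwargs,
) -> BootstrapResult:
    """Bootstrap the second-order fit over resampled trial subsets.

    Each replicate fits ``n_per_boot`` trials drawn uniformly with
    replacement.  Replicates with any parameter more than ``outlier_sd``
    SDs from the across-replicate mean are discarded before computing
    means, SDs and 1.96*SD confidence halfwidths.
    """
    if not trials:
        raise ValueError("no trials supplied")
    rng = np.random.default_rng() if rng is None else rng
    fits = np.empty((n_boot, 4))
    warm: SecondOrderParams | None = None
    for b in range(n_boot):
        idx = rng.integers(0, len(trials), size=n_per_boot)
        sub = [trials[i] for i in idx]
        if warm is None:
            p = fit_second_order(sub, rng=rng, **fit_kwargs)
            warm = p
        else:
            # warm-start replicates at the first full fit; resampling noise
            # keeps the landscape near that optimum
            p = fit_second_order(sub, init=warm, **fit_kwargs)
        fits[b] = (p.zeta, p.omega_n, p.g, p.delay)

    mu = fits.mean(axis=0)
    sd = fits.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(fits - mu) / np.where(sd > 0, sd, np.inf)
    keep = ~(z > outlier_sd).any(axis=1)
    if not keep.any():
        raise RuntimeError("all bootstrap fits discarded as outliers")
    kept = fits[keep]
    names = PARAM_NAMES
    means = dict(zip(names, kept.mean(axis=0)))
    sds = dict(zip(names, kept.std(axis=0, ddof=1) if len(kept) > 1 else np.zeros(4)))
    samples = {n: kept[:, i].copy() for i, n in enumerate(names)}
    # derived amplitude G, reported alongside the primitive parameters
    Gs = samples["g"] / (samples["omega_n"] * np.sqrt(1 - samples["zeta"] ** 2))
    samples["G"] = Gs
    means["G"] = float(Gs.mean())
    sds["G"] = float(Gs.std(ddof=1)) if len(Gs) > 1 else 0.0
    ci = {n: 1.96 * s for n, s in sds.items()}
    return BootstrapResult(
        samples=samples, means=means, sds=sds, ci_halfwidths=ci,
        n_boot=n_boot, n_per_boot=n_per_boot, outlier_sd=outlier_sd,
        outlier_fraction=float(1.0 - keep.mean()),
    )


def compare_contexts(ref: BootstrapResult, test: BootstrapResult) -> ContextComparison:
    """Percent change and significance of each parameter across contexts.

    percent change = 100 (mean_test - mean_ref) / mean_ref;
    t = (mean_test - mean_ref) / sqrt(var_test + var_ref), two-tailed p
    with df = n_boot - 1.
    """
    common = [n for n in ref.means if n in test.means]
    if not common:
        raise ValueError("no common parameters to compare")
    pc, ts, ps = {}, {}, {}
    df = ref.n_boot - 1
    for name in common:
        m0, m1 = ref.means[name], test.means[name]
        if m0 == 0:
            raise ValueError(f"zero reference mean for {name}: percent change undefined")
        pc[name] = 100.0 * (m1 - m0) / m0
        denom = np.sqrt(ref.sds[name] ** 2 + test.sds[name] ** 2)
        t = (m1 - m0) / denom if denom > 0 else (0.0 if m1 == m0 else np.inf)
        ts[name] = float(t)
        ps[name] = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return ContextComparison(percent_change=pc, t_stat=ts, p_value=ps, df=df)


def percent_change(reference_mean: float, test_mean: float) -> float:
    """100 (test - reference)/reference — the published-table convention."""
    if reference_mean == 0:
        raise ValueError("zero reference mean")
    return 100.0 * (test_mean - reference_mean) / reference_mean
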