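"""Distribution and curve fitting for single-molecule and stopped-flow data.

Run lengths and dwell times from kymograph analysis are exponentially
distributed but left-truncated by detection limits (events shorter than
3 pixels / 3 frames are invisible). For a truncated exponential the maximum-
likelihood estimate is closed-form: by memorylessness, tau = mean(x - c)
over the samples at or above the cutoff c. Mixtures of two exponentials are
fit by expectation-maximization on the shifted data, with deterministic
multi-start from data quantiles.

Saturation curves (Michaelis-Menten for ATP-triggered half-site release,
Langmuir isotherms for pelleting assays) go through scipy least squares;
linear stopped-flow and charge-run-length fits go through statsmodels
OLS/WLS. All estimators quote symmetric 95% confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import ConvergenceError, DomainError, InsufficientDataError

__all__ = [
    "ExponentialFitResult",
    "SaturationFitResult",
    "LinearFitResult",
    "SegmentedVelocityResult",
    "fit_exponential_truncated",
    "fit_biexponential_truncated",
    "fit_michaelis_menten",
    "fit_langmuir",
    "fit_linear",
    "estimate_segmented_velocity",
    "empirical_survival",
]

DEGENERACY_RATIO = 0.9  # tau1/tau2 above this flags a near-degenerate mixture


@dataclass(frozen=True)
class ExponentialFitResult:
    """Single- or multi-component (truncated) exponential fit.

    ``components`` are (weight, tau) pairs sorted by ascending tau; for a
    truncated fit the weights describe the observed (post-cutoff) population.
    ``tau_ci95`` are half-widths of the 95% CIs, one per component.
    """

    components: tuple[tuple[float, float], ...]
    tau_ci95: tuple[float, ...]
    n_used: int
    n_input: int
    cutoff: float
    degenerate: bool = False
    method: str = "mle"
    log_likelihood: float = math.nan

    @property
    def tau(self) -> float:
        """Tau of the single component (errors if the fit has several)."""
        if len(self.components) != 1:
            raise ValueError("fit has multiple components; index .components")
        return self.components[0][1]

    @property
    def taus(self) -> tuple[float, ...]:
        return tuple(t for _, t in self.components)

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(w for w, _ in self.components)


@dataclass(frozen=True)
class SaturationFitResult:
    """Hyperbolic saturation fit: amplitude * x / (half_saturation + x).

    ``amplitude`` is k_max for Michaelis-Menten fits or V_max for Langmuir
    isotherms; ``half_saturation`` is K_M or K_D correspondingly.
    """

    amplitude: float
    amplitude_ci95: float
    half_saturation: float
    half_saturation_ci95: float
    rss: float
    n: int
    amplitude_name: str = "k_max"
    half_saturation_name: str = "K_M"
    flags: tuple[str, ...] = ()

    # assay-specific aliases
    @property
    def k_max(self) -> float:
        return self.amplitude

    @property
    def K_M(self) -> float:
        return self.half_saturation

    @property
    def V_max(self) -> float:
        return self.amplitude

    @property
    def K_D(self) -> float:
        return self.half_saturation


@dataclass(frozen=True)
class LinearFitResult:
    """Straight-line fit with 95% CIs from the t distribution (n-2 df)."""

    slope: float
    intercept: float
    slope_ci95: float
    intercept_ci95: float
    weighted: bool
    n: int
    r_squared: float


@dataclass(frozen=True)
class SegmentedVelocityResult:
    """Per-segment velocities of a trace after pause removal."""

    segment_velocities: tuple[float, ...]
    mean: float
    sem: float
    n_segments: int
    n_excluded: int


# ---------------------------------------------------------------------------
# truncated exponential fits
# ---------------------------------------------------------------------------

def _validated_tail(samples: Sequence[float], cutoff: float, minimum: int) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.size and np.any(x <= 0):
        raise DomainError("samples must be strictly positive")
    if cutoff < 0:
        raise DomainError("cutoff must be >= 0")
    tail = x[x >= cutoff]
    if tail.size < minimum:
        raise InsufficientDataError(
            f"need >= {minimum} samples at or above the cutoff, got {tail.size}"
        )
    return tail


def fit_exponential_truncated(
    samples: Sequence[float],
    cutoff: float = 0.0,
    method: str = "mle",
) -> ExponentialFitResult:
    """Fit a left-truncated exponential to run lengths or dwell times.

    ``method='mle'`` (default) uses the closed-form maximum-likelihood
    estimate tau = mean(x - cutoff) over x >= cutoff, with a 95% CI of
    1.96 tau / sqrt(n). ``method='survival'`` instead least-squares fits
    exp(-(x - cutoff)/tau) to the empirical survival (1-CDF) curve, the
    graphical procedure commonly used on 1-CDF plots; the two agree within
    CI on exponential data.
    """
    tail = _validated_tail(samples, cutoff, minimum=5)
    n = tail.size
    shifted = tail - cutoff
    if method == "mle":
        tau = float(shifted.mean())
        ci = 1.96 * tau / math.sqrt(n)
        loglik = float(-n * math.log(tau) - n) if tau > 0 else math.nan
    elif method == "survival":
        xs, surv = zip(*empirical_survival(shifted))
        (tau,), cov = optimize.curve_fit(
            lambda x, t: np.exp(-x / t),
            np.array(xs),
            np.array(surv),
            p0=[max(float(shifted.mean()), 1e-12)],
        )
        tau = float(tau)
        ci = 1.96 * float(np.sqrt(cov[0, 0]))
        loglik = math.nan
    else:
        raise DomainError(f"unknown method {method!r}")
    return ExponentialFitResult(
        components=((1.0, tau),),
        tau_ci95=(ci,),
        n_used=n,
        n_input=len(samples),
        cutoff=cutoff,
        method=method,
        log_likelihood=loglik,
    )


def _em_biexponential(
    y: np.ndarray, w0: float, tau0: tuple[float, float], max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """EM for a 2-component exponential mixture on shifted data y >= 0."""
    w = np.array([w0, 1.0 - w0])
    tau = np.array(tau0, dtype=float)
    loglik = -np.inf
    for _ in range(max_iter):
        dens = w[None, :] / tau[None, :] * np.exp(-y[:, None] / tau[None, :])
        total = dens.sum(axis=1)
        total = np.maximum(total, 1e-300)
        new_loglik = float(np.log(total).sum())
        resp = dens / total[:, None]
        w = resp.mean(axis=0)
        w = np.maximum(w, 1e-12)
        w /= w.sum()
        tau = resp.T @ y / np.maximum(resp.sum(axis=0), 1e-12)
        tau = np.maximum(tau, 1e-12)
        if abs(new_loglik - loglik) < tol * (1 + abs(new_loglik)):
            return w, tau, new_loglik, True
        loglik = new_loglik
    return w, tau, loglik, False


def fit_biexponential_truncated(
    samples: Sequence[float],
    cutoff: float = 0.0,
    max_iter: int = 5000,
    tol: float = 1e-12,
) -> ExponentialFitResult:
    """Fit a two-component left-truncated exponential mixture by EM.

    By memorylessness, shifting the post-cutoff samples by the cutoff leaves
    a plain two-exponential mixture whose taus equal the untruncated ones
    (only the weights are reweighted toward the slow component), so EM runs
    on the shifted data. Starts are deterministic, drawn from data quantile
    pairs; the best log-likelihood wins. Components are returned ordered
    tau1 < tau2, and ``degenerate`` is flagged when tau1/tau2 > 0.9 (the two
    components are then not separately identifiable and the fit collapses to
    the single-exponential answer).

    Per-tau 95% CIs use the per-component effective sample size
    (1.96 * tau_k / sqrt(n * w_k)).
    """
    tail = _validated_tail(samples, cutoff, minimum=50)
    y = tail - cutoff
    n = y.size
    q = np.quantile(y, [0.05, 0.10, 0.25, 0.50, 0.75, 0.90])
    mean = float(y.mean())
    starts = [
        (0.5, (max(q[1], 1e-9), max(q[4], 2e-9))),
        (0.5, (max(q[0], 1e-9), max(q[5], 2e-9))),
        (0.3, (max(q[2], 1e-9), max(q[3], 2e-9))),
        (0.7, (max(mean / 5, 1e-9), max(mean * 2, 2e-9))),
    ]
    best = None
    for w0, tau0 in starts:
        w, tau, loglik, converged = _em_biexponential(y, w0, tau0, max_iter, tol)
        if converged and (best is None or loglik > best[2]):
            best = (w, tau, loglik)
    if best is None:
        raise ConvergenceError("EM failed to converge from every start")
    w, tau, loglik = best
    order = np.argsort(tau)
    w, tau = w[order], tau[order]
    degenerate = bool(tau[0] / tau[1] > DEGENERACY_RATIO)
    ci = tuple(
        1.96 * float(t) / math.sqrt(max(n * float(wk), 1.0)) for wk, t in zip(w, tau)
    )
    return ExponentialFitResult(
        components=tuple((float(wk), float(t)) for wk, t in zip(w, tau)),
        tau_ci95=ci,
        n_used=n,
        n_input=len(samples),
        cutoff=cutoff,
        degenerate=degenerate,
        method="em",
        log_likelihood=loglik,
    )


# ---------------------------------------------------------------------------
# saturation fits
# ---------------------------------------------------------------------------

def _hyperbola(x: np.ndarray, amp: float, khalf: float) -> np.ndarray:
    return amp * x / (khalf + x)


def _fit_saturation(
    x: Sequence[float],
    y: Sequence[float],
    amplitude_name: str,
    half_saturation_name: str,
) -> SaturationFitResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError("x and y must have equal length")
    if np.unique(x).size < 3:
        raise DomainError("need >= 3 distinct concentrations")
    flags: list[str] = []
    if np.max(np.abs(y)) == 0:
        # no signal: amplitude 0, half-saturation unidentifiable
        return SaturationFitResult(
            0.0, 0.0, math.nan, math.nan, 0.0, x.size,
            amplitude_name, half_saturation_name, ("no_signal",),
        )
    amp0 = float(np.max(y)) * 1.05
    half_idx = int(np.argmin(np.abs(y - amp0 / 2)))
    khalf0 = max(float(x[half_idx]), float(np.median(x[x > 0])) if np.any(x > 0) else 1.0)
    popt, pcov = optimize.curve_fit(
        _hyperbola, x, y, p0=[amp0, khalf0], bounds=([0, 1e-12], [np.inf, np.inf]),
        maxfev=20000,
    )
    resid = y - _hyperbola(x, *popt)
    rss = float(resid @ resid)
    df = max(x.size - 2, 1)
    tcrit = float(stats.t.ppf(0.975, df))
    perr = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    return SaturationFitResult(
        amplitude=float(popt[0]),
        amplitude_ci95=tcrit * float(perr[0]),
        half_saturation=float(popt[1]),
        half_saturation_ci95=tcrit * float(perr[1]),
        rss=rss,
        n=int(x.size),
        amplitude_name=amplitude_name,
        half_saturation_name=half_saturation_name,
        flags=tuple(flags),
    )


def fit_michaelis_menten(
    x_uM: Sequence[float], y_per_s: Sequence[float]
) -> SaturationFitResult:
    """Fit k_obs = k_max * [S] / (K_M + [S]) to observed rates."""
    return _fit_saturation(x_uM, y_per_s, "k_max", "K_M")


def fit_langmuir(
    mt_uM: Sequence[float], fraction: Sequence[float]
) -> SaturationFitResult:
    """Fit fraction bound = V_max * [Mt] / (K_D + [Mt]) to pelleting data.

    Fractions above 1 are allowed (normalization to an AMPPNP control can
    overshoot 100%).
    """
    return _fit_saturation(mt_uM, fraction, "V_max", "K_D")


# ---------------------------------------------------------------------------
# linear fits
# ---------------------------------------------------------------------------

def fit_linear(
    x: Sequence[float],
    y: Sequence[float],
    y_err: Sequence[float] | None = None,
) -> LinearFitResult:
    """Ordinary (or inverse-variance weighted) least squares y = a + b*x.

    95% CIs come from the t distribution with n-2 degrees of freedom. For
    n = 2 (zero residual df) the CIs are 0 for an exact fit and inf
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError("x and y must have equal length")
    if np.unique(x).size < 2:
        raise DomainError("need >= 2 distinct x values")
    design = sm.add_constant(x)
    if y_err is not None:
        w = 1.0 / np.square(np.asarray(y_err, dtype=float))
        model = sm.WLS(y, design, weights=w)
    else:
        model = sm.OLS(y, design)
    res = model.fit()
    intercept, slope = res.params
    if x.size > 2:
        ci = res.conf_int(alpha=0.05)
        intercept_ci = float((ci[0, 1] - ci[0, 0]) / 2)
        slope_ci = float((ci[1, 1] - ci[1, 0]) / 2)
    else:
        exact = bool(np.allclose(res.resid, 0.0))
        intercept_ci = slope_ci = 0.0 if exact else math.inf
    return LinearFitResult(
        slope=float(slope),
        intercept=float(intercept),
        slope_ci95=slope_ci,
        intercept_ci95=intercept_ci,
        weighted=y_err is not None,
        n=int(x.size),
        r_squared=float(res.rsquared) if x.size > 2 else 1.0,
    )


# ---------------------------------------------------------------------------
# segmented velocity
# ---------------------------------------------------------------------------

def estimate_segmented_velocity(
    positions_um: Sequence[float],
    times_s: Sequence[float],
    pixel_size_um: float = 0.0567,
    min_segment_pixels: int = 3,
    pause_speed_fraction: float = 0.25,
    window: int = 3,
) -> SegmentedVelocityResult:
    """Mean velocity of the motile segments of a trace, pauses excluded.

    Motors at low ionic strength intersperse runs with pauses, so the
    end-to-end velocity underestimates the stepping speed. This two-pass
    procedure (1) computes instantaneous speeds over a ``window``-frame
    sliding window and classifies frames as paused when their speed falls
    below ``pause_speed_fraction`` times the trace median speed, then
    (2) merges contiguous motile stretches into segments, dropping segments
    whose displacement is under ``min_segment_pixels`` pixels. Returns the
    per-segment velocities and their mean +/- SEM.
    """
    pos = np.asarray(positions_um, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if pos.size != t.size:
        raise DomainError("positions and times must have equal length")
    if pos.size < 2:
        raise InsufficientDataError("need >= 2 points")
    if np.any(np.diff(t) < 0):
        raise DomainError("times must be non-decreasing")
    n = pos.size
    half = max(window // 2, 1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    dt = t[hi] - t[lo]
    with np.errstate(divide="ignore", invalid="ignore"):
        speeds = np.where(dt > 0, np.abs(pos[hi] - pos[lo]) / dt, 0.0)
    median_speed = float(np.median(speeds))
    if median_speed > 0:
        motile = speeds >= pause_speed_fraction * median_speed
    else:
        # mostly stationary trace: any movement at all counts as motile
        motile = speeds > 0

    velocities: list[float] = []
    n_excluded = 0
    min_disp = min_segment_pixels * pixel_size_um
    i = 0
    while i < n:
        if not motile[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and motile[j + 1]:
            j += 1
        disp = abs(pos[j] - pos[i])
        span = t[j] - t[i]
        if disp >= min_disp and span > 0:
            velocities.append(disp / span)
        else:
            n_excluded += 1
        i = j + 1
    if velocities:
        arr = np.array(velocities)
        mean = float(arr.mean())
        sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    else:
        mean = math.nan
        sem = math.nan
    return SegmentedVelocityResult(
        tuple(velocities), mean, sem, len(velocities), n_excluded
    )


# ---------------------------------------------------------------------------
# survival curves (1-CDF)
# ---------------------------------------------------------------------------

def empirical_survival(samples: Sequence[float]) -> list[tuple[float, float]]:
    """Right-continuous empirical survival curve: (value, fraction >= value).

    Starts at 1 at the minimum sample and ends at 1/n at the maximum (ties
    collapse to a single step).
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("empty sample")
    values = np.unique(x)
    n = x.size
    frac = [float(np.sum(x >= v)) / n for v in values]
    return list(zip(values.tolist(), frac))
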