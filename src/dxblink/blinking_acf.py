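"""Per-pixel intensity autocorrelation and constrained exponential fitting.

The central statistic is the normalized time autocorrelation of one pixel's
photon-count series,

    ACF(tau) = < I(t) * I(t + tau) > / < I(t) >^2,

with time averages over the recording and the normalization using the
single global mean (not windowed means).  For a pixel watching a blinking
diffraction spot with exponential on/off kinetics the curve decays as a
single exponential, ACF(t) = A * exp(-Gamma * t) + y, and the decay
constant Gamma estimates the sum of the entry and exit rates.

Pixels split into two populations: ACFs that decay with lag (spot-exit
dominated) and ACFs that grow (spot-entry dominated).  Because the
autocorrelation is an even function, reversing the time axis of the trace
cannot change this estimator — the set of lag-m products is
reversal-symmetric — so "time-reversal" handling is implemented as fitting
growing curves with the mirrored model y - A * exp(-Gamma * t) (the decay
curve reflected about its plateau), which recovers the same decay constant
from a curve that saturates upward.  Each pixel receives exactly one
direction label.

A fit is accepted when all of: A > 0, y > 0, Gamma > 0, and the residual
(sum of squared differences between fit and data over all fitted lags)
is below 1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import (
    PixelTrace,
    RingROI,
    detrend_matrix,
    detrend_trace,
    select_ring_pixels,
)
from .stack_io import DetectorGeometry, FrameStack

logger = logging.getLogger(__name__)

__all__ = [
    "ACFCurve",
    "ExpFit",
    "AnalysisParams",
    "compute_acf",
    "fit_acf",
    "classify_and_fit",
    "analyze_stack",
]

#: Optimizer lower bound implementing the strict-positivity constraints.
POSITIVITY_BOUND = 1e-12
#: Amplitudes below this after convergence are treated as violating A > 0.
MIN_AMPLITUDE = 1e-6
#: Printed acceptance threshold on the residual.
RESIDUAL_THRESHOLD = 1.0


@dataclass
class ACFCurve:
    """Normalized autocorrelation values at lags tau = dt, 2 dt, ... (lag 0 excluded)."""

    lags: np.ndarray  # seconds, strictly increasing
    values: np.ndarray
    n_frames_used: int

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have equal length")
        if self.lags.size and np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ACF values must be finite")


@dataclass
class ExpFit:
    """Result of the constrained single-exponential fit to one ACF curve."""

    A: float
    gamma: float
    y: float
    residual: float
    direction: str  # "decay" | "growth"
    accepted: bool
    reason: str = ""  # violated condition when not accepted


@dataclass(frozen=True)
class AnalysisParams:
    """Knobs of the per-pixel analysis stage."""

    max_lag_fraction: float = 0.25
    detrend_policy: str = "auto"
    residual_rule: str = "sum"  # "sum" | "mean" squared residuals
    residual_threshold: float = RESIDUAL_THRESHOLD


def compute_acf(
    trace: PixelTrace,
    max_lag_fraction: float = 0.25,
    max_lag: int | None = None,
) -> ACFCurve:
    """Normalized intensity autocorrelation of one pixel trace.

    For each lag m (1 <= m <= floor(N * max_lag_fraction), or ``max_lag``
    when given), the value is ``mean_t[I(t) I(t+m)] / mean[I]**2`` with the
    product average over the N - m available pairs and the single global
    mean in the denominator.  Lag 0 is excluded; it carries shot noise, not
    dynamics.  The default quarter-length lag ceiling avoids the poorly
    averaged long-lag tail.

    Raises
    ------
    ZeroDivisionError
        If the trace mean is not positive (normalization undefined).
    """
    y = trace.intensities
    n = y.size
    if n < 8:
        raise ValueError("trace too short for ACF (need >= 8 frames)")
    # forward+backward summation keeps the mean bit-identical under reversal
    mean = 0.5 * (y.sum() + y[::-1].sum()) / n
    if mean <= 0:
        raise ZeroDivisionError("trace mean <= 0: normalized ACF undefined")
    if max_lag is None:
        max_lag = int(np.floor(n * max_lag_fraction))
    max_lag = max(1, min(max_lag, n - 1))
    values = np.empty(max_lag)
    for m in range(1, max_lag + 1):
        prod = y[: n - m] * y[m:]
        # forward+backward pairwise sum: exactly invariant under trace reversal
        values[m - 1] = 0.5 * (prod.sum() + prod[::-1].sum()) / (n - m)
    values /= mean**2
    lags = np.arange(1, max_lag + 1) * trace.frame_interval
    return ACFCurve(lags=lags, values=values, n_frames_used=n)


def batch_acf(traces: np.ndarray, frame_interval: float, max_lag_fraction: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Normalized ACF of many traces at once via FFT correlation.

    ``traces`` has shape ``(n_pixels, n_frames)``; rows with non-positive
    mean get NaN curves (normalization undefined) and must be filtered by
    the caller.  Numerically equivalent to :func:`compute_acf` per row
    (FFT round-off ~1e-12 relative); used by the stack analysis for speed.

    Returns ``(lags, values)`` with ``values`` of shape
    ``(n_pixels, max_lag)``.
    """
    traces = np.asarray(traces, dtype=float)
    n_pix, n = traces.shape
    if n < 8:
        raise ValueError("traces too short for ACF (need >= 8 frames)")
    max_lag = max(1, min(int(np.floor(n * max_lag_fraction)), n - 1))
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(traces, nfft, axis=1)
    raw = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, 1 : max_lag + 1]
    raw /= (n - np.arange(1, max_lag + 1))[None, :]
    means = traces.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = raw / means[:, None] ** 2
    values[means <= 0] = np.nan
    lags = np.arange(1, max_lag + 1) * frame_interval
    return lags, values


def _residual_score(resid: np.ndarray, rule: str) -> float:
    if rule == "mean":
        return float(np.mean(resid**2))
    return float(np.sum(resid**2))


def _initial_guess_batch(
    lags: np.ndarray, values: np.ndarray, signs: np.ndarray
) -> np.ndarray:
    """Data-driven starts per curve: plateau from the tail quartile,
    amplitude from the first lag, rate from the half-crossing lag
    (fallback 1/tau_max)."""
    quarter = max(1, values.shape[1] // 4)
    y0 = values[:, -quarter:].mean(axis=1)
    a0 = np.maximum(-signs * (values[:, 0] - y0), MIN_AMPLITUDE)
    half = (y0 - signs * a0 / 2.0)[:, None]
    crossed = np.where(signs[:, None] < 0, values < half, values > half)
    has_cross = crossed.any(axis=1)
    first = np.argmax(crossed, axis=1)
    g0 = np.where(has_cross, 1.0 / lags[first], 1.0 / lags[-1])
    return np.column_stack(
        [a0, np.maximum(g0, POSITIVITY_BOUND), np.maximum(y0, POSITIVITY_BOUND)]
    )


def _lm_fit_batch(
    lags: np.ndarray,
    values: np.ndarray,
    signs: np.ndarray,
    max_iter: int = 1200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Projected Levenberg-Marquardt over many curves simultaneously.

    Damped Gauss-Newton steps with the Marquardt lambda schedule, the
    parameters projected onto [POSITIVITY_BOUND, inf) after every step —
    the same local descent from the same data-driven start for every
    curve, vectorized across pixels.  Local descent is deliberate: on
    noisy single-pixel curves the globally minimal sum of squares often
    sits in a degenerate noise-chasing basin, while the half-crossing
    start tracks the visible decay.

    Returns ``(params (P, 3), ssr (P,), converged (P,))``.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    signs = np.atleast_1d(np.asarray(signs, dtype=float))
    n_pix = values.shape[0]
    p = _initial_guess_batch(lags, values, signs)
    e = np.exp(-np.outer(p[:, 1], lags))
    resid = (p[:, 2:3] - signs[:, None] * p[:, 0:1] * e) - values
    ssr = np.einsum("ij,ij->i", resid, resid)
    lam = np.full(n_pix, 1e-3)
    converged = np.zeros(n_pix, dtype=bool)

    for _ in range(max_iter):
        act = np.nonzero(~converged)[0]
        if act.size == 0:
            break
        pa, sa = p[act], signs[act]
        e = np.exp(-np.outer(pa[:, 1], lags))
        ra = resid[act]
        # Jacobian columns: d/dA, d/dGamma, d/dy
        j0 = -sa[:, None] * e
        j1 = sa[:, None] * pa[:, 0:1] * lags[None, :] * e
        jac = np.stack([j0, j1, np.broadcast_to(np.ones_like(lags), e.shape)], axis=2)
        g = np.einsum("plk,pl->pk", jac, ra)
        hess = np.einsum("plk,plm->pkm", jac, jac)
        diag = np.einsum("pkk->pk", hess).copy()
        diag[diag <= 0] = 1e-30
        aug = hess + lam[act, None, None] * diag[:, :, None] * np.eye(3)
        try:
            delta = np.linalg.solve(aug, -g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:  # pragma: no cover - singular batch
            lam[act] *= 10.0
            continue
        p_new = np.maximum(pa + delta, POSITIVITY_BOUND)
        e_new = np.exp(-np.outer(p_new[:, 1], lags))
        r_new = (p_new[:, 2:3] - sa[:, None] * p_new[:, 0:1] * e_new) - values[act]
        ssr_new = np.einsum("ij,ij->i", r_new, r_new)
        better = ssr_new <= ssr[act]

        rel_step = np.max(np.abs(p_new - pa) / (np.abs(pa) + 1e-12), axis=1)
        rel_drop = (ssr[act] - ssr_new) / np.maximum(ssr[act], 1e-300)
        done = better & ((rel_step < 1e-10) | (rel_drop < 1e-14))

        acc = act[better]
        p[acc] = p_new[better]
        resid[acc] = r_new[better]
        ssr[acc] = ssr_new[better]
        lam[acc] = np.maximum(lam[acc] / 3.0, 1e-12)
        lam[act[~better]] *= 4.0
        converged[act[done]] = True
        # a runaway lambda means no improving step exists: a local minimum
        converged[act[lam[act] > 1e10]] = True
    return p, ssr, converged


def fit_acf(
    acf: ACFCurve,
    direction: str = "decay",
    params: AnalysisParams | None = None,
) -> ExpFit:
    """Constrained nonlinear least-squares fit of A*exp(-Gamma*t) + y.

    Projected Levenberg-Marquardt with an analytic Jacobian from a
    data-driven start (plateau from the tail quartile, amplitude from the
    first lag, rate from the half-crossing lag); the same engine fits one
    curve here and whole stacks in :func:`analyze_stack`.  All three
    parameters are bounded below at ``POSITIVITY_BOUND``; a converged
    amplitude below ``MIN_AMPLITUDE`` — or a model amplitude at the first
    lag below it (the large-rate ridge on which A is unidentifiable) — is
    treated as violating the A > 0 condition.  ``direction="growth"``
    fits the mirrored model y - A*exp(-Gamma*t) with the same constraints
    and residual rule.  Optimizer failure yields a rejected fit with the
    reason recorded, not an exception.
    """
    params = params or AnalysisParams()
    if direction not in ("decay", "growth"):
        raise ValueError(f"unknown direction {direction!r}")
    if acf.lags.size < 4:
        raise ValueError("need >= 4 lag points to fit")
    sign = -1.0 if direction == "decay" else 1.0
    try:
        with np.errstate(all="ignore"):
            p, _, ok = _lm_fit_batch(acf.lags, acf.values[None, :], np.array([sign]))
    except Exception as exc:  # pragma: no cover - optimizer pathologies
        return ExpFit(np.nan, np.nan, np.nan, np.inf, direction, False, f"optimizer: {exc}")
    a, gamma, y0 = p[0]
    model = y0 - sign * a * np.exp(-gamma * acf.lags)
    score = _residual_score(model - acf.values, params.residual_rule)
    return _classify_acceptance(
        a, gamma, y0, score, bool(ok[0]), acf.lags[0], direction, params
    )


def _classify_acceptance(
    a: float,
    gamma: float,
    y0: float,
    score: float,
    converged: bool,
    first_lag: float,
    direction: str,
    params: AnalysisParams,
) -> ExpFit:
    # amplitude the model actually exhibits over the observed lags; a huge
    # gamma with arbitrary A is the same degenerate "no dynamics" ridge
    resolvable = a * np.exp(-gamma * first_lag)
    reason = ""
    if not converged or not np.isfinite(a) or not np.isfinite(gamma):
        reason = "no-convergence"
    elif a <= MIN_AMPLITUDE or resolvable <= MIN_AMPLITUDE:
        reason = "amplitude<=0"
    elif gamma <= POSITIVITY_BOUND:
        reason = "gamma<=0"
    elif y0 <= POSITIVITY_BOUND:
        reason = "offset<=0"
    elif score >= params.residual_threshold:
        reason = "residual>=threshold"
    return ExpFit(
        A=float(a),
        gamma=float(gamma),
        y=float(y0),
        residual=score,
        direction=direction,
        accepted=reason == "",
        reason=reason,
    )


def classify_direction(acf: ACFCurve) -> str:
    """Label a curve decay/growth by the slope over the first quarter of lags.

    Slope exactly zero (degenerate) classifies as decay.
    """
    quarter = max(2, acf.lags.size // 4)
    lags, values = acf.lags[:quarter], acf.values[:quarter]
    lc = lags - lags.mean()
    # direct covariance form: exactly zero slope for constant values
    slope = np.dot(lc, values - values.mean()) / np.dot(lc, lc)
    return "growth" if slope > 0 else "decay"


def classify_and_fit(trace: PixelTrace, params: AnalysisParams | None = None) -> ExpFit:
    """Compute the ACF, pick the single direction, and fit it.

    Decaying curves are fitted directly; growing curves get the mirrored
    (plateau-reflected) growth model, which yields the same decay constant.
    """
    params = params or AnalysisParams()
    acf = compute_acf(trace, max_lag_fraction=params.max_lag_fraction)
    direction = classify_direction(acf)
    return fit_acf(acf, direction=direction, params=params)


def analyze_stack(
    stack: FrameStack,
    roi: RingROI | None,
    geometry: DetectorGeometry | None,
    params: AnalysisParams | None = None,
    bin_size: int = 1,
    pixels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Trace, detrend, classify and fit every valid ROI pixel of a stack.

    The stack must already be masked/binned; ``bin_size`` only annotates the
    output coordinates.  Pixels can be given explicitly (``(n, 2)`` row/col
    array) instead of via ``roi`` + ``geometry``.  Rejected pixels stay in
    the table with ``accepted = False`` and the violated condition named;
    pixels whose (detrended) trace has non-positive mean are skipped with
    reason ``nonpositive-mean`` and never fitted.
    """
    params = params or AnalysisParams()
    if pixels is None:
        if roi is None or geometry is None:
            raise ValueError("need either explicit pixels or roi + geometry")
        pixels = select_ring_pixels(geometry, roi, stack.mask, bin_size=bin_size)
    rows: list[dict] = []
    n_skipped = 0
    if len(pixels):
        traces = stack.counts[:, pixels[:, 0], pixels[:, 1]].T.astype(float)
        traces = detrend_matrix(traces, policy=params.detrend_policy)
        lags, all_values = batch_acf(
            traces, stack.frame_interval, max_lag_fraction=params.max_lag_fraction
        )
        means = traces.mean(axis=1)
    if len(pixels):
        ok_rows = np.nonzero(means > 0)[0]
        n_skipped = int(len(pixels) - ok_rows.size)
        fits: dict[int, ExpFit] = {}
        if ok_rows.size:
            vals = all_values[ok_rows]
            quarter = max(2, lags.size // 4)
            lc = lags[:quarter] - lags[:quarter].mean()
            slopes = (vals[:, :quarter] - vals[:, :quarter].mean(axis=1, keepdims=True)) @ lc
            signs = np.where(slopes > 0, 1.0, -1.0)
            with np.errstate(all="ignore"):
                fitted, _, ok_flags = _lm_fit_batch(lags, vals, signs)
            for j, idx in enumerate(ok_rows):
                a, gamma, y0 = fitted[j]
                sign = signs[j]
                model = y0 - sign * a * np.exp(-gamma * lags)
                score = _residual_score(model - vals[j], params.residual_rule)
                fits[int(idx)] = _classify_acceptance(
                    a, gamma, y0, score, bool(ok_flags[j]), lags[0],
                    "decay" if sign < 0 else "growth", params,
                )
    for idx, (row, col) in enumerate(pixels):
        record = {"row": int(row), "col": int(col), "bin_size": bin_size}
        fit = fits.get(idx)
        if fit is None:
            record.update(
                direction="",
                A=np.nan,
                gamma=np.nan,
                y=np.nan,
                residual=np.nan,
                accepted=False,
                reason="nonpositive-mean",
            )
        else:
            record.update(
                direction=fit.direction,
                A=fit.A,
                gamma=fit.gamma,
                y=fit.y,
                residual=fit.residual,
                accepted=fit.accepted,
                reason=fit.reason,
            )
        rows.append(record)
    table = pd.DataFrame(
        rows,
        columns=[
            "row",
            "col",
            "bin_size",
            "direction",
            "A",
            "gamma",
            "y",
            "residual",
            "accepted",
            "reason",
        ],
    )
    if len(pixels) == 0:
        import warnings

        warnings.warn("empty ROI: no pixels analyzed", stacklevel=2)
    logger.info(
        "analyze_stack: %d pixels in, %d skipped (mean<=0), %d accepted",
        len(pixels),
        n_skipped,
        int(table["accepted"].sum()) if len(table) else 0,
    )
    return table
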