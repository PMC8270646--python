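"""Preprocessing ahead of the correlation analysis.

Binning sums non-overlapping b x b pixel blocks (raising signal-to-noise at
the cost of spatial resolution), the ring ROI restricts analysis to the
Debye-Scherrer annulus, detrending removes slow linear intensity drifts
that would otherwise masquerade as long-lag correlation, and frame
splitting supports observation-time robustness studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .stack_io import DetectorGeometry, FrameStack

__all__ = [
    "PixelTrace",
    "RingROI",
    "bin_pixels",
    "select_ring_pixels",
    "detrend_trace",
    "split_frames",
]


@dataclass
class PixelTrace:
    """One (possibly binned) pixel's intensity time series.

    ``row``/``col`` are coordinates on the binned grid; binned pixel (i, j)
    covers original rows ``[b*i, b*i + b)`` and cols ``[b*j, b*j + b)``.
    """

    intensities: np.ndarray
    row: int
    col: int
    bin_size: int = 1
    frame_interval: float = 0.05
    detrended: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size < 2:
            raise ValueError("trace must be 1-D with length >= 2")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("trace contains non-finite values")

    def __len__(self) -> int:
        return self.intensities.size


@dataclass(frozen=True)
class RingROI:
    """Annular region of interest around a powder ring, in scattering angle."""

    two_theta_center: float  # degrees
    two_theta_halfwidth: float  # degrees

    def __post_init__(self) -> None:
        if not 0.0 < self.two_theta_center < 90.0:
            raise ValueError("two_theta_center must be in (0, 90) degrees")
        if self.two_theta_halfwidth <= 0:
            raise ValueError("two_theta_halfwidth must be positive")


def bin_pixels(stack: FrameStack, b: int) -> FrameStack:
    """Sum non-overlapping ``b x b`` pixel blocks per frame (b in {1, 2, 3}).

    Trailing rows/cols that do not fill a block are dropped, never
    zero-padded (padding would bias the ACF normalization).  A binned pixel
    is valid only when all ``b**2`` constituent pixels are valid.
    """
    if b not in (1, 2, 3):
        raise ValueError(f"bin size must be 1, 2 or 3; got {b}")
    if b == 1:
        return stack
    n, rows, cols = stack.counts.shape
    br, bc = rows // b, cols // b
    trimmed = stack.counts[:, : br * b, : bc * b]
    binned = trimmed.reshape(n, br, b, bc, b).sum(axis=(2, 4))
    mask = stack.mask[: br * b, : bc * b].reshape(br, b, bc, b).all(axis=(1, 3))
    return FrameStack(
        binned,
        frame_interval=stack.frame_interval,
        exposure=stack.exposure,
        mask=mask,
    )


def select_ring_pixels(
    geometry: DetectorGeometry,
    roi: RingROI,
    mask: np.ndarray,
    bin_size: int = 1,
) -> np.ndarray:
    """Binned pixels whose center lies inside the Debye-Scherrer annulus.

    Flat-detector small-solid-angle mapping: ring radius r = L * tan(2theta)
    in pixel units.  Masked (invalid) binned pixels are excluded.  Returns
    an ``(n, 2)`` array of (row, col) coordinates on the binned grid;
    empty when the ROI misses the detector entirely (warning, not error).
    """
    if bin_size not in (1, 2, 3):
        raise ValueError(f"bin size must be 1, 2 or 3; got {bin_size}")
    rows, cols = mask.shape
    r_lo = geometry.ring_radius_px(max(roi.two_theta_center - roi.two_theta_halfwidth, 1e-9))
    r_hi = geometry.ring_radius_px(roi.two_theta_center + roi.two_theta_halfwidth)
    # binned-pixel centers in original pixel units
    i = np.arange(rows)
    j = np.arange(cols)
    rc = bin_size * i + (bin_size - 1) / 2.0
    cc = bin_size * j + (bin_size - 1) / 2.0
    dr = rc[:, None] - geometry.beam_center[0]
    dc = cc[None, :] - geometry.beam_center[1]
    radius = np.hypot(dr, dc)
    inside = (radius >= r_lo) & (radius <= r_hi) & mask
    sel = np.argwhere(inside)
    if sel.size == 0:
        import warnings

        warnings.warn("ring ROI selected no pixels on the detector", stacklevel=2)
    return sel


def detrend_trace(trace: PixelTrace, policy: str = "auto") -> PixelTrace:
    """Remove a fitted linear trend, preserving the trace mean.

    The OLS line is subtracted and the original mean added back, so the
    normalization of the intensity autocorrelation stays meaningful.  Under
    ``auto`` the trend is removed only when the slope differs from zero at
    the 5% level, using a slope t-test whose variance is inflated by the
    effective-sample-size factor 1 + 2 sum_k rho_k (rho_k: residual
    autocorrelations, truncated at the first nonpositive lag): blinking
    traces are strongly autocorrelated, and the naive iid t-test would flag
    most of them as "trending" and strip genuine low-frequency dynamics
    that the correlation analysis needs.  Trend removal is
    applied "when a trend is present" without a published criterion, so the
    test form and threshold are this package's choice.
    """
    if policy not in ("always", "auto", "never"):
        raise ValueError(f"unknown detrend policy {policy!r}")
    if policy == "never":
        return trace
    y = trace.intensities
    if y.size < 3:
        return trace
    if np.ptp(y) == 0:  # constant trace: slope 0, nothing to remove
        return replace(trace, detrended=False)
    t = np.arange(y.size, dtype=float)
    res = stats.linregress(t, y)
    if policy == "auto" and _slope_pvalue_autocorr(y, t, res.slope) >= 0.05:
        return trace
    fitted = res.intercept + res.slope * t
    out = y - fitted + y.mean()
    return replace(trace, intensities=out, detrended=True)


def _variance_inflation(resid: np.ndarray) -> np.ndarray:
    """Effective-sample-size variance inflation 1 + 2 sum_k rho_k per row.

    ``resid`` is ``(n_rows, n)``; rho_k are residual autocorrelations,
    summed up to the first nonpositive value (truncated-sum rule), capped
    at n // 4 lags.  Inflation is 1 for white residuals and large for
    blinking traces, whose correlation times span many frames.
    """
    n = resid.shape[1]
    max_k = max(1, min(n // 4, 200))
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(resid, nfft, axis=1)
    acov = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, : max_k + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = acov[:, 1:] / acov[:, :1]
    rho = np.nan_to_num(rho, nan=0.0)
    # zero out everything from the first nonpositive autocorrelation on
    alive = np.cumprod(rho > 0, axis=1).astype(bool)
    return 1.0 + 2.0 * np.where(alive, rho, 0.0).sum(axis=1)


def _slope_pvalue_autocorr(y: np.ndarray, t: np.ndarray, slope: float) -> float:
    """Two-sided slope p-value with effective-sample-size correction."""
    n = y.size
    tc = t - t.mean()
    sxx = float(np.dot(tc, tc))
    resid = y - y.mean() - slope * tc
    rss = float(np.dot(resid, resid))
    if rss == 0:
        return 0.0
    inflation = float(_variance_inflation(resid[None, :])[0])
    se = np.sqrt(rss / (n - 2) / sxx) * np.sqrt(inflation)
    return float(2.0 * stats.t.sf(abs(slope) / se, n - 2))


def detrend_matrix(traces: np.ndarray, policy: str = "auto") -> np.ndarray:
    """Vectorized :func:`detrend_trace` over rows of ``(n_pixels, n_frames)``.

    Matches the per-trace semantics: OLS line removed with the mean added
    back; under ``auto`` only rows whose slope is significant at the 5%
    level under the AR(1)-corrected t-test are touched; constant rows pass
    through.
    """
    if policy not in ("always", "auto", "never"):
        raise ValueError(f"unknown detrend policy {policy!r}")
    traces = np.asarray(traces, dtype=float)
    if policy == "never" or traces.shape[1] < 3:
        return traces
    n = traces.shape[1]
    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    sxx = float(np.dot(tc, tc))
    means = traces.mean(axis=1)
    slope = (traces @ tc) / sxx
    if policy == "auto":
        resid = traces - means[:, None] - slope[:, None] * tc[None, :]
        rss = np.sum(resid**2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inflation = _variance_inflation(resid)
            se = np.sqrt(rss / (n - 2) / sxx) * np.sqrt(inflation)
            tstat = np.where(se > 0, np.abs(slope) / se, 0.0)
        pval = 2.0 * stats.t.sf(tstat, n - 2)
        # rss == 0 with a nonzero spread is an exact line: always remove
        apply = ((pval < 0.05) | (rss == 0)) & (np.ptp(traces, axis=1) > 0)
    else:
        apply = np.ptp(traces, axis=1) > 0
    out = traces.copy()
    out[apply] -= slope[apply, None] * tc[None, :]
    return out


def split_frames(stack: FrameStack, k: int) -> list[FrameStack]:
    """Split into k contiguous equal-length substacks (tail remainder dropped)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > stack.n_frames:
        raise ValueError(f"cannot split {stack.n_frames} frames into {k} parts")
    length = stack.n_frames // k
    return [
        FrameStack(
            stack.counts[i * length : (i + 1) * length],
            frame_interval=stack.frame_interval,
            exposure=stack.exposure,
            mask=stack.mask,
        )
        for i in range(k)
    ]
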