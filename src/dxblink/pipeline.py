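"""End-to-end orchestration: mask -> bin -> ROI -> ACF -> fits -> ensemble -> D_R."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .blinking_acf import analyze_stack
from .config import RunConfig
from .dynamics import bragg_d, pixel_subtense_estimate, rotational_diffusion_coefficient
from .ensemble_stats import MIN_HISTOGRAM_FIT, DecayEnsemble, rank_sum_test, summarize
from .preprocess import bin_pixels, select_ring_pixels
from .stack_io import FrameStack

logger = logging.getLogger(__name__)

__all__ = ["run_analysis", "compare_ensembles"]


def run_analysis(
    stack: FrameStack,
    config: RunConfig,
    condition: str = "",
) -> tuple[pd.DataFrame, dict]:
    """Run the full per-pixel analysis and assemble the ensemble summary.

    Returns the per-pixel fit table and a JSON-ready summary dict with the
    ensemble statistics and, when the configuration provides ``phi_theta``,
    the rotational diffusion coefficient.
    """
    b = config.bin_size
    binned = bin_pixels(stack, b)
    logger.info("pipeline: %d frames, frame %s -> binned %s (b=%d)",
                stack.n_frames, stack.frame_shape, binned.frame_shape, b)
    if config.roi is not None:
        pixels = select_ring_pixels(config.geometry, config.roi, binned.mask, bin_size=b)
    else:
        pixels = np.argwhere(binned.mask)
    logger.info("pipeline: %d ROI pixels enter analysis", len(pixels))
    table = analyze_stack(binned, None, None, params=config.analysis, bin_size=b, pixels=pixels)
    ensemble = DecayEnsemble.from_table(table, condition=condition)
    summary: dict = {
        "condition": condition,
        "bin_size": b,
        "n_frames": stack.n_frames,
        "n_pixels_roi": int(len(pixels)),
        "n_accepted": len(ensemble),
        "n_rejected": int(ensemble.n_rejected),
    }
    if len(ensemble):
        summary.update(summarize(ensemble, lorentz=len(ensemble) >= MIN_HISTOGRAM_FIT))
    if config.roi is not None:
        two_theta = config.roi.two_theta_center
        d = bragg_d(two_theta, config.geometry.wavelength)
        summary["two_theta_deg"] = two_theta
        summary["d_space_angstrom"] = d
        summary["phi_theta_pixel_subtense_pm_diagnostic"] = pixel_subtense_estimate(
            d, config.geometry, bin_size=b
        )
    if config.phi_theta is not None and len(ensemble):
        summary["phi_theta_pm"] = config.phi_theta
        summary["d_r_pm2_per_s"] = rotational_diffusion_coefficient(
            summary["median_gamma"], config.phi_theta
        )
    return table, summary


def compare_ensembles(summaries: list[dict], ensembles: list[DecayEnsemble]) -> pd.DataFrame:
    """Pairwise rank-sum comparisons between conditions (raw p-values)."""
    if len(ensembles) < 2:
        raise ValueError("need at least two ensembles to compare")
    rows = []
    for i in range(len(ensembles)):
        for j in range(i + 1, len(ensembles)):
            res = rank_sum_test(ensembles[i], ensembles[j])
            rows.append(
                {
                    "condition_a": ensembles[i].condition or f"#{i}",
                    "condition_b": ensembles[j].condition or f"#{j}",
                    "median_a": float(np.median(ensembles[i].gammas)),
                    "median_b": float(np.median(ensembles[j].gammas)),
                    **res,
                }
            )
    return pd.DataFrame(rows)
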