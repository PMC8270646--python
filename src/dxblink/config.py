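"""Run configuration: one YAML file describing geometry, timing, and analysis.

Frame timing always comes from here, never from image metadata.  The same
file drives simulation, analysis, and comparison runs, and every run echoes
its fully-resolved configuration to the output directory so stochastic
outputs can be reproduced bit-identically from the recorded seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .blinking_acf import AnalysisParams
from .preprocess import RingROI
from .simulate import AngularConfig, RingGeometry, SimulationConfig
from .stack_io import DetectorGeometry


@dataclass
class RunConfig:
    """Everything one simulate/analyze run needs, resolved and validated."""

    geometry: DetectorGeometry
    frame_interval: float = 0.05
    exposure: float = 0.042
    bin_size: int = 1
    roi: RingROI | None = None
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    phi_theta: float | None = None  # pm; required for D_R reporting
    simulation: SimulationConfig | None = None
    ring: RingGeometry | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _require(block: dict, key: str, where: str):
    if key not in block:
        raise KeyError(f"configuration missing required key '{where}.{key}'")
    return block[key]


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    geo = _require(raw, "geometry", "")
    geometry = DetectorGeometry(
        wavelength=float(_require(geo, "wavelength", "geometry")),
        distance=float(_require(geo, "distance", "geometry")),
        pixel_pitch=float(_require(geo, "pixel_pitch", "geometry")),
        beam_center=tuple(_require(geo, "beam_center", "geometry")),
    )
    timing = raw.get("timing", {})
    analysis = raw.get("analysis", {})
    roi = None
    if "roi" in analysis:
        roi = RingROI(
            two_theta_center=float(analysis["roi"]["two_theta_center"]),
            two_theta_halfwidth=float(analysis["roi"]["two_theta_halfwidth"]),
        )
    params = AnalysisParams(
        max_lag_fraction=float(analysis.get("max_lag_fraction", 0.25)),
        detrend_policy=str(analysis.get("detrend_policy", "auto")),
        residual_rule=str(analysis.get("residual_rule", "sum")),
        residual_threshold=float(analysis.get("residual_threshold", 1.0)),
    )
    physics = raw.get("physics", {})
    sim = None
    ring = None
    if "simulation" in raw:
        s = raw["simulation"]
        angular = AngularConfig(**s.get("angular", {}))
        sim = SimulationConfig(
            n_spots=int(s.get("n_spots", 200)),
            k_on=float(s.get("k_on", 0.3)),
            k_off=float(s.get("k_off", 0.3)),
            on_intensity=float(s.get("on_intensity", 180.0)),
            background=float(s.get("background", 2.0)),
            psf_size=int(s.get("psf_size", 3)),
            n_frames=int(s.get("n_frames", 2000)),
            frame_interval=float(timing.get("frame_interval", 0.05)),
            drift_slope=float(s.get("drift_slope", 0.0)),
            seed=int(raw.get("seed", 0)),
            mode=str(s.get("mode", "telegraph")),
            angular=angular,
        )
        r = s.get("ring", {})
        ring = RingGeometry(
            shape=tuple(r.get("shape", (200, 200))),
            center=tuple(r.get("center", (100.0, 100.0))),
            radius=float(r.get("radius", 75.0)),
            halfwidth=float(r.get("halfwidth", 4.0)),
        )
    return RunConfig(
        geometry=geometry,
        frame_interval=float(timing.get("frame_interval", 0.05)),
        exposure=float(timing.get("exposure", 0.042)),
        bin_size=int(analysis.get("bin_size", 1)),
        roi=roi,
        analysis=params,
        phi_theta=(float(physics["phi_theta"]) if "phi_theta" in physics else None),
        simulation=sim,
        ring=ring,
        seed=int(raw.get("seed", 0)),
    )


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Echo the fully-resolved configuration (reproducibility record)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
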