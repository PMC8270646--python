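"""Synthetic blinking-diffraction movies with known ground-truth kinetics.

Diffraction spots from individual crystallites sit on a Debye-Scherrer ring
and appear/disappear as the crystallites rotate in and out of the Bragg
condition.  Two state models are provided:

* ``telegraph`` — each spot is an independent two-state (on/off) Markov
  process with entry rate ``k_on`` and exit rate ``k_off``.  Its state
  autocovariance decays as ``exp(-(k_on + k_off) * tau)``, which is the
  ground truth the analysis stages must recover.
* ``angular_diffusion`` — each spot's crystallite orientation performs a
  reflected Brownian walk; the spot is "on" while the orientation sits
  inside the angular acceptance window of the Bragg condition.

Rendered movies place each spot as a small (default 3x3 pixel) footprint on
an annulus, add uniform background, optional linear intensity drift, and
per-pixel Poisson photon noise.  Counts represent the full frame interval;
detector dead time between exposures only rescales intensities and the
normalized autocorrelation is scale-invariant, so it is deliberately not
modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack_io import FrameStack

__all__ = [
    "SimulationConfig",
    "RingGeometry",
    "simulate_telegraph_states",
    "simulate_angular_diffusion_states",
    "expected_normalized_acf",
    "place_spots",
    "render_movie",
    "simulate_movie",
]


@dataclass(frozen=True)
class RingGeometry:
    """Annulus on which simulated diffraction spots live, in pixel units."""

    shape: tuple[int, int] = (220, 220)
    center: tuple[float, float] = (110.0, 110.0)
    radius: float = 102.0
    halfwidth: float = 0.5

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.halfwidth <= 0:
            raise ValueError("radius and halfwidth must be positive")


@dataclass(frozen=True)
class AngularConfig:
    """Parameters of the angular-diffusion state model."""

    diffusion: float = 0.01  # orientational diffusion coefficient, rad^2/s
    halfwidth: float = 0.1  # Bragg acceptance half-width, rad
    angle_range: float = 0.5  # reflecting walls at +/- angle_range, rad


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic blinking movie.

    Defaults emulate the laboratory measurement conditions: 2000 frames at a
    50 ms frame interval, ~3x3-pixel spots on a Debye-Scherrer ring, and
    photon-counting statistics.  The spot flux / background ratio is chosen
    so a single-spot pixel's blinking contrast Var[I]/E[I]^2 is about 0.1,
    the amplitude scale of measured single-pixel ACF exemplars (laboratory
    sources leave substantial diffuse background under the ring).
    """

    n_spots: int = 200
    k_on: float = 0.3  # spot entry rate, 1/s
    k_off: float = 0.3  # spot exit rate, 1/s
    on_intensity: float = 90.0  # expected photons/frame per spot while on
    background: float = 10.0  # expected photons/frame per pixel
    psf_size: int = 3  # odd; spot footprint edge, pixels
    n_frames: int = 2000
    frame_interval: float = 0.05  # s
    drift_slope: float = 0.0  # counts/frame added at spot pixels
    seed: int = 0
    mode: str = "telegraph"  # "telegraph" | "angular_diffusion"
    placement: str = "grid"  # "grid" | "rejection"
    angular: AngularConfig = field(default_factory=AngularConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("telegraph", "angular_diffusion"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rates must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.psf_size < 1 or self.psf_size % 2 == 0:
            raise ValueError("psf_size must be odd and >= 1")
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def rate_sum(self) -> float:
        """k_on + k_off: the decay rate of the state autocovariance."""
        return self.k_on + self.k_off


def simulate_telegraph_states(
    k_on: float,
    k_off: float,
    n_frames: int,
    frame_interval: float,
    n_spots: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Sample stationary two-state telegraph trajectories at the frame times.

    Uses the exact master-equation propagator over one frame interval, so
    transition statistics are unbiased at any interval length (no small-dt
    approximation).  The initial state is drawn from the stationary
    distribution ``p_on = k_on / (k_on + k_off)``.

    Returns
    -------
    ndarray of shape ``(n_spots, n_frames)``, dtype int8, values 0/1.
    """
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rates must be positive")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    rate = k_on + k_off
    p_on = k_on / rate
    decay = np.exp(-rate * frame_interval)
    # Exact one-interval propagator:
    #   P(on  | on)  = p_on + (1 - p_on) * decay
    #   P(on  | off) = p_on * (1 - decay)
    p_on_given_on = p_on + (1.0 - p_on) * decay
    p_on_given_off = p_on * (1.0 - decay)

    u = rng.random((n_spots, n_frames))
    states = np.empty((n_spots, n_frames), dtype=np.int8)
    states[:, 0] = u[:, 0] < p_on
    for t in range(1, n_frames):
        prev_on = states[:, t - 1] == 1
        thresh = np.where(prev_on, p_on_given_on, p_on_given_off)
        states[:, t] = u[:, t] < thresh
    return states


def simulate_angular_diffusion_states(
    diffusion: float,
    halfwidth: float,
    n_frames: int,
    frame_interval: float,
    n_spots: int,
    seed: int | np.random.Generator,
    angle_range: float = 0.5,
) -> np.ndarray:
    """Binary on/off states from reflected orientational Brownian motion.

    Each spot's orientation angle performs a Brownian walk with reflecting
    walls at ``+/- angle_range`` (keeping the stationary density uniform);
    the spot diffracts while ``|angle| < halfwidth``.  Initial angles are
    uniform over the full range, so the stationary on-fraction is
    ``halfwidth / angle_range`` (clipped at 1).
    """
    if diffusion <= 0 or halfwidth <= 0 or angle_range <= 0:
        raise ValueError("diffusion, halfwidth and angle_range must be positive")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    step_sd = np.sqrt(2.0 * diffusion * frame_interval)
    angles = rng.uniform(-angle_range, angle_range, size=n_spots)
    states = np.empty((n_spots, n_frames), dtype=np.int8)
    states[:, 0] = np.abs(angles) < halfwidth
    for t in range(1, n_frames):
        angles = angles + rng.normal(0.0, step_sd, size=n_spots)
        # fold into [-range, range] by reflection
        angles = np.mod(angles + angle_range, 4.0 * angle_range)
        angles = np.where(angles > 2.0 * angle_range, 4.0 * angle_range - angles, angles)
        angles = angles - angle_range
        states[:, t] = np.abs(angles) < halfwidth
    return states


def expected_normalized_acf(
    k_on: float,
    k_off: float,
    on_intensity: float,
    background: float,
    tau: float | np.ndarray,
) -> float | np.ndarray:
    """Closed-form normalized intensity autocorrelation of a single-spot pixel.

    For intensity ``I = on_intensity * S + background`` with ``S`` a
    stationary telegraph state,

        ACF(tau) = 1 + (Var[I] / E[I]^2) * exp(-(k_on + k_off) * tau).

    This is the independent oracle the estimator is validated against.
    """
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rates must be positive")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    p = k_on / (k_on + k_off)
    mean = on_intensity * p + background
    if mean == 0:
        raise ZeroDivisionError("E[I] = 0: normalized ACF undefined")
    var = on_intensity**2 * p * (1.0 - p)
    out = 1.0 + (var / mean**2) * np.exp(-(k_on + k_off) * tau)
    return float(out) if out.ndim == 0 else out


def place_spots_grid(
    ring: RingGeometry,
    n_spots: int,
    psf_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Place spots at jittered, evenly spaced angles along the ring.

    Dense ring coverage (what measured Debye-Scherrer images show) is not
    reachable by random sequential placement, which jams well below full
    coverage; an angular grid with random angular and radial jitter is
    deterministically feasible at any density up to one spot per psf arc.
    Continuous-coordinate center separation stays >= psf_size; after
    rounding to the pixel grid, near-tangent neighbors may touch at a
    corner pixel, which leaves the decay constant unaffected because
    co-located spots share the same kinetics.

    Returns integer ``(row, col)`` centers, shape ``(n_spots, 2)``.
    """
    if n_spots == 0:
        return np.empty((0, 2), dtype=int)
    r_min = ring.radius - ring.halfwidth
    arc = 2.0 * np.pi * r_min / n_spots
    if arc < psf_size:
        raise RuntimeError(
            f"cannot place {n_spots} spots with separation {psf_size} on a "
            f"ring of inner radius {r_min:.1f} (max {int(2 * np.pi * r_min / psf_size)})"
        )
    jitter_ang = 0.45 * (arc - psf_size) / ring.radius
    theta = 2.0 * np.pi * np.arange(n_spots) / n_spots + rng.uniform(
        -jitter_ang, jitter_ang, size=n_spots
    )
    theta += rng.uniform(0.0, 2.0 * np.pi)  # random global phase
    radius = ring.radius + rng.uniform(-ring.halfwidth, ring.halfwidth, size=n_spots)
    rows = np.round(ring.center[0] + radius * np.sin(theta)).astype(int)
    cols = np.round(ring.center[1] + radius * np.cos(theta)).astype(int)
    half = psf_size // 2
    if (
        rows.min() < half
        or cols.min() < half
        or rows.max() >= ring.shape[0] - half
        or cols.max() >= ring.shape[1] - half
    ):
        raise RuntimeError("ring does not fit the detector with the psf margin")
    return np.column_stack([rows, cols])


def place_spots(
    ring: RingGeometry,
    n_spots: int,
    psf_size: int,
    rng: np.random.Generator,
    max_tries: int = 200_000,
) -> np.ndarray:
    """Rejection-sample spot centers on the annulus, min separation psf_size.

    The separation keeps every pixel's trace single-spot.  Returns integer
    ``(row, col)`` centers, shape ``(n_spots, 2)``.  Jams well below full
    ring coverage; :func:`place_spots_grid` reaches realistic densities.
    """
    half = psf_size // 2
    centers: list[tuple[int, int]] = []
    placed = np.empty((0, 2))
    tries = 0
    while len(centers) < n_spots:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_spots} spots with separation {psf_size} "
                f"on the ring (placed {len(centers)})"
            )
        theta = rng.uniform(0.0, 2.0 * np.pi)
        r = ring.radius + rng.uniform(-ring.halfwidth, ring.halfwidth)
        row = int(round(ring.center[0] + r * np.sin(theta)))
        col = int(round(ring.center[1] + r * np.cos(theta)))
        if not (half <= row < ring.shape[0] - half and half <= col < ring.shape[1] - half):
            continue
        if placed.size:
            d2 = (placed[:, 0] - row) ** 2 + (placed[:, 1] - col) ** 2
            if d2.min() < psf_size**2:
                continue
        centers.append((row, col))
        placed = np.asarray(centers, dtype=float)
    return np.asarray(centers, dtype=int)


def expected_frames(
    states: np.ndarray,
    spots: np.ndarray,
    config: SimulationConfig,
    shape: tuple[int, int],
) -> np.ndarray:
    """Noise-free expectation images: background + spot flux + drift.

    Each on spot spreads ``on_intensity`` uniformly over its
    ``psf_size x psf_size`` footprint; ``drift_slope * frame_index`` is added
    at spot pixels (drift emulates slow source/alignment trends on the
    diffracting regions).
    """
    n_frames = states.shape[1]
    half = config.psf_size // 2
    per_pixel = config.on_intensity / config.psf_size**2
    expect = np.full((n_frames, *shape), float(config.background))
    drift = config.drift_slope * np.arange(n_frames)
    for s, (row, col) in enumerate(spots):
        sl = np.s_[:, row - half : row + half + 1, col - half : col + half + 1]
        expect[sl] += (states[s] * per_pixel + drift)[:, None, None]
    return expect


def render_movie(
    states: np.ndarray,
    ring: RingGeometry,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[FrameStack, pd.DataFrame]:
    """Render binary spot states into a Poisson-noisy photon-count movie.

    Returns the movie as a :class:`FrameStack` plus a ground-truth table
    (one row per spot: center coordinates and rate parameters).
    """
    if states.shape[0] != config.n_spots:
        raise ValueError("states row count != n_spots")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    placer = place_spots_grid if config.placement == "grid" else place_spots
    spots = placer(ring, config.n_spots, config.psf_size, rng)
    n_frames = states.shape[1] if states.size else config.n_frames
    # Poisson additivity: background and spot photons drawn independently
    # and summed is exactly Poisson(background + spot expectation).
    if config.background > 0:
        counts = rng.poisson(config.background, size=(n_frames, *ring.shape))
    else:
        counts = np.zeros((n_frames, *ring.shape), dtype=np.int64)
    half = config.psf_size // 2
    per_pixel = config.on_intensity / config.psf_size**2
    drift = config.drift_slope * np.arange(n_frames)
    for s, (row, col) in enumerate(spots):
        lam = np.clip(states[s] * per_pixel + drift, 0.0, None)
        extra = rng.poisson(lam[:, None, None], size=(n_frames, config.psf_size, config.psf_size))
        counts[:, row - half : row + half + 1, col - half : col + half + 1] += extra
    counts = counts.astype(np.uint32)
    stack = FrameStack(
        counts,
        frame_interval=config.frame_interval,
        exposure=min(0.042, config.frame_interval),
    )
    truth = pd.DataFrame(
        {
            "spot": np.arange(config.n_spots),
            "row": spots[:, 0] if len(spots) else np.array([], dtype=int),
            "col": spots[:, 1] if len(spots) else np.array([], dtype=int),
            "k_on": config.k_on,
            "k_off": config.k_off,
            "rate_sum": config.rate_sum,
            "on_intensity": config.on_intensity,
            "mode": config.mode,
        }
    )
    return stack, truth


def simulate_movie(
    config: SimulationConfig,
    ring: RingGeometry | None = None,
) -> tuple[FrameStack, pd.DataFrame]:
    """Generate states and render the movie in one deterministic step.

    All randomness flows from ``config.seed`` through named substreams
    (states vs rendering), so identical configs give bit-identical movies.
    """
    ring = ring or RingGeometry()
    state_ss, render_ss = np.random.SeedSequence(config.seed).spawn(2)
    if config.mode == "telegraph":
        states = simulate_telegraph_states(
            config.k_on,
            config.k_off,
            config.n_frames,
            config.frame_interval,
            config.n_spots,
            np.random.default_rng(state_ss),
        )
    else:
        states = simulate_angular_diffusion_states(
            config.angular.diffusion,
            config.angular.halfwidth,
            config.n_frames,
            config.frame_interval,
            config.n_spots,
            np.random.default_rng(state_ss),
            angle_range=config.angular.angle_range,
        )
    return render_movie(states, ring, config, rng=np.random.default_rng(render_ss))
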