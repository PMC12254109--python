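"""Synthetic scenario generator closing the inference loop.

Generates macrophage-like nuclei tracks in a pupal-wing-scale field of
view for each modelled scenario: a control wound (full ring of attractant
sources), a knockdown wound (geometry present, sources silent), a half
wound (semicircular source arc), and two competing wounds (both active, or
one silenced). Tracks follow the biased-persistent random walk whose local
observed bias w*b equals, by construction, the production-diffusion
model's predicted bias at the cell's position and time — the property the
two-stage inference assumes — so stage-1 and stage-2 recovery can be
tested without imaging data.

Defaults emulate the imaging: ~40 cells starting 50-250 um from the wound
centre, 25 min of tracking at 0.5-min frames (imaging started within 1 min
post-wounding, one frame every 30 s), wound radius 40 um.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from woundwalk.attractant import AttractantParams, predicted_bias
from woundwalk.brw import sample_wrapped_normal
from woundwalk.brw_infer import BinPosterior
from woundwalk.tracks import BinGrid, Track, WoundGeometry

# A realistic default parameter set for generated scenarios. D and tau are
# the values used for the half-wound model snapshots (200 um^2/min, 18 min);
# q sits mid-prior; R0 and kd are round mid-scale receptor values; m is set
# so the predicted bias peaks near ~0.3 just outside the exclusion zone,
# the magnitude binned track data shows near a fresh wound.
DEFAULT_TRUE_PARAMS = AttractantParams(
    q=1500.0, D=200.0, tau=18.0, m=2.5, R0=1000.0, kd=1000.0, b0=0.02, delta_r=15.0
)


def _default_wound() -> WoundGeometry:
    return WoundGeometry(center=(0.0, 0.0), radius=40.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of a synthetic experiment."""

    wounds: tuple[WoundGeometry, ...] = field(default_factory=lambda: (_default_wound(),))
    params: AttractantParams = DEFAULT_TRUE_PARAMS
    n_cells: int = 40
    duration: float = 25.0  # min
    frame_interval: float = 0.5  # min
    init_r_range: tuple[float, float] = (50.0, 250.0)  # annulus about first wound
    step_length: float = 2.0  # um per frame
    b_fixed: float = 0.95  # bias width of a biased step in generation
    p_fixed: float = 0.5  # persistence of a persistent step
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.duration <= 0 or self.frame_interval <= 0:
            raise ValueError("duration and frame_interval must be positive")
        if not 0 < self.b_fixed <= 1 or not 0 <= self.p_fixed <= 1:
            raise ValueError("b_fixed in (0,1], p_fixed in [0,1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1


def control_scenario(**kw) -> ScenarioConfig:
    """Single wild-type wound, full source ring."""
    return ScenarioConfig(**kw)


def knockdown_scenario(**kw) -> ScenarioConfig:
    """Single wound whose sources are silent: cells see only baseline bias."""
    kw.setdefault("wounds", (dataclasses.replace(_default_wound(), active=False),))
    return ScenarioConfig(**kw)


def half_wound_scenario(**kw) -> ScenarioConfig:
    """Sources on the anterior semicircle only (azimuth 0..pi)."""
    kw.setdefault(
        "wounds",
        (WoundGeometry(center=(0.0, 0.0), radius=40.0, source_arc=((0.0, math.pi),)),),
    )
    return ScenarioConfig(**kw)


def two_wound_scenario(separation: float = 300.0, kd_second: bool = False, **kw) -> ScenarioConfig:
    """Two equal wounds ``separation`` um apart; optionally one silenced."""
    half = separation / 2.0
    kw.setdefault(
        "wounds",
        (
            WoundGeometry(center=(-half, 0.0), radius=40.0),
            WoundGeometry(center=(half, 0.0), radius=40.0, active=not kd_second),
        ),
    )
    return ScenarioConfig(**kw)


def _sample_start(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Area-uniform draw in the annulus about the first wound's centre."""
    r_lo, r_hi = config.init_r_range
    cx, cy = config.wounds[0].center
    for _ in range(1000):
        r = math.sqrt(rng.uniform(r_lo**2, r_hi**2))
        phi = rng.uniform(-math.pi, math.pi)
        pos = np.array([cx + r * math.cos(phi), cy + r * math.sin(phi)])
        on_source = any(
            w.active and np.min(np.linalg.norm(w.source_positions() - pos, axis=1)) < 1e-6
            for w in config.wounds
        )
        if not on_source:
            return pos
    raise RuntimeError("could not place cell off the sources")


def generate_tracks(
    config: ScenarioConfig, rng: np.random.Generator | int | None = None
) -> tuple[list[Track], dict]:
    """Simulate tracks under the scenario; returns (tracks, ground truth).

    At each step the cell's local observed bias is read off the true
    attractant field (toward the nearest wound centre), converted to a
    mixture weight w = clip(bias / b_fixed, 0, 1), and the heading is
    drawn from the biased component (mean = bearing, width from b_fixed)
    with probability w, else from the persistent component (mean =
    previous heading, width from p_fixed). The first step substitutes a
    uniform heading for the undefined persistent component. By
    construction the walk's observed bias w * b_fixed equals the forward
    model's prediction wherever that prediction is within [0, b_fixed].
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    sigma_b = math.sqrt(-2.0 * math.log(config.b_fixed)) if config.b_fixed < 1 else 0.0
    sigma_p = (
        math.inf if config.p_fixed == 0 else math.sqrt(-2.0 * math.log(config.p_fixed))
    )
    wounds = list(config.wounds)
    any_active = any(w.active for w in wounds)
    n_steps = config.n_frames - 1
    tracks: list[Track] = []
    for c in range(config.n_cells):
        pos = _sample_start(config, rng)
        xs, ys = [pos[0]], [pos[1]]
        prev_heading: float | None = None
        for k in range(n_steps):
            t = k * config.frame_interval
            nearest = min(wounds, key=lambda w: float(np.hypot(*(pos - np.array(w.center)))))
            if any_active:
                ob = predicted_bias(pos, t, wounds, config.params, toward=nearest)
            else:
                ob = config.params.b0
            w_eff = min(max(ob / config.b_fixed, 0.0), 1.0)
            cxy = np.array(nearest.center)
            beta = math.atan2(cxy[1] - pos[1], cxy[0] - pos[0])
            if rng.random() < w_eff:
                heading = float(sample_wrapped_normal(beta, sigma_b, (), rng))
            elif prev_heading is None:
                heading = rng.uniform(-math.pi, math.pi)
            else:
                heading = float(sample_wrapped_normal(prev_heading, sigma_p, (), rng))
            pos = pos + config.step_length * np.array([math.cos(heading), math.sin(heading)])
            xs.append(pos[0])
            ys.append(pos[1])
            prev_heading = heading
        t_axis = config.frame_interval * np.arange(config.n_frames)
        tracks.append(Track(track_id=f"cell{c:03d}", t=t_axis, x=np.array(xs), y=np.array(ys)))
    truth = {
        "params": {k: getattr(config.params, k) for k in
                   ("q", "D", "tau", "m", "R0", "kd", "b0", "delta_r")},
        "b_fixed": config.b_fixed,
        "p_fixed": config.p_fixed,
        "n_cells": config.n_cells,
        "wounds": [
            {"center": list(w.center), "radius": w.radius, "active": w.active,
             "source_arc": [list(a) for a in w.source_arc]}
            for w in wounds
        ],
    }
    return tracks, truth


def generate_binned_bias(
    config: ScenarioConfig,
    grid: BinGrid,
    noise_sd: float = 0.005,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[BinPosterior], dict]:
    """Bin-level observed-bias summaries straight from the forward model.

    Bypasses track simulation and stage 1: each bin's mean is the model's
    predicted bias at the bin centre plus Gaussian noise of sd
    ``noise_sd``, and its sd is ``noise_sd``. This is the stage-2 test
    fixture: with noise_sd = 0 the means equal the forward model exactly.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    wounds = list(config.wounds)
    any_active = any(w.active for w in wounds)
    anchor = wounds[0]
    cx, cy = anchor.center
    bins: list[BinPosterior] = []
    r_centers = grid.spatial_centers()
    t_centers = grid.temporal_centers()
    for i in range(grid.n_temporal):
        for j in range(grid.n_spatial):
            pos = np.array([cx + r_centers[j], cy])
            if any_active:
                ob = predicted_bias(pos, float(t_centers[i]), wounds, config.params, toward=anchor)
            else:
                ob = config.params.b0
            mean = ob + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            bins.append(
                BinPosterior(
                    i_time=i,
                    j_space=j,
                    k_azimuth=None,
                    observed_bias_mean=float(mean),
                    observed_bias_sd=float(noise_sd),
                    observed_persistence_mean=float("nan"),
                    observed_persistence_sd=float("nan"),
                    n_steps=1,
                    flag="synthetic",
                )
            )
    truth = {
        "params": {k: getattr(config.params, k) for k in
                   ("q", "D", "tau", "m", "R0", "kd", "b0", "delta_r")},
        "noise_sd": noise_sd,
    }
    return bins, truth
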