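"""The biased-persistent random walk (BRW) model of cell motion.

Cells are non-interacting particles in 2D. The heading gamma_t of each step
is a circular random variable: with probability w the step is *biased*
(heading centred on beta, the direction to the wound) and with probability
1 - w it is *persistent* (heading centred on the previous heading). Both
components are wrapped normal densities whose widths derive from the bias
and persistence parameters b, p in [0, 1]:

    sigma_b^2 = -2 log b,    sigma_p^2 = -2 log p,

so b = 1 gives perfectly aimed steps (sigma_b = 0) and b = 0 the uniform
circle (sigma_b -> inf). The product w*b is the "observed bias" and
(1 - w)*p the "observed persistence" — the quantities stage-1 inference
summarises per bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from woundwalk.tracks import Track, WoundGeometry, wrap_angle

TWO_PI = 2.0 * math.pi
UNIFORM_DENSITY = 1.0 / TWO_PI
# Beyond this width the wrapped normal is uniform to < 1e-9.
SIGMA_UNIFORM_CUTOFF = 6.0


@dataclass(frozen=True)
class BRWParams:
    """Walk parameters w (mixture weight), b (bias), p (persistence)."""

    w: float
    b: float
    p: float

    def __post_init__(self):
        for name in ("w", "b", "p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def sigma_b(self) -> float:
        return math.inf if self.b == 0.0 else math.sqrt(-2.0 * math.log(self.b))

    @property
    def sigma_p(self) -> float:
        return math.inf if self.p == 0.0 else math.sqrt(-2.0 * math.log(self.p))

    @property
    def observed_bias(self) -> float:
        return self.w * self.b

    @property
    def observed_persistence(self) -> float:
        return (1.0 - self.w) * self.p


def _wrap_terms(sigma: float) -> int:
    # K wraps cover ~2*pi*(K+0.5)/sigma standard deviations; K = ceil(sigma)
    # keeps the missed tail mass below 1e-9 for all sigma up to the uniform
    # cutoff
    return max(3, math.ceil(sigma))


def wrapped_normal_pdf(gamma, mu, sigma: float):
    """Density of the wrapped normal N_w(gamma | mu, sigma) on (-pi, pi].

    Computed as a truncated sum over wraps, with enough terms that the
    truncation error is negligible; for sigma above ~6 the density is
    uniform to better than 1e-9 and 1/(2 pi) is returned. sigma = 0 is a
    point mass at mu: density evaluation is refused (sample instead).
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0.0:
        raise ValueError("sigma=0 is a point mass; evaluate by sampling, not density")
    gamma = np.asarray(gamma, dtype=float)
    if not math.isfinite(sigma) or sigma > SIGMA_UNIFORM_CUTOFF:
        out = np.full_like(gamma, UNIFORM_DENSITY)
        return out if out.ndim else float(out)
    delta = wrap_angle(gamma - mu)
    k = _wrap_terms(sigma)
    i = np.arange(-k, k + 1)
    z = (np.expand_dims(delta, -1) + TWO_PI * i) / sigma
    dens = np.exp(-0.5 * z * z).sum(axis=-1) / (sigma * math.sqrt(TWO_PI))
    return dens if dens.ndim else float(dens)


def sample_wrapped_normal(mu: float, sigma: float, size, rng: np.random.Generator):
    """Draw wrapped-normal headings; sigma=0 returns mu, sigma=inf uniform."""
    if sigma == 0.0:
        return np.full(size, wrap_angle(mu))
    if not math.isfinite(sigma) or sigma > SIGMA_UNIFORM_CUTOFF:
        return rng.uniform(-math.pi, math.pi, size)
    return wrap_angle(rng.normal(mu, sigma, size))


def step_density(gamma_t, gamma_prev, beta, params: BRWParams):
    """Mixture density of one step's heading.

    w * N_w(gamma_t | beta, sigma_b) + (1-w) * N_w(gamma_t | gamma_prev, sigma_p).
    b = 0 or p = 0 send that component to the uniform circle, keeping the
    density positive everywhere so likelihoods stay finite on the closed
    parameter cube.
    """
    gamma_t = np.asarray(gamma_t, dtype=float)
    gamma_prev = np.asarray(gamma_prev, dtype=float)
    beta = np.asarray(beta, dtype=float)
    w = params.w

    def component(mu, sigma):
        if sigma == 0.0:
            raise ValueError(
                "deterministic component (b=1 or p=1) has no density; use sampling"
            )
        if not math.isfinite(sigma) or sigma > SIGMA_UNIFORM_CUTOFF:
            return np.broadcast_to(UNIFORM_DENSITY, gamma_t.shape).astype(float)
        delta = wrap_angle(gamma_t - mu)
        k = _wrap_terms(sigma)
        i = np.arange(-k, k + 1)
        z = (np.expand_dims(delta, -1) + TWO_PI * i) / sigma
        return np.exp(-0.5 * z * z).sum(axis=-1) / (sigma * math.sqrt(TWO_PI))

    if w == 1.0:
        dens = component(beta, params.sigma_b)
    elif w == 0.0:
        dens = component(gamma_prev, params.sigma_p)
    else:
        dens = w * component(beta, params.sigma_b) + (1.0 - w) * component(
            gamma_prev, params.sigma_p
        )
    return dens if dens.ndim else float(dens)


def simulate_track(
    start: tuple[float, float],
    wound: WoundGeometry,
    params: BRWParams,
    n_steps: int,
    step_length: float = 2.0,
    frame_interval: float = 0.5,
    rng: np.random.Generator | int | None = None,
    track_id: str = "sim",
    t0: float = 0.0,
) -> Track:
    """Simulate one BRW track with fixed per-parameter walk statistics.

    Each step flips a w-coin: heads draws the heading from the biased
    component (mean = current direction to the wound centre), tails from
    the persistent component (mean = previous heading). The first step is
    drawn from the biased component, there being no previous heading.
    Step length is constant; the default 2 um per 0.5-min frame matches
    typical macrophage speeds of ~4 um/min.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if step_length <= 0:
        raise ValueError("step_length must be positive")
    rng = np.random.default_rng(rng)
    cx, cy = wound.center
    x, y = float(start[0]), float(start[1])
    if x == cx and y == cy:
        raise ValueError("start coincides with wound centre; bearing undefined")
    xs, ys = [x], [y]
    prev_heading: float | None = None
    for k in range(n_steps):
        beta = math.atan2(cy - y, cx - x)
        biased = True if prev_heading is None else (rng.random() < params.w)
        if biased:
            heading = float(sample_wrapped_normal(beta, params.sigma_b, (), rng))
        else:
            heading = float(sample_wrapped_normal(prev_heading, params.sigma_p, (), rng))
        x += step_length * math.cos(heading)
        y += step_length * math.sin(heading)
        xs.append(x)
        ys.append(y)
        prev_heading = heading
    t = t0 + frame_interval * np.arange(n_steps + 1)
    return Track(track_id=track_id, t=t, x=np.array(xs), y=np.array(ys))
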