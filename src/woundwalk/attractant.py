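"""Chemoattractant production-diffusion-sensing forward model.

Attractant is released at a constant total rate q from point sources on the
wound edge, starting at wounding (t = 0) and stopping at t = tau, and
spreads by 2D diffusion with diffusivity D. For a single point source the
concentration is the time integral of the 2D diffusion Green's function,

    A(r, t) = int_0^min(tau, t) q / (4 pi D (t - t')) exp(-r^2 / (4 D (t - t'))) dt',

which evaluates in closed form via the exponential integral Ei:

    A(r, t) = -(q / 4 pi D) Ei(-r^2 / 4 D t)                      for t < tau
    A(r, t) =  (q / 4 pi D) [Ei(-r^2 / 4 D (t - tau)) - Ei(-r^2 / 4 D t)]  for t >= tau.

Cells read the field through receptors: the steady-state bound-receptor
(complex) concentration C solves (R0 - C)(A - C) = kd C, and the walk's
observed bias is a linear readout of the front-rear complex difference
across the cell body,

    bias(r, t) = m [C(r - dr, t) - C(r + dr, t)] + b0,

with dr the cell's sensing half-length. Concentration units are arbitrary
throughout; only D (um^2/min) and tau (min) carry absolute units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expi

from woundwalk.tracks import WoundGeometry

FOUR_PI = 4.0 * math.pi
_SOURCE_EPS = 1e-9  # um; closer than this to a source counts as "on" it


@dataclass(frozen=True)
class AttractantParams:
    """Production-diffusion-sensing parameters.

    q: total production rate per wound (a.u./min), split over its sources.
    D: diffusivity (um^2/min). tau: production duration (min).
    m: bias scaling (per a.u. of complex). R0: total receptor concentration
    (a.u.). kd: dissociation constant (a.u.). b0: baseline observed bias.
    delta_r: sensing half-length (um), half the cell diameter; fixed, not
    inferred.
    """

    q: float
    D: float
    tau: float
    m: float
    R0: float
    kd: float
    b0: float
    delta_r: float = 15.0

    def __post_init__(self):
        for name in ("q", "D", "tau", "m", "R0", "kd", "b0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.b0 <= 1.0:
            raise ValueError("b0 must be in [0, 1]")
        if self.delta_r <= 0:
            raise ValueError("delta_r must be positive")

    def as_vector(self) -> np.ndarray:
        return np.array([self.q, self.D, self.tau, self.m, self.R0, self.kd, self.b0])

    @classmethod
    def from_vector(cls, theta, delta_r: float = 15.0) -> "AttractantParams":
        q, D, tau, m, R0, kd, b0 = (float(v) for v in theta)
        return cls(q=q, D=D, tau=tau, m=m, R0=R0, kd=kd, b0=b0, delta_r=delta_r)


PARAM_NAMES = ("q", "D", "tau", "m", "R0", "kd", "b0")


@dataclass(frozen=True)
class ConcentrationField:
    """Sampled field: long-format table with x_um, y_um, t_min, A, C, bias."""

    table: pd.DataFrame
    params: AttractantParams
    wounds: tuple[WoundGeometry, ...]


def _ei_concentration(r2_over_4D, t, tau):
    """Closed-form single-source concentration for squared-distance/4D input.

    Broadcasts over arrays; returns A without the q/(4 pi D) prefactor.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast_shapes(np.shape(r2_over_4D), t.shape))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
        grow = t > 0
        arg_now = np.where(grow, -np.asarray(r2_over_4D) / np.where(grow, t, 1.0), -np.inf)
        ei_now = np.where(grow, expi(arg_now), 0.0)
        decay = t > tau
        dt = np.where(decay, t - tau, 1.0)
        arg_then = np.where(decay, -np.asarray(r2_over_4D) / dt, -np.inf)
        ei_then = np.where(decay, expi(arg_then), 0.0)
    return np.where(t > tau, ei_then - ei_now, -ei_now)


def point_source_concentration(r, t, q: float, D: float, tau: float):
    """Attractant concentration A(r, t) of a single point source.

    r in um (must be > 0: the 2D Green's function diverges logarithmically
    at the source), t in minutes. A(r, 0) = 0; A is continuous in t at tau,
    strictly decreasing in r, and increasing in t while production lasts.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive (2D point source is singular at r=0)")
    if D <= 0:
        raise ValueError("D must be positive")
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be nonnegative")
    a = (q / (FOUR_PI * D)) * _ei_concentration(r * r / (4.0 * D), t, tau)
    return a if np.ndim(a) else float(a)


def concentration_from_distances(dists, t, q_per_source: float, D: float, tau: float):
    """Superposed concentration from sources at the given distances.

    ``dists`` has sources on the last axis; t broadcasts against the
    leading axes. Used internally by the field and likelihood code where
    source distances are precomputed.
    """
    d2 = np.asarray(dists, dtype=float) ** 2 / (4.0 * D)
    t = np.asarray(t, dtype=float)[..., None]
    contrib = _ei_concentration(d2, t, tau)
    return (q_per_source / (FOUR_PI * D)) * contrib.sum(axis=-1)


def field_concentration(
    pos, t, wounds: WoundGeometry | Sequence[WoundGeometry], params: AttractantParams
):
    """Total attractant concentration at position(s) from all active wounds.

    Each active wound contributes n_sources point sources spread over its
    source arc, each producing at rate q / n_sources, so q is the total
    rate per wound regardless of discretisation. ``pos`` is (2,) or (n, 2).
    """
    if isinstance(wounds, WoundGeometry):
        wounds = [wounds]
    pos = np.asarray(pos, dtype=float)
    single = pos.ndim == 1
    pos = np.atleast_2d(pos)
    total = np.zeros(pos.shape[0])
    for w in wounds:
        if not w.active:
            continue
        src = w.source_positions()
        d = np.linalg.norm(pos[:, None, :] - src[None, :, :], axis=-1)
        if np.any(d < _SOURCE_EPS):
            raise ValueError("evaluation position coincides with a point source")
        total = total + concentration_from_distances(d, t, params.q / w.n_sources, params.D, params.tau)
    return float(total[0]) if single else total


def complex_concentration(A, R0: float, kd: float):
    """Steady-state receptor-ligand complex concentration.

    The minus root of C^2 - (kd + R0 + A) C + R0 A = 0, the only root with
    0 <= C <= min(R0, A); it satisfies (R0 - C)(A - C) = kd C. Evaluated
    in the cancellation-free product form R0 A / (s + sqrt(s^2 - R0 A)).
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0) or R0 < 0 or kd < 0:
        raise ValueError("A, R0, kd must be nonnegative")
    s = 0.5 * (kd + R0 + A)
    big = s + np.sqrt(np.maximum(s * s - R0 * A, 0.0))
    with np.errstate(invalid="ignore"):
        c = np.where(big > 0, R0 * A / np.where(big > 0, big, 1.0), 0.0)
    return c if c.ndim else float(c)


def predicted_bias(
    pos,
    t,
    wounds: WoundGeometry | Sequence[WoundGeometry],
    params: AttractantParams,
    toward: WoundGeometry | None = None,
) -> float:
    """Observed bias the walk model should show at a position and time.

    The cell senses the superposed field at its front and rear along the
    radial direction toward the assigned wound (``toward``; defaults to the
    nearest wound centre), and the bias is the linear readout
    m [C(front) - C(rear)] + b0. With no active wound the field is zero
    everywhere and the bias is b0.
    """
    if isinstance(wounds, WoundGeometry):
        wounds = [wounds]
    pos = np.asarray(pos, dtype=float)
    if toward is None:
        toward = min(wounds, key=lambda w: float(np.hypot(*(pos - np.asarray(w.center)))))
    center = np.asarray(toward.center)
    disp = center - pos
    dist = float(np.linalg.norm(disp))
    if dist == 0.0:
        raise ValueError("position at wound centre: sensing direction undefined")
    u = disp / dist
    if not any(w.active for w in wounds):
        return params.b0
    front = pos + params.delta_r * u
    rear = pos - params.delta_r * u
    a = field_concentration(np.stack([front, rear]), t, wounds, params)
    c = complex_concentration(a, params.R0, params.kd)
    return float(params.m * (c[0] - c[1]) + params.b0)


def sample_field(
    wounds: WoundGeometry | Sequence[WoundGeometry],
    params: AttractantParams,
    times: Sequence[float],
    extent: tuple[float, float, float, float],
    spacing: float = 2.0,
) -> ConcentrationField:
    """Sample A, C and predicted bias on a Cartesian grid (long format)."""
    if isinstance(wounds, WoundGeometry):
        wounds = [wounds]
    x0, x1, y0, y1 = extent
    xs = np.arange(x0, x1 + spacing / 2, spacing)
    ys = np.arange(y0, y1 + spacing / 2, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    any_active = any(w.active for w in wounds)
    frames = []
    for t in times:
        try:
            a = np.asarray(field_concentration(pts, t, wounds, params))
        except ValueError:  # some grid point sits on a source
            a = np.empty(pts.shape[0])
            for k, p in enumerate(pts):
                try:
                    a[k] = field_concentration(p, t, wounds, params)
                except ValueError:
                    a[k] = np.nan
        c = complex_concentration(np.nan_to_num(a, nan=0.0), params.R0, params.kd)
        c[np.isnan(a)] = np.nan
        bias = np.empty(pts.shape[0])
        for k, p in enumerate(pts):
            if not any_active:
                bias[k] = params.b0
                continue
            try:
                bias[k] = predicted_bias(p, t, wounds, params)
            except ValueError:  # wound centre or on-source point
                bias[k] = np.nan
        frames.append(
            pd.DataFrame(
                {"x_um": pts[:, 0], "y_um": pts[:, 1], "t_min": t, "A": a, "C": c, "bias": bias}
            )
        )
    return ConcentrationField(
        table=pd.concat(frames, ignore_index=True), params=params, wounds=tuple(wounds)
    )


def radial_gradient(
    wounds: WoundGeometry | Sequence[WoundGeometry],
    params: AttractantParams,
    t: float,
    azimuth_range: tuple[float, float],
    r_max: float,
    center: tuple[float, float] | None = None,
    r_min: float | None = None,
    dr: float = 1.0,
    n_azimuth: int = 64,
) -> pd.DataFrame:
    """Radial concentration gradient profile over an azimuth sector.

    Samples the superposed field on polar rays from ``center`` (default the
    first wound's centre) at azimuths spanning ``azimuth_range``, takes the
    central-difference derivative of A along each ray, and returns per
    radius the mean, min and max of dA/dr across the sector.
    """
    if isinstance(wounds, WoundGeometry):
        wounds = [wounds]
    lo, hi = azimuth_range
    if not hi > lo:
        raise ValueError("azimuth range must be a nonempty increasing interval")
    if center is None:
        center = wounds[0].center
    if r_min is None:
        r_min = wounds[0].radius + dr
    cx, cy = center
    radii = np.arange(r_min, r_max + dr / 2, dr)
    phis = np.linspace(lo, hi, n_azimuth)
    rr, pp = np.meshgrid(radii, phis)  # (n_az, n_r)
    pts = np.column_stack([(cx + rr * np.cos(pp)).ravel(), (cy + rr * np.sin(pp)).ravel()])
    a = np.asarray(field_concentration(pts, t, wounds, params)).reshape(rr.shape)
    grad = np.gradient(a, radii, axis=1)  # central differences along r
    return pd.DataFrame(
        {
            "r_um": radii,
            "grad_mean": grad.mean(axis=0),
            "grad_min": grad.min(axis=0),
            "grad_max": grad.max(axis=0),
        }
    )
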