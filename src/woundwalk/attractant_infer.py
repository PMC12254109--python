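"""Stage-2 Bayesian inference of attractant parameters from binned bias.

Each bin's stage-1 posterior of the observed bias is approximated as a
normal distribution, so the stage-2 likelihood of theta = (q, D, tau, m,
R0, kd, b0) is a product over time and space bins of Gaussian densities of
the forward model's predicted bias at the bin's representative point. The
innermost spatial bin (0-70 um: wound radius ~40 um plus a macrophage
diameter ~30 um) is excluded, since cells already at the wound edge are no
longer driven by the gradient.

Sampling uses an affine-invariant ensemble (40 walkers). Chains run until
the autocorrelation times of the identifiable parameters D, tau and b0
have stabilised (< 2% change between checks) and the chain exceeds 50
times the largest of them, or until the step cap; burn-in is twice the
autocorrelation time. q, m, R0 and kd are sampled but only weakly
identified (the data constrain combinations of them) and are flagged as
such in summaries.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import emcee
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expi

from woundwalk.attractant import (
    PARAM_NAMES,
    AttractantParams,
    complex_concentration,
    concentration_from_distances,
)
from woundwalk.brw_infer import BinPosterior
from woundwalk.tracks import BinGrid, WoundGeometry

logger = logging.getLogger(__name__)

SD_FLOOR = 1e-3  # on bin bias SDs, avoids degenerate likelihood spikes
WEAKLY_IDENTIFIED = ("q", "m", "R0", "kd")
IDENTIFIABLE = ("D", "tau", "b0")
_IDENT_IDX = [PARAM_NAMES.index(n) for n in IDENTIFIABLE]


@dataclass(frozen=True)
class Uniform:
    """Uniform(lo, hi) prior with fast vectorised log-density."""

    lo: float
    hi: float

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where((self.lo <= x) & (x <= self.hi), -math.log(self.hi - self.lo), -np.inf)
        return out if out.ndim else float(out)

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size)

    def cdf(self, x):
        return np.clip((np.asarray(x, dtype=float) - self.lo) / (self.hi - self.lo), 0.0, 1.0)


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mean, sd) truncated to [lo, hi]; fast vectorised log-density."""

    mean: float
    sd: float
    lo: float = 0.0
    hi: float = math.inf

    @property
    def _dist(self):
        return stats.truncnorm(
            (self.lo - self.mean) / self.sd,
            (self.hi - self.mean) / self.sd if math.isfinite(self.hi) else np.inf,
            loc=self.mean,
            scale=self.sd,
        )

    def __post_init__(self):
        # normalising constant of the truncated density
        z = stats.norm.cdf((self.hi - self.mean) / self.sd) - stats.norm.cdf(
            (self.lo - self.mean) / self.sd
        )
        object.__setattr__(self, "_log_norm", math.log(z * self.sd * math.sqrt(2.0 * math.pi)))

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        z = (x - self.mean) / self.sd
        out = np.where(
            (self.lo <= x) & (x <= self.hi), -0.5 * z * z - self._log_norm, -np.inf
        )
        return out if out.ndim else float(out)

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self._dist.rvs(size=size, random_state=rng)

    def cdf(self, x):
        return self._dist.cdf(x)


@dataclass(frozen=True)
class PriorSpec:
    """Independent priors for the seven attractant parameters."""

    q: object
    D: object
    tau: object
    m: object
    R0: object
    kd: object
    b0: object

    def dists(self) -> list:
        return [getattr(self, n) for n in PARAM_NAMES]

    def log_prior(self, theta: np.ndarray) -> np.ndarray | float:
        """Vectorised over a (..., 7) array of parameter vectors."""
        theta = np.asarray(theta, dtype=float)
        lp = sum(d.logpdf(theta[..., i]) for i, d in enumerate(self.dists()))
        return lp

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.column_stack([d.rvs(rng, size) for d in self.dists()])


def prior_presets(which: str = "wildtype") -> PriorSpec:
    """Priors for wild-type and knockdown analyses.

    Wild type uses informative truncated normals for D (200 +/- 50
    um^2/min) and tau (18 +/- 3 min), carried over from earlier wound
    chemoattractant inference; the knockdown preset replaces them with
    flat Uniform(0, 1000) and Uniform(0, 25) so an absent signal leaves
    those marginals at their priors. Truncation is at zero (b0 also at 1).
    """
    common = dict(
        q=Uniform(0, 3500),
        m=Uniform(0, 100),
        R0=Uniform(0, 10000),
        kd=Uniform(0, 10000),
        b0=TruncatedNormal(0.02, 0.02, 0.0, 1.0),
    )
    if which == "wildtype":
        return PriorSpec(D=TruncatedNormal(200.0, 50.0), tau=TruncatedNormal(18.0, 3.0), **common)
    if which == "kd":
        return PriorSpec(D=Uniform(0, 1000), tau=Uniform(0, 25), **common)
    raise ValueError(f"unknown preset {which!r}; use 'wildtype' or 'kd'")


class AttractantLikelihood:
    """Gaussian bin likelihood with precomputed source-distance geometry.

    Bin representative points sit at the bin centre in r and t, placed at
    the centre azimuth of the bin's azimuth range (or azimuth 0), at
    distance r from the wound centre. For each point the cell's front and
    rear sensing positions (+/- delta_r along the radial direction toward
    the assigned wound) are fixed, so the distances to every attractant
    source can be computed once.
    """

    def __init__(
        self,
        bins: Sequence[BinPosterior],
        wounds: WoundGeometry | Sequence[WoundGeometry],
        grid: BinGrid,
        *,
        delta_r: float = 15.0,
        exclude_first_spatial: bool = True,
        exclusion_range: tuple[float, float] | None = None,
    ):
        if isinstance(wounds, WoundGeometry):
            wounds = [wounds]
        self.wounds = list(wounds)
        self.grid = grid
        self.delta_r = float(delta_r)
        r_centers = grid.spatial_centers()
        t_centers = grid.temporal_centers()
        if exclusion_range is None and exclude_first_spatial:
            exclusion_range = (grid.spatial_edges[0], grid.spatial_edges[1])

        used: list[BinPosterior] = []
        fronts, rears, times = [], [], []
        for b in bins:
            if not math.isfinite(b.observed_bias_mean) or b.flag.startswith("failed"):
                continue
            if b.n_steps == 0:
                continue
            r_c = r_centers[b.j_space]
            if exclusion_range is not None and exclusion_range[0] <= r_c < exclusion_range[1]:
                continue
            if b.k_azimuth is not None and grid.azimuth_ranges is not None:
                lo, hi = grid.azimuth_ranges[b.k_azimuth]
                phi = 0.5 * (lo + hi)
            else:
                phi = 0.0
            # representative point: distance r_c from the first wound's
            # centre at azimuth phi, sensing axis radially toward it
            anchor = np.array(self.wounds[0].center)
            ray = np.array([math.cos(phi), math.sin(phi)])
            pos = anchor + r_c * ray
            u = -ray
            used.append(b)
            fronts.append(pos + self.delta_r * u)
            rears.append(pos - self.delta_r * u)
            times.append(t_centers[b.i_time])
        if not used:
            raise ValueError("all bins excluded; nothing to fit")
        self.bins = used
        self.means = np.array([b.observed_bias_mean for b in used])
        self.sds = np.maximum(np.array([b.observed_bias_sd for b in used]), SD_FLOOR)
        self.times = np.array(times)  # (n_bins,)
        pts = np.stack([np.array(fronts), np.array(rears)], axis=1)  # (n_bins, 2, 2)
        src = [w.source_positions() for w in self.wounds if w.active]
        if src:
            allsrc = np.concatenate(src, axis=0)  # (n_src_total, 2)
            self.dists = np.linalg.norm(pts[:, :, None, :] - allsrc[None, None, :, :], axis=-1)
            # per-source weight 1/n_sources of its wound: each active wound
            # emits q total, split evenly over its own sources
            weights = np.concatenate([np.full(s.shape[0], 1.0 / s.shape[0]) for s in src])
            shape = self.dists.shape  # (n_bins, 2, S)
            self._d2_flat = (self.dists**2).ravel()
            self._t_flat = np.broadcast_to(self.times[:, None, None], shape).ravel()
            self._w_flat = np.broadcast_to(weights[None, None, :], shape).ravel()
            self._shape = shape
        else:
            self.dists = None
        self._gauss_norm = float(np.sum(np.log(self.sds * math.sqrt(2.0 * math.pi))))

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def predicted_batch(self, thetas: np.ndarray) -> np.ndarray:
        """Model bias at each bin point for a (k, 7) batch of thetas."""
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        q, D, tau, m, R0, kd, b0 = (thetas[:, i] for i in range(7))
        k = thetas.shape[0]
        if self.dists is None:
            return np.tile(b0[:, None], (1, self.n_bins))
        d2 = self._d2_flat[None, :]
        tf = self._t_flat[None, :]
        with np.errstate(divide="ignore", over="ignore", under="ignore"):
            ei_now = expi(-d2 / (4.0 * D[:, None] * tf))
            mask = tf > tau[:, None]
            contrib = -ei_now
            if mask.any():  # decay term only exists after production stops
                dt = (tf - tau[:, None])[mask]
                d2m = np.broadcast_to(d2, mask.shape)[mask]
                dm = np.broadcast_to(D[:, None], mask.shape)[mask]
                contrib[mask] += expi(-d2m / (4.0 * dm * dt))
        contrib *= self._w_flat[None, :]
        a = (q / (4.0 * math.pi * D))[:, None, None] * contrib.reshape(
            k, *self._shape
        ).sum(axis=-1)  # (k, n_bins, 2)
        p = R0[:, None, None] * a
        s = 0.5 * (kd[:, None, None] + R0[:, None, None] + a)
        big = s + np.sqrt(np.maximum(s * s - p, 0.0))
        c = np.where(big > 0, p / np.where(big > 0, big, 1.0), 0.0)
        return m[:, None] * (c[:, :, 0] - c[:, :, 1]) + b0[:, None]

    def predicted(self, theta: np.ndarray) -> np.ndarray:
        """Model bias at each bin representative point for one theta."""
        return self.predicted_batch(np.asarray(theta, dtype=float))[0]

    def log_likelihood_batch(self, thetas: np.ndarray) -> np.ndarray:
        pred = self.predicted_batch(thetas)
        resid = (pred - self.means[None, :]) / self.sds[None, :]
        return -0.5 * (resid * resid).sum(axis=1) - self._gauss_norm

    def log_likelihood(self, theta: np.ndarray) -> float:
        return float(self.log_likelihood_batch(np.asarray(theta, dtype=float))[0])


def theta_log_likelihood(
    theta,
    bins: Sequence[BinPosterior],
    wounds: WoundGeometry | Sequence[WoundGeometry],
    grid: BinGrid,
    **kwargs,
) -> float:
    """Log-likelihood of attractant parameters given binned bias posteriors.

    ``theta`` is an AttractantParams or a (q, D, tau, m, R0, kd, b0)
    vector. Convenience wrapper over :class:`AttractantLikelihood`; build
    the class directly for repeated evaluation.
    """
    if isinstance(theta, AttractantParams):
        kwargs.setdefault("delta_r", theta.delta_r)
        theta = theta.as_vector()
    return AttractantLikelihood(bins, wounds, grid, **kwargs).log_likelihood(theta)


@dataclass
class ThetaPosterior:
    """Retained posterior samples of theta with summaries and diagnostics."""

    samples: pd.DataFrame  # columns q, D, tau, m, R0, kd, b0
    modes: dict[str, float]
    means: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    autocorr_times: dict[str, float]
    chain_length: int
    converged: bool
    weakly_identified: tuple[str, ...] = WEAKLY_IDENTIFIED

    def to_dict(self) -> dict:
        return {
            "modes": self.modes,
            "means": self.means,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "autocorr_times": self.autocorr_times,
            "chain_length": self.chain_length,
            "converged": self.converged,
            "weakly_identified": list(self.weakly_identified),
        }

    def save(self, path: str | Path, *, samples_csv: str | Path | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))
        if samples_csv is not None:
            self.samples.to_csv(samples_csv, index=False)


def marginal_mode(samples: np.ndarray, n_grid: int = 512) -> float:
    """Mode of a 1-D marginal estimated by Gaussian KDE on a grid."""
    samples = np.asarray(samples, dtype=float)
    if samples.size > 20000:
        samples = samples[:: samples.size // 20000 + 1]
    lo, hi = samples.min(), samples.max()
    if hi <= lo:
        return float(lo)
    grid = np.linspace(lo, hi, n_grid)
    dens = stats.gaussian_kde(samples)(grid)
    return float(grid[np.argmax(dens)])


def sample_theta(
    bins: Sequence[BinPosterior],
    prior: PriorSpec | str,
    wounds: WoundGeometry | Sequence[WoundGeometry],
    grid: BinGrid,
    *,
    n_walkers: int = 40,
    max_steps: int = 1_000_000,
    check_every: int = 1000,
    autocorr_multiple: float = 50.0,
    autocorr_rtol: float = 0.02,
    seed: int = 0,
    delta_r: float = 15.0,
    exclude_first_spatial: bool = True,
) -> ThetaPosterior:
    """Ensemble MCMC over theta with autocorrelation-based stopping.

    Walkers are initialised from the prior. Every ``check_every`` steps the
    integrated autocorrelation times of D, tau and b0 are estimated; the
    run stops once they change by less than ``autocorr_rtol`` between
    checks and the chain exceeds ``autocorr_multiple`` times the largest,
    or at ``max_steps`` with a warning. Burn-in is twice the largest
    autocorrelation time; thinning half the smallest.
    """
    if isinstance(prior, str):
        prior = prior_presets(prior)
    like = AttractantLikelihood(
        bins, wounds, grid, delta_r=delta_r, exclude_first_spatial=exclude_first_spatial
    )

    def log_prob(thetas):
        thetas = np.atleast_2d(thetas)
        lp = np.asarray(prior.log_prior(thetas), dtype=float)
        ok = np.isfinite(lp)
        out = np.full(thetas.shape[0], -np.inf)
        if ok.any():
            out[ok] = lp[ok] + like.log_likelihood_batch(thetas[ok])
        return out

    rng = np.random.default_rng(seed)
    p0 = prior.sample(rng, n_walkers)
    for _ in range(100):  # re-draw walkers that land at zero density
        bad = ~np.isfinite(log_prob(p0))
        if not bad.any():
            break
        p0[bad] = prior.sample(rng, int(bad.sum()))
    else:
        raise RuntimeError("could not initialise walkers at finite density")

    sampler = emcee.EnsembleSampler(n_walkers, 7, log_prob, vectorize=True)
    state = emcee.State(p0, random_state=np.random.RandomState(seed).get_state())
    old_tau = np.full(3, np.inf)
    converged = False
    steps_done = 0
    while steps_done < max_steps:
        todo = min(check_every, max_steps - steps_done)
        state = sampler.run_mcmc(state, todo, progress=False)
        steps_done += todo
        tau_all = sampler.get_autocorr_time(tol=0, quiet=True)
        tau = np.asarray(tau_all)[_IDENT_IDX]
        if np.all(np.isfinite(tau)) and np.all(tau > 0):
            stable = np.all(np.abs(tau - old_tau) / tau < autocorr_rtol)
            long_enough = steps_done > autocorr_multiple * tau.max()
            if stable and long_enough:
                converged = True
                break
            old_tau = tau
    if not converged:
        logger.warning(
            "chain stopped at max_steps=%d before autocorrelation convergence", max_steps
        )

    tau_all = np.asarray(sampler.get_autocorr_time(tol=0, quiet=True))
    tau = tau_all[_IDENT_IDX]
    max_tau = float(np.nanmax(tau)) if np.any(np.isfinite(tau)) else steps_done / 10
    burn = min(int(2 * max_tau), steps_done // 2)
    thin = max(1, int(0.5 * float(np.nanmin(tau))) if np.any(np.isfinite(tau)) else 1)
    flat = sampler.get_chain(discard=burn, thin=thin, flat=True)

    df = pd.DataFrame(flat, columns=list(PARAM_NAMES))
    modes = {n: marginal_mode(df[n].to_numpy()) for n in PARAM_NAMES}
    means = {n: float(df[n].mean()) for n in PARAM_NAMES}
    ci_low = {n: float(np.percentile(df[n], 2.5)) for n in PARAM_NAMES}
    ci_high = {n: float(np.percentile(df[n], 97.5)) for n in PARAM_NAMES}
    autoc = {n: float(tau_all[i]) for i, n in enumerate(PARAM_NAMES)}
    return ThetaPosterior(
        samples=df,
        modes=modes,
        means=means,
        ci_low=ci_low,
        ci_high=ci_high,
        autocorr_times=autoc,
        chain_length=steps_done,
        converged=converged,
    )
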