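"""Stage-1 Bayesian inference of walk parameters (w, b, p) per bin.

Steps pooled within a spatiotemporal bin are treated as independent draws
from the biased-persistent mixture; the likelihood is the exact product of
per-step mixture densities. Priors are Uniform(0, 1) on each of w, b, p,
and the posterior is sampled with an affine-invariant ensemble sampler.
The reported quantity per bin is the posterior of the observed bias w*b
(and observed persistence (1-w)*p).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import emcee
import numpy as np

from woundwalk.brw import SIGMA_UNIFORM_CUTOFF, TWO_PI, UNIFORM_DENSITY
from woundwalk.tracks import (
    BinGrid,
    StepRecord,
    Track,
    WoundGeometry,
    assign_bins,
    compute_steps,
    wrap_angle,
)

logger = logging.getLogger(__name__)

_DENSITY_FLOOR = 1e-300  # keeps the log finite at the b=1 / p=1 corners


@dataclass(frozen=True)
class MCMCConfig:
    """Ensemble-sampler settings for per-bin inference.

    Defaults follow the full-length analysis runs: 10 walkers, 10000 steps,
    burn-in the larger of ``burn_in`` (3000) and twice the maximum
    autocorrelation time. Thinning is half the minimum autocorrelation
    time. ``n_steps`` can be reduced for quick runs; burn-in is then capped
    at half the chain.
    """

    n_walkers: int = 10
    n_steps: int = 10000
    burn_in: int = 3000
    seed: int = 0

    def __post_init__(self):
        if self.n_walkers < 6:  # ensemble moves need >= 2*ndim walkers
            raise ValueError("need at least 6 walkers for 3 parameters")
        if self.n_steps < 10:
            raise ValueError("n_steps too small")


@dataclass
class BinPosterior:
    """Posterior summary of the walk parameters in one bin."""

    i_time: int
    j_space: int
    k_azimuth: int | None
    observed_bias_mean: float
    observed_bias_sd: float
    observed_persistence_mean: float
    observed_persistence_sd: float
    n_steps: int
    samples: np.ndarray | None = None  # (n, 3) retained (w, b, p) draws
    flag: str = "ok"

    def to_dict(self) -> dict:
        d = {
            "i_time": self.i_time,
            "j_space": self.j_space,
            "k_azimuth": self.k_azimuth,
            "observed_bias_mean": self.observed_bias_mean,
            "observed_bias_sd": self.observed_bias_sd,
            "observed_persistence_mean": self.observed_persistence_mean,
            "observed_persistence_sd": self.observed_persistence_sd,
            "n_steps": self.n_steps,
            "flag": self.flag,
        }
        return d


def _step_arrays(steps: Sequence[StepRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Fixed per-step angle offsets entering the likelihood.

    Only steps with a previous heading contribute. Returns the wrapped
    offsets gamma_t - beta (biased component) and gamma_t - gamma_prev
    (persistent component).
    """
    usable = [s for s in steps if s.previous_heading is not None]
    if not usable:
        return np.empty(0), np.empty(0)
    gt = np.array([s.heading for s in usable])
    beta = np.array([s.bearing for s in usable])
    gp = np.array([s.previous_heading for s in usable])
    return wrap_angle(gt - beta), wrap_angle(gt - gp)


def _wrapped_component(delta: np.ndarray, sigma: float) -> np.ndarray:
    """Wrapped-normal density at precomputed wrapped offsets."""
    if not math.isfinite(sigma) or sigma > SIGMA_UNIFORM_CUTOFF:
        return np.full(delta.shape, UNIFORM_DENSITY)
    sigma = max(sigma, 1e-6)  # b or p exactly 1: near-point-mass limit
    k = max(3, math.ceil(sigma))
    i = np.arange(-k, k + 1)
    z = (delta[:, None] + TWO_PI * i) / sigma
    with np.errstate(under="ignore"):
        return np.exp(-0.5 * z * z).sum(axis=1) / (sigma * math.sqrt(TWO_PI))


def _log_likelihood_arrays(delta_b: np.ndarray, delta_p: np.ndarray, w, b, p) -> float:
    sigma_b = math.inf if b == 0.0 else math.sqrt(-2.0 * math.log(b))
    sigma_p = math.inf if p == 0.0 else math.sqrt(-2.0 * math.log(p))
    dens = w * _wrapped_component(delta_b, sigma_b) + (1.0 - w) * _wrapped_component(
        delta_p, sigma_p
    )
    return float(np.log(np.maximum(dens, _DENSITY_FLOOR)).sum())


def bin_log_likelihood(steps: Sequence[StepRecord], params) -> float:
    """Exact log-likelihood of (w, b, p) for the steps pooled in a bin.

    ``params`` is a BRWParams or a (w, b, p) triple. First steps (no
    previous heading) are skipped. An empty bin contributes 0 (posterior
    equals prior).
    """
    w, b, p = (params.w, params.b, params.p) if hasattr(params, "w") else params
    delta_b, delta_p = _step_arrays(steps)
    if delta_b.size == 0:
        logger.warning("bin_log_likelihood: no usable steps; returning 0")
        return 0.0
    return _log_likelihood_arrays(delta_b, delta_p, w, b, p)


def _run_mcmc(delta_b: np.ndarray, delta_p: np.ndarray, config: MCMCConfig) -> tuple[np.ndarray, str]:
    """Sample (w, b, p); returns retained flat samples and a status flag."""

    def log_prob(theta):
        w, b, p = theta
        if not (0.0 <= w <= 1.0 and 0.0 <= b <= 1.0 and 0.0 <= p <= 1.0):
            return -np.inf
        return _log_likelihood_arrays(delta_b, delta_p, w, b, p)

    rng = np.random.default_rng(config.seed)
    p0 = rng.uniform(0.05, 0.95, size=(config.n_walkers, 3))
    sampler = emcee.EnsembleSampler(config.n_walkers, 3, log_prob)
    state = emcee.State(p0, random_state=np.random.RandomState(config.seed).get_state())
    sampler.run_mcmc(state, config.n_steps, progress=False)

    flag = "ok"
    try:
        tau = sampler.get_autocorr_time(tol=0)
        max_tau = float(np.nanmax(tau))
        if not math.isfinite(max_tau):
            raise ValueError("non-finite autocorrelation time")
        burn = max(config.burn_in, int(2 * max_tau))
        thin = max(1, int(0.5 * float(np.nanmin(tau))))
    except Exception as exc:  # autocorr estimation can fail on short chains
        logger.warning("autocorrelation estimate failed (%s); fixed burn-in", exc)
        burn, thin, flag = config.burn_in, 1, "autocorr_failed"
    burn = min(burn, config.n_steps // 2)
    return sampler.get_chain(discard=burn, thin=thin, flat=True), flag


def sample_bin_posterior(
    steps: Sequence[StepRecord],
    config: MCMCConfig | None = None,
    *,
    i_time: int = 0,
    j_space: int = 0,
    k_azimuth: int | None = None,
    keep_samples: bool = True,
) -> BinPosterior:
    """Posterior over (w, b, p) for one bin under Uniform(0,1)^3 priors.

    An empty bin (no steps with a previous heading) returns the prior
    itself, sampled directly.
    """
    config = config or MCMCConfig()
    delta_b, delta_p = _step_arrays(steps)
    if delta_b.size == 0:
        logger.warning("empty bin (%d, %d, %s): posterior equals prior", i_time, j_space, k_azimuth)
        rng = np.random.default_rng(config.seed)
        flat = rng.uniform(0.0, 1.0, size=(5000, 3))
        flag = "empty"
    else:
        flat, flag = _run_mcmc(delta_b, delta_p, config)
    ob = flat[:, 0] * flat[:, 1]
    op = (1.0 - flat[:, 0]) * flat[:, 2]
    return BinPosterior(
        i_time=i_time,
        j_space=j_space,
        k_azimuth=k_azimuth,
        observed_bias_mean=float(ob.mean()),
        observed_bias_sd=float(ob.std(ddof=1)),
        observed_persistence_mean=float(op.mean()),
        observed_persistence_sd=float(op.std(ddof=1)),
        n_steps=int(delta_b.size),
        samples=flat if keep_samples else None,
        flag=flag,
    )


def steps_for_tracks(
    tracks: Sequence[Track], wounds: WoundGeometry | Sequence[WoundGeometry]
) -> list[StepRecord]:
    """Step records for all tracks, each step referenced to its assigned wound.

    With several wounds, a step is assigned to the wound whose centre is
    nearest its start position — for two equal wounds this is the side of
    the inter-wound midline the cell is on.
    """
    if isinstance(wounds, WoundGeometry):
        wounds = [wounds]
    steps: list[StepRecord] = []
    if len(wounds) == 1:
        for tr in tracks:
            steps.extend(compute_steps(tr, wounds[0]))
        return steps
    for tr in tracks:
        per_wound = [compute_steps(tr, w) for w in wounds]
        # compute_steps drops the same degenerate steps for every wound, so
        # records align index-by-index across wounds
        for recs in zip(*per_wound):
            steps.append(min(recs, key=lambda s: s.distance))
    return steps


def infer_all_bins(
    tracks: Sequence[Track],
    wounds: WoundGeometry | Sequence[WoundGeometry],
    grid: BinGrid,
    config: MCMCConfig | None = None,
    *,
    keep_samples: bool = False,
) -> list[BinPosterior]:
    """Run per-bin posterior sampling over the whole grid.

    Failures in individual bins are flagged and do not abort the rest.
    Bin seeds are derived from the config seed so runs are reproducible
    and bins are independent.
    """
    config = config or MCMCConfig()
    steps = steps_for_tracks(tracks, wounds)
    binned = assign_bins(steps, grid)
    out: list[BinPosterior] = []
    for key in sorted(binned):
        i, j = key[0], key[1]
        k = key[2] if len(key) == 3 else None
        bin_seed = int(np.random.SeedSequence([config.seed, i, j, 0 if k is None else k + 1]).generate_state(1)[0] % (2**31))
        try:
            out.append(
                sample_bin_posterior(
                    binned[key],
                    replace(config, seed=bin_seed),
                    i_time=i,
                    j_space=j,
                    k_azimuth=k,
                    keep_samples=keep_samples,
                )
            )
        except Exception as exc:
            logger.error("bin (%d, %d, %s) failed: %s", i, j, k, exc)
            out.append(
                BinPosterior(
                    i_time=i,
                    j_space=j,
                    k_azimuth=k,
                    observed_bias_mean=float("nan"),
                    observed_bias_sd=float("nan"),
                    observed_persistence_mean=float("nan"),
                    observed_persistence_sd=float("nan"),
                    n_steps=len(binned[key]),
                    flag=f"failed: {exc}",
                )
            )
    return out


def save_bins(bins: Sequence[BinPosterior], grid: BinGrid, path: str | Path) -> None:
    """Serialize bin posteriors (summaries + grid edges) as JSON."""
    payload = {
        "spatial_edges": list(grid.spatial_edges),
        "temporal_edges": list(grid.temporal_edges),
        "azimuth_ranges": [list(r) for r in grid.azimuth_ranges] if grid.azimuth_ranges else None,
        "bins": [b.to_dict() for b in bins],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_bins(path: str | Path) -> tuple[list[BinPosterior], BinGrid]:
    """Load bin posteriors written by :func:`save_bins`."""
    payload = json.loads(Path(path).read_text())
    grid = BinGrid(
        spatial_edges=tuple(payload["spatial_edges"]),
        temporal_edges=tuple(payload["temporal_edges"]),
        azimuth_ranges=tuple(tuple(r) for r in payload["azimuth_ranges"])
        if payload.get("azimuth_ranges")
        else None,
    )
    bins = [BinPosterior(**d) for d in payload["bins"]]
    return bins, grid
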