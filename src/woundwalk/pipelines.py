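"""Composite pipeline runs used by the analysis drivers and acceptance checks.

These wire the modules together at reduced-but-sufficient MCMC lengths:
stage-2 chains of ~10^4 steps with 40 walkers give stable marginal modes
for D, tau and b0 on synthetic data (the full-length analysis settings are
the module defaults). All randomness derives from a single seed.
"""

from __future__ import annotations

import zlib

import numpy as np

from woundwalk.attractant_infer import ThetaPosterior, sample_theta
from woundwalk.brw_infer import BinPosterior, MCMCConfig, infer_all_bins
from woundwalk.synthetic import control_scenario, generate_binned_bias, generate_tracks
from woundwalk.tracks import BinGrid, Track

STAGE2_GRID = BinGrid(
    spatial_edges=(70.0, 110.0, 150.0, 190.0, 230.0),
    temporal_edges=(0.0, 5.0, 10.0, 15.0, 20.0, 25.0),
)


def _subseed(seed: int, label: str) -> int:
    ss = np.random.SeedSequence([seed, zlib.crc32(label.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def stage2_recovery_run(
    seed: int,
    noise_sd: float = 0.005,
    max_steps: int = 12000,
    grid: BinGrid = STAGE2_GRID,
) -> tuple[ThetaPosterior, dict]:
    """Fit stage 2 to forward-model bias data with flat D and tau priors.

    Bin summaries are generated at the default true parameters (D = 200
    um^2/min, tau = 18 min) over 70-230 um x 0-25 min, perturbed by
    Gaussian noise of sd ``noise_sd``; the fit uses the knockdown-style
    uniform priors (D ~ U(0, 1000), tau ~ U(0, 25)) so the recovered modes
    are data-driven, not prior-driven.
    """
    scen = control_scenario(seed=_subseed(seed, "truth"))
    bins, truth = generate_binned_bias(scen, grid, noise_sd=noise_sd, rng=_subseed(seed, "noise"))
    post = sample_theta(
        bins,
        "kd",
        list(scen.wounds),
        grid,
        max_steps=max_steps,
        check_every=max(1000, max_steps // 4),
        seed=_subseed(seed, "mcmc"),
        exclude_first_spatial=False,  # grid already starts at 70 um
    )
    return post, truth


def end_to_end_run(
    seed: int,
    n_cells: int = 40,
    stage1_steps: int = 1500,
    stage2_max_steps: int = 6000,
    grid: BinGrid | None = None,
) -> tuple[list[Track], list[BinPosterior], ThetaPosterior, dict]:
    """Control scenario through the whole pipeline: tracks -> bins -> theta.

    Stage 1 runs per-bin ensemble MCMC on the simulated tracks; stage 2
    fits the wild-type priors to the resulting bin posteriors (the
    treatment the control samples receive in the real analysis).
    """
    grid = grid or BinGrid()
    scen = control_scenario(seed=_subseed(seed, "tracks"), n_cells=n_cells)
    tracks, truth = generate_tracks(scen)
    s1 = MCMCConfig(n_steps=stage1_steps, burn_in=max(200, stage1_steps // 3),
                    seed=_subseed(seed, "stage1"))
    bins = infer_all_bins(tracks, list(scen.wounds), grid, s1)
    post = sample_theta(
        bins,
        "wildtype",
        list(scen.wounds),
        grid,
        max_steps=stage2_max_steps,
        check_every=max(1000, stage2_max_steps // 4),
        seed=_subseed(seed, "stage2"),
    )
    return tracks, bins, post, truth


def knockdown_run(
    seed: int,
    noise_sd: float = 0.01,
    max_steps: int = 4000,
    grid: BinGrid = STAGE2_GRID,
) -> ThetaPosterior:
    """Fit the knockdown priors to flat (no-signal) bias data.

    With nothing but baseline bias in the bins, the D marginal should stay
    at its Uniform(0, 1000) prior — the no-evidence signature.
    """
    from woundwalk.synthetic import knockdown_scenario

    scen = knockdown_scenario(seed=_subseed(seed, "kd-truth"))
    bins, _ = generate_binned_bias(scen, grid, noise_sd=noise_sd, rng=_subseed(seed, "kd-noise"))
    return sample_theta(
        bins,
        "kd",
        list(scen.wounds),
        grid,
        max_steps=max_steps,
        check_every=max(1000, max_steps // 4),
        seed=_subseed(seed, "kd-mcmc"),
        exclude_first_spatial=False,
    )
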