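#!/usr/bin/env python
"""Stage 2: infer attractant production-diffusion parameters from the bins.

Fits theta = (q, D, tau, m, R0, kd, b0) to the stage-1 bin posteriors of
step 02: wild-type priors for the control scenario, knockdown priors for
the kd scenario (reduced chains, 40 walkers x <= 8000 steps). Writes
theta.json and posterior-sample CSVs under results/theta/. Expected: the
control D mode near the generating 200 um^2/min; the kd D marginal close
to its flat prior.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from woundwalk.attractant_infer import sample_theta
from woundwalk.brw_infer import load_bins
from woundwalk.tracks import WoundGeometry

SEED = 42
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    wound = WoundGeometry(center=(0.0, 0.0), radius=40.0)
    out = ROOT / "theta"
    out.mkdir(parents=True, exist_ok=True)
    for name, prior in [("control", "wildtype"), ("kd", "kd")]:
        bins, grid = load_bins(ROOT / "bins" / f"{name}.json")
        post = sample_theta(bins, prior, wound, grid, max_steps=8000,
                            check_every=2000, seed=SEED)
        post.save(out / f"{name}.json", samples_csv=out / f"{name}_samples.csv")
        print(f"{name:8s}: D mode {post.modes['D']:.0f} um^2/min "
              f"[{post.ci_low['D']:.0f}, {post.ci_high['D']:.0f}], "
              f"tau mode {post.modes['tau']:.1f} min, b0 {post.modes['b0']:.3f} "
              f"(converged={post.converged})")


if __name__ == "__main__":
    main()
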