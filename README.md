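# woundwalk

Bayesian inference of a wound-induced chemoattractant from immune-cell
tracks.

When an epithelium is wounded, innate immune cells (in the fly pupal
wing, macrophages) turn and migrate toward the damage within minutes,
guided by a diffusible attractant released at the wound edge. The
attractant itself is invisible; what can be measured are the cell
trajectories. `woundwalk` turns those trajectories into posterior
distributions over the attractant's physical parameters with a two-stage
pipeline:

1. **Stage 1 — walk inference.** Step headings γ_t are modelled as a
   biased-persistent random walk: with probability w a step is drawn
   from a wrapped normal centred on the direction β to the wound
   (width σ_b² = −2 log b), otherwise from one centred on the previous
   heading (σ_p² = −2 log p). The likelihood of (w, b, p) is exact, and
   ensemble MCMC under Uniform(0,1)³ priors yields, per spatiotemporal
   bin, a posterior of the *observed bias* w·b.

2. **Stage 2 — attractant inference.** The binned bias posteriors are
   fit by a production–diffusion–sensing model: point sources on the
   wound edge produce attractant at total rate q until time τ, it
   diffuses with diffusivity D (concentration in closed form via the
   exponential integral Ei), cells bind it with receptor number R0 and
   dissociation constant κd, and the observed bias is the linear
   front–rear difference in bound receptor: m·[C(r−Δr) − C(r+Δr)] + b0.
   Ensemble MCMC over θ = (q, D, τ, m, R0, κd, b0) with
   autocorrelation-based stopping yields the attractant posterior; D, τ
   and b0 are the identifiable parameters.

A scenario generator closes the loop: it simulates macrophage-like
tracks whose local observed bias equals the forward model's prediction
by construction, for a control wound, a knockdown wound (silent
sources), a half wound (semicircular source arc) and two competing
wounds — so the whole pipeline can be validated by parameter recovery
without any imaging data.

## Worked example

```python
from woundwalk import BinGrid, synthetic
from woundwalk.brw_infer import MCMCConfig, infer_all_bins
from woundwalk.attractant_infer import sample_theta

scen = synthetic.control_scenario(seed=3)          # 40 cells, 25 min, wound r=40 um
tracks, truth = synthetic.generate_tracks(scen)    # true D=200, tau=18
grid = BinGrid()                                   # 70-um-first spatial bins, 5-min time bins

bins = infer_all_bins(tracks, list(scen.wounds), grid,
                      MCMCConfig(n_steps=1500, burn_in=500, seed=1))
for b in bins:
    if b.i_time == 3:
        print(b.j_space, round(b.observed_bias_mean, 3), "+/-", round(b.observed_bias_sd, 3))

post = sample_theta(bins, "wildtype", list(scen.wounds), grid,
                    max_steps=6000, seed=1)
print("D mode:", round(post.modes["D"], 1), "tau mode:", round(post.modes["tau"], 1))
```

Stage 1 prints the observed bias falling with distance in the 15–20 min
window — cells near the wound step toward it far more often than distant
ones (j_space indexes the distance bin, 0 = 0–70 μm):

```
0 0.234 +/- 0.079
1 0.245 +/- 0.126
2 0.133 +/- 0.082
3 0.1   +/- 0.059
4 0.056 +/- 0.037
```

and stage 2 recovers the attractant parameters that generated the
tracks: `D mode: 215.8 tau mode: 14.6`, with a 95% interval for D of
142–307 μm²/min around the generating 200 — the same analysis on the
knockdown scenario leaves D at its flat prior, the no-signal signature.

The same pipeline runs from the shell (`woundwalk simulate`,
`woundwalk infer-brw`, `woundwalk infer-attractant`,
`woundwalk predict-field`, `woundwalk metrics`, `woundwalk run`), and
the `analysis/` scripts run the full study: scenario simulation (01),
per-bin bias inference (02), attractant inference for control vs
knockdown (03) and field/gradient predictions for the half-wound and
two-wound geometries (04), writing tables under `results/`.

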