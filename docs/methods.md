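# Methods

`woundwalk` infers the properties of a diffusible wound chemoattractant
from the trajectories of responding immune cells. It was built around the
wound-healing assay in the *Drosophila* pupal wing, where macrophage
nuclei are tracked for ~25 minutes after a laser wound (~40 μm radius) at
30-second frames, but nothing in the model is specific to that system
beyond the default scales.

## Stage 1 — the biased-persistent random walk

Cell motion is modelled as a sequence of step headings γ_t on the circle.
Each step is *biased* with probability w — heading drawn from a wrapped
normal centred on the bearing β to the wound — or *persistent* with
probability 1 − w — centred on the previous heading γ_{t−1}:

    p(γ_t) = w·N_w(γ_t | β, σ_b) + (1 − w)·N_w(γ_t | γ_{t−1}, σ_p),

with σ_b² = −2 log b and σ_p² = −2 log p, so b, p ∈ [0, 1] interpolate
from uniform headings (0) to deterministic ones (1). The product w·b is
the **observed bias** and (1 − w)·p the **observed persistence**; these
are the bin-level summaries the second stage consumes. A useful identity:
the mean resultant length of the wrapped normal with σ² = −2 log b is
exactly b, so w·b is also the expected wound-ward drift per step in units
of the step length.

Heading convention. Although the field often calls γ_t a "turning angle",
the persistent component's mean being the *previous heading* is only
coherent if γ_t is the absolute direction of motion of step t. We use
absolute headings throughout; β is the direction from the step's start
position to the wound centre (not the nearest edge point — the model's
sources sit on the edge, but the bias geometry treats the wound as a
whole, and at the distances retained for inference the difference is
small).

Likelihood and sampling. Step angles pooled in a spatiotemporal bin
(half-open bins; default spatial edges 0, 70, 110, 150, 190, 230 μm and
5-minute time bins to 25 min) are treated as independent, so the bin
likelihood of (w, b, p) is an exact product of mixture densities. First
steps of a track (no previous heading) and degenerate steps (zero
displacement, or starting exactly at the wound centre) are excluded and
counted. Priors are Uniform(0,1)³; sampling uses the affine-invariant
ensemble sampler (`emcee`) with 10 walkers and 10 000 steps per bin at
full length, burn-in the larger of 3000 samples and twice the maximum
integrated autocorrelation time, thinning by half the minimum
autocorrelation time. Walkers start uniformly in (0.05, 0.95)³. At the
cube's open edges b → 0 or p → 0 the component tends to the uniform
density 1/2π, which keeps the likelihood finite everywhere on [0,1]³; at
the opposite corners (b or p = 1) the density is a point mass, handled by
a σ floor of 10⁻⁶ and a density floor of 10⁻³⁰⁰, so proposals there are
effectively—but finitely—rejected.

The wrapped-normal density is a truncated wrap sum with max(3, ⌈σ⌉)
terms per side, which keeps the missed tail mass below 10⁻⁹ at every σ;
for σ > 6 the distribution is uniform to better than 10⁻⁸ in relative
terms and 1/2π is returned directly.

## Stage 2 — attractant production, diffusion and sensing

Attractant is produced at total rate q per wound, split equally over
n_sources point sources (default 36) placed along the wound-edge arc that
is producing (full circle, semicircle, etc.), from wounding until time τ,
and diffuses in 2D with diffusivity D. A single point source gives

    A(r, t) = −(q/4πD)·Ei(−r²/4Dt)                             t < τ
    A(r, t) =  (q/4πD)·[Ei(−r²/4D(t−τ)) − Ei(−r²/4Dt)]          t ≥ τ,

the closed form (via the exponential integral) of the time integral of
the 2D diffusion Green's function; fields from several sources and wounds
superpose. Splitting q over sources keeps the inferred rate comparable
across discretisations: doubling n_sources changes the field outside the
wound by well under 1%.

Cells read the field through receptor binding at steady state. The bound
complex C solves the binding quadratic C² − (κd + R0 + A)C + R0·A = 0; we
take the minus root, the only one satisfying 0 ≤ C ≤ min(R0, A) and
(R0 − C)(A − C) = κd·C. The predicted observed bias is the linear
front-rear readout across the cell body,

    bias(r, t) = m·[C(r − Δr, t) − C(r + Δr, t)] + b0,

with Δr = 15 μm (half a 30 μm macrophage) fixed, evaluated along the
radial direction to the assigned wound on the full superposed field.

Likelihood. Each stage-1 bin posterior of observed bias is approximated
as Normal(mean, sd); the stage-2 likelihood is the product over time and
space bins of the Gaussian density of the model's predicted bias at the
bin's representative point (bin centre in r and t, at the bin's centre
azimuth; bin-averaging is deliberately not done — at these bin widths the
bias is nearly linear across a bin). The innermost spatial bin (0–70 μm:
wound radius ~40 μm plus one macrophage diameter ~30 μm) is excluded,
because cells already at the wound are no longer gradient-driven. A floor
of 10⁻³ on bin sds prevents degenerate spikes.

Priors. Wild-type preset: q ~ U(0, 3500), D ~ TruncNormal(200, 50),
τ ~ TruncNormal(18, 3), m ~ U(0, 100), R0 ~ U(0, 10⁴), κd ~ U(0, 10⁴),
b0 ~ TruncNormal(0.02, 0.02); the informative D and τ priors carry over
earlier wound-attractant inference in the same system. Knockdown preset:
D ~ U(0, 1000) and τ ~ U(0, 25) instead, so that absent signal leaves
those marginals flat. The prior table specifies means and sds only; we
truncate at [0, ∞) on physical grounds, and b0 further to [0, 1] since it
lives on the bias scale.

Sampling. 40 walkers initialised from the prior, run (at full length) to
10⁶ steps or until the integrated autocorrelation times of D, τ and b0 —
the identifiable parameters; q, m, R0, κd enter the bias only through
near-degenerate combinations and are flagged "weakly identified" — change
by < 2% between checks and the chain exceeds 50× the largest of them.
Burn-in is twice the autocorrelation time, thinning half of it. Marginal
modes are reported from a Gaussian-KDE density on each marginal.

## The scenario generator

The generator produces the study's scenarios in silico: control wound
(full source ring), knockdown (sources silenced, geometry kept), half
wound (semicircular arc), and two competing wounds 300 μm apart (both
active, or one silenced). Defaults emulate the imaging: 40 cells starting
area-uniformly 50–250 μm from the wound centre, 25 min at 0.5-min frames,
wound radius 40 μm, step length 2 μm/frame (~4 μm/min).

Field → walk coupling. No generative recipe linking the attractant field
to (w, b, p) is implied by the two-stage analysis itself, so the
generator makes the coupling that the pipeline's consistency assumes: at
each step the local predicted bias `ob` is read off the true field and
the step is drawn with mixture weight w = clip(ob / b_fixed, 0, 1), bias
width from b_fixed = 0.95 and persistence width from p_fixed = 0.5. The
walk's observed bias w·b_fixed then *equals* the forward model's
prediction wherever it lies in [0, b_fixed], making stage-1's estimand
identical to stage-2's model prediction by construction. A first step
with no heading history substitutes a uniform draw for the persistent
component.

True parameters. D = 200 μm²/min and τ = 18 min are the model's
canonical operating point for this system (damage signals diffuse at
100–300 μm²/min and production lasts on the order of 20 min). The
remaining parameters have no canonical point values; we fixed one
realistic set before any recovery experiment and kept it: q = 1500 a.u./min and R0 = κd = 1000 a.u.
(mid-prior scales), b0 = 0.02 (the prior's centre), and m = 2.5 chosen so
the predicted observed bias peaks at ≈ 0.3 just outside the 70 μm
exclusion radius — the magnitude binned bias data reaches near a fresh
wound. These are also the defaults of `synthetic.DEFAULT_TRUE_PARAMS`.

What the generator does *not* emulate: cell–cell interactions, variable
step lengths and speeds, wound contraction, tracking noise and gaps, and
pupa-to-pupa heterogeneity. Passing recovery tests therefore demonstrates
the *inference machinery* is correct and calibrated under the model's own
assumptions, not that the model is adequate for any particular imaging
data set.

## Problem sizes and numerical choices

Recovery checks run at reduced MCMC lengths chosen for stable marginal
modes on synthetic data: stage-2 fits use 40 walkers × 12 000 steps (the
D and τ modes move by ≲ 2% on doubling), stage-1 per-bin fits 10 walkers ×
1500–2500 steps, and interval-coverage replicates 15 tracks × 25 steps ×
20 repetitions. The acceptance script reports: recovery of D and τ from
forward-model bin data (noise sd 0.005, 70–230 μm × 0–25 min bins, flat
D/τ priors), and the end-to-end pipeline's D mode on the default control
scenario under wild-type priors. On the noiseless version of the first
problem the recovered modes are D = 200.2 μm²/min and τ = 18.0 min, so
the residual spread seen with noise is data noise, not estimator bias.

Degenerate inputs are handled explicitly: empty bins return the prior
(flagged), zero-length steps are excluded, r = 0 evaluations of the
Green's function raise, wounds with no active sources yield bias = b0
everywhere, and stage-2 refuses to fit when every bin falls in the
exclusion zone.

## Known limitations

- The two-wound stage-2 likelihood places bin representative points
  relative to the first wound only; the default stage-2 analysis uses
  radial-temporal bins around a single wound.
- Marginal posterior modes from KDE are reported to match how posterior
  point estimates are usually read off; they inherit KDE bandwidth
  sensitivity of order a few percent of the marginal's sd.
- q, m, R0, κd are reported but should not be interpreted individually;
  only their combination is constrained by bias data.
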