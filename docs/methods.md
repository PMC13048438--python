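# Methods

## Setting and conventions

A trial places N ∈ {7..10} avatars in a square arena of half-extent 75 m
with four circular candidate sites centred at (±40, ±40) m. Three sites
have radius 12 m; the correct site is strictly larger: 15 m (*easy*), 14 m
(*medium*) or 13 m (*hard*), i.e. a relative radius excess of 25%, 16.6%
and 8.3%. Avatars move at a fixed 8 m/s and rotate at π rad/s; trials end
at the first whole second at which every avatar is inside one site disc
(consensus) or at 100 s. A successful (correct-consensus) trial earns
`100 − consensus time` gold points.

Coordinates are arena-centred, x right / y up, in meters; time is 0-based
seconds; analysis bins are half-open `[t, t+1)` with all per-second
covariates read at the bin start. Raw trajectories are logged at 10 Hz by
default; all published-style analyses run on the 1 Hz bin-start resample.

Three information conditions: *global* (site sizes visible from anywhere),
*local* (a site's size only visible within `local_visibility_radius`,
default 25 m — a configuration knob, since only the geometry of the
close-range zone is fixed by the task design), and *informed minority*
(global visibility plus two avatars told the correct site outright).

## The synthetic-data generator

The generator is this package's own behavioural model; it is designed so
that **every covariate of the downstream fitted models has a true,
recoverable counterpart**, not to imitate human micro-behaviour. Per agent
and trial:

1. **Perception.** Each site's radius is perceived once with additive
   N(0, σ²) noise (default σ = 1 m — large enough that the 1 m radius gap
   of *hard* trials is genuinely ambiguous while the 3 m gap of *easy*
   trials rarely is). In the local condition the estimate is revealed only
   on first entering the visibility zone.
2. **Target choice.** An agent without a target picks the known site
   maximising `perceived radius + w_social × supporter count`
   (`w_social = 0.5` m per supporter); with nothing known (local), it
   travels to the nearest unexplored site centre. Informed agents head to
   the correct site.
3. **Switch hazard.** Each second, an agent holding a target abandons it
   with probability `logistic(α + β_ds·ds + β_d·d + β_τ·τ)` where `ds` is
   DeltaSocial over the other agents' current targets, `d` the distance to
   the target centre and `τ` the occupancy time. Defaults: α = −3.5
   (a few-percent baseline hazard per second), β_ds = 0.3, β_d = 0.03 /m,
   β_τ = −0.05 /s. The destination is the most-supported alternative
   (ties: larger perceived radius, then label order). Informed agents
   multiply `w_social` and `β_ds` by `informed_social_discount`
   (default 0) and at discount 0 never leave the correct site.
4. **Kinematics.** Rotate toward the goal at ≤ π rad/s, advance at 8 m/s
   once the heading error is below 15°, halt at a uniformly drawn interior
   point of the target disc; Euler integration at the sample rate.
   Avatar–avatar collisions are ignored and a site disc can hold the whole
   group.

All randomness in a trial is pre-drawn from one per-trial seed
(`SeedSequence(master_seed, index)`), so a trial's outcome is a pure
function of its seed regardless of batching, and batch simulation is fully
vectorised across trials.

Two presets define reference conditions. `AgentParams.noiseless()` (σ = 0,
no social terms, hazard off) makes every agent travel straight to the
largest site: success is 100% by construction and consensus time is travel
time. `AgentParams.random_policy()` is the chance-level baseline:
perception disabled, initial site choice uniform per agent, and a strong
majority-following hazard (α = −2, β_ds = 1) so that the group almost
surely converges within the time limit; destination ties are broken
uniformly at random rather than by label order, because a deterministic
label preference would bias which site wins and break the symmetry that
makes the correct site win exactly 1/4 of the time.

### Calibration of the distance coefficient

The event-building rules (below) are deliberately those a trajectory
analyst would use, and they are lossy: a switch only counts if the new
opinion is *sustained* for at least a further second, and opinions are
invisible while an avatar rotates in place. Simulation shows two
systematic consequences for the distance effect specifically: 1-second
"excursions" (switch followed by an immediate switch-back or switch-on)
are filtered out yet occur disproportionately at large distance (a fresh
target is typically far away), while switches very close to the old site
are often missed because the post-switch rotation spans the next bin.
With a weak true β_d the measured distance effect is attenuated to zero
even though a fit on the generator's internal covariates recovers it
exactly. The default β_d = 0.03 /m is therefore chosen strong enough that
its sign and approximate magnitude survive the measurement chain; β_ds and
β_τ are essentially undistorted (recovered within ~±15% and ~±10%). A
post-commitment refractory period (`refractory_s`) exists as an
alternative mechanism but defaults to 0: gating the hazard after each
commitment concentrates forced zero-hazard exposure at large distances and
biases the fitted slope negative.

What passing the recovery tests does and does not show: the pipeline
faithfully measures a hazard-form opinion process under this kinematic
model; it does not show that human participants follow such a process, and
the generator makes no attempt to reproduce human success rates, reaction
times, persuasion behaviour or inter-individual variability (there are no
per-agent random effects — the participant random-intercept variance in
recovery fits is genuinely ~0).

## Opinion extraction

An avatar *supports* a site when **moving toward** it — speed above
0.1 m/s and the angle between the velocity and the line to the site centre
below 30° — or **occupying** it: speed ≤ 0.1 m/s with the avatar's centre
point strictly inside the disc (the avatar footprint is ignored). The
0.1 m/s floor replaces an exact zero-speed test, which is fragile under
finite differencing. If two sites fall within the cone, the smaller angle
wins, then the nearer site. Classification happens at each 1 Hz bin start
with velocities taken as central finite differences on the trajectory's
native grid (one-sided at the ends); classifying on raw-grid velocities
rather than 1 Hz displacement averages keeps the "not moving" state crisp
during turns and arrivals.

## Metrics

DeltaSocial counts the **other** group members only (range ±(N−1)); the
focal individual is excluded because a self-inclusive count would make the
extreme values unreachable. The centre of mass **includes** the focal
avatar. Approach speed is `‖v‖ × (−Δd(p, COM)/Δt)` with the distance
derivative taken as a symmetric finite difference across a 1 s window
(m²/s², positive when actively approaching); its sign flips with the
focal velocity and it vanishes for tangential motion. The distance
covariate of the switching models is the distance to the supported site's
**centre** (not its boundary).

## Switch events

Moving samples: every whole second spent moving toward a site, provided a
successor bin exists (terminal bins are dropped since the switch indicator
is defined by the successor). `Switch = 1` iff the next bin supports a
*different* site in moving mode and the bin after that confirms the new
site (sustained ≥ 1 s); lost opinions, arrivals and unsustained excursions
are `Switch = 0`. Still samples mirror this for occupying seconds, with
`TimePassed` the occupancy duration in seconds (1, 2, … along a contiguous
occupation — the clock restarts after ≥ 1 s of interruption). A departure
only counts as a switch when it is a sustained move toward an alternative.
`OnCorrect` flags support for the correct site at the current bin.

## Statistical layer

`fit_model` takes a declarative spec (response, fixed terms incl.
interactions and `I(delta_social**2)`-style quadratics, random-intercept
grouping columns, family). Gaussian responses use OLS (no random terms) or
statsmodels `MixedLM` with variance components for crossed random
intercepts, REML. Binomial responses use this package's Laplace
random-intercept logistic model: penalized IRLS finds the joint
(β, u) mode for candidate variance components, a Nelder–Mead search
maximises the Laplace marginal over the log-variances, and a final L-BFGS
refinement maximises it jointly over (β, log σ²) with the random effects
profiled out. The result matches `lme4::glmer` (default Laplace) to ~0.5%
on coefficients and log-likelihood in the cross-check test. On
non-convergence the fit falls back to a fixed-effects GLM with
cluster-robust covariance by the first grouping column, flagged in the
result. Reported coefficients use treatment coding (reference levels:
condition *global*, difficulty *easy*).

The Type II Wald χ² ANOVA tests each term under sum-to-zero coding in a
refit containing all other terms except interactions that involve the
tested term; the statistic is `b' V⁻¹ b` over the term's coefficients.
This equals `car::Anova(type = 2, test = "Wald")` applied to the
corresponding reduced model (for interaction terms, the full model) and
reduces to the squared z statistic for 1-df terms. Under a simulated null
the factor test's type-I error is ~5% at α = 0.05 (4.97% in a 4,000-rep
gaussian null at n = 120).

EMM pairwise contrasts average model predictions over the levels of the
other factors with equal weights, covariates at their observed means, on
the linear-predictor scale; all pairs of one factor within one model form
the FDR family, adjusted by Benjamini–Hochberg. Predicted switch curves
are fixed-effect probabilities with random effects at zero.

## Numerical and degenerate-input choices

Logistic weights are clipped at 1e-10; variance components are optimised
on the log scale clipped to e⁻¹²..e⁸; a variance estimate at the lower
boundary reproduces the plain GLM to ~1e-4. `α = −∞` is honoured exactly
(hazard 0). Consensus is tested on the 1 Hz grid, so detected consensus
times carry ≤ 1 s discretisation relative to a continuous check. Wilson
intervals are used for success proportions. Empty summary cells yield NaN
time fields rather than errors; single-level factors, singular designs,
non-0/1 binomial responses, out-of-range p-values and duplicate event keys
raise descriptive errors.

## Problem sizes

The bundled checks use 10,000 trials for the chance baseline, 200 trials
per design cell for the calibration sweep, 500 trials (plus 50 replicates
of 200) for parameter recovery and 1,000 repetitions of an n = 120
gaussian null for ANOVA calibration — sizes at which every Monte-Carlo
margin in the tests is several standard errors wide on a single CPU.

## Known limitations

Local-condition agents commit to the first site they can evaluate and
thereafter compare options only through social counts, so local success
rates sit near chance — the exploration–comparison strategies real
participants use are out of scope. The simulator checks consensus only at
whole seconds; the original platform presumably checked continuously.
GLMMs support independent random intercepts only (no random slopes), and
group-level grouping factors in simulated data carry no true variance.
The Laplace approximation, like `glmer`'s, can be biased for very sparse
binary clusters.
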