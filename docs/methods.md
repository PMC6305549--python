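# Methods

This note documents the models, algorithms and numerical choices behind
`mcdiff`, and what the synthetic studies do and do not demonstrate.

## Signal models

All internal quantities are SI: b-values in s/m², diffusivities in m²/s,
times in s, radii in m.  Readers treat incoming b-values below 1e5 as
s/mm² and convert them; the two unit systems differ by six orders of
magnitude, so the heuristic cannot misfire on physical data.  Orientations
use n(θ, φ) = (sinθ cosφ, sinθ sinφ, cosθ), θ polar from +z, φ azimuth
from +x.

Compartments:

- **Ball** — isotropic Gaussian, S = exp(−b d).
- **Stick** — zero-radius cylinder, S = exp(−b d (n·g)²).
- **Tensor** — full Gaussian ellipsoid.  The secondary eigenvector is
  constructed by rotating a *canonical perpendicular* of n (the component
  of ẑ orthogonal to n, with an x̂ fallback within 1e-6 of the poles)
  about n by ψ.  Because the frame construction is chiral, flipping the
  axis (n → −n) represents the same tensor only if ψ → −ψ (mod π); the
  sampler's hemisphere fold applies that co-transformation.
- **Watson-dispersed stick** (NODDI intra-neurite) — the stick averaged
  over a Watson orientation distribution f(n; μ, κ) ∝ exp(κ(μ·n)²),
  normalised via M(1/2, 3/2, κ).
- **Dispersed zeppelin** (NODDI extra-cellular) — Gaussian signal under
  the Watson-averaged cylindrically symmetric tensor.  The average has
  eigenvalue τ(κ) = ⟨(μ·n)²⟩ along μ and (1−τ)/2 transverse, so the
  trace d∥ + 2d⊥ is preserved for every κ.  By default d⊥ is coupled to
  the intra fraction by tortuosity, d⊥ = d∥(1 − ν_ic) with
  ν_ic = w_in/(w_in + w_ex); `tortuosity=False` fixes d⊥ = d∥/2 instead.
- **Restricted cylinders** (CHARMED intra-axonal) — parallel Gaussian
  term exp(−4π²|q|²(n·g)²(Δ−δ/3)d) times a Neuman-type perpendicular
  term per radius, summed over a radius grid with gamma-distributed
  weights.  Both factors of the perpendicular exponent are
  nondimensionalised by d·TE; the exponent is clamped at zero so the
  attenuation never exceeds one where the small-radius expansion breaks
  down.  |q| is derived from b and the timing via b = 4π²|q|²(Δ−δ/3).

Composite models combine compartments as S0·Σ wᵢSᵢ with the last volume
fraction derived (1 − Σ of the sampled ones).  Sampled-parameter counts,
including S0: BallStick_in1/2/3 = 4/7/10, Tensor = 7, NODDI = 6,
CHARMED_in1/2/3 = 11/15/19.

Fixed constants (all overridable through `build_model(..., constants=...)`):
Stick/Ball&Stick d = 1.7e-9 m²/s, free-water d = 3.0e-9 m²/s, NODDI
intra d = 1.7e-9 m²/s, iso d = 3.0e-9 m²/s, extra-cellular d∥ = 1.7e-9
m²/s; CHARMED radius grid of 6 radii equally spaced on [1.5, 9] µm with
gamma(shape 2.0, scale 1.5 µm) weights normalised to sum one.  These are
conventional literature values; they pin the parameter counts above.

## Watson integrals

Both Watson averages are evaluated by quadrature, not closed-form
shortcuts.  The dispersed stick uses a fixed product rule on the sphere —
Gauss-Legendre order 64 in cosθ × 72-point trapezoid in azimuth
(4,608 nodes) — with the Watson weights self-normalised on the node set,
which makes b=0 columns exactly one and cancels the overflow-safe
exponent shift.  Against adaptive 2-D integration the rule is accurate to
better than 1e-8 relative for κ ≤ 60 and b·d ≤ ~10 (the sampled regime;
the κ prior is capped at 64).  Above κ = 100 a μ-frame substitution
y = κ(1−u²) with 64-point Gauss-Legendre on y ∈ [0, min(κ, 40)] takes
over, handling arbitrarily sharp concentrations (the κ→∞ limit matches
the stick to ~1e-4).  τ(κ) for the zeppelin uses 96-point Gauss-Legendre
on [0, 1] with the same overflow shift.

For model evaluation the stick table exp(−bⱼ d (n_k·gⱼ)²) is precomputed
once per scheme, so each posterior evaluation costs one exponential over
the nodes and a vector-matrix product.

## Posterior

The Offset-Gaussian log-likelihood is
−Σ(O−√(S²+σ²))²/(2σ²) − m·ln(σ√2π); √(S²+σ²) approximates the mean of a
Rician magnitude measurement, making the likelihood well behaved at low
SNR without the cost of Bessel functions.  σ is a required input (scalar
or per-voxel map); in simulations it is known by construction, σ = S0/SNR.

Priors are uniform boxes (fractions [0,1]; diffusivities [0, 1e-8] m²/s;
θ ∈ [0, π], φ ∈ [−π, π], ψ ∈ [0, π]; κ ∈ [0, 64]; S0 ∈ [0, 1e7]) with
normalisation constants dropped — Metropolis ratios only need
differences.  Structural priors: sampled fractions satisfy Σ ≤ 1, and
tensor diffusivities are strictly decreasing.  Infeasible points carry
log-prior −∞ and are rejected rather than reflected, preserving proposal
symmetry.

MLE initialisation runs bounded Powell searches from the model defaults
plus 4 seeded perturbations (5 starts total) and returns the best
feasible point; Tensor-like estimates are post-processed by sorting the
diffusivities and recomputing θ, φ, ψ from the permuted eigenvector
frame, which leaves the predicted signal unchanged to 1e-10.

## Sampler

Metropolis-Within-Gibbs cycles through the sampled parameters in
declaration order, proposing each from a centred Normal and accepting
with min(1, π(Y)/π(X)).  ψ proposals wrap modulo π.  After every θ or φ
update the axis is folded to the canonical hemisphere (non-negative x,
ties toward non-negative y), rewriting both angles — and negating a tied
ψ modulo π — without changing the represented signal.

Default initial proposal stds: 0.25 for fractions, 0.1 rad for angles,
1e-10 m²/s for diffusivities, 1 for κ, and 5% of the voxel's mean b0
intensity for S0.

Adaptation strategies (batch size 50 throughout):

- **SCAM** — after t_s = 100 sweeps, σᵢ = 2.4·√(Var(chain history) + εᵢ)
  with floor εᵢ = 1e-5·σᵢ(0).  The 2.4·(Var+ε) form assigns a variance to
  a standard deviation; the square-root reading is dimensionally
  consistent with the classic scaling (proposal variance 2.4²·Var), and
  `scam_literal=True` restores the verbatim form.
- **FSL** — σᵢ ← σᵢ·(a+1)/(b−a+1) after each batch (a accepted of
  b = 50), steering acceptance toward 0.5; adaptation never stops, so
  strict ergodicity is forfeited.
- **AMWG** — ln σᵢ ± δ(n) after batch n depending on whether the batch
  acceptance exceeded 0.44 (ties take the shrink branch).  The default
  schedule is δ(n) = 1/n: it adapts aggressively in the first few batches
  (necessary to traverse the ~2 log-units between the default S0 proposal
  width and its posterior scale within a 10,000-sample run) while still
  diminishing, so ergodicity holds.  δ(n) = min(0.01, n^(−1/2)) is
  available as `amwg_schedule="sqrt"`.

Default run lengths: burn-in 200 with MLE initialisation, 3,000 from the
a-priori default start; thinning 1 (estimators using all samples beat
thinned ones, which the test suite demonstrates).  Volume-level sampling
derives each voxel's RNG stream from the global seed and the voxel's flat
index, so results are bit-identical regardless of processing order or
parallelism.

## Diagnostics

Multivariate ESS uses batch means with batch size ⌊√s⌋ and ⌊s/⌊√s⌋⌋
batches (trailing samples dropped), the standard strongly consistent
choice; sample and batch-means covariances both use the ddof=1
convention, making the p=1 case coincide with univariate batch-means ESS
exactly.  Degenerate (stuck) chains are flagged and reported with
ESS = 0 instead of raising.  Run-length planning rounds ŝ = s·W/ESS up to
the nearest 1,000 for reporting and returns the raw value alongside.
Posterior summaries use circular mean/std for ψ (period π); ESS itself is
defined on linear moments, a documented caveat for strongly dispersed
orientation posteriors.

## Synthetic studies

The phantom generator draws ground-truth parameters uniformly inside
narrower ranges than the prior support (fractions [0.2, 0.8] redrawn
until the simplex holds; diffusivities [5e-11, 5e-9] m²/s, sorted for
Tensor blocks; angles [0, π]; κ [0.1, 60]), fixes S0 = 1e4, and applies
Rician noise at SNR 30 (σ = 333.3).  With `noise=False` the generator
stores the expected magnitude signal √(S²+σ²), so the truth is the exact
zero-residual maximum of the Offset-Gaussian likelihood — the right
reference for optimiser and recovery checks.

Two preset schemes emulate common protocols: a 3-shell 134-volume scheme
(b = 1000/2000/3000 s/mm², 30/40/50 directions, 14 interleaved b0,
Δ/δ/TE = 45.8/16.3/90 ms) and a 4-shell 552-volume scheme
(b = 1000/3000/5000/10000 s/mm², 64/64/128/256 directions, 40 b0,
Δ/δ/TE = 21.8/12.9/57 ms).  Directions come from electrostatic-repulsion
relaxation of a seeded random start (200 fixed iterations) — approximately
uniform hemisphere coverage, not any scanner's exact table.

What the phantoms do **not** emulate: spatial structure (each voxel is
independent), partial voluming and crossing-fibre mixtures beyond the
model's own compartments, eddy/motion artefacts, spatially varying σ, and
Gibbs ringing.  Passing recovery tests therefore shows correctness of the
inference machinery under the model's own assumptions, not robustness to
real-data model mismatch.

Experiment scales are desk-sized by design — 50–200 voxels and 1–10
trials with 2,000–10,000 samples per chain, against tens of thousands of
voxels in a full study — chosen so the whole suite runs on one CPU core
in minutes.  The conclusions exercised (adaptation reaching its target
rate, ESS gains of adaptation, more-samples-beats-thinning, MLE
initialisation removing burn-in) are qualitative and scale-free; the
harness accepts larger settings through its arguments.

## Known limitations

- Fixed compartment constants stand in for per-study calibration; they
  are config-exposed but not fitted.
- No Rician or noncentral-χ exact likelihoods; the Offset-Gaussian
  approximation degrades below SNR ≈ 3.
- No multi-chain (Gelman-Rubin) diagnostics and no spectral ESS variants.
- Single-threaded reference implementation; the voxel-independence
  contract makes external parallelisation trivial but none is built in.
- CHARMED's perpendicular term is a small-radius expansion; the clamp at
  unit attenuation is a validity guard, not a physical model, for the
  largest radii of the default grid.
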