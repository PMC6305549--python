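# mcdiff

Bayesian sampling of diffusion-MRI multi-compartment microstructure models
with component-wise adaptive Metropolis MCMC.

Point estimates of microstructure parameters (axon density, orientation,
dispersion) hide how well the data constrain them.  `mcdiff` recovers the
full per-voxel posterior of popular diffusion compartment models —
Ball&Stick (1–3 fibres), Tensor, NODDI and CHARMED (1–3 restricted
compartments) — yielding uncertainty (std) and inter-parameter correlation
maps next to the usual mean maps.  It is aimed at dMRI researchers who
want calibrated uncertainties from multi-shell acquisitions, and at
methodologists studying MCMC behaviour on these models.

## Model

A composite model predicts the signal as a volume-fraction weighted sum of
compartment attenuations,

    S(x) = S0 · Σᵢ wᵢ Sᵢ(x),

and the posterior combines an Offset-Gaussian likelihood for magnitude MRI
data with flat priors on a constrained feasible set:

    ln p(x | O) ∝ −Σⱼ (Oⱼ − √(Sⱼ(x)² + σ²))² / (2σ²) + ln p(x),

where σ is the noise standard deviation of the underlying complex data.
Structural priors keep sampled volume fractions on the simplex and force
strictly decreasing Tensor diffusivities (d∥ > d⊥₁ > d⊥₂) to prevent
orientation aliasing.

Sampling is Metropolis-Within-Gibbs: one parameter at a time, symmetric
Normal proposals centred on the current value (circular modulo π for the
tensor rotation ψ; polar/azimuth pairs re-folded onto a canonical
hemisphere after every update).  Proposal widths can adapt by three
strategies — SCAM (empirical-variance scaling), FSL batch rescaling
toward acceptance 0.5, and AMWG (diminishing log-std steps toward the
component-wise optimum 0.44).  Chains are diagnosed with the multivariate
Effective Sample Size

    ESS = s · (|Λ_s| / |Σ_s|)^(1/p),

(Λ_s sample covariance, Σ_s batch-means Monte-Carlo covariance), and the
closed-form threshold W(p, α, ε) = 2^(2/p)π/(pΓ(p/2))^(2/p) · χ²₁₋α,p/ε²
tells you how many effective samples suffice for a (1−α) confidence
region with relative precision ε — about 2,200 at α = 0.05, ε = 0.1,
nearly independently of p.

## Worked example

Simulate one Ball&Stick voxel on a synthetic 3-shell, 134-volume scheme at
SNR 30, start the chain at the maximum-likelihood estimate, and sample:

```python
from mcdiff import (build_model, fit_mle, min_ess_threshold,
                    multivariate_ess, posterior_summaries, preset_scheme,
                    required_samples, run_chain, simulate_ground_truth,
                    SamplerConfig)

scheme = preset_scheme("rls", seed=0)        # 3-shell, 134-volume protocol
model = build_model("BallStick_in1")         # S0, FS, theta, phi  (p = 4)
phantom = simulate_ground_truth(model, n_voxels=1, scheme=scheme,
                                snr=30, seed=2)
voxel = phantom.voxel(0)

mle = fit_mle(model, voxel, seed=0)
chain = run_chain(model, voxel,
                  SamplerConfig(n_samples=10000, burn_in=0,
                                strategy="amwg", seed=3),
                  init=mle.x)

summary = posterior_summaries(chain)
report = multivariate_ess(chain)
w = min_ess_threshold(model.p, alpha=0.05, epsilon=0.1)
```

This prints:

```
true FS      : 0.357
posterior FS : 0.367 +/- 0.006
S0-FS corr   : -0.56
multivariate ESS = 1989 of 10000 samples
W(4, 0.05, 0.1)  = 2108  ->  recommended s_hat = 10599
```

The posterior mean of the stick fraction (FS) sits within two posterior
standard deviations of the ground truth; S0 and FS are anti-correlated
(raising the baseline signal can be traded against the stick weight); and
the 10,000-sample AMWG chain carries 1,989 effective samples — slightly
short of the 2,108 needed for a 95% confidence region at 90% relative
precision, so the planning rule recommends extending the run to ~10,600
samples.

The same machinery is available from the shell:

```bash
mcdiff simulate --model BallStick_in1 --voxels 200 --scheme rls --seed 1 --out phantom/
mcdiff sample --model BallStick_in1 --data phantom/signals.nii.gz \
    --mask phantom/mask.nii.gz --bval phantom/scheme.bval \
    --bvec phantom/scheme.bvec --protocol phantom/protocol.txt \
    --sigma 333.3 --strategy amwg --samples 10000 --seed 42 --out fit/
mcdiff plan --p 6                      # ESS target for NODDI
mcdiff benchmark-strategies --out strategies.tsv
mcdiff plan-samples --models BallStick_in1,NODDI --out plan.tsv
```

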