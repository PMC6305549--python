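"""Component-wise Metropolis-Within-Gibbs (MWG) sampling.

One MWG iteration ("sweep") cycles through all p sampled parameters,
proposing each from a symmetric Normal centred on the current value and
accepting with the Metropolis probability min(1, π(Y)/π(X)).  Orientation
parameters get special proposals: ψ uses a circular Normal modulo π, and a
(θ, φ) polar/azimuth pair is re-folded after every update so the
represented axis lies in the canonical hemisphere (non-negative x
component), which is harmless because every compartment signal is
antipodally symmetric.

Three proposal-adaptation strategies are available next to fixed proposals
(``none``):

``scam``
    Single Component Adaptive Metropolis: after ``t_start`` sweeps the
    proposal std of each component tracks the empirical marginal std of
    its own chain history, scaled by 2.4, with a small floor ε_i that
    prevents collapse.
``fsl``
    Batch rescaling as in FSL BedpostX: after every batch of 50 proposals
    the std is multiplied by (a+1)/(b−a+1) with a accepted of b proposed,
    steering the acceptance rate toward 0.5.  Adaptation never stops.
``amwg``
    Adaptive MWG: after the n-th batch of 50 sweeps, log σ_i moves up or
    down by a diminishing amount δ(n) depending on whether the batch
    acceptance rate exceeded the 0.44 optimum for component-wise updates.

Out-of-bounds or constraint-violating candidates are rejected through the
−∞ log-prior rather than reflected, preserving proposal symmetry.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import bayes
from .acquisition import cart_to_sphere, sphere_to_cart
from .compartments import CompositeModel

__all__ = [
    "SamplerConfig",
    "ProposalState",
    "Chain",
    "metropolis_accept",
    "fold_axis",
    "propose_component",
    "mwg_sweep",
    "adapt_scam",
    "adapt_fsl",
    "adapt_amwg",
    "scam_std",
    "fsl_multiplier",
    "amwg_delta",
    "run_mwg",
    "run_chain",
    "sample_volume",
]

AR_TARGETS = {"amwg": 0.44, "fsl": 0.5}


@dataclasses.dataclass
class SamplerConfig:
    """Run-length and adaptation settings for one chain."""

    n_samples: int = 10000
    burn_in: int | None = None   # None: 200 with MLE init, 3000 otherwise
    thinning: int = 1
    strategy: str = "amwg"       # none | scam | fsl | amwg
    seed: int = 0
    init: str = "mle"            # "mle" | "default"
    batch_size: int = 50
    t_start: int = 100           # SCAM adaptation start (sweeps)
    scam_literal: bool = False   # σ = 2.4(Var+ε) instead of 2.4 √(Var+ε)
    amwg_schedule: str = "paper"  # "paper": δ(n)=1/n; "sqrt": min(0.01, n^-1/2)
    mle_restarts: int = 5
    store_sigma_trace: bool = False

    def resolved_burn_in(self) -> int:
        if self.burn_in is not None:
            return self.burn_in
        return 200 if self.init == "mle" else 3000


@dataclasses.dataclass
class ProposalState:
    """Per-component proposal distributions and their adaptation state."""

    sigma: np.ndarray                 # current proposal stds, > 0
    families: list                    # per component: normal|circular_pi|polar|azimuth
    partners: np.ndarray              # partner index for polar/azimuth, else -1
    psi_partners: np.ndarray | None = None  # ψ tied to a polar angle, else -1
    strategy: str = "none"
    batch_size: int = 50
    t_start: int = 100
    scam_literal: bool = False
    amwg_schedule: str = "paper"

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float).copy()
        if np.any(self.sigma < 0):
            raise ValueError("proposal stds must be non-negative")
        self.sigma0 = self.sigma.copy()
        self.epsilon = 1e-5 * self.sigma0          # SCAM floor ε_i
        p = len(self.sigma)
        if self.psi_partners is None:
            self.psi_partners = np.full(p, -1, dtype=int)
        self.batch_accepts = np.zeros(p, dtype=int)
        self.batch_proposals = 0                   # sweeps in current batch
        self.n_batches = 0
        # running moments of the component chains (Welford), for SCAM
        self._mean = np.zeros(p)
        self._m2 = np.zeros(p)
        self._t = 0

    @property
    def ar_target(self) -> float:
        return AR_TARGETS.get(self.strategy, 0.44)

    def observe(self, x: np.ndarray):
        """Feed the position at the end of a sweep into the running moments."""
        self._t += 1
        delta = x - self._mean
        self._mean += delta / self._t
        self._m2 += delta * (x - self._mean)

    def marginal_variance(self) -> np.ndarray:
        if self._t < 2:
            return np.zeros_like(self._mean)
        return self._m2 / self._t


def metropolis_accept(logpost_current: float, logpost_candidate: float,
                      uniform_draw: float) -> bool:
    """Symmetric-proposal Metropolis acceptance test.

    Accepts iff ln(u) < log π(Y) − log π(X); a −∞ candidate is always
    rejected and a candidate at least as probable is always accepted.
    """
    if not math.isfinite(logpost_current):
        raise ValueError("current log-posterior must be finite")
    if logpost_candidate == -math.inf:
        return False
    diff = logpost_candidate - logpost_current
    if diff >= 0.0:
        return True
    return uniform_draw < math.exp(diff)


def _fold_axis(theta: float, phi: float) -> tuple[float, float, bool]:
    n = sphere_to_cart(theta, phi)
    flipped = n[0] < 0.0 or (n[0] == 0.0 and n[1] < 0.0)
    if flipped:
        n = -n
    th, ph = cart_to_sphere(n)
    return th, ph, flipped


def fold_axis(theta: float, phi: float) -> tuple[float, float]:
    """Canonicalise an axis to the hemisphere with non-negative x.

    Ties (x = 0) break toward non-negative y.  The returned angles satisfy
    θ ∈ [0, π], φ ∈ [−π/2, π/2] and represent the same axis.  When the
    axis carries a frame-rotation angle ψ (Tensor-like compartments), a
    fold that flips the axis must be accompanied by ψ → −ψ (mod π) to
    leave the represented tensor frame — and hence the signal — unchanged;
    the sampler applies that co-transformation automatically.
    """
    th, ph, _ = _fold_axis(theta, phi)
    return th, ph


def _apply_fold(y: np.ndarray, i_theta: int, i_phi: int,
                state: ProposalState):
    th, ph, flipped = _fold_axis(y[i_theta], y[i_phi])
    y[i_theta], y[i_phi] = th, ph
    i_psi = state.psi_partners[i_theta]
    if flipped and i_psi >= 0:
        y[i_psi] = (-y[i_psi]) % math.pi


def canonicalize(x: np.ndarray, state: ProposalState) -> np.ndarray:
    """Fold every polar/azimuth pair and wrap ψ into [0, π)."""
    x = np.asarray(x, dtype=float).copy()
    for i, fam in enumerate(state.families):
        if fam == "polar":
            _apply_fold(x, i, state.partners[i], state)
        elif fam == "circular_pi":
            x[i] = x[i] % math.pi
    return x


def propose_component(i: int, x: np.ndarray, state: ProposalState,
                      rng: np.random.Generator) -> np.ndarray:
    """Candidate vector differing from ``x`` in component i only (a paired
    θ/φ fold may rewrite both angles — and a tied ψ — without changing the
    represented axis frame)."""
    y = x.copy()
    step = state.sigma[i] * rng.standard_normal()
    fam = state.families[i]
    if fam == "circular_pi":
        y[i] = (x[i] + step) % math.pi
    elif fam in ("polar", "azimuth"):
        y[i] = x[i] + step
        j = state.partners[i]
        if fam == "polar":
            _apply_fold(y, i, j, state)
        else:
            _apply_fold(y, j, i, state)
    else:
        y[i] = x[i] + step
    return y


def mwg_sweep(x: np.ndarray, logpost_x: float, state: ProposalState,
              logpost, rng: np.random.Generator):
    """One MWG iteration: cycle through all components in declared order,
    proposing from the partially updated position.

    Returns ``(x, logpost_x, accepted)`` with ``accepted`` a boolean flag
    per component.
    """
    p = len(x)
    accepted = np.zeros(p, dtype=bool)
    for i in range(p):
        y = propose_component(i, x, state, rng)
        ly = logpost(y)
        if metropolis_accept(logpost_x, ly, rng.random()):
            x, logpost_x = y, ly
            accepted[i] = True
    state.batch_accepts += accepted
    state.batch_proposals += 1
    return x, logpost_x, accepted


def scam_std(sigma0: float, variance: float, epsilon: float,
             literal: bool = False) -> float:
    """SCAM proposal std from the empirical marginal variance.

    The default reading is σ = 2.4·√(Var + ε), dimensionally consistent
    with a proposal variance of 2.4²(Var + ε); ``literal=True`` applies
    the 2.4·(Var + ε) form verbatim.
    """
    if literal:
        return 2.4 * (variance + epsilon)
    return 2.4 * math.sqrt(variance + epsilon)


def adapt_scam(state: ProposalState, t: int,
               history: np.ndarray | None = None):
    """Update all proposal stds from the chains' marginal variances.

    No-op for t ≤ t_start.  ``history`` (t × p positions) may be passed
    explicitly; by default the running moments fed via ``state.observe``
    are used.
    """
    if t <= state.t_start:
        return
    if history is not None:
        var = np.var(np.asarray(history, dtype=float), axis=0)
    else:
        var = state.marginal_variance()
    if state.scam_literal:
        state.sigma = 2.4 * (var + state.epsilon)
    else:
        state.sigma = 2.4 * np.sqrt(var + state.epsilon)


def fsl_multiplier(a: int, b: int) -> float:
    """Batch rescaling factor (a+1)/(b−a+1) for a accepted of b proposals."""
    return (a + 1.0) / (b - a + 1.0)


def adapt_fsl(state: ProposalState):
    """Rescale every proposal std by (a+1)/(b−a+1) and start a new batch."""
    b = state.batch_proposals
    state.sigma *= (state.batch_accepts + 1.0) / (b - state.batch_accepts + 1.0)
    state.batch_accepts[:] = 0
    state.batch_proposals = 0
    state.n_batches += 1


def amwg_delta(n: int, schedule: str = "paper") -> float:
    """Diminishing adaptation amount δ(n) after the n-th batch."""
    if schedule == "paper":
        return 1.0 / n
    if schedule == "sqrt":
        return min(0.01, n ** -0.5)
    raise ValueError(f"unknown AMWG schedule {schedule!r}")


def adapt_amwg(state: ProposalState):
    """Move log σ_i by ±δ(n): up when the batch acceptance rate exceeded
    the 0.44 target, down otherwise (ties included)."""
    state.n_batches += 1
    delta = amwg_delta(state.n_batches, state.amwg_schedule)
    ar = state.batch_accepts / state.batch_proposals
    factor = np.where(ar > state.ar_target, math.exp(delta), math.exp(-delta))
    state.sigma *= factor
    state.batch_accepts[:] = 0
    state.batch_proposals = 0


@dataclasses.dataclass
class Chain:
    """Stored MCMC output of one voxel (post burn-in, thinned)."""

    samples: np.ndarray          # (s, p)
    log_posterior: np.ndarray    # (s,)
    accepted: np.ndarray         # (total sweeps, p) acceptance flags
    parameter_names: list
    seed: int
    burn_in: int
    thinning: int
    sigma_final: np.ndarray
    sigma_trace: np.ndarray | None = None  # (n_batches+1, p) if recorded
    init: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def p(self) -> int:
        return self.samples.shape[1]

    def acceptance_rates(self, last: int | None = None) -> np.ndarray:
        """Per-component acceptance rate, optionally over the last ``last``
        sweeps only."""
        acc = self.accepted if last is None else self.accepted[-last:]
        return acc.mean(axis=0)


def run_mwg(logpost, x0, proposal_std, n_samples, *, burn_in=0, thinning=1,
            strategy="none", seed=0, families=None, partners=None,
            psi_partners=None,
            batch_size=50, t_start=100, scam_literal=False,
            amwg_schedule="paper", store_sigma_trace=False,
            parameter_names=None,
            rng: np.random.Generator | None = None) -> Chain:
    """Sample an arbitrary target density with the adaptive MWG sampler.

    This is the generic engine behind :func:`run_chain`; it accepts any
    ``logpost`` callable over p-vectors, which is also how the sampler is
    validated against analytically tractable targets.
    """
    x0 = np.asarray(x0, dtype=float)
    p = len(x0)
    if families is None:
        families = ["normal"] * p
    if partners is None:
        partners = np.full(p, -1, dtype=int)
    state = ProposalState(
        sigma=np.broadcast_to(np.asarray(proposal_std, float), (p,)),
        families=list(families), partners=np.asarray(partners, dtype=int),
        psi_partners=(None if psi_partners is None
                      else np.asarray(psi_partners, dtype=int)),
        strategy=strategy, batch_size=batch_size, t_start=t_start,
        scam_literal=scam_literal, amwg_schedule=amwg_schedule)
    if rng is None:
        rng = np.random.default_rng(seed)

    x = canonicalize(x0, state)
    lx = logpost(x)
    if lx == -math.inf:
        raise ValueError("infeasible initial point")
    state.observe(x)

    total = burn_in + n_samples * thinning
    samples = np.empty((n_samples, p))
    logs = np.empty(n_samples)
    accepted = np.zeros((total, p), dtype=bool)
    sig_trace = [state.sigma.copy()] if store_sigma_trace else None

    stored = 0
    for t in range(1, total + 1):
        x, lx, acc = mwg_sweep(x, lx, state, logpost, rng)
        accepted[t - 1] = acc
        state.observe(x)
        if strategy == "scam":
            adapt_scam(state, t)
        elif strategy in ("fsl", "amwg") and state.batch_proposals >= batch_size:
            (adapt_fsl if strategy == "fsl" else adapt_amwg)(state)
            if sig_trace is not None:
                sig_trace.append(state.sigma.copy())
        if t > burn_in and (t - burn_in) % thinning == 0:
            samples[stored] = x
            logs[stored] = lx
            stored += 1

    return Chain(samples=samples, log_posterior=logs, accepted=accepted,
                 parameter_names=list(parameter_names or
                                      [f"x{i}" for i in range(p)]),
                 seed=seed, burn_in=burn_in, thinning=thinning,
                 sigma_final=state.sigma.copy(),
                 sigma_trace=(np.array(sig_trace) if sig_trace is not None
                              else None),
                 init=x0.copy())


def _proposal_stds(model: CompositeModel, voxel: bayes.VoxelData) -> np.ndarray:
    return np.array([0.05 * voxel.b0_mean if q.proposal_std is None
                     else q.proposal_std for q in model.parameters])


def run_chain(model: CompositeModel, voxel: bayes.VoxelData,
              config: SamplerConfig, init: np.ndarray | None = None,
              priors: bayes.PriorSet | None = None) -> Chain:
    """Sample one voxel's posterior under ``model``.

    ``init`` overrides the configured initialisation ("mle": multi-start
    Powell point estimate; "default": the model's a-priori defaults with
    S0 at the voxel's b0 mean).  Deterministic given ``config.seed``.
    """
    priors = priors or bayes.default_priors(model)
    seq = np.random.SeedSequence(config.seed)
    mle_seed, chain_seed = seq.spawn(2)
    if init is None:
        if config.init == "mle":
            start = bayes.fit_mle(
                model, voxel, n_restarts=config.mle_restarts,
                seed=mle_seed.generate_state(1)[0] % (2**31),
                priors=priors).x
            start = bayes.prepare_tensor_init(model, start)
        else:
            start = bayes.default_init(model, voxel)
    else:
        start = np.asarray(init, dtype=float)
    logpost = bayes.make_log_posterior(model, voxel, priors)
    partners = np.full(model.p, -1, dtype=int)
    psi_partners = np.full(model.p, -1, dtype=int)
    names = model.parameter_names
    for i, q in enumerate(model.parameters):
        if q.partner is not None:
            partners[i] = model.index(q.partner)
        if q.ptype == "polar":
            # a ψ parameter sharing the θ suffix rotates this axis' frame
            psi_name = "psi" + q.name[len("theta"):]
            if psi_name in names:
                psi_partners[i] = model.index(psi_name)
    families = []
    for q in model.parameters:
        families.append({"polar": "polar", "azimuth": "azimuth",
                         "psi": "circular_pi"}.get(q.ptype, "normal"))
    return run_mwg(
        logpost, start, _proposal_stds(model, voxel), config.n_samples,
        burn_in=config.resolved_burn_in(), thinning=config.thinning,
        strategy=config.strategy, seed=config.seed, families=families,
        partners=partners, psi_partners=psi_partners,
        batch_size=config.batch_size,
        t_start=config.t_start, scam_literal=config.scam_literal,
        amwg_schedule=config.amwg_schedule,
        store_sigma_trace=config.store_sigma_trace,
        parameter_names=model.parameter_names,
        rng=np.random.default_rng(chain_seed))


def sample_volume(model: CompositeModel, data, mask, scheme, sigma,
                  config: SamplerConfig, keep_chains: bool = False):
    """Sample every voxel inside ``mask`` of a 4-D volume independently.

    Per-voxel seeds are derived from the global seed and the voxel's flat
    index, so results are identical regardless of processing order or
    parallelism.  Returns a dict with ``mean``, ``std`` and ``correlation``
    maps (and ``chains`` keyed by voxel index when requested).
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if data.shape[:-1] != mask.shape:
        raise ValueError("data and mask dimensions disagree")
    if data.shape[-1] != scheme.n_volumes:
        raise ValueError("data volume count does not match scheme")
    if not mask.any():
        raise ValueError("empty mask")
    sigma_map = np.broadcast_to(np.asarray(sigma, dtype=float), mask.shape)
    if np.any(sigma_map[mask] <= 0):
        raise ValueError("sigma must be positive inside the mask")

    p = model.p
    mean = np.full(mask.shape + (p,), np.nan)
    std = np.full(mask.shape + (p,), np.nan)
    corr = np.full(mask.shape + (p, p), np.nan)
    chains = {}
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        flat = int(np.ravel_multi_index(idx, mask.shape))
        voxel_seed = int(np.random.SeedSequence(
            entropy=config.seed, spawn_key=(flat,)).generate_state(1)[0]
            % (2**31))
        voxel_config = dataclasses.replace(config, seed=voxel_seed)
        voxel = bayes.VoxelData(data[idx], float(sigma_map[idx]), scheme)
        chain = run_chain(model, voxel, voxel_config)
        from .diagnostics import posterior_summaries
        summ = posterior_summaries(chain)
        mean[idx] = summ["mean"]
        std[idx] = summ["std"]
        corr[idx] = summ["correlation"]
        if keep_chains:
            chains[idx] = chain
    out = {"mean": mean, "std": std, "correlation": corr,
           "parameter_names": model.parameter_names}
    if keep_chains:
        out["chains"] = chains
    return out
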