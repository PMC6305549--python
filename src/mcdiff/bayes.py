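"""Posterior assembly for voxel-wise model fitting.

The log-posterior is the sum of an Offset-Gaussian log-likelihood and a
flat prior restricted to the feasible set:

    l(O|x) = −Σ_i (O_i − √(S_i(x)² + σ²))² / (2σ²) − m ln(σ√(2π))

where O are the m observed volume intensities, S(x) the predicted signal
and σ the standard deviation of the complex Gaussian noise before
magnitude reconstruction.  The offset √(S²+σ²) approximates the mean of a
Rician-distributed magnitude measurement.  σ is an input (global or
per-voxel); in simulations it is known by construction as S0/SNR.

Priors are uniform per parameter plus structural model priors: the sampled
volume fractions must stay on the simplex (Σ w_k ≤ 1) and tensor
diffusivities must be strictly decreasing (d∥ > d⊥1 > d⊥2, preventing
orientation aliasing).  Uniform normalisation constants are dropped: the
log-prior is 0 on the feasible set and −∞ outside, which is all a
Metropolis ratio needs.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import optimize

from .acquisition import AcquisitionScheme, cart_to_sphere, sphere_to_cart
from .compartments import CompositeModel, canonical_perpendicular, _tensor_frame

__all__ = [
    "VoxelData",
    "PriorSet",
    "default_priors",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "make_log_posterior",
    "default_init",
    "MLEResult",
    "fit_mle",
    "prepare_tensor_init",
]


@dataclasses.dataclass(frozen=True)
class VoxelData:
    """Observed signal of one voxel with its noise level and scheme."""

    observations: np.ndarray
    noise_sigma: float
    scheme: AcquisitionScheme

    def __post_init__(self):
        obs = np.asarray(self.observations, dtype=float)
        object.__setattr__(self, "observations", obs)
        if len(obs) != self.scheme.n_volumes:
            raise ValueError("observation count does not match scheme volumes")
        if not self.noise_sigma > 0:
            raise ValueError("noise sigma must be positive")

    @property
    def b0_mean(self) -> float:
        mask = self.scheme.b0_mask
        if mask.any():
            return float(self.observations[mask].mean())
        return float(self.observations.mean())


@dataclasses.dataclass(frozen=True)
class PriorSet:
    """Uniform box bounds plus structural (model-level) constraints."""

    lower: np.ndarray
    upper: np.ndarray
    simplex: tuple = ()      # indices of sampled volume fractions
    orderings: tuple = ()    # tuples of indices with strictly decreasing values

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if np.any(lo >= hi):
            raise ValueError("every prior requires lower < upper")

    def feasible(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        if np.any(x < self.lower) or np.any(x > self.upper):
            return False
        if self.simplex and np.sum(x[list(self.simplex)]) > 1.0:
            return False
        for group in self.orderings:
            vals = x[list(group)]
            if np.any(np.diff(vals) >= 0):
                return False
        return True


def default_priors(model: CompositeModel) -> PriorSet:
    """The model's uniform bounds and structural constraints."""
    return PriorSet(
        lower=np.array([q.lower for q in model.parameters]),
        upper=np.array([q.upper for q in model.parameters]),
        simplex=model.simplex,
        orderings=model.orderings)


def log_likelihood(voxel: VoxelData, predicted: np.ndarray) -> float:
    """Offset-Gaussian log-likelihood of the predicted signal."""
    predicted = np.asarray(predicted, dtype=float)
    if not np.all(np.isfinite(predicted)):
        raise ValueError("non-finite predicted signal")
    sigma = voxel.noise_sigma
    resid = voxel.observations - np.sqrt(predicted * predicted + sigma * sigma)
    m = len(resid)
    return float(-(resid @ resid) / (2.0 * sigma * sigma)
                 - m * math.log(sigma * math.sqrt(2.0 * math.pi)))


def log_prior(model: CompositeModel, priors: PriorSet, x: np.ndarray) -> float:
    """0 on the feasible set, −∞ outside (unnormalised uniform product)."""
    x = np.asarray(x, dtype=float)
    if len(x) != model.p:
        raise ValueError(f"expected {model.p} parameters, got {len(x)}")
    return 0.0 if priors.feasible(x) else -math.inf


def log_posterior(model: CompositeModel, priors: PriorSet, voxel: VoxelData,
                  x: np.ndarray) -> float:
    """Unnormalised log-posterior; −∞ for infeasible points."""
    lp = log_prior(model, priors, x)
    if lp == -math.inf:
        return -math.inf
    return lp + log_likelihood(voxel, model.predict(x, voxel.scheme))


def make_log_posterior(model: CompositeModel, voxel: VoxelData,
                       priors: PriorSet | None = None):
    """Fast closure ``x -> log posterior`` bound to one voxel.

    Avoids re-dispatching the model binding on every call; this is the
    inner loop of both the sampler and the MLE.
    """
    priors = priors or default_priors(model)
    predictor = model.bind(voxel.scheme)
    obs = voxel.observations
    sigma = voxel.noise_sigma
    s2 = sigma * sigma
    const = -len(obs) * math.log(sigma * math.sqrt(2.0 * math.pi))
    inv = -0.5 / s2
    feasible = priors.feasible

    def logpost(x):
        if not feasible(x):
            return -math.inf
        s = predictor(x)
        resid = obs - np.sqrt(s * s + s2)
        return inv * float(resid @ resid) + const

    return logpost


def default_init(model: CompositeModel, voxel: VoxelData) -> np.ndarray:
    """A-priori starting point: parameter defaults, S0 from the b0 mean."""
    x = np.array([voxel.b0_mean if q.default is None else q.default
                  for q in model.parameters])
    return x


@dataclasses.dataclass(frozen=True)
class MLEResult:
    x: np.ndarray
    log_posterior: float
    converged: bool
    n_evaluations: int


def fit_mle(model: CompositeModel, voxel: VoxelData,
            init: np.ndarray | None = None, n_restarts: int = 5,
            seed: int = 0, priors: PriorSet | None = None,
            maxiter: int = 4000) -> MLEResult:
    """Maximum-likelihood (flat-prior maximum-posterior) point estimate.

    Runs a bounded derivative-free Powell search from ``init`` plus
    ``n_restarts − 1`` seeded perturbations of it, and returns the best
    feasible local maximiser found.  A failed optimisation is reported via
    ``converged=False``; the returned point is always feasible.
    """
    priors = priors or default_priors(model)
    if init is None:
        init = default_init(model, voxel)
    init = np.asarray(init, dtype=float)
    if not priors.feasible(init):
        raise ValueError("infeasible initial point")
    logpost = make_log_posterior(model, voxel, priors)
    rng = np.random.default_rng(seed)
    lo, hi = priors.lower, priors.upper
    span = np.minimum(hi - lo, 2.0 * np.array(
        [q.proposal_std if q.proposal_std is not None else 0.05 * voxel.b0_mean
         for q in model.parameters]))

    def objective(x):
        lp = logpost(x)
        return 1e12 if lp == -math.inf else -lp

    starts = [init]
    for _ in range(max(0, n_restarts - 1)):
        for _ in range(100):
            cand = np.clip(init + span * rng.uniform(-1, 1, len(init)), lo, hi)
            if priors.feasible(cand):
                starts.append(cand)
                break

    best_x, best_lp, ok, nfev = init, logpost(init), False, 0
    for start in starts:
        res = optimize.minimize(objective, start, method="Powell",
                                bounds=list(zip(lo, hi)),
                                options={"maxiter": maxiter, "xtol": 1e-8,
                                         "ftol": 1e-10})
        nfev += res.nfev
        lp = logpost(res.x)
        if lp > best_lp and priors.feasible(res.x):
            best_x, best_lp = np.asarray(res.x, dtype=float), lp
            ok = ok or res.success
        elif res.success:
            ok = True
    return MLEResult(best_x, best_lp, ok, nfev)


def prepare_tensor_init(model: CompositeModel, x: np.ndarray) -> np.ndarray:
    """Sort tensor diffusivities into strictly decreasing order.

    Re-expresses θ, φ, ψ so the predicted signal is unchanged: the three
    tensor eigenvectors are recovered, paired with their diffusivities,
    sorted, and the angles are recomputed from the new principal frame.
    A no-op when the diffusivities are already ordered.
    """
    if not model.orderings:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float).copy()
    (i_par, i_p1, i_p2), = model.orderings
    if x[i_par] > x[i_p1] > x[i_p2]:
        return x

    try:
        it = model.index("theta")
        ip = model.index("phi")
        ipsi = model.index("psi")
    except ValueError:
        it, ip, ipsi = (model.index("theta_h"), model.index("phi_h"),
                        model.index("psi_h"))

    d = np.array([x[i_par], x[i_p1], x[i_p2]])
    e1, e2, e3 = _tensor_frame(x[it], x[ip], x[ipsi])
    order = np.argsort(-d, kind="stable")
    d_sorted = d[order]
    vecs = np.array([e1, e2, e3])[order]
    # tiny symmetric breaks keep the ordering strict without moving the signal
    for k in (1, 2):
        if d_sorted[k] >= d_sorted[k - 1]:
            d_sorted[k] = np.nextafter(d_sorted[k - 1], -np.inf)
    x[i_par], x[i_p1], x[i_p2] = d_sorted

    n = vecs[0]
    theta, phi = cart_to_sphere(n)
    n = sphere_to_cart(theta, phi)  # re-derive to keep frame consistent
    c = canonical_perpendicular(n)
    e2n = vecs[1]
    psi = math.atan2(float(np.dot(np.cross(c, e2n), n)), float(np.dot(c, e2n)))
    psi %= math.pi
    x[it], x[ip], x[ipsi] = theta, phi, psi
    return x
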