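"""Chain diagnostics: autocorrelation, moving summaries, multivariate
Effective Sample Size (ESS) and run-length planning.

The multivariate ESS of an s × p chain is

    ESS = s · (|Λ_s| / |Σ_s|)^(1/p)

with Λ_s the sample covariance of the chain and Σ_s the batch-means
estimate of the Monte Carlo (asymptotic) covariance.  Sampling may stop
once ESS exceeds the closed-form threshold

    W(p, α, ε) = 2^(2/p) π / (p Γ(p/2))^(2/p) · χ²_{1−α,p} / ε²

which guarantees a (1−α) confidence region for the posterior mean with
relative precision ε.  For α = 0.05, ε = 0.1 the threshold is nearly flat
in p at about 2,200 effective samples.  Given a chain of length s with an
estimated ESS below W, the linear extrapolation ŝ = s + (W − ESS)/(ESS/s)
recommends a total run length.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

__all__ = [
    "ESSReport",
    "autocorrelation",
    "moving_summary",
    "batch_means_covariance",
    "multivariate_ess",
    "univariate_ess",
    "min_ess_threshold",
    "required_samples",
    "posterior_summaries",
]


@dataclasses.dataclass(frozen=True)
class ESSReport:
    """Multivariate ESS of one chain with its ingredient covariances."""

    s: int
    p: int
    sample_covariance: np.ndarray      # Λ_s
    mc_covariance: np.ndarray          # Σ_s (batch means)
    ess: float
    univariate: np.ndarray             # per-parameter batch-means ESS
    degenerate: bool = False


def _as_chain(chain) -> np.ndarray:
    x = getattr(chain, "samples", chain)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def autocorrelation(chain, lag: int) -> float:
    """Empirical lag autocorrelation under stationarity (single mean and
    variance for the whole chain)."""
    x = _as_chain(chain).ravel()
    s = len(x)
    if not 0 <= lag < s:
        raise ValueError("require chain length > lag >= 0")
    x = x - x.mean()
    var = float(x @ x)
    if var == 0.0:
        raise ValueError("zero-variance chain")
    if lag == 0:
        return 1.0
    return float(x[:-lag] @ x[lag:]) / var


def moving_summary(chain, window: int):
    """Sliding-window mean and std over increasing burn-in offsets.

    Entry k summarises samples [k, k + window); std uses the population
    (ddof=0) convention.  Requires window ≥ 2 so the std is defined.
    """
    x = _as_chain(chain).ravel()
    if window > len(x):
        raise ValueError("window exceeds chain length")
    if window <= 1:
        raise ValueError("window must exceed 1 for a moving std")
    views = np.lib.stride_tricks.sliding_window_view(x, window)
    return views.mean(axis=1), views.std(axis=1)


def batch_means_covariance(x: np.ndarray, batch_size: int | None = None):
    """Batch-means estimate Σ_s of the Monte Carlo covariance.

    Non-overlapping batches of size ⌊√s⌋ (trailing samples dropped);
    Σ_s = b/(a−1) · Σ_k (Ȳ_k − μ̄)(Ȳ_k − μ̄)ᵀ over the a batch means Ȳ_k.
    """
    x = _as_chain(x)
    s = x.shape[0]
    b = batch_size or int(math.floor(math.sqrt(s)))
    a = s // b
    if a < 2:
        raise ValueError("too few samples for batch means")
    y = x[:a * b].reshape(a, b, -1).mean(axis=1)
    centred = y - x[:a * b].mean(axis=0)
    return b * (centred.T @ centred) / (a - 1)


def univariate_ess(x: np.ndarray, batch_size: int | None = None) -> float:
    """Batch-means ESS of a single component: s · λ² / σ²_bm."""
    x = _as_chain(x).ravel()
    s = len(x)
    lam = float(np.var(x, ddof=1))
    sig = float(batch_means_covariance(x, batch_size)[0, 0])
    if lam <= 0 or sig <= 0:
        return 0.0
    return s * lam / sig


def multivariate_ess(chain, batch_size: int | None = None) -> ESSReport:
    """Multivariate ESS = s (|Λ_s|/|Σ_s|)^(1/p) with batch-means Σ_s.

    Degenerate chains (singular Λ_s or Σ_s) are flagged and reported with
    ess = 0 rather than raising.
    """
    x = _as_chain(chain)
    s, p = x.shape
    if s < 4 * p:
        raise ValueError("require at least 4·p samples")
    lam = np.cov(x, rowvar=False).reshape(p, p)
    sig = batch_means_covariance(x, batch_size)
    uni = np.array([univariate_ess(x[:, j], batch_size) for j in range(p)])
    (s_lam, ld_lam) = np.linalg.slogdet(lam)
    (s_sig, ld_sig) = np.linalg.slogdet(sig)
    if s_lam <= 0 or s_sig <= 0:
        return ESSReport(s, p, lam, sig, 0.0, uni, degenerate=True)
    ess = s * math.exp((ld_lam - ld_sig) / p)
    return ESSReport(s, p, lam, sig, ess, uni)


def min_ess_threshold(p: int, alpha: float, epsilon: float) -> float:
    """Theoretical minimum ESS W(p, α, ε) for a (1−α) confidence region
    with relative precision ε."""
    if p < 1:
        raise ValueError("p must be at least 1")
    if not (0 < alpha < 1 and 0 < epsilon < 1):
        raise ValueError("alpha and epsilon must lie in (0, 1)")
    pref = 2.0 ** (2.0 / p) * math.pi / (p * math.gamma(p / 2.0)) ** (2.0 / p)
    return pref * stats.chi2.ppf(1.0 - alpha, p) / epsilon ** 2


def required_samples(s: int, ess: float, w: float) -> float:
    """Linear run-length extrapolation ŝ = s + (W − ESS)/(ESS/s).

    Equals s when ESS = W and drops below s when the chain already holds
    more effective samples than required.
    """
    if ess <= 0:
        raise ValueError("ess must be positive")
    if s <= 0:
        raise ValueError("s must be positive")
    return s + (w - ess) / (ess / s)


def _circular_mean_std(x: np.ndarray, period: float):
    ang = x * (2.0 * np.pi / period)
    z = np.exp(1j * ang).mean()
    mean = (np.angle(z) % (2.0 * np.pi)) * period / (2.0 * np.pi)
    r = np.abs(z)
    if r <= 0:
        return float(mean), float("inf")
    std = math.sqrt(max(0.0, -2.0 * math.log(r))) * period / (2.0 * np.pi)
    return float(mean), std


def posterior_summaries(chain, circular: dict | None = None) -> dict:
    """Gaussian-fit posterior summaries of a chain.

    Returns per-parameter mean and std (the parameters of a Gaussian fit
    to the marginal samples) and the inter-parameter sample correlation
    matrix.  Parameters listed in ``circular`` (name → period) are
    summarised with circular statistics instead; for a :class:`Chain` the
    ψ parameters default to period π.  Zero-variance components leave
    their correlation entries flagged as NaN.
    """
    x = _as_chain(chain)
    s, p = x.shape
    if s < 2:
        raise ValueError("need at least 2 samples")
    names = list(getattr(chain, "parameter_names", [f"x{i}" for i in range(p)]))
    if circular is None:
        circular = {n: math.pi for n in names if n.startswith("psi")}
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    for j, name in enumerate(names):
        if name in circular:
            mean[j], std[j] = _circular_mean_std(x[:, j], circular[name])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False).reshape(p, p)
    degenerate = bool(np.any(x.std(axis=0) == 0.0))
    return {"mean": mean, "std": std, "correlation": corr,
            "parameter_names": names, "degenerate": degenerate}
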