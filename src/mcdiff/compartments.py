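"""Compartment signal models and their multi-compartment composites.

Each compartment returns a dimensionless attenuation in (0, 1] per acquired
volume (1 at b=0), and a composite model combines compartments as a
volume-fraction weighted sum scaled by the non-diffusion-weighted signal:

    S = S0 · Σ_i w_i S_i

with the last volume fraction derived as one minus the sum of the others.

Available composites (``build_model``): Ball&Stick with 1–3 sticks
(``BallStick_in1/2/3``), ``Tensor``, ``NODDI`` (Watson-dispersed stick +
dispersed zeppelin + ball) and ``CHARMED_in1/2/3`` (restricted cylinders +
hindered tensor).  Parameter counts (sampled, including S0) are 4/7/10, 7,
6 and 11/15/19 respectively.

Orientations use n(θ, φ) = (sinθ cosφ, sinθ sinφ, cosθ) with θ the polar
and φ the azimuth angle.  All compartment signals are antipodally symmetric
(n and −n are indistinguishable), which is what licenses the sampler's
hemisphere fold of the angle pairs.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import special, stats

from .acquisition import AcquisitionScheme, sphere_to_cart

__all__ = [
    "DEFAULT_CONSTANTS",
    "ParameterSpec",
    "CompositeModel",
    "InfeasibleParametersError",
    "MODEL_NAMES",
    "ball_signal",
    "stick_signal",
    "tensor_signal",
    "watson_density",
    "noddi_in_signal",
    "noddi_ex_signal",
    "charmed_in_signal",
    "composite_signal",
    "build_model",
    "canonical_perpendicular",
]


class InfeasibleParametersError(ValueError):
    """Raised when a parameter vector violates a structural constraint."""


#: Fixed (non-sampled) model constants.  Diffusivities in m²/s, radii in m.
#: All values can be overridden via ``build_model(..., constants=...)``.
DEFAULT_CONSTANTS: dict = {
    "stick_d": 1.7e-9,           # Stick intra-axonal diffusivity
    "ball_d": 3.0e-9,            # free-water (isotropic) diffusivity
    "noddi_d_in": 1.7e-9,        # NODDI intra-neurite diffusivity
    "noddi_d_iso": 3.0e-9,       # NODDI isotropic diffusivity
    "noddi_d_ex_par": 1.7e-9,    # NODDI extra-cellular parallel diffusivity
    "tortuosity": True,          # couple extra-cellular d⊥ to the intra fraction
    "charmed_n_radii": 6,        # cylinder radius grid size
    "charmed_radius_range": (1.5e-6, 9.0e-6),
    "charmed_gamma_shape": 2.0,  # gamma weighting of the radius grid
    "charmed_gamma_scale": 1.5e-6,
    "watson_n_polar": 64,        # Gauss-Legendre order for spherical quadrature
    "watson_n_azimuth": 72,      # trapezoid order for spherical quadrature
}

MODEL_NAMES = ("BallStick_in1", "BallStick_in2", "BallStick_in3",
               "Tensor", "NODDI",
               "CHARMED_in1", "CHARMED_in2", "CHARMED_in3")


# ---------------------------------------------------------------------------
# elementary compartments

def ball_signal(scheme: AcquisitionScheme, d: float) -> np.ndarray:
    """Isotropic Gaussian attenuation exp(−b d)."""
    if d < 0:
        raise ValueError("negative diffusivity")
    return np.exp(-scheme.b_values * d)


def stick_signal(scheme: AcquisitionScheme, d: float, theta: float,
                 phi: float) -> np.ndarray:
    """Zero-radius cylinder attenuation exp(−b d (n·g)²)."""
    if d < 0:
        raise ValueError("negative diffusivity")
    n = sphere_to_cart(theta, phi)
    ng = scheme.directions @ n
    return np.exp(-scheme.b_values * d * ng * ng)


def canonical_perpendicular(n: np.ndarray) -> np.ndarray:
    """Unit vector perpendicular to ``n``: the z-axis component orthogonal
    to n, or the x-axis equivalent when n is within 1e-6 of ±z."""
    n = np.asarray(n, dtype=float)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(abs(n[2]) - 1.0) < 1e-6:
        ref = np.array([1.0, 0.0, 0.0])
    c = ref - np.dot(ref, n) * n
    return c / np.linalg.norm(c)


def _tensor_frame(theta: float, phi: float, psi: float):
    n = sphere_to_cart(theta, phi)
    c = canonical_perpendicular(n)
    # axis-angle rotation of c about n by ψ; n·c = 0 simplifies Rodrigues
    n_perp1 = c * math.cos(psi) + np.cross(n, c) * math.sin(psi)
    n_perp2 = np.cross(n, n_perp1)
    return n, n_perp1, n_perp2


def tensor_signal(scheme: AcquisitionScheme, d_par: float, d_perp1: float,
                  d_perp2: float, theta: float, phi: float,
                  psi: float) -> np.ndarray:
    """Full diffusion-tensor attenuation.

    exp(−b(d∥(n·g)² + d⊥1(n⊥1·g)² + d⊥2(n⊥2·g)²)) with n⊥1 obtained by
    rotating the canonical perpendicular of n about n by ψ and n⊥2 = n×n⊥1.
    """
    if min(d_par, d_perp1, d_perp2) < 0:
        raise ValueError("negative diffusivity")
    n, n1, n2 = _tensor_frame(theta, phi, psi)
    G = scheme.directions
    q = (d_par * (G @ n) ** 2 + d_perp1 * (G @ n1) ** 2
         + d_perp2 * (G @ n2) ** 2)
    return np.exp(-scheme.b_values * q)


# ---------------------------------------------------------------------------
# Watson distribution and NODDI compartments

def watson_density(n: np.ndarray, mu: np.ndarray, kappa: float) -> float:
    """Watson density f(n; μ, κ) ∝ exp(κ(μ·n)²) on the unit sphere.

    Normalised through the confluent hypergeometric function
    M(1/2, 3/2, κ) so the density integrates to one over the sphere;
    κ = 0 gives the uniform density 1/(4π).
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    n = np.asarray(n, dtype=float)
    t = n @ np.asarray(mu, dtype=float)
    norm = 4.0 * np.pi * special.hyp1f1(0.5, 1.5, kappa)
    return np.exp(kappa * t * t) / norm


def _sphere_quadrature(n_polar: int, n_azimuth: int):
    """Product quadrature on S²: Gauss-Legendre in cosθ × trapezoid in φ.

    Returns (K, 3) unit nodes and (K,) weights summing to 4π.  The
    trapezoid rule is spectrally accurate for the periodic azimuth; the
    polar order must resolve exp(κ u²) up to the largest κ of interest
    (the default order 64 holds relative errors below 1e-4 for κ ≤ 60).
    """
    if n_polar < 8 or n_azimuth < 8:
        raise ValueError("quadrature order below minimum (8)")
    u, wu = leggauss(n_polar)
    ph = 2.0 * np.pi * np.arange(n_azimuth) / n_azimuth
    su = np.sqrt(1.0 - u * u)
    nodes = np.empty((n_polar * n_azimuth, 3))
    nodes[:, 0] = np.outer(su, np.cos(ph)).ravel()
    nodes[:, 1] = np.outer(su, np.sin(ph)).ravel()
    nodes[:, 2] = np.repeat(u, n_azimuth)
    weights = np.repeat(wu, n_azimuth) * (2.0 * np.pi / n_azimuth)
    return nodes, weights


class WatsonStickIntegrator:
    """Fixed-node spherical quadrature of the Watson-dispersed stick.

    Pre-tabulates exp(−b_j d (n_k·g_j)²) over the quadrature nodes n_k so
    that evaluating the dispersed signal for a new (μ, κ) costs one
    exponential over the nodes and one vector-matrix product.  The Watson
    weights are self-normalised on the node set, which makes the b=0
    columns exactly one.
    """

    #: above this concentration the Watson spike is too narrow for the
    #: fixed node set and a μ-frame substitution quadrature takes over
    KAPPA_TABLE_MAX = 100.0

    def __init__(self, scheme: AcquisitionScheme, d: float,
                 n_polar: int = 64, n_azimuth: int = 72):
        if d < 0:
            raise ValueError("negative diffusivity")
        self.nodes, self.weights = _sphere_quadrature(n_polar, n_azimuth)
        ng = self.nodes @ scheme.directions.T          # (K, m)
        self._table = np.exp(-scheme.b_values * d * ng * ng)
        self._bd = scheme.b_values * d
        self._directions = scheme.directions
        self._n_azimuth = n_azimuth

    def __call__(self, mu: np.ndarray, kappa: float) -> np.ndarray:
        if kappa > self.KAPPA_TABLE_MAX:
            return self._dispersed_dense(mu, kappa)
        t = self.nodes @ mu
        # exponent shifted by κ (its maximum over the sphere): the shift
        # cancels in the self-normalised ratio and avoids overflow
        c = self.weights * np.exp(kappa * (t * t - 1.0))
        return (c @ self._table) / c.sum()

    def _dispersed_dense(self, mu: np.ndarray, kappa: float) -> np.ndarray:
        """High-concentration branch: quadrature in the μ-frame.

        With u = μ·n the Watson weight is exp(κ(u²−1)); substituting
        y = κ(1−u²) turns the polar integral into an exponentially
        damped one that Gauss-Legendre on y ∈ [0, min(κ, 40)] resolves
        for arbitrarily large κ.  Antipodal symmetry restricts u to the
        upper hemisphere.
        """
        y, wy = leggauss(64)
        y_max = min(kappa, 40.0)
        y = 0.5 * y_max * (y + 1.0)
        wy = 0.5 * y_max * wy
        u = np.sqrt(1.0 - y / kappa)
        c_u = wy * np.exp(-y) / (2.0 * kappa * u)
        e1 = canonical_perpendicular(mu)
        e2 = np.cross(mu, e1)
        ph = 2.0 * np.pi * np.arange(self._n_azimuth) / self._n_azimuth
        su = np.sqrt(1.0 - u * u)
        # (K_u * K_phi, 3) nodes in the global frame
        nodes = (np.outer(np.outer(su, np.cos(ph)).ravel(), e1)
                 + np.outer(np.outer(su, np.sin(ph)).ravel(), e2)
                 + np.outer(np.repeat(u, self._n_azimuth), mu))
        c = np.repeat(c_u, self._n_azimuth)
        ng = nodes @ self._directions.T
        table = np.exp(-self._bd * ng * ng)
        return (c @ table) / c.sum()


def noddi_in_signal(scheme: AcquisitionScheme, d: float, theta: float,
                    phi: float, kappa: float,
                    n_polar: int | None = None,
                    n_azimuth: int | None = None) -> np.ndarray:
    """Intra-neurite NODDI attenuation: Watson-weighted spherical average
    of the stick signal, ∫ f(n; μ, κ) exp(−b d (n·g)²) dn."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    integrator = WatsonStickIntegrator(
        scheme, d,
        n_polar or DEFAULT_CONSTANTS["watson_n_polar"],
        n_azimuth or DEFAULT_CONSTANTS["watson_n_azimuth"])
    return integrator(sphere_to_cart(theta, phi), kappa)


_TAU_U, _TAU_W = leggauss(96)
_TAU_U = 0.5 * (_TAU_U + 1.0)  # map to [0, 1]
_TAU_W = 0.5 * _TAU_W


def watson_cos2_moment(kappa: float) -> float:
    """⟨(μ·n)²⟩ under the Watson distribution, by 1-D quadrature.

    Equals 1/3 at κ=0 (isotropic) and tends to 1 as κ→∞ (parallel)."""
    e = np.exp(kappa * (_TAU_U * _TAU_U - 1.0))  # shifted for overflow safety
    return float(np.sum(_TAU_W * _TAU_U * _TAU_U * e) / np.sum(_TAU_W * e))


def noddi_ex_signal(scheme: AcquisitionScheme, d_par: float, d_perp: float,
                    theta: float, phi: float, kappa: float) -> np.ndarray:
    """Extra-cellular NODDI attenuation under the Watson-averaged tensor.

    The orientation average of the cylindrically symmetric tensor
    D(n) = (d∥−d⊥) n nᵀ + d⊥ I has eigenvalue τ(κ) along μ and (1−τ)/2 in
    the perpendicular plane, with τ the Watson second moment; the signal is
    exp(−b gᵀ⟨D⟩g).  The trace (d∥ + 2d⊥) is preserved for every κ.
    """
    if d_perp > d_par:
        raise ValueError("require d_perp <= d_par")
    if min(d_par, d_perp) < 0:
        raise ValueError("negative diffusivity")
    tau = watson_cos2_moment(kappa)
    mu = sphere_to_cart(theta, phi)
    c2 = (scheme.directions @ mu) ** 2
    gDg = d_perp + (d_par - d_perp) * (tau * c2 + 0.5 * (1.0 - tau) * (1.0 - c2))
    return np.exp(-scheme.b_values * gDg)


# ---------------------------------------------------------------------------
# CHARMED restricted cylinders

def default_charmed_radii(constants: dict | None = None):
    """Radius grid R_i and gamma-distributed weights v_i (summing to one)."""
    c = {**DEFAULT_CONSTANTS, **(constants or {})}
    lo, hi = c["charmed_radius_range"]
    radii = np.linspace(lo, hi, c["charmed_n_radii"])
    w = stats.gamma.pdf(radii, a=c["charmed_gamma_shape"],
                        scale=c["charmed_gamma_scale"])
    return radii, w / w.sum()


def charmed_in_signal(scheme: AcquisitionScheme, d: float, theta: float,
                      phi: float, radii: np.ndarray,
                      weights: np.ndarray) -> np.ndarray:
    """Restricted-cylinder (CHARMED intra-axonal) attenuation.

    Parallel component exp(−4π²|q|²(n·g)²(Δ−δ/3)d) composed with the
    Neuman-type perpendicular component per cylinder radius R_i, summed
    with radius weights v_i.  The perpendicular exponent is clamped at
    zero where the small-radius expansion would exceed unit attenuation.
    """
    if not scheme.has_timing:
        raise ValueError("CHARMED requires Δ/δ/TE timing in the scheme")
    if d <= 0:
        raise ValueError("require d > 0")
    radii = np.asarray(radii, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("radius weights must sum to 1")
    q = scheme.q_magnitudes
    q2 = 4.0 * np.pi**2 * q * q
    n = sphere_to_cart(theta, phi)
    ct2 = (scheme.directions @ n) ** 2
    tau_par = scheme.big_delta - scheme.small_delta / 3.0
    s_par = np.exp(-q2 * ct2 * tau_par * d)
    dte = d * scheme.echo_time
    out = np.zeros(scheme.n_volumes)
    for R, v in zip(radii, weights):
        expo = -(q2 * (1.0 - ct2) * R**4 / dte) * (7.0 / 96.0) \
            * (2.0 - (99.0 / 112.0) * R**2 / dte)
        out += v * s_par * np.exp(np.minimum(expo, 0.0))
    return out


# ---------------------------------------------------------------------------
# composite models

@dataclasses.dataclass(frozen=True)
class ParameterSpec:
    """Metadata for one sampled model parameter."""

    name: str
    ptype: str            # fraction | diffusivity | polar | azimuth | psi | kappa | s0
    lower: float
    upper: float
    default: float | None     # None: derived from the data at run time (S0)
    proposal_std: float | None  # None: derived from the data (S0)
    partner: str | None = None  # paired angle parameter (polar <-> azimuth)


def _angle_pair(suffix: str = "") -> list[ParameterSpec]:
    return [
        ParameterSpec(f"theta{suffix}", "polar", 0.0, np.pi, np.pi / 2, 0.1,
                      partner=f"phi{suffix}"),
        ParameterSpec(f"phi{suffix}", "azimuth", -np.pi, np.pi, 0.0, 0.1,
                      partner=f"theta{suffix}"),
    ]


def _fraction(name: str, default: float) -> ParameterSpec:
    return ParameterSpec(name, "fraction", 0.0, 1.0, default, 0.25)


def _diffusivity(name: str, default: float) -> ParameterSpec:
    return ParameterSpec(name, "diffusivity", 0.0, 1.0e-8, default, 1.0e-10)


_S0 = ParameterSpec("S0", "s0", 0.0, 1.0e7, None, None)


@dataclasses.dataclass(frozen=True)
class CompositeModel:
    """A named multi-compartment model with its sampled-parameter metadata.

    ``parameters`` lists the sampled parameters in sampling order; fixed
    constants live in ``constants`` and the derived (last) volume fraction
    is implicit.  ``simplex`` holds the indices of the sampled volume
    fractions (their sum may not exceed one) and ``orderings`` holds index
    triples of diffusivities constrained to be strictly decreasing.
    """

    name: str
    compartments: tuple  # (name, role) pairs, informational
    parameters: tuple
    constants: dict
    simplex: tuple = ()
    orderings: tuple = ()
    headline_fraction: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "_bindings", [])

    @property
    def p(self) -> int:
        return len(self.parameters)

    @property
    def parameter_names(self) -> list:
        return [q.name for q in self.parameters]

    def index(self, name: str) -> int:
        return self.parameter_names.index(name)

    def bind(self, scheme: AcquisitionScheme):
        """Return (and cache) a fast ``x -> predicted signal`` callable."""
        for sch, fn in self._bindings:
            if sch is scheme:
                return fn
        fn = _make_predictor(self, scheme)
        self._bindings.append((scheme, fn))
        return fn

    def predict(self, x: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
        return self.bind(scheme)(np.asarray(x, dtype=float))

    def derived_fraction(self, x: np.ndarray) -> float:
        """The non-sampled last volume fraction, 1 − Σ sampled fractions."""
        if not self.simplex:
            return 0.0
        return 1.0 - float(np.sum(np.asarray(x)[list(self.simplex)]))


def composite_signal(model: CompositeModel, x: np.ndarray,
                     scheme: AcquisitionScheme) -> np.ndarray:
    """S0 times the weight-combined compartment attenuations (Eq. form
    S = S0 Σ w_i S_i), with the last weight derived from the simplex."""
    return model.predict(x, scheme)


def _check_derived_fraction(w_last: float):
    if w_last < -1e-12 or w_last > 1.0 + 1e-12:
        raise InfeasibleParametersError(
            f"derived volume fraction {w_last} outside [0, 1]")


def _make_predictor(model: CompositeModel, scheme: AcquisitionScheme):
    c = model.constants
    name = model.name
    b = scheme.b_values

    if name.startswith("BallStick"):
        n_sticks = int(name[-1])
        bd = b * c["stick_d"]
        ball = np.exp(-b * c["ball_d"])
        G = scheme.directions
        idx = [(model.index(f"w_stick{i}"), model.index(f"theta{i}"),
                model.index(f"phi{i}")) for i in range(n_sticks)]

        def predict(x):
            acc = 0.0
            wsum = 0.0
            for iw, it, ip in idx:
                w = x[iw]
                wsum += w
                st = math.sin(x[it])
                nvec = (st * math.cos(x[ip]), st * math.sin(x[ip]),
                        math.cos(x[it]))
                ng = G @ nvec
                acc = acc + w * np.exp(-bd * ng * ng)
            _check_derived_fraction(1.0 - wsum)
            return x[0] * (acc + (1.0 - wsum) * ball)

        return predict

    if name == "Tensor":
        i = [model.index(k) for k in
             ("d_par", "d_perp1", "d_perp2", "theta", "phi", "psi")]

        def predict(x):
            return x[0] * tensor_signal(scheme, x[i[0]], x[i[1]], x[i[2]],
                                        x[i[3]], x[i[4]], x[i[5]])

        return predict

    if name == "NODDI":
        integrator = WatsonStickIntegrator(
            scheme, c["noddi_d_in"], c["watson_n_polar"], c["watson_n_azimuth"])
        ball_iso = np.exp(-b * c["noddi_d_iso"])
        d_ex_par = c["noddi_d_ex_par"]
        tortuosity = c["tortuosity"]
        iw_in, iw_ex = model.index("w_in"), model.index("w_ex")
        it, ip, ik = model.index("theta"), model.index("phi"), model.index("kappa")

        def predict(x):
            w_in, w_ex = x[iw_in], x[iw_ex]
            _check_derived_fraction(1.0 - w_in - w_ex)
            mu = sphere_to_cart(x[it], x[ip])
            kappa = x[ik]
            a_in = integrator(mu, kappa)
            if tortuosity:
                nu = w_in / (w_in + w_ex) if (w_in + w_ex) > 0 else 0.0
                d_perp = d_ex_par * (1.0 - nu)
            else:
                d_perp = d_ex_par * 0.5
            tau = watson_cos2_moment(kappa)
            c2 = (scheme.directions @ mu) ** 2
            gDg = d_perp + (d_ex_par - d_perp) * (
                tau * c2 + 0.5 * (1.0 - tau) * (1.0 - c2))
            a_ex = np.exp(-b * gDg)
            return x[0] * (w_in * a_in + w_ex * a_ex
                           + (1.0 - w_in - w_ex) * ball_iso)

        return predict

    if name.startswith("CHARMED"):
        n_res = int(name[-1])
        radii, rweights = default_charmed_radii(c)
        ih = [model.index(k) for k in
              ("d_par", "d_perp1", "d_perp2", "theta_h", "phi_h", "psi_h")]
        res_idx = [(model.index(f"w_res{i}"), model.index(f"d_res{i}"),
                    model.index(f"theta_r{i}"), model.index(f"phi_r{i}"))
                   for i in range(n_res)]

        def predict(x):
            acc = 0.0
            wsum = 0.0
            for iw, idd, it, ip in res_idx:
                w = x[iw]
                wsum += w
                acc = acc + w * charmed_in_signal(
                    scheme, x[idd], x[it], x[ip], radii, rweights)
            _check_derived_fraction(1.0 - wsum)
            hindered = tensor_signal(scheme, x[ih[0]], x[ih[1]], x[ih[2]],
                                     x[ih[3]], x[ih[4]], x[ih[5]])
            return x[0] * (acc + (1.0 - wsum) * hindered)

        return predict

    raise ValueError(f"unknown model {name!r}")  # pragma: no cover


def build_model(name: str, constants: dict | None = None) -> CompositeModel:
    """Construct one of the catalogued composite models by name.

    ``constants`` overrides entries of :data:`DEFAULT_CONSTANTS` (fixed
    diffusivities, tortuosity coupling, CHARMED radius grid, quadrature
    orders).
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    c = {**DEFAULT_CONSTANTS, **(constants or {})}

    if name.startswith("BallStick"):
        n = int(name[-1])
        params = [_S0]
        comps = []
        for i in range(n):
            params.append(_fraction(f"w_stick{i}", round(0.5 / n, 6)))
            params.extend(_angle_pair(str(i)))
            comps.append((f"Stick{i}", "restricted"))
        comps.append(("Ball", "isotropic"))
        simplex = tuple(i for i, q in enumerate(params)
                        if q.ptype == "fraction")
        return CompositeModel(name, tuple(comps), tuple(params), c,
                              simplex=simplex, headline_fraction="w_stick0")

    if name == "Tensor":
        params = [_S0,
                  _diffusivity("d_par", 1.7e-9),
                  _diffusivity("d_perp1", 8.0e-10),
                  _diffusivity("d_perp2", 4.0e-10),
                  *_angle_pair(),
                  ParameterSpec("psi", "psi", 0.0, np.pi, 0.0, 0.1)]
        return CompositeModel(name, (("Tensor", "hindered"),), tuple(params), c,
                              orderings=((1, 2, 3),))

    if name == "NODDI":
        params = [_S0,
                  _fraction("w_in", 0.4),
                  _fraction("w_ex", 0.4),
                  *_angle_pair(),
                  ParameterSpec("kappa", "kappa", 0.0, 64.0, 1.0, 1.0)]
        comps = (("NODDI_in", "restricted"), ("NODDI_ex", "hindered"),
                 ("Ball", "isotropic"))
        return CompositeModel(name, comps, tuple(params), c,
                              simplex=(1, 2), headline_fraction="w_in")

    # CHARMED_in[n]
    n = int(name[-1])
    params = [_S0,
              _diffusivity("d_par", 1.7e-9),
              _diffusivity("d_perp1", 8.0e-10),
              _diffusivity("d_perp2", 4.0e-10)]
    params.extend(ParameterSpec(nm, pt, lo, hi, df, ps, partner=pa)
                  for nm, pt, lo, hi, df, ps, pa in [
                      ("theta_h", "polar", 0.0, np.pi, np.pi / 2, 0.1, "phi_h"),
                      ("phi_h", "azimuth", -np.pi, np.pi, 0.0, 0.1, "theta_h"),
                      ("psi_h", "psi", 0.0, np.pi, 0.0, 0.1, None)])
    comps = []
    for i in range(n):
        params.append(_fraction(f"w_res{i}", round(0.4 / n, 6)))
        params.append(_diffusivity(f"d_res{i}", 1.0e-9))
        params.append(ParameterSpec(f"theta_r{i}", "polar", 0.0, np.pi,
                                    np.pi / 2, 0.1, partner=f"phi_r{i}"))
        params.append(ParameterSpec(f"phi_r{i}", "azimuth", -np.pi, np.pi,
                                    0.0, 0.1, partner=f"theta_r{i}"))
        comps.append((f"CHARMED_in{i}", "restricted"))
    comps.append(("Tensor", "hindered"))
    simplex = tuple(i for i, q in enumerate(params) if q.ptype == "fraction")
    return CompositeModel(name, tuple(comps), tuple(params), c,
                          simplex=simplex, orderings=((1, 2, 3),),
                          headline_fraction="w_res0")
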