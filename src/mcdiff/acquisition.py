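"""Diffusion acquisition schemes.

An :class:`AcquisitionScheme` holds, per acquired volume, the gradient
direction, the b-value and (optionally) the pulse timing: gradient
separation Δ (``big_delta``), gradient duration δ (``small_delta``) and echo
time TE.  All quantities are stored in SI units (b in s/m², times in s);
readers convert the conventional s/mm² on ingest.  Directions are unit
vectors; b=0 volumes may carry the zero vector.

Synthetic multi-shell schemes mimicking typical in-vivo protocols (e.g. a
3-shell b = 1000/2000/3000 s/mm² scheme with 30/40/50 directions plus 14
interleaved b0 volumes) can be generated with :func:`make_shell_scheme`.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "read_scheme",
    "write_scheme",
    "make_shell_scheme",
    "restrict_to_bmax",
    "sphere_to_cart",
    "cart_to_sphere",
]

#: b-values below this threshold (in whatever unit they arrive) are taken to
#: be expressed in s/mm² and are converted to s/m² on ingest.  Physical
#: b-values never exceed ~5e4 s/mm² while even b=1000 s/mm² is 1e9 s/m², so
#: the two unit systems are separated by orders of magnitude.
_SMM2_THRESHOLD = 1e5
_SMM2_TO_SM2 = 1e6


def sphere_to_cart(theta: float, phi: float) -> np.ndarray:
    """Unit vector n(θ, φ) = (sinθ cosφ, sinθ sinφ, cosθ).

    θ is the polar angle (from +z), φ the azimuth (from +x in the x-y
    plane).  This convention is fixed repository-wide.
    """
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def cart_to_sphere(n: np.ndarray) -> tuple[float, float]:
    """Inverse of :func:`sphere_to_cart` (θ ∈ [0, π], φ ∈ (−π, π])."""
    n = np.asarray(n, dtype=float)
    theta = math.acos(min(1.0, max(-1.0, n[2] / np.linalg.norm(n))))
    phi = math.atan2(n[1], n[0])
    return theta, phi


@dataclasses.dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume acquisition description, all fields in SI units."""

    directions: np.ndarray  # (m, 3) unit vectors; zero vector allowed at b=0
    b_values: np.ndarray  # (m,) s/m²
    big_delta: np.ndarray | None = None  # (m,) s, gradient separation Δ
    small_delta: np.ndarray | None = None  # (m,) s, gradient duration δ
    echo_time: np.ndarray | None = None  # (m,) s, TE

    def __post_init__(self):
        directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        b_values = np.atleast_1d(np.asarray(self.b_values, dtype=float))
        object.__setattr__(self, "directions", directions)
        object.__setattr__(self, "b_values", b_values)
        for name in ("big_delta", "small_delta", "echo_time"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, np.broadcast_to(
                    np.asarray(val, dtype=float), b_values.shape).copy())
        self._validate()

    def _validate(self):
        m = len(self.b_values)
        if self.directions.shape != (m, 3):
            raise ValueError(
                f"directions shape {self.directions.shape} does not match "
                f"{m} b-values")
        if not np.all(np.isfinite(self.b_values)):
            raise ValueError("non-finite b-values")
        if np.any(self.b_values < 0):
            raise ValueError("negative b-values")
        norms = np.linalg.norm(self.directions, axis=1)
        dw = self.b_values > 0
        if np.any(np.abs(norms[dw] - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted directions must be unit vectors")
        if np.any((norms > 1e-12) & (np.abs(norms - 1.0) > 1e-6)):
            raise ValueError("directions must be unit vectors or zero")
        if self.has_timing:
            if np.any(self.small_delta >= self.big_delta):
                raise ValueError("require δ < Δ")
            if np.any(self.echo_time <= 0):
                raise ValueError("require TE > 0")
        for name in ("big_delta", "small_delta", "echo_time"):
            val = getattr(self, name)
            if val is not None and len(val) != m:
                raise ValueError(f"{name} length mismatch")

    @property
    def n_volumes(self) -> int:
        return len(self.b_values)

    @property
    def has_timing(self) -> bool:
        return (self.big_delta is not None and self.small_delta is not None
                and self.echo_time is not None)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b_values == 0

    @property
    def q_magnitudes(self) -> np.ndarray:
        """|q| in 1/m derived from b = 4π²|q|²(Δ − δ/3)."""
        if not self.has_timing:
            raise ValueError("scheme has no Δ/δ timing; cannot derive |q|")
        tau = self.big_delta - self.small_delta / 3.0
        return np.sqrt(self.b_values / (4.0 * np.pi**2 * tau))

    def subset(self, index: np.ndarray) -> "AcquisitionScheme":
        def take(a):
            return None if a is None else a[index]
        return AcquisitionScheme(
            directions=self.directions[index],
            b_values=self.b_values[index],
            big_delta=take(self.big_delta),
            small_delta=take(self.small_delta),
            echo_time=take(self.echo_time),
        )


def _parse_table(path) -> np.ndarray:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError as exc:
            raise ValueError(f"non-numeric entry in {path}: {line!r}") from exc
    return np.asarray(rows, dtype=float)


def read_scheme(bval_path, bvec_path, protocol_path=None) -> AcquisitionScheme:
    """Read an FSL-dialect bval/bvec pair, optionally with a protocol table.

    The bvec file carries three rows of m columns.  The optional protocol
    table is whitespace-delimited with columns ``gx gy gz b Delta delta TE``
    in SI units ('#' starts a comment); its timing columns are attached to
    the scheme.  b-values smaller than 1e5 are interpreted as s/mm² and
    converted to s/m².
    """
    bvals = _parse_table(bval_path).ravel()
    bvecs = _parse_table(bvec_path)
    if bvecs.shape[0] != 3:
        bvecs = bvecs.T
    if bvecs.shape != (3, len(bvals)):
        raise ValueError(
            f"bvec shape {bvecs.shape} does not match {len(bvals)} b-values")
    if np.any(bvals < 0):
        raise ValueError("negative b-value")
    if np.all(bvals < _SMM2_THRESHOLD):
        bvals = bvals * _SMM2_TO_SM2
    big_delta = small_delta = echo_time = None
    if protocol_path is not None:
        table = _parse_table(protocol_path)
        if table.shape != (len(bvals), 7):
            raise ValueError(
                f"protocol table shape {table.shape}; expected ({len(bvals)}, 7)")
        big_delta, small_delta, echo_time = table[:, 4], table[:, 5], table[:, 6]
    return AcquisitionScheme(
        directions=bvecs.T, b_values=bvals,
        big_delta=big_delta, small_delta=small_delta, echo_time=echo_time)


def write_scheme(scheme: AcquisitionScheme, bval_path, bvec_path,
                 protocol_path=None) -> None:
    """Write ``scheme`` as bval/bvec (s/mm²) plus an optional protocol table.

    Round-trips bit-exactly through :func:`read_scheme` at the written
    precision (%.17g).
    """
    bvals_mm = scheme.b_values / _SMM2_TO_SM2
    Path(bval_path).write_text(
        " ".join("%.17g" % b for b in bvals_mm) + "\n")
    lines = [" ".join("%.17g" % x for x in scheme.directions[:, ax])
             for ax in range(3)]
    Path(bvec_path).write_text("\n".join(lines) + "\n")
    if protocol_path is not None:
        if not scheme.has_timing:
            raise ValueError("scheme has no timing; cannot write protocol table")
        with open(protocol_path, "w") as fh:
            fh.write("# gx gy gz b Delta delta TE (SI units)\n")
            for i in range(scheme.n_volumes):
                g = scheme.directions[i]
                fh.write("%.17g %.17g %.17g %.17g %.17g %.17g %.17g\n" % (
                    g[0], g[1], g[2], scheme.b_values[i],
                    scheme.big_delta[i], scheme.small_delta[i],
                    scheme.echo_time[i]))


def _repulsion_directions(n: int, rng: np.random.Generator,
                          n_iter: int = 200, step: float = 0.1) -> np.ndarray:
    """n approximately uniform hemisphere directions.

    Seeded random points are relaxed by electrostatic-style repulsion among
    the antipodally symmetrised point set for a fixed number of iterations.
    """
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    v[v[:, 2] < 0] *= -1.0
    for _ in range(n_iter):
        # pairwise forces from both each point and its antipode
        force = np.zeros_like(v)
        for sign in (1.0, -1.0):
            diff = v[:, None, :] - sign * v[None, :, :]
            dist2 = np.sum(diff * diff, axis=-1)
            np.fill_diagonal(dist2, np.inf)
            dist2[dist2 < 1e-12] = np.inf
            force += np.sum(diff / dist2[..., None] ** 1.5, axis=1)
        v = v + step / n * force
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    v[v[:, 2] < 0] *= -1.0
    return v


def make_shell_scheme(shells, n_b0: int,
                      timing: tuple[float, float, float] | None = None,
                      seed: int = 0) -> AcquisitionScheme:
    """Build a synthetic multi-shell scheme.

    Parameters
    ----------
    shells:
        List of ``(b_value_s_per_mm2, n_directions)`` pairs; b > 0 and at
        least 6 directions per shell.
    n_b0:
        Number of b=0 volumes, interleaved evenly among the weighted volumes.
    timing:
        Optional ``(Δ, δ, TE)`` in seconds, applied to every volume.
    seed:
        Seeds the direction generator; identical seeds give identical
        schemes.
    """
    shells = list(shells)
    if not shells:
        raise ValueError("empty shell list")
    for b, nd in shells:
        if b <= 0:
            raise ValueError("shell b-values must be positive")
        if nd < 6:
            raise ValueError("at least 6 directions per shell")
    rng = np.random.default_rng(seed)
    dw_dirs, dw_b = [], []
    for b, nd in shells:
        dirs = _repulsion_directions(nd, rng)
        dw_dirs.append(dirs)
        dw_b.append(np.full(nd, float(b) * _SMM2_TO_SM2))
    dw_dirs = np.vstack(dw_dirs)
    dw_b = np.concatenate(dw_b)
    n_dw = len(dw_b)
    m = n_dw + n_b0
    # interleave b0 volumes evenly
    b0_positions = set(np.round(np.linspace(0, m - 1, n_b0)).astype(int)) \
        if n_b0 > 0 else set()
    directions = np.zeros((m, 3))
    b_values = np.zeros(m)
    j = 0
    for i in range(m):
        if i in b0_positions:
            continue
        directions[i] = dw_dirs[j]
        b_values[i] = dw_b[j]
        j += 1
    kwargs = {}
    if timing is not None:
        big_delta, small_delta, echo_time = timing
        kwargs = dict(big_delta=np.full(m, big_delta),
                      small_delta=np.full(m, small_delta),
                      echo_time=np.full(m, echo_time))
    return AcquisitionScheme(directions=directions, b_values=b_values, **kwargs)


def restrict_to_bmax(scheme: AcquisitionScheme, b_max: float) -> AcquisitionScheme:
    """Keep only volumes with b ≤ b_max (b_max in s/m²), order preserved."""
    if b_max <= 0:
        raise ValueError("b_max must be positive")
    keep = scheme.b_values <= b_max
    if not np.any(scheme.b_values[keep] > 0):
        raise ValueError("restriction would leave no diffusion-weighted volumes")
    return scheme.subset(keep)
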