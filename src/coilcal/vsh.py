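"""Real vector-spherical-harmonic (VSH) basis for source-free magnetic fields.

A magnetic field in a source-free sphere (all sources, i.e. the coils,
outside) is the gradient of a harmonic scalar potential and can be expanded
in gradients of regular real solid harmonics::

    B(r) = sum_{l=1}^{lmax} sum_{m=-l}^{l}  beta_lm  w_lm(r),
    w_lm(r) = grad( r^l Y_lm(theta, phi) ) / N_l,

where ``Y_lm`` are real orthonormal spherical harmonics (no Condon-Shortley
phase) and ``N_l`` scales each basis field to unit RMS magnitude over a
reference sphere.  Degree l=1 terms are the three spatially homogeneous
field components; l=2 terms are the five independent first-order gradients;
higher degrees encode finer spatial structure.

Conventions (fixed, used everywhere in this package):

* spherical angles: ``theta`` = polar angle from +z, ``phi`` = azimuth
  from +x; right-handed Cartesian frame; SI units (T, m).
* component ordering: degree ``l`` ascending, order ``m`` from ``-l`` to
  ``l``; the total count is ``C = lmax*(lmax+2)`` (35 for lmax=5).
* normalization tag ``"rms_sphere_<R>"``: unit RMS field magnitude on the
  sphere of radius ``R`` (default 0.1 m) centred on the expansion origin.
  For orthonormal ``Y_lm`` the constant is analytic,
  ``N_l = R^(l-1) * sqrt(l*(2l+1)/(4*pi))``.

The basis fields are evaluated from exact monomial tables generated
symbolically once per ``lmax`` (each Cartesian component of ``w_lm`` is a
homogeneous polynomial of degree ``l-1``), so divergence- and curl-freeness
hold to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "VSHModel",
    "n_components",
    "degree_order_pairs",
    "build_basis_matrix",
    "evaluate_field",
    "uniform_part",
    "gradient_part",
    "spectrum",
    "truncate",
]

DEFAULT_REFERENCE_RADIUS = 0.1  # m; sphere over which basis fields have unit RMS


def n_components(lmax: int) -> int:
    """Number of basis components for degrees 1..lmax: sum(2l+1) = lmax(lmax+2)."""
    return lmax * (lmax + 2)


def degree_order_pairs(lmax: int) -> list[tuple[int, int]]:
    """Component ordering: (l ascending, m from -l to l)."""
    return [(l, m) for l in range(1, lmax + 1) for m in range(-l, l + 1)]


# ---------------------------------------------------------------------------
# Exact monomial tables for grad(r^l Y_lm)
# ---------------------------------------------------------------------------

def _solid_harmonic_poly(l: int, m: int):
    """Sympy polynomial (in x, y, z) of the regular solid harmonic r^l Y_lm.

    ``Y_lm`` real, orthonormal over the unit sphere, no Condon-Shortley
    phase:  m=0 -> Y_l0;  m>0 -> sqrt(2)(-1)^m Re Y_l^m;
    m<0 -> sqrt(2)(-1)^|m| Im Y_l^|m|  (the (-1)^|m| cancels the phase
    carried by the associated Legendre function).
    """
    import sympy as sp

    x, y, z, u = sp.symbols("x y z u", real=True)
    r2 = x * x + y * y + z * z
    am = abs(m)
    # strip the (1-u^2)^(am/2) prefactor; the remainder is a polynomial in u
    D = sp.cancel(sp.expand_trig(sp.assoc_legendre(l, am, u)) / sp.sqrt(1 - u**2) ** am)
    body = sp.Integer(0)
    for (k,), c in sp.Poly(sp.simplify(D), u).terms():
        j = l - am - k
        body += c * z**k * r2 ** (j // 2)  # j is even by Legendre parity
    norm = sp.sqrt(sp.Rational(2 * l + 1, 4) / sp.pi * sp.factorial(l - am) / sp.factorial(l + am))
    if m == 0:
        expr = norm * body
    else:
        w = sp.expand((x + sp.I * y) ** am)
        ang = sp.re(w) if m > 0 else sp.im(w)
        expr = sp.sqrt(2) * norm * (-1) ** am * body * ang
    return sp.Poly(sp.expand(expr), x, y, z)


@lru_cache(maxsize=8)
def _basis_tables(lmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Monomial tables of the (unnormalized) basis gradients.

    Returns ``(exponents, coeffs)`` with ``exponents`` of shape (K, 3) and
    ``coeffs`` of shape (C, 3, K) such that Cartesian component ``j`` of
    ``grad(r^l Y_lm)`` at point p equals
    ``sum_k coeffs[c, j, k] * prod(p**exponents[k])``.
    """
    grads: list[dict[tuple[int, int, int], float]] = []
    for l, m in degree_order_pairs(lmax):
        poly = _solid_harmonic_poly(l, m)
        comp: list[dict[tuple[int, int, int], float]] = [{}, {}, {}]
        for (a, b, c), coef in poly.terms():
            coef = float(coef)
            for j, e in enumerate((a, b, c)):
                if e > 0:
                    key = (a - (j == 0), b - (j == 1), c - (j == 2))
                    comp[j][key] = comp[j].get(key, 0.0) + e * coef
        grads.append({(j, k): v for j, d in enumerate(comp) for k, v in d.items()})
    exps = sorted({k for g in grads for (_, k) in g})
    index = {k: i for i, k in enumerate(exps)}
    C = len(grads)
    coeffs = np.zeros((C, 3, len(exps)))
    for ci, g in enumerate(grads):
        for (j, k), v in g.items():
            coeffs[ci, j, index[k]] = v
    return np.asarray(exps, dtype=int), coeffs


def _normalization_scales(lmax: int, reference_radius: float) -> np.ndarray:
    """Per-component divisor giving unit RMS magnitude on the reference sphere."""
    ls = np.array([l for l, _ in degree_order_pairs(lmax)], dtype=float)
    return reference_radius ** (ls - 1) * np.sqrt(ls * (2 * ls + 1) / (4 * np.pi))


def _basis_fields(
    points: np.ndarray, lmax: int, origin: np.ndarray, reference_radius: float
) -> np.ndarray:
    """Evaluate all basis fields: returns array of shape (M, 3, C)."""
    exps, coeffs = _basis_tables(lmax)
    rel = np.atleast_2d(points) - origin
    # monomials: (M, K)
    mono = np.prod(rel[:, None, :] ** exps[None, :, :], axis=2)
    W = np.einsum("mk,cjk->mjc", mono, coeffs)
    W /= _normalization_scales(lmax, reference_radius)[None, None, :]
    return W


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class VSHModel:
    """VSH representation of one coil's magnetic field.

    Coefficients are in tesla per basis unit (basis fields are dimensionless
    with unit RMS on the reference sphere); when fitted from per-unit-current
    measurements they carry T/A.
    """

    origin: np.ndarray
    lmax: int
    coeffs: np.ndarray
    normalization_tag: str = ""
    reference_radius: float = DEFAULT_REFERENCE_RADIUS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.coeffs = np.asarray(self.coeffs, dtype=float).reshape(-1)
        if self.lmax < 1:
            raise ValueError("lmax must be >= 1")
        if not np.all(np.isfinite(self.origin)):
            raise ValueError("origin must be finite")
        C = n_components(self.lmax)
        if self.coeffs.size != C:
            raise ValueError(
                f"coefficient vector has {self.coeffs.size} entries; "
                f"lmax={self.lmax} requires {C}"
            )
        if not self.normalization_tag:
            self.normalization_tag = f"rms_sphere_{self.reference_radius:g}"

    @property
    def n_coeffs(self) -> int:
        return self.coeffs.size

    def degree_orders(self) -> list[tuple[int, int]]:
        return degree_order_pairs(self.lmax)

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "lmax": int(self.lmax),
            "normalization_tag": self.normalization_tag,
            "reference_radius": float(self.reference_radius),
            "coeffs": self.coeffs.tolist(),
            "units": {"origin": "m", "coeffs": "T_per_basis_unit"},
            "metadata": {k: v for k, v in self.metadata.items() if _json_safe(v)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VSHModel":
        return cls(
            origin=np.asarray(d["origin"], dtype=float),
            lmax=int(d["lmax"]),
            coeffs=np.asarray(d["coeffs"], dtype=float),
            normalization_tag=d.get("normalization_tag", ""),
            reference_radius=float(d.get("reference_radius", DEFAULT_REFERENCE_RADIUS)),
            metadata=dict(d.get("metadata", {})),
        )


def _json_safe(v) -> bool:
    return isinstance(v, (int, float, str, bool, type(None)))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_basis_matrix(
    points: np.ndarray,
    lmax: int,
    origin: np.ndarray,
    projections: np.ndarray | None = None,
    reference_radius: float = DEFAULT_REFERENCE_RADIUS,
    projection_tol: float = 1e-8,
) -> np.ndarray:
    """Design matrix of basis fields evaluated at measurement points.

    Parameters
    ----------
    points : (M, 3) array, m
        Measurement positions.
    lmax : int
        Degree cutoff (>= 1); the matrix has ``C = lmax*(lmax+2)`` columns.
    origin : (3,) array, m
        Expansion origin.
    projections : (M, 3) array, optional
        Unit measurement directions.  If given the matrix has M rows, each
        the projection of the basis fields onto the direction; otherwise it
        has 3M rows ordered point-major (Bx, By, Bz of point 0, then
        point 1, ...).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    origin = np.asarray(origin, dtype=float).reshape(3)
    if lmax < 1:
        raise ValueError("lmax must be >= 1")
    if not (np.all(np.isfinite(points)) and np.all(np.isfinite(origin))):
        raise ValueError("points and origin must be finite")
    W = _basis_fields(points, lmax, origin, reference_radius)  # (M, 3, C)
    if projections is None:
        M, _, C = W.shape
        return W.reshape(M * 3, C)
    projections = np.atleast_2d(np.asarray(projections, dtype=float))
    if projections.shape != points.shape:
        raise ValueError("projections must match points in shape")
    norms = np.linalg.norm(projections, axis=1)
    if np.any(np.abs(norms - 1.0) > projection_tol):
        raise ValueError("projection vectors must be unit-norm")
    return np.einsum("mjc,mj->mc", W, projections)


def evaluate_field(model: VSHModel, points: np.ndarray, warn_outside: bool = True) -> np.ndarray:
    """Field vectors (M, 3) [T] of the model at given points.

    Points outside the model's validity radius (largest source-free sphere,
    recorded at fit time) trigger a warning: the expansion still evaluates
    but is extrapolating.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    radius = model.metadata.get("validity_radius")
    if warn_outside and radius is not None:
        dist = np.linalg.norm(points - model.origin, axis=1)
        if np.any(dist > radius * (1 + 1e-9)):
            warnings.warn(
                f"evaluating VSH model outside its validity radius "
                f"({dist.max():.3g} m > {radius:.3g} m); extrapolation",
                stacklevel=2,
            )
    W = _basis_fields(points, model.lmax, model.origin, model.reference_radius)
    return np.einsum("mjc,c->mj", W, model.coeffs)


def truncate(model: VSHModel, lmax: int) -> VSHModel:
    """Model restricted to degrees <= lmax (coefficients simply dropped)."""
    if lmax < 1 or lmax > model.lmax:
        raise ValueError("truncation lmax must be in [1, model.lmax]")
    return VSHModel(
        origin=model.origin,
        lmax=lmax,
        coeffs=model.coeffs[: n_components(lmax)],
        normalization_tag=model.normalization_tag,
        reference_radius=model.reference_radius,
        metadata=dict(model.metadata),
    )


def uniform_part(model: VSHModel) -> np.ndarray:
    """Spatially constant (homogeneous) field from the degree-1 coefficients [T].

    All basis fields of degree l >= 2 are homogeneous polynomials of degree
    l-1 and vanish at the origin, so this equals the full field evaluated at
    the expansion origin.
    """
    only_l1 = np.zeros_like(model.coeffs)
    only_l1[:3] = model.coeffs[:3]
    W = _basis_fields(model.origin[None, :], model.lmax, model.origin, model.reference_radius)
    return np.einsum("mjc,c->mj", W, only_l1)[0]


def gradient_part(model: VSHModel, step: float | None = None) -> np.ndarray:
    """First-order gradient tensor G[j, k] = dB_j/dx_k at the origin [T/m].

    Only the degree-2 coefficients contribute; in a source-free region the
    tensor is symmetric and traceless.  Central differences are exact here
    because degree-2 basis fields are linear in position.
    """
    if model.lmax < 2:
        raise ValueError("gradient_part requires lmax >= 2")
    only_l2 = np.zeros_like(model.coeffs)
    only_l2[3:8] = model.coeffs[3:8]
    sub = VSHModel(
        origin=model.origin,
        lmax=model.lmax,
        coeffs=only_l2,
        normalization_tag=model.normalization_tag,
        reference_radius=model.reference_radius,
    )
    h = step if step is not None else 1e-3 * model.reference_radius
    G = np.zeros((3, 3))
    for k in range(3):
        dp = np.zeros(3)
        dp[k] = h
        bp = evaluate_field(sub, model.origin + dp, warn_outside=False)[0]
        bm = evaluate_field(sub, model.origin - dp, warn_outside=False)[0]
        G[:, k] = (bp - bm) / (2 * h)
    return G


def spectrum(model: VSHModel) -> pd.DataFrame:
    """VSH spectrum: squared coefficient per (l, m) plus degree sums.

    Columns: ``l``, ``m``, ``coeff``, ``power`` (= coeff**2) and
    ``degree_power`` (sum of ``power`` over the degree, repeated on each of
    its rows).  ``power`` sums to ``||coeffs||^2``.
    """
    pairs = model.degree_orders()
    df = pd.DataFrame(
        {
            "l": [l for l, _ in pairs],
            "m": [m for _, m in pairs],
            "coeff": model.coeffs,
            "power": model.coeffs**2,
        }
    )
    df["degree_power"] = df.groupby("l")["power"].transform("sum")
    return df
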