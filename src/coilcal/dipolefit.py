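"""Magnetic-dipole forward modeling and localization with a calibrated array.

Phantom sources (small current loops) are modelled as ideal point magnetic
dipoles, ``B = mu0/(4 pi) * (3 (m.rhat) rhat - m) / d^3``.  Localization is
a grid search over candidate positions — the moment enters the forward
amplitudes linearly and is solved by least squares at every candidate
(separable least squares) — followed by derivative-free refinement of the
position from the best node.  Channels whose time course does not track the
excitation reference (latency-adjusted correlation below a threshold) are
rejected before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .calibrate import SensorParameters

__all__ = [
    "DipoleSource",
    "GridSpec",
    "DipoleFitResult",
    "dipole_field",
    "forward_amplitudes",
    "correlation_mask",
    "fit_dipole",
]

MU0 = 4e-7 * np.pi  # T*m/A
SINGULARITY_GUARD = 1e-3  # m; minimum sensor-dipole distance


@dataclass
class DipoleSource:
    """Point magnetic dipole: position [m] and moment vector [A*m^2]."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.moment = np.asarray(self.moment, dtype=float).reshape(3)
        if not (np.all(np.isfinite(self.position)) and np.all(np.isfinite(self.moment))):
            raise ValueError("dipole position and moment must be finite")


def dipole_field(dipole: DipoleSource, points: np.ndarray) -> np.ndarray:
    """Free-space point-dipole field at given points, (M, 3) [T]."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    diff = points - dipole.position
    dist = np.linalg.norm(diff, axis=1)
    if np.any(dist < SINGULARITY_GUARD):
        raise ValueError(
            f"field point within {SINGULARITY_GUARD*1e3:.0f} mm of the dipole position"
        )
    rhat = diff / dist[:, None]
    mdotr = rhat @ dipole.moment
    return MU0 / (4 * np.pi) * (3 * mdotr[:, None] * rhat - dipole.moment) / dist[:, None] ** 3


def _lead_field(positions: np.ndarray, sensors: list[SensorParameters]) -> np.ndarray:
    """Lead-field tensor L of shape (P, n_ch, 3): amplitude = L[p] @ moment.

    L[p, c, :] = g_c * mu0/(4 pi d^3) * (3 (n_c . rhat) rhat - n_c) for a
    dipole at candidate position p seen by channel c.
    """
    pos = np.vstack([s.position for s in sensors])
    ori = np.vstack([s.orientation for s in sensors])
    gains = np.array([s.gain for s in sensors])
    diff = pos[None, :, :] - np.atleast_2d(positions)[:, None, :]  # (P, C, 3)
    dist = np.linalg.norm(diff, axis=2)
    dist = np.maximum(dist, SINGULARITY_GUARD)
    rhat = diff / dist[..., None]
    ndotr = np.einsum("pcj,cj->pc", rhat, ori)
    L = 3 * ndotr[..., None] * rhat - ori[None, :, :]
    L *= (gains / (4 * np.pi / MU0))[None, :, None] / dist[..., None] ** 3
    return L


def forward_amplitudes(dipole: DipoleSource, sensors: list[SensorParameters]) -> np.ndarray:
    """Per-channel lock-in amplitudes [V]: g_c * B(r_c) . n_c."""
    pos = np.vstack([s.position for s in sensors])
    dist = np.linalg.norm(pos - dipole.position, axis=1)
    if np.any(dist < SINGULARITY_GUARD):
        raise ValueError("sensor within the dipole singularity guard distance")
    return _lead_field(dipole.position[None, :], sensors)[0] @ dipole.moment


def correlation_mask(
    channel_series: np.ndarray,
    reference: np.ndarray,
    threshold: float = 0.9,
    frequency: float | None = None,
    sample_rate: float | None = None,
) -> np.ndarray:
    """Reject channels that do not track the excitation reference.

    For each channel the maximum normalized cross-correlation with the
    reference over lags within +/- one reference period (``sample_rate /
    frequency`` samples; all lags if the period is not given) is compared
    with ``threshold``.  Zero-variance channels are masked out with a
    warning.
    """
    series = np.atleast_2d(np.asarray(channel_series, dtype=float))
    ref = np.asarray(reference, dtype=float).reshape(-1)
    if series.shape[1] != ref.size:
        raise ValueError("channel series and reference must have equal length")
    ref_c = ref - ref.mean()
    ref_norm = np.linalg.norm(ref_c)
    if ref_norm == 0:
        raise ValueError("reference has zero variance")
    max_lag = series.shape[1] - 1
    if frequency is not None and sample_rate is not None:
        max_lag = min(max_lag, int(round(sample_rate / frequency)))
    mask = np.zeros(series.shape[0], dtype=bool)
    for c, v in enumerate(series):
        vc = v - v.mean()
        vnorm = np.linalg.norm(vc)
        if vnorm == 0:
            warnings.warn(f"channel {c} has zero variance; rejected", stacklevel=2)
            continue
        # full cross-correlation, restricted to the allowed lag window
        xc = np.correlate(vc, ref_c, mode="full") / (vnorm * ref_norm)
        center = ref.size - 1
        window = xc[max(0, center - max_lag): center + max_lag + 1]
        mask[c] = np.max(window) >= threshold
    return mask


@dataclass
class GridSpec:
    """Uniform search grid: axis-aligned box with fixed node spacing."""

    lower: np.ndarray  # (3,) m
    upper: np.ndarray  # (3,) m
    spacing: float = 5e-3  # m

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float).reshape(3)
        self.upper = np.asarray(self.upper, dtype=float).reshape(3)
        if np.any(self.upper <= self.lower) or self.spacing <= 0:
            raise ValueError("grid box must have positive extent and spacing")

    def nodes(self) -> np.ndarray:
        axes = [
            np.arange(lo, hi + 0.5 * self.spacing, self.spacing)
            for lo, hi in zip(self.lower, self.upper)
        ]
        g = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([a.ravel() for a in g])

    @classmethod
    def default_below_array(
        cls, sensors: list[SensorParameters], extent=(0.12, 0.12, 0.06), spacing: float = 5e-3
    ) -> "GridSpec":
        """12 x 12 x 6 cm box below (toward -z from) the array's footprint."""
        pos = np.vstack([s.position for s in sensors])
        cx, cy = pos[:, :2].mean(axis=0)
        ztop = pos[:, 2].min() - 0.01
        ex, ey, ez = extent
        return cls(
            lower=np.array([cx - ex / 2, cy - ey / 2, ztop - ez]),
            upper=np.array([cx + ex / 2, cy + ey / 2, ztop]),
            spacing=spacing,
        )


@dataclass
class DipoleFitResult:
    dipole: DipoleSource
    residual_norm: float  # |y - L m| [V]
    relative_residual: float  # residual_norm / |y|
    grid_residual: float
    n_channels: int


def _solve_moment(L: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares moments for a batch of lead fields (P, C, 3).

    Returns (moments (P, 3), residual norms (P,)).
    """
    LtL = np.einsum("pci,pcj->pij", L, L)
    Lty = np.einsum("pci,c->pi", L, y)
    # guard singular normal matrices (degenerate geometry) with pinv fallback
    try:
        m = np.linalg.solve(LtL, Lty[..., None])[..., 0]
    except np.linalg.LinAlgError:
        m = np.einsum("pij,pj->pi", np.linalg.pinv(LtL), Lty)
    resid = np.einsum("pcj,pj->pc", L, m) - y[None, :]
    return m, np.linalg.norm(resid, axis=1)


def fit_dipole(
    amplitudes: np.ndarray,
    sensors: list[SensorParameters],
    grid: GridSpec,
    mask: np.ndarray | None = None,
    position_step: float = 5e-3,
    maxiter: int = 2000,
) -> DipoleFitResult:
    """Localize one dipole from per-channel amplitudes [V].

    Stage 1 scores every grid node by the residual of the linearly solved
    moment (ties broken by first index); stage 2 refines the best node's
    position with Nelder-Mead, re-solving the moment at each evaluation.
    Requires >= 6 unmasked channels (six dipole parameters).
    """
    y = np.asarray(amplitudes, dtype=float).reshape(-1)
    if len(sensors) != y.size:
        raise ValueError("one amplitude per channel is required")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool).reshape(-1)
        if mask.size != y.size:
            raise ValueError("mask length must match channel count")
        sensors = [s for s, keep in zip(sensors, mask) if keep]
        y = y[mask]
    if y.size < 6:
        raise ValueError(f"only {y.size} channels available; >= 6 required")

    nodes = grid.nodes()
    L = _lead_field(nodes, sensors)
    _, resid = _solve_moment(L, y)
    best = int(np.argmin(resid))  # argmin takes the first minimum on ties
    grid_residual = float(resid[best])
    x0 = nodes[best]

    def fun(xs):
        p = x0 + xs * position_step
        Lp = _lead_field(p[None, :], sensors)
        _, r = _solve_moment(Lp, y)
        return float(r[0])

    simplex = np.vstack([np.zeros(3), np.eye(3)])
    res = minimize(
        fun,
        np.zeros(3),
        method="Nelder-Mead",
        options=dict(initial_simplex=simplex, xatol=1e-6, fatol=1e-300, maxiter=maxiter),
    )
    position = x0 + res.x * position_step
    Lp = _lead_field(position[None, :], sensors)
    moment, r = _solve_moment(Lp, y)
    ynorm = float(np.linalg.norm(y))
    return DipoleFitResult(
        dipole=DipoleSource(position=position, moment=moment[0]),
        residual_norm=float(r[0]),
        relative_residual=float(r[0]) / ynorm if ynorm > 0 else np.nan,
        grid_residual=grid_residual,
        n_channels=y.size,
    )
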