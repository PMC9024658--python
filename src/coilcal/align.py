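"""Rigid alignment of estimated point sets to reference positions.

Estimated sensor or dipole positions live in the frame of the VSH expansion
origin; reference (CAD/ground-truth) positions live in their own frame.
Relative geometry is scored by first aligning the estimates to the
reference with the closed-form least-squares rigid transform (Umeyama) and
then reporting the per-point distances.  Correspondences are given by
channel/dipole index; no matching problem is solved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["umeyama_rigid", "apply_transform", "position_errors", "PositionErrorReport"]


def umeyama_rigid(
    source: np.ndarray, target: np.ndarray, with_scale: bool = False
):
    """Least-squares similarity transform mapping source points onto target.

    Returns ``(R, t)`` — or ``(R, t, s)`` with ``with_scale`` — minimizing
    ``mean || target_i - s R source_i - t ||^2`` with R a proper rotation
    (det +1; reflections are disallowed via the standard sign correction).
    Requires >= 3 non-collinear correspondences.
    """
    X = np.atleast_2d(np.asarray(source, dtype=float))
    Y = np.atleast_2d(np.asarray(target, dtype=float))
    if X.shape != Y.shape or X.shape[0] < 3 or X.shape[1] != 3:
        raise ValueError("source and target must be matching (M >= 3, 3) arrays")
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    cov = Yc.T @ Xc / X.shape[0]
    U, D, Vt = np.linalg.svd(cov)
    if D[1] <= 1e-12 * max(D[0], 1e-300):
        raise ValueError("degenerate (collinear) point configuration")
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    if with_scale:
        var_x = np.mean(np.sum(Xc**2, axis=1))
        s = float(np.trace(np.diag(D) @ S) / var_x)
        t = my - s * R @ mx
        return R, t, s
    t = my - R @ mx
    return R, t


def apply_transform(points: np.ndarray, R: np.ndarray, t: np.ndarray, s: float = 1.0):
    return s * np.atleast_2d(np.asarray(points, dtype=float)) @ np.asarray(R).T + np.asarray(t)


@dataclass
class PositionErrorReport:
    distances: np.ndarray  # per-point Euclidean distance [m]
    mean: float
    rms: float
    max: float
    min: float

    def as_dict(self) -> dict:
        return {
            "mean_m": self.mean,
            "rms_m": self.rms,
            "min_m": self.min,
            "max_m": self.max,
            "distances_m": self.distances.tolist(),
        }


def position_errors(
    source: np.ndarray, target: np.ndarray, align: bool = True
) -> PositionErrorReport:
    """Per-point distances (optionally after unit-scale rigid alignment).

    With ``align`` the source set is first mapped onto the target with
    :func:`umeyama_rigid`, which scores relative geometry only; alignment
    never increases the mean squared distance.
    """
    X = np.atleast_2d(np.asarray(source, dtype=float))
    Y = np.atleast_2d(np.asarray(target, dtype=float))
    if X.shape != Y.shape:
        raise ValueError("point sets must have matching shapes")
    if align:
        R, t = umeyama_rigid(X, Y)
        X = apply_transform(X, R, t)
    d = np.linalg.norm(X - Y, axis=1)
    return PositionErrorReport(
        distances=d,
        mean=float(d.mean()),
        rms=float(np.sqrt(np.mean(d**2))),
        max=float(d.max()),
        min=float(d.min()),
    )
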