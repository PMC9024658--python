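"""Synthesis of coil currents that excite targeted VSH field components.

Given the coefficient matrix ``B`` of a coil set, the minimum-norm currents
producing a desired coefficient vector ``target`` are ``i = pinv(B) @ target``.
Whether an arrangement can produce a component at all is diagnosed from the
rank/conditioning of ``B`` and from the achieved-to-requested coefficient
ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fieldmodel import DEFAULT_SV_CUTOFF, CoilModelSet
from .vsh import degree_order_pairs, n_components

__all__ = [
    "currents_for_harmonic",
    "harmonic_target",
    "synthesis_diagnostics",
    "quantize_currents",
    "SynthesisReport",
    "AchievabilityWarning",
]

DEFAULT_ACHIEVABILITY_THRESHOLD = 0.5  # heuristic warning level


class AchievabilityWarning(UserWarning):
    """Requested VSH component poorly reproducible by the coil arrangement."""


def harmonic_target(lmax: int, l: int, m: int, amplitude: float = 1.0) -> np.ndarray:
    """Coefficient vector with a single nonzero entry at component (l, m)."""
    pairs = degree_order_pairs(lmax)
    if (l, m) not in pairs:
        raise ValueError(f"component (l={l}, m={m}) not in basis with lmax={lmax}")
    target = np.zeros(len(pairs))
    target[pairs.index((l, m))] = amplitude
    return target


def currents_for_harmonic(
    model_set: CoilModelSet,
    target: np.ndarray,
    sv_cutoff: float = DEFAULT_SV_CUTOFF,
    achievability_threshold: float = DEFAULT_ACHIEVABILITY_THRESHOLD,
) -> np.ndarray:
    """Minimum-norm currents ``i = pinv(B) @ target`` [A].

    Warns when the achieved/requested ratio of any targeted component falls
    below ``achievability_threshold`` (the arrangement cannot produce that
    component well).
    """
    target = np.asarray(target, dtype=float).reshape(-1)
    B = model_set.coefficient_matrix
    if target.size != B.shape[0]:
        raise ValueError(
            f"target has {target.size} entries; basis has {B.shape[0]} components"
        )
    currents = np.linalg.pinv(B, rcond=sv_cutoff) @ target
    achieved = B @ currents
    nz = np.abs(target) > 0
    if np.any(nz):
        ratio = achieved[nz] / target[nz]
        if np.any(ratio < achievability_threshold):
            worst = float(np.min(ratio))
            warnings.warn(
                f"achieved/requested coefficient ratio {worst:.2f} below "
                f"{achievability_threshold}; coil arrangement cannot generate the "
                "requested component well",
                AchievabilityWarning,
                stacklevel=2,
            )
    return currents


@dataclass
class SynthesisReport:
    """Diagnostics of a coil arrangement's ability to synthesize VSH fields."""

    condition_number: float
    rank: int
    n_rows: int
    n_coils: int
    degree_cutoff: int | None
    achieved_ratio: np.ndarray  # per basis component within the cutoff
    components: list  # (l, m) labels matching achieved_ratio

    def achievable(self, threshold: float = DEFAULT_ACHIEVABILITY_THRESHOLD) -> np.ndarray:
        return self.achieved_ratio >= threshold


def synthesis_diagnostics(
    model_set: CoilModelSet,
    degree_cutoff: int | None = None,
    sv_cutoff: float = DEFAULT_SV_CUTOFF,
) -> SynthesisReport:
    """Condition number, numerical rank, and per-component achievability of B.

    With ``degree_cutoff`` the coefficient matrix is restricted to the rows
    of degrees <= cutoff (e.g. 2 to ask only about homogeneous and
    first-order gradient fields).  The achieved ratio of component k is the
    k-th coefficient of ``B @ pinv(B) @ e_k`` — 1 when the component lies in
    the column space of B, < 1 otherwise.
    """
    B = model_set.coefficient_matrix
    pairs = degree_order_pairs(model_set.lmax)
    if degree_cutoff is not None:
        rows = n_components(degree_cutoff)
        B = B[:rows]
        pairs = pairs[:rows]
    sv = np.linalg.svd(B, compute_uv=False)
    rank = int(np.sum(sv > sv_cutoff * sv[0]))
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    projector = B @ np.linalg.pinv(B, rcond=sv_cutoff)
    achieved = np.diag(projector).copy()
    return SynthesisReport(
        condition_number=cond,
        rank=rank,
        n_rows=B.shape[0],
        n_coils=B.shape[1],
        degree_cutoff=degree_cutoff,
        achieved_ratio=achieved,
        components=pairs,
    )


def quantize_currents(currents: np.ndarray, step: float) -> np.ndarray:
    """Round currents to a uniform step, emulating finite DAC bit resolution.

    Off by default in all pipelines; a nonzero ``step`` [A] rounds each
    current to the nearest multiple.
    """
    if step <= 0:
        raise ValueError("quantization step must be positive")
    return np.round(np.asarray(currents, dtype=float) / step) * step
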