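"""Fitting VSH field models to discrete coil-field measurements.

A coil's field is mapped with a calibrated vector magnetometer at known
positions; the VSH coefficients are the least-squares solution
``beta = pinv(S) @ m`` where ``S`` is the basis design matrix and ``m`` the
stacked measurements.  Measured fields are stored per unit applied current
(T/A) so a model scales linearly with the drive current.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .vsh import (
    DEFAULT_REFERENCE_RADIUS,
    VSHModel,
    build_basis_matrix,
    evaluate_field,
    n_components,
)

__all__ = [
    "FieldMeasurementSet",
    "CoilModelSet",
    "RankDeficiencyWarning",
    "fit_coefficients",
    "normalized_rms_error",
    "superpose_models",
]

DEFAULT_SV_CUTOFF = 1e-10  # relative singular-value cutoff for pseudo-inverses


class RankDeficiencyWarning(UserWarning):
    """Design or coefficient matrix numerically rank-deficient."""


@dataclass
class FieldMeasurementSet:
    """Field map of one coil: positions plus measured field per unit current.

    ``values`` may be (M, 3) triaxial field vectors, or (M,) scalars with
    ``projections`` giving the M unit measurement directions.  Raw values
    are divided by ``current`` on construction, so ``values`` is in T/A.
    """

    coil_id: str
    positions: np.ndarray
    values: np.ndarray
    current: float = 1.0
    projections: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3 or len(self.positions) < 1:
            raise ValueError("positions must be a nonempty (M, 3) array")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        if self.current == 0 or not np.isfinite(self.current):
            raise ValueError("applied current must be finite and nonzero")
        if self.projections is not None:
            self.projections = np.atleast_2d(np.asarray(self.projections, dtype=float))
            if self.values.shape != (len(self.positions),):
                raise ValueError("projected measurements require values of shape (M,)")
            if self.projections.shape != self.positions.shape:
                raise ValueError("projections must be (M, 3)")
        elif self.values.shape != self.positions.shape:
            raise ValueError("triaxial measurements require values of shape (M, 3)")
        # store per unit current
        self.values = self.values / self.current

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def is_triaxial(self) -> bool:
        return self.projections is None

    def stacked_values(self) -> np.ndarray:
        """Measurement vector as fed to the design matrix (3M or M rows)."""
        return self.values.reshape(-1)

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)


def fit_coefficients(
    meas: FieldMeasurementSet,
    lmax: int,
    origin: np.ndarray | None = None,
    sv_cutoff: float = DEFAULT_SV_CUTOFF,
    reference_radius: float = DEFAULT_REFERENCE_RADIUS,
) -> VSHModel:
    """Least-squares VSH fit ``beta = pinv(S) @ m`` to one coil's field map.

    ``origin`` defaults to the centroid of the measurement positions (this
    puts the zero crossings of the gradient components inside the mapped
    volume).  The pseudo-inverse truncates singular values below
    ``sv_cutoff`` times the largest; a numerically rank-deficient design
    raises :class:`RankDeficiencyWarning` and records the achieved rank.
    """
    origin = meas.centroid() if origin is None else np.asarray(origin, dtype=float).reshape(3)
    C = n_components(lmax)
    S = build_basis_matrix(
        meas.positions, lmax, origin, projections=meas.projections,
        reference_radius=reference_radius,
    )
    if S.shape[0] < C:
        warnings.warn(
            f"only {S.shape[0]} measurement rows for {C} coefficients; "
            "fit is underdetermined",
            RankDeficiencyWarning,
            stacklevel=2,
        )
    m = meas.stacked_values()
    coeffs, _, rank, sv = linalg.lstsq(S, m, cond=sv_cutoff)
    if rank < C:
        warnings.warn(
            f"design matrix rank {rank} < {C} for coil {meas.coil_id!r}; "
            "coefficients in the null space are unconstrained",
            RankDeficiencyWarning,
            stacklevel=2,
        )
    model = VSHModel(
        origin=origin,
        lmax=lmax,
        coeffs=coeffs,
        reference_radius=reference_radius,
        metadata={
            "coil_id": meas.coil_id,
            "rank": int(rank),
            "condition_number": float(sv[0] / sv[-1]) if sv is not None and sv[-1] > 0 else np.inf,
            "validity_radius": float(np.linalg.norm(meas.positions - origin, axis=1).max()),
        },
    )
    model.metadata["nrmse"] = normalized_rms_error(model, meas)
    return model


def normalized_rms_error(model: VSHModel, meas: FieldMeasurementSet) -> float:
    """RMS of (prediction - measurement) over all scalar components, divided
    by the RMS of the measurement (NRMSE)."""
    data = meas.stacked_values()
    rms = float(np.sqrt(np.mean(data**2)))
    if rms == 0:
        raise ValueError("all-zero measurements: NRMSE undefined")
    pred = evaluate_field(model, meas.positions, warn_outside=False)
    if not meas.is_triaxial:
        pred = np.einsum("mj,mj->m", pred, meas.projections)
    resid = pred.reshape(-1) - data
    return float(np.sqrt(np.mean(resid**2)) / rms)


@dataclass
class CoilModelSet:
    """VSH models of N coils sharing origin, lmax and normalization.

    The coefficient matrix ``B`` (C x N) stacks the per-coil coefficient
    vectors column-wise.
    """

    models: list = field(default_factory=list)

    def __post_init__(self):
        if not self.models:
            raise ValueError("CoilModelSet requires at least one model")
        ref = self.models[0]
        for mdl in self.models[1:]:
            if mdl.lmax != ref.lmax:
                raise ValueError("all models must share lmax")
            if not np.allclose(mdl.origin, ref.origin):
                raise ValueError("all models must share the expansion origin")
            if mdl.normalization_tag != ref.normalization_tag:
                raise ValueError("all models must share the basis normalization")

    @property
    def n_coils(self) -> int:
        return len(self.models)

    @property
    def lmax(self) -> int:
        return self.models[0].lmax

    @property
    def origin(self) -> np.ndarray:
        return self.models[0].origin

    @property
    def coefficient_matrix(self) -> np.ndarray:
        """B = [beta_1, ..., beta_N], shape (C, N)."""
        return np.column_stack([m.coeffs for m in self.models])

    def __iter__(self):
        return iter(self.models)

    def __len__(self):
        return len(self.models)

    def __getitem__(self, i):
        return self.models[i]


def superpose_models(model_set: CoilModelSet, currents: np.ndarray) -> VSHModel:
    """Model of the field when the coils are driven simultaneously.

    Coefficients are ``B @ currents`` [T]; by linearity the resulting field
    equals the current-weighted sum of the per-coil (per-ampere) fields.
    """
    currents = np.asarray(currents, dtype=float).reshape(-1)
    if currents.size != model_set.n_coils:
        raise ValueError(
            f"current vector has {currents.size} entries for {model_set.n_coils} coils"
        )
    ref = model_set.models[0]
    validity = min(
        (m.metadata.get("validity_radius", np.inf) for m in model_set.models),
        default=np.inf,
    )
    meta = {"superposition": True}
    if np.isfinite(validity):
        meta["validity_radius"] = validity
    return VSHModel(
        origin=ref.origin,
        lmax=ref.lmax,
        coeffs=model_set.coefficient_matrix @ currents,
        normalization_tag=ref.normalization_tag,
        reference_radius=ref.reference_radius,
        metadata=meta,
    )
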