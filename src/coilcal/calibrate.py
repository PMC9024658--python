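"""Sensor calibration: gain, position and orientation from coil excitations.

The sensor output when coil (or coil superposition) i is driven is modelled
as ``b_i = g * B_i(r) . n`` with gain g [V/T], position r [m] and unit
orientation n.  Estimation proceeds in stages:

1. *Linear initialization* from synthesized homogeneous and first-order
   gradient fields.  The responses to three (or more) homogeneous fields
   give ``gvec = g*n = pinv(H) @ bH``; with gvec known, the responses to
   gradient fields give the position ``r = pinv(G) @ (bG - HG @ gvec)``
   where row i of G is ``gvec^T @ G_i`` (first-order Taylor expansion of
   the forward model about the expansion origin), G_i the gradient tensor
   and HG the homogeneous parts of the gradient excitations.
2. *Fine-tune* (optional): derivative-free minimization of the sum of
   squared errors against the full VSH models of the same synthesized
   fields.
3. *Final refinement*: the same minimization against the full models of the
   individually driven coils.

The optimizer parametrizes each channel as the 6-vector (r, gvec) — no unit
norm constraint needed — and the joint dual-axis variant as the 9-vector
(r, gvec_x, gvec_y) with a shared position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .fieldmodel import CoilModelSet, superpose_models
from .vsh import evaluate_field, gradient_part, uniform_part

__all__ = [
    "SensorParameters",
    "CalibrationMeasurement",
    "HarmonicExcitation",
    "RefineResult",
    "CalibrationResult",
    "linear_gain_orientation",
    "linear_position",
    "sse_objective",
    "refine",
    "refine_joint",
    "calibrate_sensor",
    "calibrate_dual_axis",
]

# Simplex settings, fixed for reproducibility: initial steps of 5 mm in
# position and 5% in gain vector, relative objective tolerance 1e-10,
# parameter tolerance 1e-8 in scaled units.
DEFAULT_POSITION_STEP = 5e-3  # m
DEFAULT_GAIN_STEP = 0.05  # fraction of |gvec|
DEFAULT_MAXITER = 5000
DEFAULT_FATOL_REL = 1e-10
DEFAULT_XATOL = 1e-8


@dataclass
class SensorParameters:
    """Calibrated channel: gain [V/T], position [m], unit orientation."""

    gain: float
    position: np.ndarray
    orientation: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3)
        if not (np.all(np.isfinite(self.position)) and np.all(np.isfinite(self.orientation))):
            raise ValueError("position and orientation must be finite")
        norm = np.linalg.norm(self.orientation)
        if norm == 0:
            raise ValueError("orientation must be nonzero")
        self.orientation = self.orientation / norm
        self.gain = float(self.gain)
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    @property
    def gvec(self) -> np.ndarray:
        """Gain vector g*n [V/T]."""
        return self.gain * self.orientation

    @classmethod
    def from_gvec(cls, position: np.ndarray, gvec: np.ndarray) -> "SensorParameters":
        gvec = np.asarray(gvec, dtype=float).reshape(3)
        gain = float(np.linalg.norm(gvec))
        if gain == 0:
            raise ValueError("gain vector must be nonzero")
        return cls(gain=gain, position=position, orientation=gvec / gain)

    def to_dict(self) -> dict:
        return {
            "gain_V_per_T": self.gain,
            "position_m": self.position.tolist(),
            "orientation": self.orientation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorParameters":
        return cls(
            gain=d["gain_V_per_T"],
            position=np.asarray(d["position_m"], dtype=float),
            orientation=np.asarray(d["orientation"], dtype=float),
        )


@dataclass
class CalibrationMeasurement:
    """One lock-in response amplitude [V] to one excitation."""

    excitation_id: object
    response: float
    kind: str = "individual"  # "individual" | "superposed"

    def __post_init__(self):
        self.response = float(self.response)
        if not np.isfinite(self.response):
            raise ValueError("response must be finite")
        if self.kind not in ("individual", "superposed"):
            raise ValueError("kind must be 'individual' or 'superposed'")


@dataclass
class HarmonicExcitation:
    """A superposed-coil excitation targeting one VSH component (l, m)."""

    degree: int
    order: int
    currents: np.ndarray

    def __post_init__(self):
        self.currents = np.asarray(self.currents, dtype=float).reshape(-1)


# ---------------------------------------------------------------------------
# Linear stage
# ---------------------------------------------------------------------------

def _check_rank3(A: np.ndarray, what: str) -> None:
    sv = np.linalg.svd(A, compute_uv=False)
    if sv.size < 3 or sv[2] <= 1e-10 * sv[0]:
        raise ValueError(
            f"{what} matrix has numerical rank < 3; the fields do not span "
            "three independent directions"
        )


def linear_gain_orientation(H: np.ndarray, bH: np.ndarray) -> np.ndarray:
    """Gain vector g*n = pinv(H) @ bH from homogeneous-field responses.

    H is (N_H, 3) with row i the uniform field of excitation i [T]; bH the
    responses [V].  Requires N_H >= 3 and rank-3 H.  Gain and orientation
    follow as ``|gvec|`` and ``gvec/|gvec|``.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    bH = np.asarray(bH, dtype=float).reshape(-1)
    if H.shape[0] < 3 or H.shape[1] != 3:
        raise ValueError("H must be (N_H >= 3, 3)")
    if bH.size != H.shape[0]:
        raise ValueError("bH length must match rows of H")
    _check_rank3(H, "homogeneous-field")
    return np.linalg.pinv(H) @ bH


def linear_position(
    gradient_tensors: list[np.ndarray],
    HG: np.ndarray,
    bG: np.ndarray,
    gvec: np.ndarray,
) -> np.ndarray:
    """Position r = pinv(G) @ (bG - HG @ gvec), relative to the VSH origin.

    Row i of G is ``gvec^T @ G_i`` with G_i the 3x3 gradient tensor of
    excitation i: to first order the response is
    ``gvec . (H_i + G_i @ r)``.  Rank < 3 (e.g. only diagonal gradients
    available — a transverse gradient is then missing) raises ValueError.
    """
    gvec = np.asarray(gvec, dtype=float).reshape(3)
    HG = np.atleast_2d(np.asarray(HG, dtype=float))
    bG = np.asarray(bG, dtype=float).reshape(-1)
    tensors = [np.asarray(G, dtype=float).reshape(3, 3) for G in gradient_tensors]
    if len(tensors) < 3:
        raise ValueError("at least 3 gradient excitations are required")
    if HG.shape != (len(tensors), 3) or bG.size != len(tensors):
        raise ValueError("HG must be (N_G, 3) and bG length N_G")
    G = np.vstack([gvec @ Gi for Gi in tensors])
    _check_rank3(G, "gradient")
    return np.linalg.pinv(G) @ (bG - HG @ gvec)


# ---------------------------------------------------------------------------
# Nonlinear stage
# ---------------------------------------------------------------------------

def _responses_to_array(responses, n: int) -> np.ndarray:
    if isinstance(responses, np.ndarray) or (
        isinstance(responses, (list, tuple)) and responses and np.isscalar(responses[0])
    ):
        arr = np.asarray(responses, dtype=float).reshape(-1)
    else:
        arr = np.array([m.response for m in responses], dtype=float)
    if arr.size != n:
        raise ValueError(f"{arr.size} responses for {n} field models")
    return arr


def _model_fields_at(models: CoilModelSet, position: np.ndarray) -> np.ndarray:
    """(N, 3) field of every model at one position (single shared basis eval)."""
    from .vsh import _basis_fields  # shared low-level evaluation

    ref = models.models[0]
    W = _basis_fields(position[None, :], ref.lmax, ref.origin, ref.reference_radius)[0]
    return (W @ models.coefficient_matrix).T  # (N, 3)


def sse_objective(params: SensorParameters, models: CoilModelSet, responses) -> float:
    """Sum of squared errors sum_i (y_i - g * B_i(r) . n)^2 [V^2]."""
    y = _responses_to_array(responses, models.n_coils)
    fields = _model_fields_at(models, params.position)
    pred = fields @ params.gvec
    return float(np.sum((y - pred) ** 2))


@dataclass
class RefineResult:
    params: SensorParameters
    sse: float
    n_iterations: int
    converged: bool
    message: str = ""


def _run_simplex(fun, x0_scaled_dim, options):
    x0 = np.zeros(x0_scaled_dim)
    simplex = np.vstack([x0, np.eye(x0_scaled_dim)])  # unit steps = one scale unit
    f0 = fun(x0)
    opt = dict(
        initial_simplex=simplex,
        xatol=options.get("xatol", DEFAULT_XATOL),
        fatol=max(options.get("fatol_rel", DEFAULT_FATOL_REL) * max(f0, 1e-300), 1e-300),
        maxiter=options.get("maxiter", DEFAULT_MAXITER),
        maxfev=2 * options.get("maxiter", DEFAULT_MAXITER),
    )
    res = minimize(fun, x0, method="Nelder-Mead", options=opt)
    return res, f0


def _validity_warning(models: CoilModelSet, position: np.ndarray) -> None:
    radius = min(
        (m.metadata.get("validity_radius", np.inf) for m in models.models), default=np.inf
    )
    if np.isfinite(radius):
        dist = np.linalg.norm(position - models.origin)
        if dist > radius * (1 + 1e-9):
            warnings.warn(
                f"refined position {dist:.3g} m from origin exceeds the model "
                f"validity radius {radius:.3g} m",
                stacklevel=3,
            )


def refine(
    init: SensorParameters,
    models: CoilModelSet,
    responses,
    **options,
) -> RefineResult:
    """Nelder-Mead refinement of one channel against full VSH models.

    Parametrized as the scaled 6-vector (r, gvec); the initial simplex steps
    are 5 mm in position and 5% in the gain vector.  The returned parameters
    never have a larger objective than ``init`` (the start point is a
    simplex vertex).
    """
    y = _responses_to_array(responses, models.n_coils)
    gvec0 = init.gvec
    scales = np.r_[
        np.full(3, options.get("position_step", DEFAULT_POSITION_STEP)),
        np.full(3, options.get("gain_step", DEFAULT_GAIN_STEP) * np.linalg.norm(gvec0)),
    ]
    p0 = np.r_[init.position, gvec0]

    def fun(xs):
        p = p0 + xs * scales
        fields = _model_fields_at(models, p[:3])
        return float(np.sum((y - fields @ p[3:]) ** 2))

    res, _ = _run_simplex(fun, 6, options)
    p = p0 + res.x * scales
    _validity_warning(models, p[:3])
    if not res.success:
        warnings.warn(f"refinement did not converge: {res.message}", stacklevel=2)
    return RefineResult(
        params=SensorParameters.from_gvec(p[:3], p[3:]),
        sse=float(res.fun),
        n_iterations=int(res.nit),
        converged=bool(res.success),
        message=str(res.message),
    )


def refine_joint(
    init_x: SensorParameters,
    init_y: SensorParameters,
    models: CoilModelSet,
    responses_x,
    responses_y,
    **options,
) -> tuple[RefineResult, RefineResult]:
    """Joint dual-axis refinement with a shared position.

    The two channels of one sensor measure two field components at the same
    point; the optimization vector is (r, gvec_x, gvec_y) and the objective
    the sum of both channels' SSE.  The returned pair has an identical
    position by construction.
    """
    yx = _responses_to_array(responses_x, models.n_coils)
    yy = _responses_to_array(responses_y, models.n_coils)
    gx0, gy0 = init_x.gvec, init_y.gvec
    r0 = 0.5 * (init_x.position + init_y.position)
    scales = np.r_[
        np.full(3, options.get("position_step", DEFAULT_POSITION_STEP)),
        np.full(3, options.get("gain_step", DEFAULT_GAIN_STEP) * np.linalg.norm(gx0)),
        np.full(3, options.get("gain_step", DEFAULT_GAIN_STEP) * np.linalg.norm(gy0)),
    ]
    p0 = np.r_[r0, gx0, gy0]

    def fun(xs):
        p = p0 + xs * scales
        fields = _model_fields_at(models, p[:3])
        rx = yx - fields @ p[3:6]
        ry = yy - fields @ p[6:9]
        return float(rx @ rx + ry @ ry)

    res, _ = _run_simplex(fun, 9, options)
    p = p0 + res.x * scales
    _validity_warning(models, p[:3])
    if not res.success:
        warnings.warn(f"joint refinement did not converge: {res.message}", stacklevel=2)
    fields = _model_fields_at(models, p[:3])
    sse_x = float(np.sum((yx - fields @ p[3:6]) ** 2))
    sse_y = float(np.sum((yy - fields @ p[6:9]) ** 2))
    out_x = RefineResult(
        SensorParameters.from_gvec(p[:3], p[3:6]), sse_x, int(res.nit), bool(res.success)
    )
    out_y = RefineResult(
        SensorParameters.from_gvec(p[:3].copy(), p[6:9]), sse_y, int(res.nit), bool(res.success)
    )
    return out_x, out_y


# ---------------------------------------------------------------------------
# Full pipeline for one channel / one dual-axis sensor
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    params: SensorParameters
    stages: list = field(default_factory=list)  # dicts: stage, params, sse_*

    def stage_names(self) -> list[str]:
        return [s["stage"] for s in self.stages]


def _linear_init(
    superposed: list,
    excitations: list[HarmonicExcitation],
    harmonic_responses: np.ndarray,
) -> SensorParameters:
    uni = [k for k, e in enumerate(excitations) if e.degree == 1]
    grad = [k for k, e in enumerate(excitations) if e.degree == 2]
    if len(uni) < 3:
        raise ValueError("linear initialization needs >= 3 homogeneous excitations")
    if len(grad) < 3:
        raise ValueError("linear initialization needs >= 3 gradient excitations")
    H = np.vstack([uniform_part(superposed[k]) for k in uni])
    gvec = linear_gain_orientation(H, harmonic_responses[uni])
    tensors = [gradient_part(superposed[k]) for k in grad]
    HG = np.vstack([uniform_part(superposed[k]) for k in grad])
    r = linear_position(tensors, HG, harmonic_responses[grad], gvec)
    return SensorParameters.from_gvec(r, gvec)


def _scale_by_currents(models: CoilModelSet, currents) -> CoilModelSet:
    """Models of the individually driven coils at their applied currents.

    The stored models are per unit current (T/A); the responses to the
    individual excitations are taken at the actual drive currents, so each
    model is scaled by its coil's current before entering the objective.
    """
    if currents is None:
        return models
    currents = np.asarray(currents, dtype=float).reshape(-1)
    if currents.size != models.n_coils:
        raise ValueError("one drive current per coil model is required")
    return CoilModelSet([superpose_models(models, i * e) for i, e in zip(currents, np.eye(models.n_coils))])


def calibrate_sensor(
    models: CoilModelSet,
    excitations: list[HarmonicExcitation],
    harmonic_responses,
    individual_responses,
    individual_currents=None,
    init: SensorParameters | None = None,
    fine_tune: bool = True,
    **options,
) -> CalibrationResult:
    """Full calibration of one single-axis channel.

    Stages: linear initialization from the synthesized homogeneous/gradient
    excitations (uniform parts and gradient tensors are extracted from the
    superposed VSH models, not from the requested targets); optional joint
    fine-tune against the full models of all superposed fields; final
    refinement against the individually driven coils.  ``individual_currents``
    are the drive currents of the individual excitations (the per-ampere
    models are scaled by them); ``None`` means unit currents.  If the
    harmonic data cannot initialize the channel a user-supplied ``init`` is
    used instead.
    """
    harmonic_responses = _responses_to_array(harmonic_responses, len(excitations))
    superposed = [superpose_models(models, e.currents) for e in excitations]
    sup_set = CoilModelSet(superposed)
    models = _scale_by_currents(models, individual_currents)
    stages = []

    try:
        params = _linear_init(superposed, excitations, harmonic_responses)
    except ValueError:
        if init is None:
            raise
        params = init
    stages.append(
        {
            "stage": "linear",
            "params": params,
            "sse_harmonic": sse_objective(params, sup_set, harmonic_responses),
            "sse_individual": sse_objective(params, models, individual_responses),
        }
    )

    if fine_tune:
        res = refine(params, sup_set, harmonic_responses, **options)
        params = res.params
        stages.append(
            {
                "stage": "fine_tune",
                "params": params,
                "sse_harmonic": res.sse,
                "sse_individual": sse_objective(params, models, individual_responses),
            }
        )

    res = refine(params, models, individual_responses, **options)
    params = res.params
    stages.append(
        {
            "stage": "final",
            "params": params,
            "sse_harmonic": sse_objective(params, sup_set, harmonic_responses),
            "sse_individual": res.sse,
        }
    )
    return CalibrationResult(params=params, stages=stages)


def calibrate_dual_axis(
    models: CoilModelSet,
    excitations: list[HarmonicExcitation],
    harmonic_responses_x,
    harmonic_responses_y,
    individual_responses_x,
    individual_responses_y,
    individual_currents=None,
    fine_tune: bool = True,
    **options,
) -> tuple[CalibrationResult, CalibrationResult]:
    """Joint calibration of a dual-axis sensor (two channels, one position).

    Each axis is initialized linearly on its own; the refinement stages run
    jointly with the shared-position constraint.
    """
    hx = _responses_to_array(harmonic_responses_x, len(excitations))
    hy = _responses_to_array(harmonic_responses_y, len(excitations))
    superposed = [superpose_models(models, e.currents) for e in excitations]
    sup_set = CoilModelSet(superposed)
    models = _scale_by_currents(models, individual_currents)

    px = _linear_init(superposed, excitations, hx)
    py = _linear_init(superposed, excitations, hy)
    stages_x = [{"stage": "linear", "params": px, "sse_harmonic": sse_objective(px, sup_set, hx)}]
    stages_y = [{"stage": "linear", "params": py, "sse_harmonic": sse_objective(py, sup_set, hy)}]

    if fine_tune:
        rx, ry = refine_joint(px, py, sup_set, hx, hy, **options)
        px, py = rx.params, ry.params
        stages_x.append({"stage": "fine_tune", "params": px, "sse_harmonic": rx.sse})
        stages_y.append({"stage": "fine_tune", "params": py, "sse_harmonic": ry.sse})

    rx, ry = refine_joint(px, py, models, individual_responses_x, individual_responses_y, **options)
    stages_x.append({"stage": "final", "params": rx.params, "sse_individual": rx.sse})
    stages_y.append({"stage": "final", "params": ry.params, "sse_individual": ry.sse})
    return (
        CalibrationResult(params=rx.params, stages=stages_x),
        CalibrationResult(params=ry.params, stages=stages_y),
    )
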