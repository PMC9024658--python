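"""Synthetic ground-truth scenarios: coils, sensors, phantom, time series.

This module emulates the hardware of a person-sized magnetically shielded
room used for OPM-MEG: 16 rectangular and 2 circular shield coils on a
cylindrical form, a triaxial fluxgate magnetometer (three orthogonal
single-axis channels spaced 2 cm along the probe) used to map the coil
fields at 108 positions, a 48-channel OPM array (6 sensors x 4 channels x
2 tangential field components), and a 9-dipole phantom (5-mm current loops,
~140 nAm^2).  Coil fields are computed with the exact finite-segment
Biot-Savart law over polyline loops and ARE the ground truth; sensor
responses are sinusoidal excitations (20 Hz, sampled at 1 kHz) with white
Gaussian noise, and amplitudes are read out by lock-in detection.

All randomness flows from the scenario seed; every stage re-derives its
generator from (seed, stage-index) so reruns are byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibrate import SensorParameters
from .dipolefit import MU0, DipoleSource
from .fieldmodel import CoilModelSet, FieldMeasurementSet, fit_coefficients, superpose_models
from .coilsynth import currents_for_harmonic, harmonic_target
from .vsh import degree_order_pairs, evaluate_field

__all__ = [
    "CoilGeometry",
    "SimulationScenario",
    "Excitation",
    "rectangular_loop",
    "circular_loop",
    "biot_savart_field",
    "default_shield_scenario",
    "default_opm_array",
    "map_coil_fields",
    "fit_coil_models",
    "make_excitation_plan",
    "simulate_responses",
    "lockin_amplitude",
    "lockin_amplitudes",
    "simulate_dipole_series",
]

SEGMENT_GUARD = 1e-3  # m; minimum distance from a field point to any wire segment
OPM_LINEAR_RANGE = 1e-9  # T; amplitudes beyond this are clipped in OPM mode


# ---------------------------------------------------------------------------
# Coil geometry and Biot-Savart
# ---------------------------------------------------------------------------

@dataclass
class CoilGeometry:
    """Polyline current loops of one coil (each loop closed: first = last)."""

    coil_id: str
    loops: list  # list of (K, 3) arrays [m]
    turns: int = 1

    def __post_init__(self):
        self.loops = [np.atleast_2d(np.asarray(lp, dtype=float)) for lp in self.loops]
        for lp in self.loops:
            if lp.shape[0] < 4 or not np.allclose(lp[0], lp[-1]):
                raise ValueError(
                    f"coil {self.coil_id!r}: each loop must be closed with >= 3 distinct vertices"
                )


def rectangular_loop(center, normal, u_axis, width: float, height: float) -> np.ndarray:
    """Closed rectangle in the plane with the given normal; u_axis sets the
    width direction (projected into the plane)."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    u = np.asarray(u_axis, dtype=float)
    u = u - (u @ n) * n
    u = u / np.linalg.norm(u)
    v = np.cross(n, u)
    c = np.asarray(center, dtype=float)
    corners = [
        c + 0.5 * width * u + 0.5 * height * v,
        c - 0.5 * width * u + 0.5 * height * v,
        c - 0.5 * width * u - 0.5 * height * v,
        c + 0.5 * width * u - 0.5 * height * v,
    ]
    return np.vstack(corners + [corners[0]])


def circular_loop(center, normal, radius: float, n_segments: int = 72) -> np.ndarray:
    """Closed regular polygon approximating a circular loop."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    ang = np.linspace(0, 2 * np.pi, n_segments + 1)
    return np.asarray(center, dtype=float) + radius * (
        np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v
    )


def biot_savart_field(coil: CoilGeometry, current: float, points: np.ndarray) -> np.ndarray:
    """Exact field of the coil's polyline loops at given points, (M, 3) [T].

    Each straight segment a->b contributes
    ``mu0 I/(4 pi) * (r1 x r2) (|r1|+|r2|) / (|r1||r2| (|r1||r2| + r1.r2))``
    with r1, r2 the vectors from the endpoints to the field point — the
    standard numerically robust closed form.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    B = np.zeros_like(points)
    for loop in coil.loops:
        a, b = loop[:-1], loop[1:]  # (S, 3) segment endpoints
        r1 = points[:, None, :] - a[None, :, :]  # (M, S, 3)
        r2 = points[:, None, :] - b[None, :, :]
        n1 = np.linalg.norm(r1, axis=2)
        n2 = np.linalg.norm(r2, axis=2)
        denom = n1 * n2 * (n1 * n2 + np.einsum("msj,msj->ms", r1, r2))
        if np.any(n1 < SEGMENT_GUARD) or np.any(n2 < SEGMENT_GUARD) or np.any(
            denom < (SEGMENT_GUARD**2) ** 2
        ):
            raise ValueError(
                f"field point within {SEGMENT_GUARD*1e3:.0f} mm of a segment of "
                f"coil {coil.coil_id!r}"
            )
        cross = np.cross(r1, r2)
        B += np.einsum("msj,ms->mj", cross, (n1 + n2) / denom)
    return MU0 / (4 * np.pi) * current * coil.turns * B


def total_field(coils: list[CoilGeometry], currents: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Superposed Biot-Savart field of all coils at the given currents."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    B = np.zeros_like(points)
    for c, i in zip(coils, currents):
        if i != 0:
            B += biot_savart_field(c, i, points)
    return B


# ---------------------------------------------------------------------------
# Scenario
# ---------------------------------------------------------------------------

@dataclass
class Excitation:
    """One excitation block: named current pattern over the active coils."""

    name: str
    currents: np.ndarray
    harmonic: tuple | None = None  # (l, m) when synthesized, None for individual
    kind: str = "individual"

    def __post_init__(self):
        self.currents = np.asarray(self.currents, dtype=float).reshape(-1)


@dataclass
class SimulationScenario:
    """Everything needed to run the synthetic calibration study.

    ``snr`` is the controlled quantity: the ratio of the maximum lock-in
    amplitude (gain x max field) to the lock-in amplitude error; the
    time-series noise standard deviation realizing it over one excitation
    block is ``sigma_t = sigma_A * sqrt(N/2)``.
    """

    coils: list  # CoilGeometry, all 18
    broken_coil: str | None
    mapping_positions: np.ndarray  # (108, 3)
    sensors: list  # true SensorParameters, one per channel
    dipoles: list = field(default_factory=list)  # DipoleSource phantom
    mode: str = "fluxgate"  # "fluxgate" | "opm"
    target_max_field: float = 12.5e-9  # T over the mapping region
    snr: float = 1900.0
    excitation_frequency: float = 20.0  # Hz
    sample_rate: float = 1000.0  # Hz
    block_duration: float = 1.0  # s, integer number of excitation periods
    seed: int = 0

    @property
    def active_coils(self) -> list:
        return [c for c in self.coils if c.coil_id != self.broken_coil]

    @property
    def n_samples(self) -> int:
        return int(round(self.block_duration * self.sample_rate))

    def amplitude_noise_sigma(self, gain: float) -> float:
        """Lock-in amplitude error [V] realizing the scenario SNR for a channel."""
        return gain * self.target_max_field / self.snr

    def timeseries_noise_sigma(self, gain: float) -> float:
        return self.amplitude_noise_sigma(gain) * np.sqrt(self.n_samples / 2.0)


def _shield_coils() -> list[CoilGeometry]:
    """16 rectangular + 2 circular coils on a cylindrical form.

    Rectangles sit tangent to a 0.85-m cylinder at 8 azimuths and two
    height rows; circular end coils close the axial direction.  The
    arrangement surrounds a 0.2-m sensor-array region at the centre and
    spans the low-order VSH components there.
    """
    coils = []
    radius, z_rows = 0.85, (-0.45, 0.45)
    for j, az in enumerate(np.arange(8) * (2 * np.pi / 8) + np.pi / 8):
        center_dir = np.array([np.cos(az), np.sin(az), 0.0])
        for k, zc in enumerate(z_rows):
            coils.append(
                CoilGeometry(
                    coil_id=f"rect_{j}{'ab'[k]}",
                    loops=[
                        rectangular_loop(
                            center=radius * center_dir + np.array([0, 0, zc]),
                            normal=center_dir,
                            u_axis=np.array([0, 0, 1.0]),
                            width=0.75,
                            height=0.55,
                        )
                    ],
                )
            )
    for name, zc in (("circ_bottom", -0.95), ("circ_top", 0.95)):
        coils.append(
            CoilGeometry(
                coil_id=name,
                loops=[circular_loop(np.array([0, 0, zc]), np.array([0, 0, 1.0]), 0.75)],
            )
        )
    return coils


def _mapping_positions() -> np.ndarray:
    """108 triaxial mapping locations: 6 x 6 x 3 lattice over the array region."""
    xs = np.linspace(-0.095, 0.095, 6)
    ys = np.linspace(-0.095, 0.095, 6)
    zs = np.linspace(-0.05, 0.05, 3)
    g = np.meshgrid(xs, ys, zs, indexing="ij")
    return np.column_stack([a.ravel() for a in g])


def _perturbed_frame(rng: np.random.Generator, max_angle_deg: float = 0.5) -> np.ndarray:
    """Nearly orthogonal channel triad: small random rotation of each axis."""
    axes = np.eye(3)
    out = []
    for ax in axes:
        tilt = rng.normal(scale=np.deg2rad(max_angle_deg), size=3)
        v = ax + np.cross(tilt, ax)
        out.append(v / np.linalg.norm(v))
    return np.vstack(out)


def _fluxgate_channels(rng: np.random.Generator) -> list[SensorParameters]:
    """18 single-axis channels: 6 triad placements, 2-cm channel spacing.

    Each placement mimics the probe in a holder slot: three orthogonal
    channels at successive 2-cm offsets along the probe axis.  Gains are
    0.1 V/uT with 0.5% scatter; channel orientations carry a +/-0.5-degree
    orthogonality perturbation.
    """
    channels = []
    bases = rng.uniform(-0.06, 0.06, size=(6, 3)) * np.array([1, 1, 0.3])
    for base in bases:
        frame = _perturbed_frame(rng)
        axis = frame[2]
        for j in range(3):
            channels.append(
                SensorParameters(
                    gain=1e5 * (1 + rng.normal(scale=0.005)),
                    position=base + 0.02 * j * axis,
                    orientation=frame[j],
                )
            )
    return channels


def default_shield_scenario(seed: int, mode: str = "fluxgate") -> SimulationScenario:
    """Default synthetic shield: 18 coils (one broken -> 17 usable), 108
    mapping points, and the mode's sensor complement and drive level.

    Fluxgate mode: 18 single-axis channels, 12.5-nT maximum field, lock-in
    amplitude SNR 1900.  OPM mode: 48 channels (24 dual-axis positions) plus
    the 9-dipole phantom, 0.5-nT fields, SNR 1e4.
    """
    rng = np.random.default_rng([int(seed), 0])
    coils = _shield_coils()
    if mode == "fluxgate":
        sensors, dipoles = _fluxgate_channels(rng), []
        target, snr = 12.5e-9, 1900.0
    elif mode == "opm":
        sensors, dipoles = _opm_channels_and_phantom(rng)
        target, snr = 0.5e-9, 1e4
    else:
        raise ValueError("mode must be 'fluxgate' or 'opm'")
    return SimulationScenario(
        coils=coils,
        broken_coil="rect_6b",
        mapping_positions=_mapping_positions(),
        sensors=sensors,
        dipoles=dipoles,
        mode=mode,
        target_max_field=target,
        snr=snr,
        seed=int(seed),
    )


def _opm_channels_and_phantom(rng: np.random.Generator):
    """48 OPM channels (24 positions x 2 tangential components) + 9 dipoles.

    Six sensors in a 3 x 2 patch, four channels per sensor in a 2x2
    sub-grid; each position hosts two nominally orthogonal tangential
    channels with a ~1-degree non-orthogonality perturbation and 2.7 V/nT
    gains with 5% scatter.  The phantom holds nine 140-nAm^2 dipoles 3-6 cm
    below the array with seeded random moment directions.
    """
    sensor_xy = [(-0.035, -0.0175), (-0.035, 0.0175), (0.0, -0.0175),
                 (0.0, 0.0175), (0.035, -0.0175), (0.035, 0.0175)]
    z_array = 0.02
    channels = []
    for sx, sy in sensor_xy:
        for dx in (-0.006, 0.006):
            for dy in (-0.006, 0.006):
                pos = np.array([sx + dx, sy + dy, z_array])
                for nominal in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])):
                    tilt = rng.normal(scale=np.deg2rad(1.0), size=3)
                    ori = nominal + np.cross(tilt, nominal)
                    channels.append(
                        SensorParameters(
                            gain=2.7e9 * (1 + rng.normal(scale=0.05 / 3)),
                            position=pos,
                            orientation=ori / np.linalg.norm(ori),
                        )
                    )
    dipole_z = [-0.01, -0.025, -0.04]
    dipoles = []
    for i, (dx, dy) in enumerate([(x, y) for x in (-0.03, 0, 0.03) for y in (-0.03, 0, 0.03)]):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dipoles.append(
            DipoleSource(
                position=np.array([dx, dy, dipole_z[i % 3]]),
                moment=140e-9 * direction,
            )
        )
    return channels, dipoles


# ---------------------------------------------------------------------------
# Mapping, model fitting, excitation plans
# ---------------------------------------------------------------------------

def map_coil_fields(scenario: SimulationScenario) -> list[FieldMeasurementSet]:
    """Noiseless triaxial field maps of the active coils per unit current."""
    return [
        FieldMeasurementSet(
            coil_id=c.coil_id,
            positions=scenario.mapping_positions,
            values=biot_savart_field(c, 1.0, scenario.mapping_positions),
            current=1.0,
        )
        for c in scenario.active_coils
    ]


def fit_coil_models(scenario: SimulationScenario, lmax: int = 5) -> CoilModelSet:
    """VSH models of all active coils, origin at the mapping centroid."""
    maps = map_coil_fields(scenario)
    origin = maps[0].centroid()
    return CoilModelSet([fit_coefficients(m, lmax=lmax, origin=origin) for m in maps])


def make_excitation_plan(
    scenario: SimulationScenario, models: CoilModelSet
) -> list[Excitation]:
    """Excitation blocks of the calibration run: 8 synthesized first-order
    VSH fields followed by the individually driven coils.

    Every block's currents are rescaled so the maximum model field over the
    mapping points equals the scenario's target amplitude (12.5 nT fluxgate
    / 0.5 nT OPM), mirroring how drive currents are set in practice.
    """
    plan = []
    for l, m in degree_order_pairs(min(2, models.lmax)):
        target = harmonic_target(models.lmax, l, m, amplitude=scenario.target_max_field)
        currents = currents_for_harmonic(models, target)
        currents *= _rescale_to_target(models, currents, scenario)
        plan.append(
            Excitation(name=f"vsh_l{l}m{m:+d}", currents=currents, harmonic=(l, m),
                       kind="superposed")
        )
    for k, coil in enumerate(scenario.active_coils):
        currents = np.zeros(models.n_coils)
        currents[k] = 1.0
        currents *= _rescale_to_target(models, currents, scenario)
        plan.append(Excitation(name=coil.coil_id, currents=currents, kind="individual"))
    return plan


def _rescale_to_target(models, currents, scenario) -> float:
    model = superpose_models(models, currents)
    fields = evaluate_field(model, scenario.mapping_positions, warn_outside=False)
    peak = float(np.max(np.linalg.norm(fields, axis=1)))
    return scenario.target_max_field / peak


# ---------------------------------------------------------------------------
# Time series, lock-in
# ---------------------------------------------------------------------------

def simulate_responses(
    scenario: SimulationScenario,
    plan: list[Excitation],
    noise: bool = True,
) -> dict[str, np.ndarray]:
    """Sensor time series for every excitation block, (n_channels, N) [V].

    The ground-truth field is the Biot-Savart superposition of the active
    coils (not the fitted models); channel c records
    ``gain_c (B(r_c) . n_c) sin(2 pi f0 t)`` plus white Gaussian noise whose
    variance realizes the scenario SNR over the block.  OPM mode clips field
    projections beyond the +/-1-nT linear range with a warning.
    """
    t = np.arange(scenario.n_samples) / scenario.sample_rate
    carrier = np.sin(2 * np.pi * scenario.excitation_frequency * t)
    positions = np.vstack([s.position for s in scenario.sensors])
    gains = np.array([s.gain for s in scenario.sensors])
    out = {}
    for k, exc in enumerate(plan):
        B = total_field(scenario.active_coils, exc.currents, positions)
        proj = np.einsum("cj,cj->c", B, np.vstack([s.orientation for s in scenario.sensors]))
        if scenario.mode == "opm" and np.any(np.abs(proj) > OPM_LINEAR_RANGE):
            warnings.warn(
                f"excitation {exc.name!r}: field projection exceeds the OPM linear "
                "range (+/-1 nT); clipping",
                stacklevel=2,
            )
            proj = np.clip(proj, -OPM_LINEAR_RANGE, OPM_LINEAR_RANGE)
        series = (gains * proj)[:, None] * carrier[None, :]
        if noise:
            rng = np.random.default_rng([scenario.seed, 1, k])
            sigma = np.array([scenario.timeseries_noise_sigma(g) for g in gains])
            series = series + rng.normal(size=series.shape) * sigma[:, None]
        out[exc.name] = series
    return out


def lockin_amplitude(
    series: np.ndarray, f0: float, fs: float, return_phase: bool = False
):
    """Lock-in estimate of the sinusoidal amplitude at reference frequency f0.

    The series is truncated to an integer number of f0 periods; the complex
    demodulate is ``z = 2/N sum v(t) exp(-i 2 pi f0 t)``.  The signed
    amplitude of a sine-referenced excitation ``A sin(2 pi f0 t)`` is
    ``-Im(z)`` (exactly A for a pure sinusoid); with ``return_phase`` the
    magnitude |z| and phase arg(z) are returned instead.
    """
    if fs <= 2 * f0:
        raise ValueError("sampling rate must exceed twice the reference frequency")
    v = np.asarray(series, dtype=float)
    n_per_period = fs / f0
    n = int(np.floor(v.shape[-1] / n_per_period) * n_per_period)
    if n < 1:
        raise ValueError("series shorter than one reference period")
    v = v[..., :n]
    t = np.arange(n) / fs
    z = 2.0 / n * (v * np.exp(-2j * np.pi * f0 * t)).sum(axis=-1)
    if return_phase:
        return np.abs(z), np.angle(z)
    return -z.imag


def lockin_amplitudes(
    responses: dict[str, np.ndarray], scenario: SimulationScenario
) -> dict[str, np.ndarray]:
    """Signed lock-in amplitude per channel for every excitation block."""
    return {
        name: lockin_amplitude(series, scenario.excitation_frequency, scenario.sample_rate)
        for name, series in responses.items()
    }


def simulate_dipole_series(
    scenario: SimulationScenario,
    sensors: list[SensorParameters] | None = None,
    noise: bool = True,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Phantom measurement: per-dipole channel time series and the reference.

    Each dipole is driven with the 20-Hz reference; channel amplitudes
    follow the point-dipole forward model through the TRUE sensor
    parameters.  Returns (series per dipole, reference waveform).
    """
    from .dipolefit import forward_amplitudes

    sensors = scenario.sensors if sensors is None else sensors
    t = np.arange(scenario.n_samples) / scenario.sample_rate
    carrier = np.sin(2 * np.pi * scenario.excitation_frequency * t)
    gains = np.array([s.gain for s in sensors])
    out = {}
    for d, dip in enumerate(scenario.dipoles):
        amps = forward_amplitudes(dip, sensors)
        series = amps[:, None] * carrier[None, :]
        if noise:
            rng = np.random.default_rng([scenario.seed, 2, d])
            # SNR referenced to the strongest channel of this dipole
            sigma_a = float(np.max(np.abs(amps))) / scenario.snr
            sigma_t = sigma_a * np.sqrt(scenario.n_samples / 2.0)
            series = series + rng.normal(size=series.shape) * sigma_t
        out[f"dipole_{d}"] = series
    return out, carrier
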