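"""Sensor-parameter estimation: linear stage, SSE refinement, full pipeline."""

import numpy as np
import pytest

from coilcal.calibrate import (
    HarmonicExcitation,
    SensorParameters,
    calibrate_dual_axis,
    calibrate_sensor,
    linear_gain_orientation,
    linear_position,
    refine,
    refine_joint,
    sse_objective,
)
from coilcal.coilsynth import currents_for_harmonic, harmonic_target
from coilcal.fieldmodel import CoilModelSet, superpose_models
from coilcal.vsh import VSHModel, degree_order_pairs, evaluate_field, n_components

ORIGIN = np.zeros(3)


def make_sensor(seed=0, gain=1e5):
    rng = np.random.default_rng(seed)
    n = rng.normal(size=3)
    return SensorParameters(
        gain=gain, position=rng.uniform(-0.05, 0.05, 3), orientation=n / np.linalg.norm(n)
    )


def random_model_set(n=10, lmax=3, seed=1, amplitude=12.5e-9):
    """Random coil models with realistic nT-scale fields near the origin."""
    rng = np.random.default_rng(seed)
    models = []
    for _ in range(n):
        c = rng.normal(size=n_components(lmax))
        c *= amplitude / np.linalg.norm(c)
        models.append(VSHModel(origin=ORIGIN, lmax=lmax, coeffs=c))
    return CoilModelSet(models)


def synthesize_responses(sensor, models):
    """Noiseless forward responses through the sensor model."""
    fields = np.vstack([evaluate_field(m, sensor.position)[0] for m in models])
    return fields @ sensor.gvec


class TestSensorParameters:
    def test_orientation_normalized(self):
        p = SensorParameters(gain=1.0, position=np.zeros(3), orientation=[0, 0, 2.0])
        np.testing.assert_allclose(np.linalg.norm(p.orientation), 1.0, atol=1e-12)

    def test_gvec_round_trip(self):
        p = make_sensor(4)
        q = SensorParameters.from_gvec(p.position, p.gvec)
        np.testing.assert_allclose(q.gain, p.gain)
        np.testing.assert_allclose(q.orientation, p.orientation)

    def test_invalid_gain(self):
        with pytest.raises(ValueError):
            SensorParameters(gain=-1.0, position=np.zeros(3), orientation=[1, 0, 0])


class TestLinearGainOrientation:
    def test_orthogonal_triplet_exact(self):
        sensor = make_sensor(1)
        B0 = 12.5e-9
        H = B0 * np.eye(3)
        gvec = linear_gain_orientation(H, H @ sensor.gvec)
        np.testing.assert_allclose(gvec, sensor.gvec, rtol=1e-12)

    def test_random_well_conditioned_recovery(self):
        rng = np.random.default_rng(2)
        sensor = make_sensor(3)
        H = 1e-8 * rng.normal(size=(6, 3))
        gvec = linear_gain_orientation(H, H @ sensor.gvec)
        np.testing.assert_allclose(gvec, sensor.gvec, rtol=1e-10)

    def test_collinear_fields_raise(self):
        H = np.array([[1e-9, 0, 0], [2e-9, 0, 0], [3e-9, 0, 0]])
        with pytest.raises(ValueError, match="rank"):
            linear_gain_orientation(H, np.ones(3))


class TestLinearPosition:
    def grad_set(self, seed=4):
        """Three well-conditioned synthetic gradient excitations."""
        rng = np.random.default_rng(seed)
        tensors = []
        for _ in range(3):
            A = 1e-7 * rng.normal(size=(3, 3))
            S = 0.5 * (A + A.T)
            tensors.append(S - np.trace(S) / 3 * np.eye(3))  # symmetric traceless
        HG = 1e-10 * rng.normal(size=(3, 3))
        return tensors, HG

    def test_sensor_at_origin(self):
        sensor = make_sensor(5)
        tensors, HG = self.grad_set()
        bG = HG @ sensor.gvec  # zero gradient contribution
        r = linear_position(tensors, HG, bG, sensor.gvec)
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_known_position_recovery(self):
        sensor = make_sensor(6)
        tensors, HG = self.grad_set(seed=7)
        r_true = np.array([0.01, -0.02, 0.015])
        bG = np.array([sensor.gvec @ (HG[i] + G @ r_true) for i, G in enumerate(tensors)])
        r = linear_position(tensors, HG, bG, sensor.gvec)
        np.testing.assert_allclose(r, r_true, atol=1e-10)

    def test_diagonal_gradients_only_raise(self):
        # only dBx/dx and dBy/dy style tensors: gvec^T G_i rows cannot have
        # rank 3 -- a transverse gradient would be needed
        gvec = np.array([0.0, 0.0, 1e5])
        t1 = np.diag([1e-7, -1e-7, 0.0])
        t2 = np.diag([0.0, -1e-7, 1e-7])
        t3 = np.diag([1e-7, 0.0, -1e-7])
        with pytest.raises(ValueError, match="rank"):
            linear_position([t1, t2, t3], np.zeros((3, 3)), np.zeros(3), gvec)


class TestSSEObjective:
    def test_zero_at_truth(self):
        models = random_model_set()
        sensor = make_sensor(8)
        y = synthesize_responses(sensor, models)
        assert sse_objective(sensor, models, y) < 1e-30

    def test_matches_brute_force_accumulation(self):
        models = random_model_set(n=3, seed=9)
        sensor = make_sensor(10)
        rng = np.random.default_rng(11)
        y = rng.normal(scale=1e-4, size=3)
        total = 0.0
        for i, m in enumerate(models):
            b = sensor.gain * (evaluate_field(m, sensor.position)[0] @ sensor.orientation)
            total += (y[i] - b) ** 2
        np.testing.assert_allclose(sse_objective(sensor, models, y), total, rtol=1e-12)

    def test_position_perturbation_increases_objective(self):
        models = random_model_set(seed=12)
        sensor = make_sensor(13)
        y = synthesize_responses(sensor, models)
        shifted = SensorParameters(
            gain=sensor.gain,
            position=sensor.position + np.array([1e-3, 0, 0]),
            orientation=sensor.orientation,
        )
        assert sse_objective(shifted, models, y) > sse_objective(sensor, models, y)


class TestRefine:
    def test_noiseless_truth_stays_put(self):
        models = random_model_set(seed=14)
        sensor = make_sensor(15)
        y = synthesize_responses(sensor, models)
        res = refine(sensor, models, y)
        assert res.sse <= sse_objective(sensor, models, y) + 1e-30
        np.testing.assert_allclose(res.params.position, sensor.position, atol=1e-9)

    def test_never_worse_than_init(self):
        models = random_model_set(seed=16)
        sensor = make_sensor(17)
        rng = np.random.default_rng(18)
        y = synthesize_responses(sensor, models) + rng.normal(scale=1e-5, size=models.n_coils)
        init = SensorParameters(
            gain=sensor.gain * 1.1,
            position=sensor.position + 3e-3,
            orientation=sensor.orientation,
        )
        res = refine(init, models, y)
        assert res.sse <= sse_objective(init, models, y) * (1 + 1e-12)

    def test_recovers_perturbed_start_noiseless(self):
        models = random_model_set(seed=19)
        sensor = make_sensor(20)
        y = synthesize_responses(sensor, models)
        init = SensorParameters(
            gain=sensor.gain * 1.05,
            position=sensor.position + np.array([2e-3, -2e-3, 1e-3]),
            orientation=sensor.orientation + np.array([0.02, 0, 0]),
        )
        res = refine(init, models, y)
        np.testing.assert_allclose(res.params.position, sensor.position, atol=2e-8)
        np.testing.assert_allclose(res.params.gain, sensor.gain, rtol=1e-7)


class TestRefineJoint:
    def make_pair(self, seed=21):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(-0.04, 0.04, 3)
        nx = np.array([1.0, 0.05, 0.0])
        ny = np.array([-0.03, 1.0, 0.02])
        px = SensorParameters(gain=1e5, position=pos, orientation=nx / np.linalg.norm(nx))
        py = SensorParameters(gain=1.1e5, position=pos, orientation=ny / np.linalg.norm(ny))
        return px, py

    def test_noiseless_exact_recovery(self):
        models = random_model_set(seed=22)
        px, py = self.make_pair()
        yx, yy = synthesize_responses(px, models), synthesize_responses(py, models)
        ix = SensorParameters(px.gain * 1.03, px.position + 2e-3, px.orientation)
        iy = SensorParameters(py.gain * 0.97, py.position - 2e-3, py.orientation)
        rx, ry = refine_joint(ix, iy, models, yx, yy)
        np.testing.assert_allclose(rx.params.position, px.position, atol=1e-8)
        np.testing.assert_allclose(rx.params.gain, px.gain, rtol=1e-8)
        np.testing.assert_allclose(ry.params.gain, py.gain, rtol=1e-8)

    def test_shared_position_bit_identical(self):
        models = random_model_set(seed=23)
        px, py = self.make_pair(seed=24)
        yx, yy = synthesize_responses(px, models), synthesize_responses(py, models)
        rx, ry = refine_joint(px, py, models, yx, yy)
        assert np.array_equal(rx.params.position, ry.params.position)


class TestCalibrateSensor:
    def setup_case(self, seed=25, lmax=3):
        models = random_model_set(n=12, lmax=lmax, seed=seed)
        excitations = []
        responses_h = []
        sensor = make_sensor(seed + 1)
        for l, m in degree_order_pairs(2):
            target = harmonic_target(lmax, l, m, 12.5e-9)
            currents = currents_for_harmonic(models, target)
            excitations.append(HarmonicExcitation(l, m, currents))
            sup = superpose_models(models, currents)
            responses_h.append(
                sensor.gain * (evaluate_field(sup, sensor.position)[0] @ sensor.orientation)
            )
        responses_i = synthesize_responses(sensor, models)
        return models, excitations, np.array(responses_h), responses_i, sensor

    def test_noiseless_end_to_end_exact_at_every_stage(self):
        # with exactly degree-<=2 coil fields every stage (including the
        # first-order linear initialization) recovers the truth
        models, exc, bh, bi, sensor = self.setup_case(lmax=2)
        result = calibrate_sensor(models, exc, bh, bi)
        assert result.stage_names() == ["linear", "fine_tune", "final"]
        for stage in result.stages:
            p = stage["params"]
            np.testing.assert_allclose(p.position, sensor.position, atol=1e-7)
            np.testing.assert_allclose(p.gain, sensor.gain, rtol=1e-6)
            np.testing.assert_allclose(p.orientation, sensor.orientation, atol=1e-7)

    def test_higher_order_content_corrected_by_refinement(self):
        # with degree-3 content the linear stage is only a first-order
        # approximation; the final refinement against full models is exact
        models, exc, bh, bi, sensor = self.setup_case(lmax=3)
        result = calibrate_sensor(models, exc, bh, bi)
        final = result.params
        np.testing.assert_allclose(final.position, sensor.position, atol=1e-7)
        np.testing.assert_allclose(final.gain, sensor.gain, rtol=1e-6)

    def test_stagewise_objectives_non_increasing(self):
        models, exc, bh, bi, sensor = self.setup_case(seed=27)
        rng = np.random.default_rng(28)
        bh = bh + rng.normal(scale=5e-5, size=bh.size)
        bi = bi + rng.normal(scale=5e-5, size=bi.size)
        result = calibrate_sensor(models, exc, bh, bi)
        sse_h = [s["sse_harmonic"] for s in result.stages]
        # fine-tune refines the harmonic objective from the linear start
        assert sse_h[1] <= sse_h[0] * (1 + 1e-12)
        # final refinement starts from the fine-tuned parameters
        assert result.stages[2]["sse_individual"] <= result.stages[1]["sse_individual"] * (1 + 1e-12)

    def test_individual_current_scaling(self):
        # doubling a drive current doubles the modeled response, not the fit
        models, exc, bh, bi, sensor = self.setup_case(seed=29)
        currents = np.full(models.n_coils, 2.0)
        result = calibrate_sensor(
            models, exc, bh, 2.0 * bi, individual_currents=currents
        )
        np.testing.assert_allclose(result.params.gain, sensor.gain, rtol=1e-6)
        np.testing.assert_allclose(result.params.position, sensor.position, atol=1e-7)

    def test_dual_axis_matches_separate_on_noiseless_data(self):
        models, exc, bh_x, bi_x, sx = self.setup_case(seed=30)
        sy = SensorParameters(gain=1.07e5, position=sx.position, orientation=[0.1, 0.99, 0.05])
        bh_y = np.array(
            [
                sy.gain
                * (evaluate_field(superpose_models(models, e.currents), sy.position)[0] @ sy.orientation)
                for e in exc
            ]
        )
        bi_y = synthesize_responses(sy, models)
        rx, ry = calibrate_dual_axis(models, exc, bh_x, bh_y, bi_x, bi_y)
        assert np.array_equal(rx.params.position, ry.params.position)
        np.testing.assert_allclose(rx.params.position, sx.position, atol=1e-7)
        np.testing.assert_allclose(ry.params.gain, sy.gain, rtol=1e-6)


class TestEstimatorInvariances:
    def test_exact_linear_recovery_on_degree_two_fields(self):
        # with purely degree-<=2 fields and noiseless responses the linear
        # stage alone is exact -- no refinement needed
        rng = np.random.default_rng(31)
        models = []
        for _ in range(10):
            c = np.zeros(n_components(2))
            c[:] = 1e-8 * rng.normal(size=8)
            models.append(VSHModel(origin=ORIGIN, lmax=2, coeffs=c))
        models = CoilModelSet(models)
        sensor = make_sensor(32)
        exc = []
        bh = []
        for l, m in degree_order_pairs(2):
            currents = currents_for_harmonic(models, harmonic_target(2, l, m, 1e-8))
            exc.append(HarmonicExcitation(l, m, currents))
            sup = superpose_models(models, currents)
            bh.append(sensor.gain * (evaluate_field(sup, sensor.position)[0] @ sensor.orientation))
        result = calibrate_sensor(models, exc, np.array(bh), synthesize_responses(sensor, models),
                                  fine_tune=False)
        lin = result.stages[0]["params"]
        np.testing.assert_allclose(lin.position, sensor.position, atol=1e-10)
        np.testing.assert_allclose(lin.gain, sensor.gain, rtol=1e-10)
        np.testing.assert_allclose(lin.orientation, sensor.orientation, atol=1e-10)

    def test_coil_order_invariance(self):
        models = random_model_set(n=9, seed=33)
        sensor = make_sensor(34)
        y = synthesize_responses(sensor, models)
        perm = np.random.default_rng(35).permutation(9)
        permuted = CoilModelSet([models[i] for i in perm])
        res_a = refine(sensor, models, y)
        res_b = refine(sensor, permuted, y[perm])
        np.testing.assert_allclose(res_a.params.position, res_b.params.position, atol=1e-8)
        np.testing.assert_allclose(res_a.params.gain, res_b.params.gain, rtol=1e-8)

    def test_gauge_consistency_across_basis_normalizations(self, fluxgate_scenario):
        # refit the same physical field maps with two different basis
        # reference radii; calibrating against identical responses must give
        # the same sensor parameters
        from coilcal.fieldmodel import fit_coefficients
        from coilcal.simulate import map_coil_fields

        maps = map_coil_fields(fluxgate_scenario)[:10]
        origin = maps[0].centroid()
        set_a = CoilModelSet([fit_coefficients(m, 3, origin, reference_radius=0.1) for m in maps])
        set_b = CoilModelSet([fit_coefficients(m, 3, origin, reference_radius=0.05) for m in maps])
        sensor = make_sensor(36)
        y = synthesize_responses(sensor, set_a)
        res_a = refine(sensor, set_a, y)
        res_b = refine(sensor, set_b, y)
        np.testing.assert_allclose(res_a.params.position, res_b.params.position, atol=1e-8)
        np.testing.assert_allclose(res_a.params.gain, res_b.params.gain, rtol=1e-8)
        np.testing.assert_allclose(res_a.params.orientation, res_b.params.orientation, atol=1e-8)
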