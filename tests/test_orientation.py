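"""Structure-tensor oracle: closed forms, equivariance, recovery."""

import numpy as np
import pytest

from fiberorder import synth
from fiberorder.orientation import (
    DegenerateInputError,
    OrderCalibration,
    _NO_CALIBRATION,
    estimate_order,
    nematic_order,
    structure_tensor_field,
)
from conftest import stripe_image


class TestNematicOrder:
    def test_parallel_angles_give_unit_order(self):
        S, dom = nematic_order([0.0, 0.0, 0.0])
        assert S == pytest.approx(1.0, abs=1e-12)
        assert dom == pytest.approx(0.0, abs=1e-12)

    def test_perpendicular_pair_cancels(self):
        S, _ = nematic_order([0.0, np.pi / 2])
        assert S == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_pair_closed_form(self):
        # |(1 + i)/2| = sqrt(2)/2, argument pi/2 -> dominant angle pi/8
        S, dom = nematic_order([0.0, np.pi / 4])
        assert S == pytest.approx(np.sqrt(2) / 2, abs=1e-12)
        assert dom == pytest.approx(np.pi / 8, abs=1e-12)

    def test_weights_shift_dominant_angle(self):
        S, dom = nematic_order([0.0, np.pi / 2], weights=[3.0, 1.0])
        assert S == pytest.approx(0.5, abs=1e-12)
        assert dom == pytest.approx(0.0, abs=1e-12)

    def test_zero_weights_degenerate(self):
        with pytest.raises(DegenerateInputError):
            nematic_order([0.1, 0.2], weights=[0.0, 0.0])

    def test_order_bounded_by_one(self):
        rng = np.random.default_rng(0)
        S, _ = nematic_order(rng.uniform(0, np.pi, 500), rng.random(500))
        assert 0.0 <= S <= 1.0


class TestStructureTensorField:
    def test_stripe_orientation_recovered(self):
        img = stripe_image(angle_deg=30.0)
        field = structure_tensor_field(img)
        m = field.valid & (field.coherence > 0.5)
        S, dom = nematic_order(field.angle[m], field.energy[m] * field.coherence[m])
        assert abs(np.rad2deg(dom) - 30.0) < 2.0
        assert S > 0.95

    def test_constant_image_has_zero_energy(self):
        field = structure_tensor_field(np.full((64, 64), 0.3))
        assert np.all(field.energy < 1e-20)
        assert not field.valid.any()

    def test_rotation_equivariance_on_exact_transpose(self):
        img = synth.generate_image(synth.GeneratorConfig(order_degree=0.8, seed=21))
        rot = np.rot90(img.pixels)  # lossless 90-degree rotation
        f0 = structure_tensor_field(img.pixels)
        f1 = structure_tensor_field(rot)
        m0 = f0.valid & (f0.coherence > 0.3)
        _, dom0 = nematic_order(f0.angle[m0], f0.energy[m0] * f0.coherence[m0])
        m1 = f1.valid & (f1.coherence > 0.3)
        _, dom1 = nematic_order(f1.angle[m1], f1.energy[m1] * f1.coherence[m1])
        diff = np.mod(dom1 - dom0, np.pi)
        assert min(diff, np.pi - diff) == pytest.approx(np.pi / 2, abs=0.05)

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            structure_tensor_field(np.zeros((32, 32)), gradient_sigma=0.0)
        with pytest.raises(ValueError):
            structure_tensor_field(np.zeros((8, 8)))


class TestEstimateOrder:
    def test_fully_aligned_mat_scores_high(self):
        cfg = synth.GeneratorConfig(order_degree=1.0, noise_sd=0.0, seed=31)
        img = synth.generate_image(cfg)
        est = estimate_order(img.pixels, calibration=_NO_CALIBRATION)
        assert est.S >= 0.95

    def test_pure_noise_scores_low(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            img = np.clip(0.1 + rng.normal(0, 0.05, (128, 128)), 0, 1)
            vals.append(estimate_order(img.pixels if hasattr(img, "pixels") else img,
                                       calibration=_NO_CALIBRATION).S)
        assert np.mean(vals) <= 0.15

    def test_monotone_in_order_degree(self):
        from scipy.stats import spearmanr

        grid = np.arange(0.1, 0.95, 0.1)
        means = []
        for d in grid:
            vals = [
                estimate_order(
                    synth.generate_image(
                        synth.GeneratorConfig(
                            order_degree=float(d),
                            seed=500 + s,
                            principal_angle=float((0.7 + 1.3 * s) % np.pi),
                        )
                    ).pixels,
                    calibration=_NO_CALIBRATION,
                ).S
                for s in range(20)
            ]
            means.append(np.mean(vals))
        rho = spearmanr(grid, means).statistic
        assert rho == pytest.approx(1.0)

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            estimate_order(np.full((64, 64), 0.5))

    def test_intensity_rescaling_invariance(self):
        img = synth.generate_image(synth.GeneratorConfig(order_degree=0.6, seed=41))
        a = estimate_order(img.pixels, calibration=_NO_CALIBRATION)
        b = estimate_order(0.5 * img.pixels + 0.2, calibration=_NO_CALIBRATION)
        assert b.S == pytest.approx(a.S, abs=1e-9)
        assert b.dominant_angle == pytest.approx(a.dominant_angle, abs=1e-9)

    def test_rotation_invariance_of_S(self):
        img = synth.generate_image(synth.GeneratorConfig(order_degree=0.7, seed=51))
        base = estimate_order(img.pixels, calibration=_NO_CALIBRATION).S
        for k in (1, 2, 3):
            rot = np.rot90(img.pixels, k=k)
            assert estimate_order(rot, calibration=_NO_CALIBRATION).S == pytest.approx(
                base, abs=0.02
            )


class TestCalibration:
    def test_piecewise_linear_roundtrip(self, tmp_path):
        cal = OrderCalibration(knots_s=(0.1, 0.5, 0.9), knots_d=(0.0, 0.4, 1.0))
        text = cal.to_json(tmp_path / "cal.json")
        loaded = OrderCalibration.from_json(text)
        assert loaded == cal
        assert cal(0.5) == pytest.approx(0.4)
        assert cal(0.0) == pytest.approx(0.0)  # clipped below
        assert cal(1.0) == pytest.approx(1.0)  # clipped above

    def test_packaged_fixture_is_monotone(self):
        from fiberorder.orientation import load_default_calibration

        cal = load_default_calibration()
        assert cal is not None
        assert np.all(np.diff(cal.knots_s) > 0)
        assert np.all(np.diff(cal.knots_d) >= 0)
        assert 0.0 <= min(cal.knots_d) and max(cal.knots_d) <= 1.0
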