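"""Compartment signal models: closed forms, degeneracies and the registry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcdmri import compartments as cpt
from mcdmri.compartments import (
    MODELS,
    ParamVector,
    ball_signal,
    composite_signal,
    get_model,
    sphere_signal,
    tensor_frame,
    tensor_signal,
    zeppelin_axis,
    zeppelin_signal,
)
from mcdmri.protocol import Measurement

TABLE_K = {
    "Ball": 3,
    "Zeppelin": 6,
    "Tensor": 8,
    "Ball-Ball": 5,
    "Zeppelin-Ball": 8,
    "Tensor-Ball": 10,
    "Ball-Sphere": 6,
    "Zeppelin-Sphere": 9,
    "Tensor-Sphere": 11,
}


class TestRegistry:
    def test_nine_models_with_published_parameter_counts(self):
        assert {name: spec.k for name, spec in MODELS.items()} == TABLE_K

    @pytest.mark.parametrize(
        "alias,canonical",
        [("BallSphere", "Ball-Sphere"), ("Zeppelin–Sphere", "Zeppelin-Sphere"),
         ("tensor ball", "Tensor-Ball"), ("Ball", "Ball")],
    )
    def test_aliases_resolve(self, alias, canonical):
        assert get_model(alias).name == canonical

    def test_unknown_model_raises(self):
        with pytest.raises(KeyError):
            get_model("Stick")

    def test_one_compartment_specs_have_no_fraction(self):
        for name in ("Ball", "Zeppelin", "Tensor"):
            assert "f_I" not in MODELS[name].free_params

    def test_bounds_match_constraints(self):
        spec = MODELS["Tensor-Sphere"]
        assert spec.bounds["D1"] == (0.01, 3.0)
        assert spec.bounds["R"] == (0.1, 20.0)
        assert spec.bounds["T2"] == (0.001, 3.0)
        assert spec.bounds["f_I"] == (0.0, 1.0)


class TestBall:
    def test_unit_attenuation_at_b0(self):
        assert ball_signal(0.0, 2.5) == 1.0

    def test_closed_form_values(self):
        assert ball_signal(1000.0, 1.0) == pytest.approx(math.exp(-1), rel=1e-12)
        assert ball_signal(928.0, 0.6) == pytest.approx(math.exp(-0.5568), rel=1e-12)

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError):
            ball_signal(-1.0, 1.0)


class TestZeppelin:
    def test_parallel_and_perpendicular_reductions(self):
        m_par = Measurement((0, 0, 1.0), 200, 3, 30, 45)
        m_perp = Measurement((1.0, 0, 0), 200, 3, 30, 45)
        # axis along z: theta = 0
        assert zeppelin_signal(m_par, 1.5, 0.5, 0.0, 0.0) == pytest.approx(
            ball_signal(m_par.b, 1.5), rel=1e-12
        )
        assert zeppelin_signal(m_perp, 1.5, 0.5, 0.0, 0.0) == pytest.approx(
            ball_signal(m_perp.b, 0.5), rel=1e-12
        )

    def test_isotropic_degeneracy(self, random_measurements):
        for m in random_measurements[:20]:
            assert zeppelin_signal(m, 1.1, 1.1, 0.3, 2.0) == pytest.approx(
                ball_signal(m.b, 1.1), abs=1e-14
            )

    def test_requires_ordered_eigenvalues(self):
        m = Measurement((1.0, 0, 0), 200, 3, 30, 45)
        with pytest.raises(ValueError):
            zeppelin_signal(m, 0.5, 1.5, 0.0, 0.0)


class TestTensor:
    def test_isotropic_and_cylindrical_degeneracies(self, random_measurements):
        for m in random_measurements[:20]:
            assert tensor_signal(m, 0.9, 0.9, 0.9, 0.7, 1.1, 0.5) == pytest.approx(
                ball_signal(m.b, 0.9), abs=1e-14
            )
            # D3 = D2: cylindrical symmetry, independent of alpha
            s1 = tensor_signal(m, 1.4, 0.6, 0.6, 0.7, 1.1, 0.0)
            s2 = tensor_signal(m, 1.4, 0.6, 0.6, 0.7, 1.1, 2.0)
            assert s1 == pytest.approx(s2, abs=1e-14)
            assert s1 == pytest.approx(
                zeppelin_signal(m, 1.4, 0.6, 0.7, 1.1), abs=1e-14
            )

    def test_rotation_invariance_explicit_matrix_oracle(self):
        """Rotating gradient and eigenframe together leaves the signal
        unchanged; oracle builds D = R diag R^T explicitly."""
        rng = np.random.default_rng(3)
        D1, D2, D3 = 1.8, 0.9, 0.4
        theta, phi, alpha = 0.9, 2.2, 0.6
        frame = tensor_frame(theta, phi, alpha)
        Dmat = frame.T @ np.diag([D1, D2, D3]) @ frame
        for _ in range(10):
            g = rng.standard_normal(3)
            g /= np.linalg.norm(g)
            m = Measurement(tuple(g), 250, 3, 30, 45)
            expected = math.exp(-m.b * 1e-3 * float(g @ Dmat @ g))
            assert tensor_signal(m, D1, D2, D3, theta, phi, alpha) == pytest.approx(
                expected, rel=1e-12
            )

    def test_frame_is_orthonormal(self):
        f = tensor_frame(0.4, 5.0, 1.2)
        assert np.allclose(f @ f.T, np.eye(3), atol=1e-12)
        assert np.allclose(f[0], zeppelin_axis(0.4, 5.0))


class TestSphere:
    def test_no_gradient_no_attenuation(self):
        m = Measurement((1, 0, 0), 0.0, 3, 10, 18)
        assert sphere_signal(m, 1.0, 8.0) == 1.0

    def test_tiny_sphere_barely_attenuates(self, full_cache):
        E = full_cache.sphere_attenuation(1.0, 0.1)
        assert np.all(E >= 0.999)

    def test_attenuation_in_unit_interval(self, full_cache):
        for R in (0.5, 2.0, 8.0, 20.0):
            E = full_cache.sphere_attenuation(1.0, R)
            assert np.all(E > 0) and np.all(E <= 1.0 + 1e-12)

    def test_orientation_independence(self):
        m1 = Measurement((1.0, 0, 0), 300, 3, 30, 45)
        m2 = Measurement((0, 0.6, 0.8), 300, 3, 30, 45)
        assert sphere_signal(m1, 1.0, 6.0) == pytest.approx(
            sphere_signal(m2, 1.0, 6.0), rel=1e-12
        )

    def test_free_diffusion_limit_slow_diffusion(self):
        """With diffusion length << R the wall is invisible and the GPD
        signal approaches exp(-b D)."""
        m = Measurement((1, 0, 0), 400, 3, 10, 18)
        D = 0.1  # length sqrt(6 D Delta) ~ 2.4 um << R = 20 um
        assert sphere_signal(m, D, 20.0) == pytest.approx(
            ball_signal(m.b, D), rel=0.02
        )

    def test_attenuation_decreases_towards_ball_with_R(self):
        m = Measurement((1, 0, 0), 400, 3, 10, 18)
        ladder = [sphere_signal(m, 1.0, R) for R in (2.0, 5.0, 10.0, 20.0)]
        assert all(a > b for a, b in zip(ladder, ladder[1:]))
        assert ladder[-1] > ball_signal(m.b, 1.0)

    def test_convergence_check_raises_with_too_few_roots(self):
        with pytest.raises(cpt.GPDConvergenceError):
            cpt.sphere_gpd_attenuation(
                np.array([0.4]), np.array([0.01]), np.array([0.08]),
                1e-9, 8e-6, 2.6752218744e8, tol=1e-12,
                roots=cpt.bessel_derivative_roots(5),
            )

    def test_bessel_derivative_roots(self):
        r = cpt.bessel_derivative_roots(4)
        assert r == pytest.approx([2.081576, 5.940370, 9.205840, 12.404445],
                                  abs=1e-5)


class TestComposite:
    def test_zero_intracellular_fraction_reduces_to_extracellular(self):
        m = Measurement((0, 0, 1.0), 200, 3, 30, 45)
        spec = get_model("Zeppelin-Sphere")
        p = ParamVector(D1=1.2, D2=0.5, theta=0.0, phi=0.0, D_I=1.0, R=8.0,
                        f_I=0.0, S0=2.0, T2=0.08)
        expected = 2.0 * math.exp(-0.045 / 0.08) * zeppelin_signal(m, 1.2, 0.5, 0, 0)
        assert composite_signal(spec, p, m) == pytest.approx(expected, rel=1e-12)

    def test_te_ratio_identity_at_b0(self):
        """Across Delta/TE blocks the b=0 signal ratio is exp(-dTE/T2)."""
        spec = get_model("Ball")
        p = ParamVector(D1=1.0, S0=1.0, T2=0.09)
        m18 = Measurement((1, 0, 0), 0.0, 3, 10, 18)
        m95 = Measurement((1, 0, 0), 0.0, 10, 80, 95)
        ratio = composite_signal(spec, p, m95) / composite_signal(spec, p, m18)
        assert ratio == pytest.approx(math.exp(-0.077 / 0.09), rel=1e-12)

    def test_monotone_in_G_within_blocks(self, study_scheme):
        """Printed-style Zeppelin-Sphere parameters: signal never grows
        with gradient strength inside a (delta, Delta) block."""
        spec = get_model("Zeppelin-Sphere")
        p = ParamVector(D1=1.1, D2=0.55, theta=0.8, phi=0.3, D_I=1.0, R=6.4,
                        f_I=0.44, S0=1.0, T2=0.07)
        by_block = {}
        for m in study_scheme:
            by_block.setdefault((m.delta, m.Delta, m.direction), []).append(m)
        for group in by_block.values():
            group.sort(key=lambda m: m.G)
            sig = [composite_signal(spec, p, m) for m in group]
            assert all(a >= b - 1e-12 for a, b in zip(sig, sig[1:]))

    def test_out_of_bounds_parameter_named(self):
        spec = get_model("Ball-Sphere")
        p = ParamVector(D1=1.0, D_I=1.0, R=25.0, f_I=0.4, S0=1.0, T2=0.1)
        m = Measurement((1, 0, 0), 100, 3, 10, 18)
        with pytest.raises(ValueError, match="'R'"):
            composite_signal(spec, p, m)

    def test_composite_never_exceeds_S0(self, random_measurements):
        spec = get_model("Zeppelin-Sphere")
        p = ParamVector(D1=1.2, D2=0.4, theta=1.2, phi=4.0, D_I=0.9, R=7.0,
                        f_I=0.5, S0=3.0, T2=0.5)
        for m in random_measurements[:30]:
            assert composite_signal(spec, p, m) <= 3.0 + 1e-12


class TestNesting:
    """Simpler models are exact special cases of richer ones."""

    CASES = [
        # (sub, super, sub params, super params at the degenerate point)
        ("Ball", "Zeppelin",
         dict(D1=1.0, S0=1.0, T2=0.1),
         dict(D1=1.0, D2=1.0, theta=0.4, phi=1.0, S0=1.0, T2=0.1)),
        ("Zeppelin", "Tensor",
         dict(D1=1.5, D2=0.6, theta=0.4, phi=1.0, S0=1.0, T2=0.1),
         dict(D1=1.5, D2=0.6, D3=0.6, theta=0.4, phi=1.0, alpha=0.7,
              S0=1.0, T2=0.1)),
        ("Ball-Ball", "Zeppelin-Ball",
         dict(D1=1.0, D_I=0.8, f_I=0.4, S0=1.0, T2=0.1),
         dict(D1=1.0, D2=1.0, theta=0.2, phi=0.5, D_I=0.8, f_I=0.4,
              S0=1.0, T2=0.1)),
        ("Zeppelin-Ball", "Tensor-Ball",
         dict(D1=1.5, D2=0.6, theta=0.4, phi=1.0, D_I=0.8, f_I=0.4,
              S0=1.0, T2=0.1),
         dict(D1=1.5, D2=0.6, D3=0.6, theta=0.4, phi=1.0, alpha=1.3,
              D_I=0.8, f_I=0.4, S0=1.0, T2=0.1)),
        ("Ball-Sphere", "Zeppelin-Sphere",
         dict(D1=1.0, D_I=0.9, R=7.0, f_I=0.45, S0=1.0, T2=0.1),
         dict(D1=1.0, D2=1.0, theta=0.2, phi=0.5, D_I=0.9, R=7.0, f_I=0.45,
              S0=1.0, T2=0.1)),
        ("Zeppelin-Sphere", "Tensor-Sphere",
         dict(D1=1.5, D2=0.6, theta=0.4, phi=1.0, D_I=0.9, R=7.0, f_I=0.45,
              S0=1.0, T2=0.1),
         dict(D1=1.5, D2=0.6, D3=0.6, theta=0.4, phi=1.0, alpha=0.2,
              D_I=0.9, R=7.0, f_I=0.45, S0=1.0, T2=0.1)),
    ]

    @pytest.mark.parametrize("sub,sup,psub,psup", CASES,
                             ids=[f"{c[0]}-in-{c[1]}" for c in CASES])
    def test_exact_equality_at_degenerate_point(
        self, sub, sup, psub, psup, random_measurements
    ):
        sub_spec, sup_spec = get_model(sub), get_model(sup)
        pv_sub, pv_sup = ParamVector(**psub), ParamVector(**psup)
        for m in random_measurements:
            a = composite_signal(sub_spec, pv_sub, m)
            b = composite_signal(sup_spec, pv_sup, m)
            assert a == pytest.approx(b, abs=1e-12)


class TestPredictScheme:
    """The vectorised hot path agrees with per-measurement evaluation."""

    @pytest.mark.parametrize("name", list(MODELS))
    def test_matches_composite_signal(self, name, full_scheme, full_cache):
        spec = get_model(name)
        vals = dict(D1=1.4, D2=0.8, D3=0.3, theta=0.7, phi=2.1, alpha=0.9,
                    D_I=0.9, R=7.0, f_I=0.4, S0=1.3, T2=0.08)
        p = ParamVector(**{k: vals[k] for k in spec.free_params})
        fast = cpt.predict_scheme(spec, p.to_array(spec), full_cache)
        slow = np.array(
            [composite_signal(spec, p, m) for m in full_scheme.measurements]
        )
        assert np.allclose(fast, slow, rtol=1e-10, atol=1e-12)


# hypothesis property tests avoid function-scoped fixtures: module cache
_CACHE = None


def _cache():
    global _CACHE
    if _CACHE is None:
        from mcdmri.protocol import build_study_protocol

        _CACHE = cpt.PrecomputedScheme(build_study_protocol())
    return _CACHE


@given(D=st.floats(0.05, 2.9), R=st.floats(0.3, 19.9))
@settings(deadline=None, max_examples=25)
def test_sphere_attenuation_in_unit_interval(D, R):
    E = _cache().sphere_attenuation(D, R)
    assert np.all(E > 0) and np.all(E <= 1 + 1e-12)
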