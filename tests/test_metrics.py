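"""Sagittal profiles and the AD / CPR / AR output parameters."""

import numpy as np
import pytest

from sclerapuff.metrics import (
    OutputParams,
    ProfileResolutionError,
    SagittalProfile,
    UndefinedRatioError,
    compute_output_params,
    displacement_at_x,
    extract_sagittal_profile,
    read_profile_csv,
)


def _profile(x, y):
    return SagittalProfile(x=np.asarray(x, float), y=np.asarray(y, float))


class TestSagittalProfile:
    def test_requires_coverage_and_density(self):
        with pytest.raises(ProfileResolutionError):
            _profile([-1.0, 0.0, 1.0], [1.0, 2.0, 1.0])  # too narrow
        with pytest.raises(ProfileResolutionError):
            _profile([-2.5, 0.0, 2.5], [1.0, 2.0, 1.0])  # too sparse

    def test_requires_strict_ordering(self):
        x = [-3, -2, -1, -1, 0, 1, 2, 3]
        with pytest.raises(ValueError):
            _profile(x, np.ones(len(x)))

    def test_out_of_range_height_rejected(self):
        x = np.linspace(-3, 3, 13)
        p = _profile(x, 10 - x**2 / 10)
        with pytest.raises(ValueError):
            p.height(5.0)


class TestDisplacementAtX:
    def test_identical_profiles_zero(self):
        x = np.linspace(-3, 3, 25)
        p = _profile(x, 10 - x**2 / 10)
        assert displacement_at_x(p, p, 0.0) == 0.0

    def test_analytic_gaussian_dent(self):
        """Y = 10, y = 10 - exp(-x^2): displacement 1 at x=0, exp(-4) at
        x = +-2."""
        x = np.linspace(-4, 4, 161)
        Y = _profile(x, np.full_like(x, 10.0))
        y = _profile(x, 10.0 - np.exp(-(x**2)))
        assert displacement_at_x(Y, y, 0.0) == pytest.approx(1.0, abs=1e-6)
        for s in (-2.0, 2.0):
            assert displacement_at_x(Y, y, s) == pytest.approx(
                np.exp(-4.0), rel=1e-3
            )

    def test_rigid_translation_invariance(self):
        """Shifting both curves by the same height leaves Y - y unchanged."""
        x = np.linspace(-3, 3, 25)
        y0 = 10 - x**2 / 10
        y1 = y0 - np.exp(-(x**2))
        d0 = displacement_at_x(_profile(x, y0), _profile(x, y1), 1.0)
        d1 = displacement_at_x(_profile(x, y0 + 5), _profile(x, y1 + 5), 1.0)
        assert d0 == pytest.approx(d1, abs=1e-12)


class TestOutputParams:
    def test_direct_arithmetic(self):
        """Spot values: Y = (9.9, 10, 9.8), y = (9.5, 9.0, 9.3) at
        x = (-2, 0, 2) give AD = 1, CPR = 2, AR = 1.25."""
        x = np.linspace(-2.5, 2.5, 11)
        # piecewise curves through the anchor heights
        Y = _profile([-2.5, -2, -1, 0, 1, 2, 2.5], [9.85, 9.9, 9.95, 10, 9.9, 9.8, 9.75])
        y = _profile([-2.5, -2, -1, 0, 1, 2, 2.5], [9.55, 9.5, 9.25, 9.0, 9.15, 9.3, 9.4])
        out = compute_output_params(Y, y)
        assert out.ad == pytest.approx(1.0)
        assert out.cpr == pytest.approx(2.0)
        assert out.ar == pytest.approx(1.25)
        assert out.heights["Y_0"] == pytest.approx(10.0)

    def test_undefined_ratio_reported(self):
        x = [-3, -2, -1, 0, 1, 2, 3]
        Y = _profile(x, [10.0] * 7)
        y = _profile(x, [10, 10, 9.9, 9.0, 9.9, 10, 10])  # zero drop at +-2
        with pytest.raises(UndefinedRatioError):
            compute_output_params(Y, y)


class TestExtraction:
    def test_apex_is_curve_maximum_at_origin(self, baseline_forward):
        prof = baseline_forward.profile_initial
        xs = np.linspace(prof.x[0], prof.x[-1], 500)
        i = np.argmax(prof.interpolator()(xs))
        assert abs(xs[i]) < 0.05  # apex defines the origin

    def test_station_on_vs_between_nodes(self, baseline_forward):
        """Interpolated displacement is insensitive (<1e-3 mm) to whether
        the station hits a mesh node exactly."""
        ini, fin = baseline_forward.profile_initial, baseline_forward.profile_final
        node_x = ini.x[np.argmin(np.abs(ini.x - 2.0))]
        d_node = displacement_at_x(ini, fin, float(node_x))
        d_near = displacement_at_x(ini, fin, float(node_x) + 0.02)
        assert abs(d_node - d_near) < 1e-3 + 0.02 * abs(d_node)

    def test_foreaft_symmetric_model_has_unit_ar(self, symmetric_forward):
        """A closed ellipsoidal shell with AL = EL, uniform thickness and
        uniform stiffness is fore-aft symmetric: AR = 1 (and the mirrored
        half reproduces x < 0)."""
        res = symmetric_forward
        assert res.outputs.ar == pytest.approx(1.0, abs=0.02)
        d_m2 = displacement_at_x(res.profile_initial, res.profile_final, -2.0)
        d_p2 = displacement_at_x(res.profile_initial, res.profile_final, 2.0)
        assert d_m2 == pytest.approx(d_p2, rel=0.02)

    def test_softer_posterior_raises_ar_and_lowers_cpr(self, baseline_forward):
        """Sign-convention self-test: mu_post < mu means the posterior
        (+x) side deforms more, so AR > 1 and CPR drops relative to the
        uniform model."""
        from conftest import forward_cached

        soft = forward_cached(mu_post_ratio=0.25)
        assert soft.outputs.ar > baseline_forward.outputs.ar
        assert soft.outputs.ar > 1.0
        assert soft.outputs.cpr < baseline_forward.outputs.cpr


def test_profile_csv_reader(tmp_path):
    path = tmp_path / "prof.csv"
    x = np.linspace(-3, 3, 25)
    y = 10 - x**2 / 10
    path.write_text(
        "# segmented OCT surface\nx,y\n"
        + "\n".join(f"{a},{b}" for a, b in zip(x, y))
    )
    prof = read_profile_csv(path)
    assert prof.height(0.0) == pytest.approx(10.0)
    assert prof.x.size == 25
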