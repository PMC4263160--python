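"""Shape, overlap and potential oracles for parallel prolate spheroids."""

import math

import numpy as np
import pytest
from scipy import integrate

from tubuloid.geometry import (
    ChargePair,
    SpheroidShape,
    charge_offset,
    contact_function,
    discrete_charge_potential,
    exact_polarized_potential,
    overlap,
)


def charge_offset_oracle(shape):
    """Independent multipole-quadrature oracle for the site offset.

    The focal-segment dipole density mu(z) ~ 1 - z^2/c^2 has dipole moment
    p1 = int mu dz and octupole p3 = 3 int mu z^2 dz; the matched charge pair
    satisfies d^2 = p3 / p1.
    """
    c = shape.focal_half_length
    if c == 0.0:
        return 0.0
    mu = lambda z: 1.0 - (z / c) ** 2
    p1, _ = integrate.quad(mu, -c, c)
    p3, _ = integrate.quad(lambda z: 3.0 * mu(z) * z * z, -c, c)
    return math.sqrt(p3 / p1)


class TestChargeOffset:
    def test_sphere_is_pure_dipole(self):
        assert charge_offset(SpheroidShape(R=1.0, rho=1.0)) == 0.0

    @pytest.mark.parametrize(
        "rho,R,expected",
        [(2.7, 1.0, 1.9427), (2.0, 0.5, 0.6708)],
    )
    def test_reference_values(self, rho, R, expected):
        assert charge_offset(SpheroidShape(R=R, rho=rho)) == pytest.approx(
            expected, abs=1e-4
        )

    @pytest.mark.parametrize("rho", [1.5, 2.0, 2.7, 5.0])
    def test_matches_multipole_quadrature(self, rho):
        s = SpheroidShape(R=1.0, rho=rho)
        d = charge_offset(s)
        assert d == pytest.approx(charge_offset_oracle(s), rel=1e-6)

    def test_sites_inside_particle(self):
        for rho in (1.0, 2.7, 8.8):
            s = SpheroidShape(R=1.0, rho=rho)
            assert 0.0 <= charge_offset(s) < s.a

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            SpheroidShape(R=1.0, rho=0.5)
        with pytest.raises(ValueError):
            SpheroidShape(R=-1.0, rho=2.0)


class TestOverlap:
    @pytest.mark.parametrize(
        "delta,rho,expected",
        [
            ((2.0, 0.0, 0.0), 2.7, False),  # side-by-side exact contact
            ((0.0, 0.0, 2 * 2.7), 2.7, False),  # tip-to-tip exact contact
            ((0.0, 0.0, 2.0), 2.7, True),  # tip distance inside the scaled core
            ((1.9, 0.0, 0.0), 1.0, True),
        ],
    )
    def test_contact_cases(self, delta, rho, expected):
        s = SpheroidShape(R=1.0, rho=rho)
        assert overlap(np.zeros(3), np.array(delta), s) is expected

    @pytest.mark.parametrize(
        "delta,expected",
        [
            ((2.0, 0.0, 0.0), 1.0),
            ((0.0, 0.0, 4 * 2.7), 4.0),
            ((1.0, 0.0, 2.7), 0.5),
        ],
    )
    def test_contact_function_values(self, shape, delta, expected):
        f = contact_function(np.zeros(3), np.array(delta), shape)
        assert f == pytest.approx(expected, abs=1e-12)

    def test_overlap_agrees_with_contact_sign(self, shape, rng):
        # affine predicate vs contact function on 10^4 random parallel pairs
        deltas = rng.uniform(-4.0, 4.0, size=(10_000, 3))
        deltas[:, 2] *= shape.rho
        for delta in deltas:
            f = contact_function(np.zeros(3), delta, shape)
            assert overlap(np.zeros(3), delta, shape) == (f < 1.0)

    def test_minimum_image_used_with_box(self, shape):
        box = np.array([10.0, 10.0, 20.0])
        # neighbours across the boundary
        assert overlap(np.array([0.5, 0, 0]), np.array([9.9, 0, 0]), shape, box=box)
        assert not overlap(np.array([0.5, 0, 0]), np.array([5.0, 0, 0]), shape, box=box)


class TestPotential:
    def test_midplane_antisymmetry(self, shape, pair):
        for p in ([3.0, 0.0, 0.0], [1.5, 2.0, 0.0]):
            assert discrete_charge_potential(p, shape, pair) == pytest.approx(0.0)
            assert exact_polarized_potential(p, shape) == pytest.approx(0.0, abs=1e-12)

    def test_z_inversion_antisymmetry(self, shape, pair):
        p = np.array([1.2, 0.4, 3.9])
        up = discrete_charge_potential(p, shape, pair)
        dn = discrete_charge_potential(p * np.array([1, 1, -1]), shape, pair)
        assert up == pytest.approx(-dn)

    def test_on_axis_reference_point(self, shape, pair):
        # Phi* = R^2/(2d) (1/(2a-d) - 1/(2a+d)) at (0, 0, 2a)
        d = pair.d
        expected = 1.0 / (2 * d) * (1.0 / (5.4 - d) - 1.0 / (5.4 + d))
        got = discrete_charge_potential((0, 0, 2 * shape.a), shape, pair)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.039392, abs=1e-5)

    @pytest.mark.parametrize("direction", [(0, 0, 1), (1, 0, 1), (1, 1, 2)])
    def test_far_field_dipole_asymptote(self, shape, pair, direction):
        u = np.asarray(direction, dtype=float)
        u /= np.linalg.norm(u)
        for r in (50.0, 200.0):
            p = r * u
            dipole = shape.R**2 * p[2] / r**3
            assert discrete_charge_potential(p, shape, pair) == pytest.approx(
                dipole, rel=5e-3 * (50.0 / r) ** 2
            )
            assert exact_polarized_potential(p, shape) == pytest.approx(
                dipole, rel=5e-3 * (50.0 / r) ** 2
            )

    @pytest.mark.parametrize("scale,bound", [(1.05, 0.15), (1.2, 0.10), (1.5, 0.07)])
    def test_discrete_close_to_exact_near_surface(self, shape, pair, scale, bound):
        # deviation normalized by the peak amplitude on each sampling shell
        # (pointwise relative error is meaningless near the equatorial node)
        devs, mags = [], []
        for t in np.linspace(0.01, math.pi - 0.01, 41):
            p = scale * np.array(
                [shape.R * math.sin(t), 0.0, shape.a * math.cos(t)]
            )
            exact = exact_polarized_potential(p, shape)
            approx = discrete_charge_potential(p, shape, pair)
            devs.append(abs(approx - exact))
            mags.append(abs(exact))
        assert max(devs) / max(mags) < bound

    def test_singularities_raise(self, shape, pair):
        with pytest.raises(ZeroDivisionError):
            discrete_charge_potential((0, 0, pair.d), shape, pair)
        with pytest.raises(ValueError):
            exact_polarized_potential((0.0, 0.0, 0.5 * shape.a), shape)

    def test_charge_pair_invariants(self):
        with pytest.raises(ValueError):
            ChargePair(d=-0.1)
        with pytest.raises(ValueError):
            ChargePair(d=1.0, site_signs=(1, 1))


class TestPropertyInvariants:
    """Derandomized property tests of the geometric invariants."""

    from hypothesis import given, settings, strategies as st

    coord = st.floats(-20.0, 20.0, allow_nan=False)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(dx=coord, dy=coord, dz=coord, sx=coord, sy=coord, sz=coord)
    def test_contact_translation_invariant_and_symmetric(
        self, dx, dy, dz, sx, sy, sz
    ):
        shape = SpheroidShape(R=1.0, rho=2.7)
        a = np.array([sx, sy, sz])
        b = a + np.array([dx, dy, dz])
        f = contact_function(a, b, shape)
        assert contact_function(b, a, shape) == pytest.approx(f, rel=1e-12)
        shift = np.array([7.7, -3.1, 11.9])
        assert contact_function(a + shift, b + shift, shape) == pytest.approx(
            f, rel=1e-9
        )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(x=coord, y=coord, z=st.floats(-20.0, 20.0, allow_nan=False))
    def test_potential_odd_under_z_inversion_with_charge_flip(self, x, y, z):
        # z -> -z with simultaneous charge-sign flip leaves physics unchanged:
        # the potential is odd in z
        shape = SpheroidShape(R=1.0, rho=2.7)
        pair = ChargePair(d=1.5)
        p = np.array([x, y, z])
        if min(np.linalg.norm(p - [0, 0, 1.5]), np.linalg.norm(p + [0, 0, 1.5])) < 0.3:
            return
        up = discrete_charge_potential(p, shape, pair)
        dn = discrete_charge_potential(p * np.array([1, 1, -1]), shape, pair)
        assert dn == pytest.approx(-up, rel=1e-9, abs=1e-12)
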