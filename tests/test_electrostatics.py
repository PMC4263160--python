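"""Direct sums, Ewald sums and the ideal-dipole control."""

import math

import numpy as np
import pytest

from tubuloid.electrostatics import (
    EwaldParams,
    dipole_pair_energy,
    direct_pair_energy,
    ewald_energy,
    move_energy_delta,
    total_energy_direct,
)
from tubuloid.geometry import site_positions
from tubuloid.system import make_state


def four_site_oracle(c1, c2, shape, pair, gamma):
    """Explicit Coulomb sum over the 4 inter-particle site pairs."""
    s1 = site_positions(c1, pair)
    s2 = site_positions(c2, pair)
    q = [1.0, -1.0]
    u = 0.0
    for i in range(2):
        for j in range(2):
            u += q[i] * q[j] / np.linalg.norm(s2[j] - s1[i])
    return 2.0 * gamma * shape.R * u


class TestDirectSums:
    def test_vanishes_at_large_separation(self, shape, pair):
        e = direct_pair_energy([0, 0, 0], [0, 0, 1e8], shape, pair, 1.0)
        assert abs(e) < 1e-15

    @pytest.mark.parametrize(
        "delta,expected",
        [
            ((0.0, 0.0, 5.4), -0.795),  # head-to-tail contact
            ((1.0169, 0.0, 4.65), -0.964),  # staggered near-minimum contact
        ],
    )
    def test_reference_contacts(self, shape, pair, delta, expected):
        e = direct_pair_energy(np.zeros(3), np.array(delta), shape, pair, 1.0)
        assert e == pytest.approx(expected, abs=5e-4)
        assert e == pytest.approx(
            four_site_oracle(np.zeros(3), np.array(delta), shape, pair, 1.0)
        )

    def test_linear_in_gamma_and_symmetric(self, shape, pair, rng):
        for _ in range(20):
            delta = rng.uniform(-8, 8, 3)
            if np.linalg.norm(delta) < 3:
                continue
            e1 = direct_pair_energy(np.zeros(3), delta, shape, pair, 1.0)
            assert direct_pair_energy(np.zeros(3), delta, shape, pair, 7.3) == (
                pytest.approx(7.3 * e1)
            )
            assert direct_pair_energy(delta, np.zeros(3), shape, pair, 1.0) == (
                pytest.approx(e1)
            )

    def test_total_energy_additive(self, shape, pair):
        a, b, c = np.zeros(3), np.array([0, 0, 5.4]), np.array([0, 0, 10.8])
        single = total_energy_direct([a], shape, pair, 1.0)
        assert single == 0.0
        two = total_energy_direct([a, b], shape, pair, 1.0)
        assert two == pytest.approx(direct_pair_energy(a, b, shape, pair, 1.0))
        three = total_energy_direct([a, b, c], shape, pair, 1.0)
        expected = sum(
            direct_pair_energy(p, q, shape, pair, 1.0)
            for p, q in ((a, b), (b, c), (a, c))
        )
        assert three == pytest.approx(expected)


class TestDipoleControl:
    def test_side_by_side_repulsive(self, shape, pair):
        for r in (2.5, 4.0, 10.0):
            assert dipole_pair_energy([0, 0, 0], [r, 0, 0], shape, pair, 1.0) > 0

    def test_head_to_tail_attractive(self, shape, pair):
        for r in (6.0, 12.0):
            assert dipole_pair_energy([0, 0, 0], [0, 0, r], shape, pair, 1.0) < 0

    # note (1,1,1) is excluded: it sits at the magic angle where the
    # dipole-dipole energy changes sign
    @pytest.mark.parametrize("direction", [(0, 0, 1), (1, 0, 0), (1, 0, 2)])
    def test_charge_pair_asymptote(self, shape, pair, direction):
        u = np.asarray(direction, dtype=float)
        u /= np.linalg.norm(u)
        delta = 50.0 * u
        e_pair = direct_pair_energy(np.zeros(3), delta, shape, pair, 1.0)
        e_dip = dipole_pair_energy(np.zeros(3), delta, shape, pair, 1.0)
        assert e_pair / e_dip == pytest.approx(1.0, abs=2e-2)


class TestEwald:
    def test_matches_direct_for_isolated_pair(self, shape):
        # tinfoil image terms decay as 1/V; a box ~30x the pair separation
        # pushes them below 1e-4 relative
        L = 150.0
        st = make_state([[0, 0, 0], [1.0169, 0, 4.65]], shape, [L, L, L], 1.0)
        e_ewald = ewald_energy(st)
        e_direct = direct_pair_energy(
            st.positions[0], st.positions[1], shape, st.pair, 1.0
        )
        assert e_ewald == pytest.approx(e_direct, rel=1e-4)

    def test_invariant_under_splitting_parameter(self, shape):
        L = 12.0
        st = make_state([[0, 0, 0], [2.5, 1.0, 3.0]], shape, [L, L, L], 2.0)
        # generous fixed cutoffs so truncation stays below 1e-6 for all alpha
        base = EwaldParams(alpha=0.9, r_cut=6.0, k_cut=2 * 0.9 * 1.3 * 5.0)
        e0 = ewald_energy(st, base)
        for fac in (0.7, 1.3):
            p = EwaldParams(alpha=0.9 * fac, r_cut=6.0, k_cut=base.k_cut)
            assert ewald_energy(st, p) == pytest.approx(e0, rel=1e-6)

    def test_matches_brute_force_image_sum(self, shape, pair):
        """Ewald (tinfoil) vs cubic-shell image sum plus the boundary term.

        The direct sum over cubic image shells converges, O(1/S^2), to the
        vacuum-boundary energy, which exceeds tinfoil by 2 pi M^2 / 3V;
        Richardson extrapolation over S removes the shell truncation.
        """
        L = 8.0
        pos = np.array([[0.0, 0.0, 0.0], [2.5, 1.0, 2.0]])
        st = make_state(pos, shape, [L, L, L], 1.0)
        e_ewald = ewald_energy(st, EwaldParams.from_box([L] * 3, accuracy=1e-10))

        sites = np.concatenate([site_positions(c, pair) for c in pos])
        q = np.array([1.0, -1.0, 1.0, -1.0])
        owner = np.array([0, 0, 1, 1])

        def shell_sum(S):
            r = np.arange(-S, S + 1) * L
            shifts = np.stack(np.meshgrid(r, r, r, indexing="ij"), -1).reshape(-1, 3)
            zero = np.all(shifts == 0, axis=1)
            u = 0.0
            for i in range(4):
                for j in range(4):
                    dv = sites[j] - sites[i] + shifts
                    rr = np.linalg.norm(dv, axis=1)
                    skip = zero & (owner[i] == owner[j])
                    keep = (rr > 0) & ~skip
                    u += 0.5 * q[i] * q[j] * np.sum(1.0 / rr[keep])
            return 2.0 * u  # prefactor 2 Gamma R

        u8, u16 = shell_sum(8), shell_sum(16)
        u_inf = u16 + (u16 - u8) / 3.0  # O(1/S^2) Richardson step
        m_z = 2 * 2 * pair.d
        surface = 2.0 * 2 * np.pi / (3 * L**3) * m_z**2
        assert u_inf - surface == pytest.approx(e_ewald, rel=1e-4)

    def test_translation_invariance(self, shape, rng):
        L = 14.0
        pos = rng.uniform(0, L, (6, 3))
        st = make_state(pos, shape, [L, L, L], 3.0)
        e0 = ewald_energy(st)
        shifted = make_state(pos + [3.1, -7.7, 12.9], shape, [L, L, L], 3.0)
        assert ewald_energy(shifted) == pytest.approx(e0, rel=1e-9)

    def test_linear_in_gamma(self, shape, rng):
        L = 14.0
        pos = rng.uniform(0, L, (4, 3))
        e1 = ewald_energy(make_state(pos, shape, [L] * 3, 1.0))
        e5 = ewald_energy(make_state(pos, shape, [L] * 3, 5.0))
        assert e5 == pytest.approx(5.0 * e1, rel=1e-12)

    def test_dipole_mode_matches_direct(self, shape, pair):
        L = 200.0
        st = make_state([[0, 0, 0], [3.0, 0, 4.0]], shape, [L] * 3, 1.0,
                        mode="point_dipole")
        e = ewald_energy(st)
        e_direct = dipole_pair_energy([0, 0, 0], [3.0, 0, 4.0], shape, pair, 1.0)
        assert e == pytest.approx(e_direct, rel=1e-3)

    def test_cutoff_validation(self, shape):
        st = make_state([[0, 0, 0], [3, 0, 0]], shape, [10.0] * 3, 1.0)
        with pytest.raises(ValueError):
            ewald_energy(st, EwaldParams(alpha=0.5, r_cut=8.0, k_cut=3.0))


class TestMoveDelta:
    def _random_state(self, shape, rng, n=10, L=18.0, mode="charge_pair"):
        from tubuloid.mc import init_random_config

        st = init_random_config(n, shape, gamma=4.0, box=[L] * 3,
                                seed=int(rng.integers(2**31)), mode=mode)
        return st

    def test_null_move_is_zero(self, shape, rng):
        st = self._random_state(shape, rng)
        assert move_energy_delta(st, 3, st.positions[3]) == pytest.approx(0.0)

    @pytest.mark.parametrize("mode", ["charge_pair", "point_dipole"])
    def test_matches_full_recompute(self, shape, rng, mode):
        st = self._random_state(shape, rng, mode=mode)
        e0 = ewald_energy(st)
        for _ in range(5):
            i = int(rng.integers(st.n))
            new = np.mod(st.positions[i] + rng.uniform(-1, 1, 3), st.box)
            du = move_energy_delta(st, i, new)
            moved = st.copy()
            moved.positions[i] = new
            assert du == pytest.approx(ewald_energy(moved) - e0, rel=1e-8, abs=1e-10)

    def test_reverse_move_antisymmetric(self, shape, rng):
        st = self._random_state(shape, rng)
        i = 2
        new = np.mod(st.positions[i] + [0.7, -0.3, 1.1], st.box)
        du = move_energy_delta(st, i, new)
        moved = st.copy()
        moved.positions[i] = new
        du_back = move_energy_delta(moved, i, st.positions[i])
        assert du + du_back == pytest.approx(0.0, abs=1e-10)
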