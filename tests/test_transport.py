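import math

import numpy as np
import pytest

from magchip.errors import (
    InvalidArgumentError,
    SingularSeparationError,
)
from magchip.field_energy import ExternalField, external_field_at
from magchip.transport import (
    DEFAULT_CHI_P,
    Particle,
    SimConfig,
    dipole_moment,
    dipole_pair_force,
    drag_velocity,
    magnetic_force,
    pair_forces,
    simulate,
    spine_progress,
)
from magchip.units import MU0, UM


def dipole_energy(m1, m2, r_um):
    """Point-dipole interaction energy (J) — independent oracle."""
    r = np.asarray(r_um) * UM
    d = np.linalg.norm(r)
    rh = r / d
    return MU0 / (4 * np.pi * d**3) * (m1 @ m2 - 3 * (m1 @ rh) * (m2 @ rh))


def numgrad_force(m1, m2, r_um, h=1e-4):
    """F on dipole 1 = -grad_r U, central differences (oracle)."""
    f = np.zeros(3)
    for k in range(3):
        e = np.zeros(3)
        e[k] = h
        f[k] = -(dipole_energy(m1, m2, r_um + e) -
                 dipole_energy(m1, m2, r_um - e)) / (2 * h * UM)
    return f


class TestDipolePairForce:
    def test_matches_numerical_gradient_on_random_configs(self, rng):
        """The closed form equals -grad of the dipole-dipole energy."""
        for _ in range(100):
            m1 = rng.normal(size=3) * 1e-13
            m2 = rng.normal(size=3) * 1e-13
            r = rng.uniform(-10, 10, size=3)
            while np.linalg.norm(r) < 2.0:
                r = rng.uniform(-10, 10, size=3)
            f = dipole_pair_force(m1, m2, r)
            fo = numgrad_force(m1, m2, r)
            assert np.linalg.norm(f - fo) / np.linalg.norm(fo) < 1e-4

    def test_vertical_moments_inplane_separation_repulsive(self):
        m = 1e-13
        d = 6.0
        f = dipole_pair_force(np.array([0, 0, m]), np.array([0, 0, m]),
                              np.array([d, 0, 0]))
        # radially outward (repulsive), magnitude 3 mu0 m^2 / (4 pi d^4)
        expect = 3 * MU0 * m**2 / (4 * np.pi * (d * UM)**4)
        assert f[0] == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(2.3e-12, rel=0.05)  # ~2.3 pN
        assert f[1] == f[2] == 0.0

    def test_collinear_moments_attractive_twice_perpendicular(self):
        m = 1e-13
        d = 6.0
        f_perp = dipole_pair_force(np.array([0, 0, m]), np.array([0, 0, m]),
                                   np.array([d, 0, 0]))
        f_coll = dipole_pair_force(np.array([m, 0, 0]), np.array([m, 0, 0]),
                                   np.array([d, 0, 0]))
        assert f_coll[0] < 0  # attractive
        assert abs(f_coll[0]) == pytest.approx(2 * abs(f_perp[0]), rel=1e-12)

    def test_newtons_third_law(self, rng):
        for _ in range(20):
            m1 = rng.normal(size=3) * 1e-13
            m2 = rng.normal(size=3) * 1e-13
            r = rng.uniform(2, 10, size=3)
            f12 = dipole_pair_force(m1, m2, r)
            f21 = dipole_pair_force(m2, m1, -r)
            assert f12 == pytest.approx(-f21, rel=1e-12)

    def test_coincident_dipoles_rejected(self):
        with pytest.raises(SingularSeparationError):
            dipole_pair_force(np.ones(3), np.ones(3), np.zeros(3))

    def test_pair_forces_matches_pairwise_sum(self, rng):
        pos = rng.uniform(0, 30, size=(4, 3))
        moms = rng.normal(size=(4, 3)) * 1e-13
        F = pair_forces(pos, moms)
        for i in range(4):
            expect = sum(dipole_pair_force(moms[i], moms[j], pos[i] - pos[j])
                         for j in range(4) if j != i)
            assert F[i] == pytest.approx(expect, rel=1e-10)


class TestMagicAngle:
    """Rotation-averaged in-plane pair force changes sign at the dipolar
    magic elevation arctan(1/sqrt(2)) ~ 35.26 deg."""

    @staticmethod
    def averaged_radial_force(elev_deg, n_phase=360):
        m0 = 1e-13
        d = np.array([6.0, 0.0, 0.0])
        el = math.radians(elev_deg)
        fr = 0.0
        for ph in np.linspace(0, 2 * np.pi, n_phase, endpoint=False):
            m = m0 * np.array([math.cos(el) * math.cos(ph),
                               math.cos(el) * math.sin(ph), math.sin(el)])
            fr += dipole_pair_force(m, m, d)[0]
        return fr / n_phase

    def test_attractive_below_magic_angle(self):
        assert self.averaged_radial_force(20.0) < 0

    def test_repulsive_at_45_degrees(self):
        assert self.averaged_radial_force(45.0) > 0

    def test_sign_change_at_magic_angle(self):
        magic = math.degrees(math.atan(1 / math.sqrt(2)))
        assert self.averaged_radial_force(magic - 1.0) < 0
        assert self.averaged_radial_force(magic + 1.0) > 0
        assert abs(self.averaged_radial_force(magic)) < abs(
            self.averaged_radial_force(45.0)) * 1e-2


class TestDragVelocity:
    def test_zero_force(self):
        assert drag_velocity(np.zeros(3), 2.5, 1e-3) == pytest.approx(np.zeros(3))

    def test_stokes_closed_form(self):
        # 1 pN on a 2.5-um bead in water -> ~21.2 um/s
        v = drag_velocity(np.array([1e-12, 0, 0]), 2.5, 1e-3)
        assert v[0] == pytest.approx(21.22, rel=1e-3)

    def test_inverse_radius_scaling(self):
        f = np.array([1e-12, 0, 0])
        assert drag_velocity(f, 5.0, 1e-3)[0] == pytest.approx(
            drag_velocity(f, 2.5, 1e-3)[0] / 2, rel=1e-12)

    def test_invalid_args(self):
        with pytest.raises(InvalidArgumentError):
            drag_velocity(np.zeros(3), 0.0, 1e-3)


class TestMagneticForce:
    def test_quadratic_energy_closed_form(self):
        k = 2.5e-15  # J / um^2
        def u(pts):
            return k * (pts[:, 0]**2 + pts[:, 1]**2)
        pos = np.array([3.0, -2.0, 1.0])
        f = magnetic_force(u, pos, step_um=0.01)
        expect = -2 * k * pos / UM
        assert f[0] == pytest.approx(expect[0], rel=1e-6)
        assert f[1] == pytest.approx(expect[1], rel=1e-6)
        assert f[2] == 0.0

    def test_uniform_energy_no_force(self):
        f = magnetic_force(lambda p: np.full(len(p), 3.3e-18), np.zeros(3))
        assert f == pytest.approx(np.zeros(3))


class TestDipoleMoment:
    def test_formula(self):
        p = Particle(radius_um=3.0, chi_p=0.5)
        h = np.array([0.0, 0.0, 5570.0])
        m = dipole_moment(p, h)
        expect = 4 * np.pi * (3e-6)**3 * 0.5 * 5570.0 / 3
        assert m[2] == pytest.approx(expect, rel=1e-12)


class TestIntegration:
    def test_zero_field_stationary(self):
        ext = ExternalField(0.0, 0.0, 0.2)
        p = Particle(radius_um=2.75, position=np.array([5.0, 5.0, 3.25]))
        cfg = SimConfig(dt=0.01, duration=1.0)
        traj = simulate([p], None, ext, cfg)[0]
        assert traj.positions[-1] == pytest.approx(traj.positions[0])

    def test_conical_field_beads_repel(self):
        """Dispersed beads under the 70/70 Oe conical drive move apart;
        the cycle-averaged separation grows monotonically."""
        ext = ExternalField(70.0, 70.0, 0.2)
        z = 1.9
        p1 = Particle(radius_um=1.4, chi_p=DEFAULT_CHI_P,
                      position=np.array([0.0, 0.0, z]), id=0)
        p2 = Particle(radius_um=1.4, chi_p=DEFAULT_CHI_P,
                      position=np.array([2 * 1.4 + 4.0, 0.0, z]), id=1)
        cfg = SimConfig(duration=15.0, record_every=4)
        t1, t2 = simulate([p1, p2], None, ext, cfg)
        sep = np.linalg.norm(t1.positions - t2.positions, axis=1)
        assert sep[-1] > sep[0] + 2.0
        # averaged over each rotation the drift is outward
        per = int(round(ext.period / (t1.times[1] - t1.times[0])))
        cyc = [sep[k * per:(k + 1) * per].mean() for k in range(3)]
        assert cyc[0] < cyc[1] < cyc[2]

    def test_inplane_field_beads_attract(self):
        """Without the vertical bias the rotation-averaged force is
        attractive and the same two beads collapse into contact."""
        ext = ExternalField(70.0, 0.0, 0.2)
        z = 1.9
        p1 = Particle(radius_um=1.4, chi_p=DEFAULT_CHI_P,
                      position=np.array([0.0, 0.0, z]), id=0)
        p2 = Particle(radius_um=1.4, chi_p=DEFAULT_CHI_P,
                      position=np.array([2 * 1.4 + 3.0, 0.0, z]), id=1)
        cfg = SimConfig(duration=15.0, record_every=4)
        t1, t2 = simulate([p1, p2], None, ext, cfg)
        sep = np.linalg.norm(t1.positions - t2.positions, axis=1)
        assert sep[-1] == pytest.approx(2 * 1.4, abs=0.2)

    def test_dt_convergence(self, canonical_track, conical_field):
        """Endpoint displacement is Cauchy under dt halving."""
        from magchip.transport import run_track_simulation
        p = Particle(radius_um=2.75, chi_p=DEFAULT_CHI_P)
        ends = []
        for dt in (conical_field.period / 400, conical_field.period / 800):
            cfg = SimConfig(dt=dt, max_disp_um=0.15)
            traj = run_track_simulation(p, canonical_track, conical_field,
                                        n_periods=1, config=cfg)
            ends.append(traj.positions[-1])
        delta = np.linalg.norm(ends[0] - ends[1])
        travel = 45.0
        assert delta / travel < 0.01


def test_spine_progress_on_straight_line():
    spine = np.array([[0.0, 0.0], [100.0, 0.0]])
    pts = np.array([[0.0, 1.0], [45.0, -2.0], [90.0, 0.5]])
    s = spine_progress(pts, spine)
    assert s == pytest.approx([0.0, 45.0, 90.0])
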