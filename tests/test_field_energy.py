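import numpy as np
import pytest

from magchip.errors import (
    DegenerateNormalizationError,
    DomainError,
    EmptyPatternError,
    InvalidArgumentError,
)
from magchip.field_energy import (
    EnergyLandscape,
    ExternalField,
    FilmResponse,
    StrayFieldModel,
    count_local_minima,
    energy_landscape,
    energy_profile,
    external_field_at,
    film_magnetization,
    normalize_minmax,
    normalize_profiles,
    stray_field,
)
from magchip.geometry import MagnetPattern, make_disk_pattern
from magchip.units import UM, OE_TO_AM


class TestExternalField:
    def test_70_70_oe_at_t0(self):
        ext = ExternalField(70.0, 70.0, 0.5)
        h = external_field_at(ext, 0.0)
        # 70 Oe = 5570.4 A/m
        assert h == pytest.approx([5570.4, 0.0, 5570.4], rel=1e-4)

    def test_zero_inplane_is_constant_vertical(self):
        ext = ExternalField(0.0, 70.0, 1.0)
        for t in (0.0, 0.3, 0.77):
            assert external_field_at(ext, t) == pytest.approx(
                [0.0, 0.0, 70 * OE_TO_AM])

    def test_periodicity(self):
        ext = ExternalField(70.0, 70.0, 2.0, phase0=0.3)
        assert external_field_at(ext, 1 / 2.0) == pytest.approx(
            external_field_at(ext, 0.0))

    def test_sense_flips_y(self):
        t = 0.1
        hy_ccw = external_field_at(ExternalField(70, 0, 1.0, sense="ccw"), t)[1]
        hy_cw = external_field_at(ExternalField(70, 0, 1.0, sense="cw"), t)[1]
        assert hy_ccw == pytest.approx(-hy_cw)


class TestFilmMagnetization:
    def test_zero_field_zero_m(self, film):
        assert film_magnetization(film, np.zeros(3)) == pytest.approx([0, 0, 0])

    def test_inplane_saturates_along_drive(self, film):
        m = film_magnetization(film, np.array([5570.0, 0.0, 0.0]))
        assert m[0] == pytest.approx(film.Ms)
        assert m[1] == m[2] == 0.0

    def test_vertical_demag_suppression(self):
        film = FilmResponse(chi_film=1000.0, demag_vertical=1.0)
        m = film_magnetization(film, np.array([0.0, 0.0, 5570.0]))
        # chi/(1+chi) ~ 0.999
        assert m[2] == pytest.approx(5570.0 * 1000 / 1001, rel=1e-9)

    def test_small_field_direction(self, film):
        m = film_magnetization(film, np.array([0.1, 0.0, 0.0]))
        assert m[0] > 0 and m[1] == 0


class TestStrayField:
    def test_superposition_of_disjoint_polygons(self):
        tri1 = np.array([[0, 0], [5, 0], [0, 5]], float)
        tri2 = tri1 + np.array([20.0, 0.0])
        M = np.array([8.6e5, 1e5, 5570.0])
        pts = np.array([[10.0, 3.0, 2.5], [3.0, -4.0, 4.0]])
        both = stray_field(MagnetPattern([tri1, tri2]), M, pts)
        a = stray_field(MagnetPattern([tri1]), M, pts)
        b = stray_field(MagnetPattern([tri2]), M, pts)
        assert both == pytest.approx(a + b, rel=1e-12)

    def test_zero_magnetization(self, single_disk):
        pts = np.array([[25.0, 0.0, 3.0]])
        assert stray_field(single_disk, np.zeros(3), pts) == pytest.approx(
            np.zeros((1, 3)))

    def test_linearity_in_m(self, single_disk):
        pts = np.array([[22.0, 1.0, 3.0]])
        M = np.array([8.6e5, 0, 0])
        h1 = stray_field(single_disk, M, pts)
        h2 = stray_field(single_disk, 2 * M, pts)
        assert h2 == pytest.approx(2 * h1, rel=1e-12)

    def test_point_inside_film_rejected(self, single_disk):
        with pytest.raises(DomainError):
            stray_field(single_disk, np.array([8.6e5, 0, 0]),
                        np.array([[10.0, 0.0, 0.05]]))

    def test_matches_brute_force_quadrature(self):
        """Closed-form edge model vs direct surface-charge integration."""
        sq = np.array([[0, 0], [4, 0], [4, 4], [0, 4]], float)
        pat = MagnetPattern([sq], thickness=0.1)
        model = StrayFieldModel(pat)
        M = np.array([8.6e5, 2.0e5, 5570.0])
        pts = np.array([[6.0, 2.0, 2.5], [2.0, 2.0, 3.0], [-3.0, 5.0, 2.0]])
        Ha = model.field(pts, M)
        Hb = _brute_force_square(sq, M, pts)
        err = np.linalg.norm(Ha - Hb, axis=1) / np.linalg.norm(Hb, axis=1)
        assert np.all(err < 0.01)

    def test_far_field_dipole_decay(self):
        """Magnetized disk field decays as 1/r^3 in the far zone."""
        disk = make_disk_pattern(diameter=2.0, n_disks=1)
        model = StrayFieldModel(disk)
        M = np.array([8.6e5, 0.0, 0.0])
        r1, r2 = 25.0, 50.0  # >= 10 diameters
        h1 = np.linalg.norm(model.field(np.array([[1 + r1, 0, 2.0]]), M))
        h2 = np.linalg.norm(model.field(np.array([[1 + r2, 0, 2.0]]), M))
        ratio = h1 / h2
        assert ratio == pytest.approx((r2 / r1) ** 3, rel=0.05)


def _brute_force_square(sq, M, points_um, nsub=300, nz=12):
    t = 0.1 * UM
    P = np.atleast_2d(points_um) * UM
    H = np.zeros((len(P), 3))
    closed = np.vstack([sq, sq[:1]]) * UM
    for i in range(4):
        a, b = closed[i], closed[i + 1]
        L = np.linalg.norm(b - a)
        u = (b - a) / L
        n = np.array([u[1], -u[0]])
        sigma = M[0] * n[0] + M[1] * n[1]
        if sigma == 0:
            continue
        lf = (np.arange(nsub) + 0.5) / nsub
        zs = (np.arange(nz) + 0.5) / nz * t
        src_xy = a[None, :] + lf[:, None] * (b - a)[None, :]
        for z in zs:
            s3 = np.concatenate([src_xy, np.full((nsub, 1), z)], axis=1)
            d = P[:, None, :] - s3[None]
            r = np.linalg.norm(d, axis=2)[..., None]
            H += sigma * (L / nsub) * (t / nz) / (4 * np.pi) * (d / r**3).sum(axis=1)
    if M[2] != 0:
        side = sq[:, 0].max() - sq[:, 0].min()
        xs = ((np.arange(nsub) + 0.5) / nsub * side + sq[:, 0].min()) * UM
        da = (side * UM / nsub) ** 2
        XX, YY = np.meshgrid(xs, xs)
        for z0, sgn in ((t, +1), (0.0, -1)):
            src = np.stack([XX.ravel(), YY.ravel(), np.full(XX.size, z0)], axis=1)
            for k in range(0, len(src), 20000):
                d = P[:, None, :] - src[None, k:k + 20000, :]
                r = np.linalg.norm(d, axis=2)[..., None]
                H += sgn * M[2] * da / (4 * np.pi) * (d / r**3).sum(axis=1)
    return H


class TestEnergyLandscape:
    def test_two_pole_wells_in_plane_only(self, single_disk, film, fluid,
                                          inplane_field):
        ls = energy_landscape(single_disk, inplane_field, film, fluid,
                              65.4, 1.0, z=2.5, t=0.0, resolution=0.5)
        n = normalize_minmax(ls)
        assert count_local_minima(n, threshold=0.2) == 2

    def test_vertical_bias_kills_one_well(self, single_disk, film, fluid,
                                          conical_field):
        ls = energy_landscape(single_disk, conical_field, film, fluid,
                              65.4, 1.0, z=2.5, t=0.0, resolution=0.5)
        n = normalize_minmax(ls)
        assert count_local_minima(n, threshold=0.2) == 1

    def test_mirror_symmetry_about_field_axis(self, single_disk, film, fluid,
                                              conical_field):
        ls = energy_landscape(single_disk, conical_field, film, fluid,
                              65.4, 1.0, z=2.5, t=0.0, resolution=0.5)
        g = ls.grid
        ny = g.shape[0]
        # field along +x at t=0; the disk row is centred on y=0
        assert np.allclose(g[: ny // 2], g[-1: ny - ny // 2 - 1: -1], rtol=1e-6)

    def test_energy_scales_with_volume_and_contrast(self, single_disk, film,
                                                    fluid, conical_field):
        kw = dict(z=2.5, t=0.0, resolution=2.0)
        base = energy_landscape(single_disk, conical_field, film, fluid,
                                100.0, 1.0, **kw).grid
        doubled_v = energy_landscape(single_disk, conical_field, film, fluid,
                                     200.0, 1.0, **kw).grid
        doubled_chi = energy_landscape(single_disk, conical_field, film, fluid,
                                       100.0, 2.0, **kw).grid
        assert doubled_v == pytest.approx(2 * base, rel=1e-12)
        assert doubled_chi == pytest.approx(2 * base, rel=1e-12)

    def test_empty_pattern_rejected(self, film, fluid, conical_field):
        with pytest.raises(EmptyPatternError):
            energy_landscape(None, conical_field, film, fluid, 65.0, 1.0,
                             z=2.5, t=0.0)


class TestNormalization:
    def test_minmax_range(self):
        g = np.array([[1.0, 3.0], [2.0, 5.0]])
        ls = EnergyLandscape(grid=g, xs=np.array([0, 1.]),
                             ys=np.array([0, 1.]), z=1.0, t=0.0)
        n = normalize_minmax(ls)
        assert n.grid.min() == 0.0 and n.grid.max() == 1.0

    def test_affine_invariance(self):
        g = np.random.default_rng(0).normal(size=(8, 8))
        a = normalize_minmax(EnergyLandscape(g, np.arange(8.), np.arange(8.),
                                             1.0, 0.0))
        b = normalize_minmax(EnergyLandscape(3.0 * g - 7.0, np.arange(8.),
                                             np.arange(8.), 1.0, 0.0))
        assert b.grid == pytest.approx(a.grid, rel=1e-12)

    def test_constant_rejected(self):
        ls = EnergyLandscape(np.ones((4, 4)), np.arange(4.), np.arange(4.),
                             1.0, 0.0)
        with pytest.raises(DegenerateNormalizationError):
            normalize_minmax(ls)


class TestEnergyProfile:
    def test_arclength_increasing_and_sampling(self, single_disk, film, fluid,
                                               conical_field):
        path = np.array([[22.0, 0.0], [40.0, 0.0]])
        prof = energy_profile(single_disk, conical_field, film, fluid,
                              65.4, 1.0, path, z=2.5, t=0.0)
        assert len(prof.arclength) >= 100
        assert np.all(np.diff(prof.arclength) > 0)

    def test_joint_normalization_spans_unit_interval(self, single_disk, film,
                                                     fluid, conical_field):
        p1 = energy_profile(single_disk, conical_field, film, fluid, 65.4, 1.0,
                            np.array([[22.0, 0.0], [35.0, 0.0]]), 2.5, 0.0)
        p2 = energy_profile(single_disk, conical_field, film, fluid, 65.4, 1.0,
                            np.array([[22.0, 0.0], [22.0, 15.0]]), 2.5, 0.0)
        n1, n2 = normalize_profiles([p1, p2])
        allv = np.concatenate([n1.energy, n2.energy])
        assert allv.min() == pytest.approx(0.0)
        assert allv.max() == pytest.approx(1.0)

    def test_short_path_rejected(self, single_disk, film, fluid, conical_field):
        with pytest.raises(InvalidArgumentError):
            energy_profile(single_disk, conical_field, film, fluid, 65.4, 1.0,
                           np.array([[0.0, 0.0]]), 2.5, 0.0)
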