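"""Field and energy landscape of a patterned soft-magnetic film.

Model
-----
The drive is a rotating *conical* field: an in-plane component of amplitude
``H_inplane`` rotating at frequency ``f`` plus a static vertical bias
``H_vertical``.  The 100-nm permalloy film is soft: its in-plane
magnetization follows the in-plane drive direction and saturates at ``Ms``;
the out-of-plane response is suppressed by the thin-film demagnetizing
factor (~1), leaving ``M_z`` close to the applied ``H_z``.

The stray field of each uniformly magnetized thin polygon is computed
analytically in the thin-film limit:

* in-plane magnetization -> magnetic surface charge on the side walls,
  collapsed to *line charges* ``lambda = (M . n) * thickness`` on the
  polygon edges (closed-form field of a finite uniformly charged segment);
* perpendicular magnetization -> a uniform dipole sheet of moment density
  ``M_z * thickness``, equivalent by Ampere's theorem to a current loop
  ``I = M_z * thickness`` around the polygon boundary (closed-form
  Biot-Savart field of finite straight segments).

A bead of volume ``V_p`` and susceptibility ``chi_p`` in a fluid of
susceptibility ``chi_f`` has dipolar energy

    U(r) = -1/2 * mu0 * V_p * (chi_p - chi_f) * |H(r)|^2

so beads with ``chi_p > chi_f`` are attracted to field maxima ("energy
wells" at the magnet poles).  The sign convention is chosen so that energy
minima coincide with the regions the beads demonstrably collect in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateNormalizationError,
    DomainError,
    EmptyPatternError,
    InvalidArgumentError,
    InvalidSpecError,
)
from .geometry import MagnetPattern
from .units import MU0, UM, oe_to_am

_TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExternalField:
    """Rotating conical drive field.

    At time ``t`` the external field (A/m) is::

        ( H_ip * cos(2 pi f t + phase0),
          s * H_ip * sin(2 pi f t + phase0),
          H_v )

    with ``s = +1`` for counter-clockwise rotation and ``-1`` for clockwise.
    Amplitudes are given in oersted, as on the bench.
    """

    h_inplane_oe: float = 70.0
    h_vertical_oe: float = 70.0
    frequency_hz: float = 0.2
    phase0: float = 0.0
    sense: str = "ccw"

    def __post_init__(self):
        if self.h_inplane_oe < 0 or self.h_vertical_oe < 0:
            raise InvalidSpecError("field amplitudes must be >= 0")
        if self.frequency_hz < 0:
            raise InvalidSpecError("frequency must be >= 0")
        if self.sense not in ("cw", "ccw"):
            raise InvalidSpecError("sense must be 'cw' or 'ccw'")

    @property
    def period(self) -> float:
        if self.frequency_hz == 0:
            return np.inf
        return 1.0 / self.frequency_hz

    def with_frequency(self, f_hz: float) -> "ExternalField":
        return ExternalField(self.h_inplane_oe, self.h_vertical_oe, f_hz,
                             self.phase0, self.sense)

    def phase_at(self, t: float) -> float:
        s = 1.0 if self.sense == "ccw" else -1.0
        return s * (_TWO_PI * self.frequency_hz * t + self.phase0)


@dataclass(frozen=True)
class FilmResponse:
    """Linear-with-saturation response of the soft permalloy film."""

    chi_film: float = 1000.0
    Ms: float = 8.6e5          # A/m, permalloy 80
    demag_inplane: float = 0.0
    demag_vertical: float = 1.0

    def __post_init__(self):
        if self.chi_film <= 0:
            raise InvalidSpecError("chi_film must be positive")
        for d in (self.demag_inplane, self.demag_vertical):
            if not (0.0 <= d <= 1.0):
                raise InvalidSpecError("demag factors must lie in [0, 1]")


@dataclass(frozen=True)
class FluidEnv:
    """Aqueous environment of the beads."""

    eta_f: float = 1.0e-3      # Pa s
    chi_f: float = 0.0

    def __post_init__(self):
        if self.eta_f <= 0:
            raise InvalidSpecError("viscosity must be positive")


@dataclass
class EnergyLandscape:
    """Dipolar potential energy on a horizontal grid at height ``z``."""

    grid: np.ndarray           # (ny, nx), J (or normalized)
    xs: np.ndarray             # (nx,), um
    ys: np.ndarray             # (ny,), um
    z: float                   # um
    t: float                   # s
    normalized: bool = False

    @property
    def extent(self):
        return self.xs[0], self.ys[0], self.xs[-1], self.ys[-1]


@dataclass
class EnergyProfile:
    """Energy sampled along a path."""

    arclength: np.ndarray      # um, strictly increasing
    energy: np.ndarray         # J or normalized
    points: np.ndarray         # (n, 2) um
    labels: tuple = ("p", "q")
    normalized: bool = False


# ---------------------------------------------------------------------------
# external field & film response
# ---------------------------------------------------------------------------

def external_field_at(ext: ExternalField, t: float) -> np.ndarray:
    """External drive field vector (A/m) at time ``t``."""
    if t < 0:
        raise InvalidArgumentError("t must be >= 0")
    hin = oe_to_am(ext.h_inplane_oe)
    hv = oe_to_am(ext.h_vertical_oe)
    ph = ext.phase_at(t)
    return np.array([hin * np.cos(ph), hin * np.sin(ph), hv])


def film_magnetization(film: FilmResponse, h_ext: np.ndarray) -> np.ndarray:
    """Film magnetization (A/m) under an external field vector.

    In-plane: along the in-plane drive, linear with slope ``chi_film`` until
    it saturates at ``Ms`` (with chi ~ 1000 and 70 Oe drive the film is
    always saturated in-plane).  Vertical: demag-suppressed,
    ``M_z = chi/(1 + chi*Nz) * H_z ~ H_z``.
    """
    h_ext = np.asarray(h_ext, dtype=float)
    if not np.all(np.isfinite(h_ext)):
        raise InvalidArgumentError("external field must be finite")
    h_ip = h_ext[:2]
    mag_ip = np.hypot(*h_ip)
    m = np.zeros(3)
    if mag_ip > 0:
        chi_eff = film.chi_film / (1.0 + film.chi_film * film.demag_inplane)
        m_mag = min(chi_eff * mag_ip, film.Ms)
        m[:2] = m_mag * h_ip / mag_ip
    m[2] = film.chi_film / (1.0 + film.chi_film * film.demag_vertical) * h_ext[2]
    return m


# ---------------------------------------------------------------------------
# stray field
# ---------------------------------------------------------------------------

class StrayFieldModel:
    """Precomputed edge representation of a pattern's stray field.

    The field is linear in the film magnetization, so it is assembled from
    per-edge closed forms at call time; edges are vectorized with numpy.
    """

    def __init__(self, pattern: MagnetPattern):
        if not pattern.polygons:
            raise EmptyPatternError("pattern has no polygons")
        A, B, poly_id = [], [], []
        for ip, poly in enumerate(pattern.polygons):
            closed = np.vstack([poly, poly[:1]])
            A.append(closed[:-1])
            B.append(closed[1:])
            poly_id.append(np.full(len(poly), ip))
        self.A = np.vstack(A) * UM          # (n, 2), m
        self.B = np.vstack(B) * UM
        self.poly_id = np.concatenate(poly_id)
        seg = self.B - self.A
        self.L = np.hypot(seg[:, 0], seg[:, 1])
        keep = self.L > 1e-15
        self.A, self.B, self.L = self.A[keep], self.B[keep], self.L[keep]
        self.poly_id = self.poly_id[keep]
        self.u = (self.B - self.A) / self.L[:, None]    # unit tangent (CCW)
        # outward normal of a CCW loop is the right-hand normal of the tangent
        self.n_out = np.stack([self.u[:, 1], -self.u[:, 0]], axis=1)
        self.thickness_m = pattern.thickness * UM
        self.z_top = pattern.thickness  # um, top surface of the film

    def field(self, points_um: np.ndarray, m_film: np.ndarray,
              check_domain: bool = True, chunk: int = 4096) -> np.ndarray:
        """Stray field (A/m) at ``points_um`` for film magnetization ``m_film``.

        ``points_um``: (m, 3) positions in um.  Points must lie outside the
        film volume (above the film plane).
        """
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        if pts.shape[1] != 3:
            raise InvalidArgumentError("points must be (m, 3)")
        if check_domain and np.any(pts[:, 2] <= self.z_top):
            raise DomainError(
                "field evaluation requires z above the film top surface")
        out = np.empty((len(pts), 3))
        for s in range(0, len(pts), chunk):
            out[s:s + chunk] = self._field_block(pts[s:s + chunk] * UM, m_film)
        return out

    def _field_block(self, P: np.ndarray, m_film: np.ndarray) -> np.ndarray:
        # P: (m, 3) in metres; charges/loops live on the film mid-plane z = t/2
        zmid = np.full((len(self.A), 1), self.thickness_m / 2.0)
        A3 = np.concatenate([self.A, zmid], axis=1)
        u3 = np.concatenate([self.u, np.zeros((len(self.u), 1))], axis=1)
        d = P[:, None, :] - A3[None, :, :]          # (m, n, 3)
        xi = np.einsum("mnk,nk->mn", d, u3)         # projection along edge
        a = -xi
        b = self.L[None, :] - xi
        rho = d - xi[..., None] * u3[None, :, :]    # perpendicular vector
        rho2 = np.einsum("mnk,mnk->mn", rho, rho) + 1e-30
        rA = np.sqrt(rho2 + a * a)
        rB = np.sqrt(rho2 + b * b)
        s = (b / rB - a / rA) / rho2                # (m, n)
        ax = (1.0 / rB - 1.0 / rA)

        # edge line charges from in-plane magnetization
        lam = self.thickness_m * (self.n_out @ m_film[:2])     # (n,)
        e_field = ax[..., None] * u3[None, :, :] + s[..., None] * rho
        H = np.einsum("n,mnk->mk", lam / (4.0 * np.pi), e_field)

        # Ampere loop for the perpendicular dipole sheet
        mz = m_film[2]
        if mz != 0.0:
            I = mz * self.thickness_m
            cross = np.cross(np.broadcast_to(u3[None, :, :], rho.shape), rho)
            H += I / (4.0 * np.pi) * np.einsum("mn,mnk->mk", s, cross)
        return H


def stray_field(pattern: MagnetPattern, m_film: np.ndarray,
                points_um: np.ndarray) -> np.ndarray:
    """Stray field (A/m) of ``pattern`` magnetized uniformly at ``m_film``."""
    return StrayFieldModel(pattern).field(points_um, np.asarray(m_film, float))


class FieldModel:
    """Total field H(r, t) = external + stray for a pattern under drive."""

    def __init__(self, pattern: MagnetPattern | None, ext: ExternalField,
                 film: FilmResponse | None = None):
        self.ext = ext
        self.film = film or FilmResponse()
        self.stray = StrayFieldModel(pattern) if pattern is not None and pattern.polygons else None

    def total(self, points_um: np.ndarray, t: float) -> np.ndarray:
        h_ext = external_field_at(self.ext, t)
        pts = np.atleast_2d(points_um)
        H = np.broadcast_to(h_ext, (len(pts), 3)).copy()
        if self.stray is not None:
            m = film_magnetization(self.film, h_ext)
            H += self.stray.field(pts, m)
        return H

    def intensity_sq(self, points_um: np.ndarray, t: float) -> np.ndarray:
        H = self.total(points_um, t)
        return np.einsum("mk,mk->m", H, H)


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------

def energy_prefactor(particle_volume_um3: float, chi_p: float,
                     chi_f: float = 0.0) -> float:
    """-1/2 mu0 V_p (chi_p - chi_f), in J per (A/m)^2."""
    return -0.5 * MU0 * particle_volume_um3 * UM**3 * (chi_p - chi_f)


def energy_landscape(pattern: MagnetPattern | None, ext: ExternalField,
                     film: FilmResponse, fluid: FluidEnv,
                     particle_volume_um3: float, chi_p: float,
                     z: float, t: float, resolution: float = 0.2,
                     pad: float = 10.0,
                     bounds=None) -> EnergyLandscape:
    """Dipolar energy U(x, y) on a uniform grid at height ``z``.

    ``bounds`` optionally overrides the padded pattern bounding box with
    ``(xmin, ymin, xmax, ymax)``.
    """
    if z <= 0:
        raise InvalidArgumentError("z must be positive")
    if resolution <= 0:
        raise InvalidArgumentError("resolution must be positive")
    if pattern is None or not pattern.polygons:
        raise EmptyPatternError("energy_landscape needs a non-empty pattern")
    if bounds is None:
        xmin, ymin, xmax, ymax = pattern.bounding_box(pad=pad)
    else:
        xmin, ymin, xmax, ymax = bounds
    xs = np.arange(xmin, xmax + resolution / 2, resolution)
    ys = np.arange(ymin, ymax + resolution / 2, resolution)
    XX, YY = np.meshgrid(xs, ys)
    pts = np.stack([XX.ravel(), YY.ravel(), np.full(XX.size, z)], axis=1)
    model = FieldModel(pattern, ext, film)
    h2 = model.intensity_sq(pts, t)
    pref = energy_prefactor(particle_volume_um3, chi_p, fluid.chi_f)
    return EnergyLandscape(grid=(pref * h2).reshape(XX.shape),
                           xs=xs, ys=ys, z=z, t=t)


def normalize_minmax(landscape: EnergyLandscape) -> EnergyLandscape:
    """Min-max normalize the landscape to [0, 1]."""
    g = landscape.grid
    lo, hi = float(np.min(g)), float(np.max(g))
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise InvalidArgumentError("landscape contains non-finite values")
    if hi == lo:
        raise DegenerateNormalizationError(
            "constant landscape cannot be min-max normalized")
    return EnergyLandscape(grid=(g - lo) / (hi - lo), xs=landscape.xs,
                           ys=landscape.ys, z=landscape.z, t=landscape.t,
                           normalized=True)


def energy_profile(pattern: MagnetPattern, ext: ExternalField,
                   film: FilmResponse, fluid: FluidEnv,
                   particle_volume_um3: float, chi_p: float,
                   path: np.ndarray, z: float, t: float,
                   samples_per_segment: int = 120,
                   labels=("p", "q")) -> EnergyProfile:
    """Energy sampled densely along a polyline path at height ``z``."""
    path = np.atleast_2d(np.asarray(path, dtype=float))
    if len(path) < 2:
        raise InvalidArgumentError("path needs at least 2 points")
    pts, arcs = [], []
    s0 = 0.0
    for i in range(len(path) - 1):
        a, b = path[i], path[i + 1]
        seglen = float(np.hypot(*(b - a)))
        frac = np.linspace(0.0, 1.0, samples_per_segment, endpoint=(i == len(path) - 2))
        pts.append(a + frac[:, None] * (b - a))
        arcs.append(s0 + frac * seglen)
        s0 += seglen
    P = np.vstack(pts)
    s = np.concatenate(arcs)
    model = FieldModel(pattern, ext, film)
    p3 = np.concatenate([P, np.full((len(P), 1), z)], axis=1)
    h2 = model.intensity_sq(p3, t)
    pref = energy_prefactor(particle_volume_um3, chi_p, fluid.chi_f)
    return EnergyProfile(arclength=s, energy=pref * h2, points=P, labels=labels)


def normalize_profiles(profiles):
    """Jointly min-max normalize profiles using their combined min and max.

    This mirrors the comparison convention for forward/backward bend paths:
    both are scaled with the minimum and maximum over the *union* of paths.
    """
    allvals = np.concatenate([p.energy for p in profiles])
    lo, hi = float(allvals.min()), float(allvals.max())
    if hi == lo:
        raise DegenerateNormalizationError("profiles are jointly constant")
    return [EnergyProfile(arclength=p.arclength,
                          energy=(p.energy - lo) / (hi - lo),
                          points=p.points, labels=p.labels, normalized=True)
            for p in profiles]


def count_local_minima(landscape: EnergyLandscape, threshold: float = 0.2,
                       min_distance_px: int = 3) -> int:
    """Count spatially distinct local minima below ``threshold``.

    Expects a normalized landscape.  Minima closer than ``min_distance_px``
    grid cells are merged (the deep wells at a magnet pole span several
    cells at the default 0.2-um resolution).
    """
    g = landscape.grid
    low = g < threshold
    if not low.any():
        return 0
    # connected low-energy basins, each counted once
    lab, n = ndimage.label(low)
    return int(n)
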