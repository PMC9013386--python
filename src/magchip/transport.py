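"""Overdamped bead transport in the rotating energy landscape.

A bead is a superparamagnetic sphere of radius ``R_p`` and susceptibility
``chi_p`` moving in water at its flight plane ``z = R_p + clearance`` above
the film.  Inertia is negligible at these scales, so the velocity follows
the force instantaneously through Stokes drag::

    v = F / (6 pi eta_f R_p)

and positions advance by a forward difference ``r_i = r_{i-1} + v_{i-1} dt``.
Forces are (a) the landscape force ``F = -grad U`` evaluated by central
finite differences of the dipolar energy and (b) pairwise point-dipole
forces between beads, with each bead's moment set by the external drive
field (``m = 4 pi R_p^3 chi_p H / 3``).  Friction and Brownian motion are
neglected by default; optional thermal kicks (Stokes-Einstein diffusivity)
are used by the pair-encounter Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    NoTransportError,
    NumericalFailureError,
    SingularSeparationError,
)
from .field_energy import (
    ExternalField,
    FieldModel,
    FilmResponse,
    FluidEnv,
    energy_prefactor,
    external_field_at,
)
from .geometry import MagnetPattern
from .units import KB, MU0, UM

#: default clearance between bead surface and the chip's non-fouling layer, um
DEFAULT_CLEARANCE = 0.5

#: default bead susceptibility calibration (see docs/methods.md)
DEFAULT_CHI_P = 0.2

#: susceptibility scale factor for the large (8-9.9 um) bead set
LARGE_BEAD_CHI_SCALE = 1.2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Particle:
    """A superparamagnetic bead."""

    radius_um: float
    chi_p: float = DEFAULT_CHI_P
    position: np.ndarray = None
    id: int = 0

    def __post_init__(self):
        if self.radius_um <= 0:
            raise InvalidArgumentError("particle radius must be positive")
        if self.position is None:
            self.position = np.array([0.0, 0.0, self.radius_um + DEFAULT_CLEARANCE])
        self.position = np.asarray(self.position, dtype=float)

    @property
    def volume_um3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius_um**3

    @property
    def flight_height(self) -> float:
        """Bead-centre plane above the substrate, um."""
        return self.radius_um + DEFAULT_CLEARANCE


@dataclass
class Trajectory:
    """Time-stamped positions of one bead."""

    times: np.ndarray          # (n,), s
    positions: np.ndarray      # (n, 3), um
    dt: float
    particle: Particle = None
    flags: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.positions)):
            raise NumericalFailureError("trajectory contains non-finite positions")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class SimConfig:
    """Integrator settings.

    ``dt`` defaults to field period / 400; the invariant ``dt <= period/200``
    guarantees the rotating landscape is resolved.  ``max_disp_um`` caps the
    per-substep displacement: where the local force is strong the base step
    is subdivided so the forward-difference scheme stays stable.
    """

    dt: float | None = None
    duration: float | None = None
    gradient_step_um: float = 0.05
    max_disp_um: float = 0.25
    contact_gap_um: float = 0.1
    thermal: bool = False
    temperature_K: float = 298.0
    seed: int = 0
    record_every: int = 1

    def resolve_dt(self, ext: ExternalField) -> float:
        period = ext.period
        if self.dt is not None:
            if self.dt <= 0:
                raise InvalidArgumentError("dt must be positive")
            if np.isfinite(period) and self.dt > period / 200.0:
                raise InvalidArgumentError("dt must be <= field period / 200")
            return self.dt
        if not np.isfinite(period):
            return 1e-2
        return period / 400.0


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def drag_velocity(force_N, radius_um: float, eta_f: float):
    """Stokes velocity (um/s) of a sphere under ``force_N`` (componentwise)."""
    if radius_um <= 0 or eta_f <= 0:
        raise InvalidArgumentError("radius and viscosity must be positive")
    force_N = np.asarray(force_N, dtype=float)
    v_ms = force_N / (6.0 * math.pi * eta_f * radius_um * UM)
    return v_ms / UM * 1.0  # m/s -> um/s


def magnetic_force(energy_fn, position_um, step_um: float = 0.05) -> np.ndarray:
    """F = -grad U (N) by central finite differences in the x-y plane.

    ``energy_fn(points)`` maps (m, 3) um positions to energies in J.
    Motion is confined to the flight plane, so only the in-plane gradient
    is evaluated.
    """
    p = np.asarray(position_um, dtype=float)
    pts = np.stack([
        p + [step_um, 0, 0], p - [step_um, 0, 0],
        p + [0, step_um, 0], p - [0, step_um, 0],
    ])
    u = np.asarray(energy_fn(pts), dtype=float)
    if not np.all(np.isfinite(u)):
        raise NumericalFailureError(f"non-finite energy near {p}")
    gx = (u[0] - u[1]) / (2.0 * step_um * UM)
    gy = (u[2] - u[3]) / (2.0 * step_um * UM)
    return np.array([-gx, -gy, 0.0])


def dipole_moment(particle: Particle, h_field: np.ndarray) -> np.ndarray:
    """Point-dipole moment m = 4 pi R_p^3 chi_p H / 3 (A m^2)."""
    r_m = particle.radius_um * UM
    return 4.0 * math.pi * r_m**3 * particle.chi_p * np.asarray(h_field) / 3.0


def dipole_pair_force(m1: np.ndarray, m2: np.ndarray,
                      r_vec_um: np.ndarray) -> np.ndarray:
    """Force (N) on dipole 1 from dipole 2 separated by ``r = r1 - r2`` (um).

    Standard point-dipole interaction force; equal and opposite acts on 2.
    """
    r = np.asarray(r_vec_um, dtype=float) * UM
    d2 = float(r @ r)
    if d2 == 0.0:
        raise SingularSeparationError("coincident dipoles")
    d = math.sqrt(d2)
    m1 = np.asarray(m1, float)
    m2 = np.asarray(m2, float)
    m1r = float(m1 @ r)
    m2r = float(m2 @ r)
    m1m2 = float(m1 @ m2)
    pref = 3.0 * MU0 / (4.0 * math.pi * d**5)
    return pref * (m1r * m2 + m2r * m1 + m1m2 * r - 5.0 * m1r * m2r * r / d2)


def pair_forces(positions_um: np.ndarray, moments: np.ndarray) -> np.ndarray:
    """Total dipolar force (N) on each bead from all others.

    ``positions_um``: (n, 3); ``moments``: (n, 3) A m^2.
    """
    n = len(positions_um)
    if n < 2:
        return np.zeros((n, 3))
    r = (positions_um[:, None, :] - positions_um[None, :, :]) * UM   # (n, n, 3)
    d2 = np.einsum("ijk,ijk->ij", r, r)
    np.fill_diagonal(d2, 1.0)
    d5 = d2**2.5
    mir = np.einsum("ik,ijk->ij", moments, r)          # m_i . r_ij
    mjr = np.einsum("jk,ijk->ij", moments, r)          # m_j . r_ij
    mimj = moments @ moments.T
    coef = (3.0 * MU0 / (4.0 * math.pi)) / d5
    np.fill_diagonal(coef, 0.0)
    f = coef[..., None] * (
        mir[..., None] * moments[None, :, :]
        + mjr[..., None] * moments[:, None, :]
        + (mimj - 5.0 * mir * mjr / d2)[..., None] * r
    )
    return f.sum(axis=1)


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

class LandscapeEnergy:
    """U(points, t) for one bead species above a pattern."""

    def __init__(self, pattern: MagnetPattern | None, ext: ExternalField,
                 film: FilmResponse, fluid: FluidEnv, particle: Particle):
        self.model = FieldModel(pattern, ext, film) if pattern is not None else None
        self.pref = energy_prefactor(particle.volume_um3, particle.chi_p,
                                     fluid.chi_f)

    def __call__(self, points_um: np.ndarray, t: float) -> np.ndarray:
        if self.model is None:
            return np.zeros(len(np.atleast_2d(points_um)))
        return self.pref * self.model.intensity_sq(points_um, t)


_TRIU_CACHE: dict = {}


def _triu_cache(n: int):
    if n not in _TRIU_CACHE:
        _TRIU_CACHE[n] = np.triu_indices(n, k=1)
    return _TRIU_CACHE[n]


def _resolve_overlaps(pos: np.ndarray, radii: np.ndarray, iters: int = 10):
    """Minimal symmetric projection of hard-sphere overlaps (in-plane).

    Jacobi-style iteration: all pairwise half-corrections are accumulated
    and applied at once, repeated until no overlap remains.
    """
    n = len(pos)
    if n < 2:
        return pos
    iu, ju = _triu_cache(n)
    rsum = radii[iu] + radii[ju]
    for _ in range(iters):
        d = pos[ju] - pos[iu]
        d[:, 2] = 0.0
        dist = np.sqrt(np.einsum("kj,kj->k", d, d))
        bad = dist < rsum - 5e-3
        if not bad.any():
            break
        db = d[bad]
        distb = np.maximum(dist[bad], 1e-12)
        push = (rsum[bad] - distb) / 2.0
        shift = db / distb[:, None] * push[:, None]
        corr = np.zeros_like(pos)
        np.add.at(corr, iu[bad], -shift)
        np.add.at(corr, ju[bad], shift)
        pos = pos + corr
    return pos


def step(positions_um: np.ndarray, t: float, dt: float,
         particles: list, energies: list, ext: ExternalField,
         fluid: FluidEnv, config: SimConfig,
         rng: np.random.Generator | None = None,
         box=None, include_pair_forces: bool = True):
    """Advance all beads by one base step ``dt`` (with adaptive substeps).

    Returns the new positions (um).  Motion is confined to each bead's
    flight plane; hard-sphere overlaps are resolved by minimal symmetric
    projection.
    """
    pos = positions_um.copy()
    radii = np.array([p.radius_um for p in particles])
    etaf = fluid.eta_f
    remaining = dt
    while remaining > 1e-15:
        F = np.zeros((len(particles), 3))
        for i, (p, en) in enumerate(zip(particles, energies)):
            if en is not None and en.model is not None:
                F[i] = magnetic_force(lambda q, en=en: en(q, t), pos[i],
                                      config.gradient_step_um)
        if include_pair_forces and len(particles) > 1:
            h_ext = external_field_at(ext, t)
            chi_r3 = np.array([p.chi_p * (p.radius_um * UM) ** 3
                               for p in particles])
            moments = (4.0 * math.pi / 3.0) * chi_r3[:, None] * h_ext[None, :]
            F += pair_forces(pos, moments)
        if not np.all(np.isfinite(F)):
            raise NumericalFailureError(f"non-finite force at t={t:.4g}s")
        v = F / (6.0 * math.pi * etaf * radii[:, None] * UM) / UM   # um/s
        v[:, 2] = 0.0
        vmax = float(np.max(np.abs(v))) if v.size else 0.0
        dt_sub = remaining if vmax * remaining <= config.max_disp_um \
            else config.max_disp_um / vmax
        pos = pos + v * dt_sub
        if config.thermal and rng is not None:
            D = KB * config.temperature_K / (6.0 * math.pi * etaf * radii * UM)
            sig = np.sqrt(2.0 * D * dt_sub) / UM              # um
            kick = rng.normal(size=(len(particles), 3)) * sig[:, None]
            kick[:, 2] = 0.0
            pos = pos + kick
        pos = _resolve_overlaps(pos, radii)
        if box is not None:
            xmin, ymin, xmax, ymax = box
            pos[:, 0] = np.clip(pos[:, 0], xmin + radii, xmax - radii)
            pos[:, 1] = np.clip(pos[:, 1], ymin + radii, ymax - radii)
        t += dt_sub
        remaining -= dt_sub
    return pos


def simulate(particles, pattern: MagnetPattern | None, ext: ExternalField,
             config: SimConfig, film: FilmResponse | None = None,
             fluid: FluidEnv | None = None, box=None,
             include_pair_forces: bool = True):
    """Integrate all beads for ``config.duration`` seconds.

    Returns a list of :class:`Trajectory`, one per bead, sampled at the base
    time step.  Deterministic for a fixed seed and config.
    """
    film = film or FilmResponse()
    fluid = fluid or FluidEnv()
    if config.duration is None or config.duration <= 0:
        raise InvalidArgumentError("config.duration must be set and positive")
    dt = config.resolve_dt(ext)
    n_steps = int(round(config.duration / dt))
    rng = np.random.default_rng(config.seed) if config.thermal else None
    energies = [LandscapeEnergy(pattern, ext, film, fluid, p)
                if pattern is not None else None for p in particles]
    pos = np.stack([np.asarray(p.position, dtype=float) for p in particles])
    times = [0.0]
    hist = [pos.copy()]
    t = 0.0
    for k in range(n_steps):
        pos = step(pos, t, dt, particles, energies, ext, fluid, config,
                   rng=rng, box=box, include_pair_forces=include_pair_forces)
        t = (k + 1) * dt
        if (k + 1) % config.record_every == 0 or k == n_steps - 1:
            times.append(t)
            hist.append(pos.copy())
    H = np.stack(hist)  # (n_rec, n_particles, 3)
    return [Trajectory(times=np.asarray(times), positions=H[:, i, :], dt=dt,
                       particle=particles[i]) for i in range(len(particles))]


# ---------------------------------------------------------------------------
# path progress, speed, critical frequency
# ---------------------------------------------------------------------------

def spine_progress(points_xy: np.ndarray, spine: np.ndarray) -> np.ndarray:
    """Arclength coordinate of the closest spine point for each position."""
    spine = np.asarray(spine, dtype=float)
    seg_a = spine[:-1]
    seg_v = spine[1:] - spine[:-1]
    seg_len = np.hypot(seg_v[:, 0], seg_v[:, 1])
    seg_cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    P = np.atleast_2d(points_xy)[:, :2]
    d = P[:, None, :] - seg_a[None, :, :]
    tpar = np.einsum("mnk,nk->mn", d, seg_v) / np.maximum(seg_len**2, 1e-30)
    tpar = np.clip(tpar, 0.0, 1.0)
    proj = seg_a[None] + tpar[..., None] * seg_v[None]
    dist = np.linalg.norm(P[:, None, :] - proj, axis=2)
    best = np.argmin(dist, axis=1)
    return seg_cum[best] + tpar[np.arange(len(P)), best] * seg_len[best]


def mean_speed(traj: Trajectory, pattern: MagnetPattern,
               ext: ExternalField, min_periods: int = 1,
               skip_periods: int = 0) -> float:
    """Path-progress speed (um/s) averaged over an integer number of periods.

    ``skip_periods`` discards the seeding transient (the bead settles into
    phase lock within the first rotation) before averaging.
    """
    period = ext.period
    if not np.isfinite(period):
        raise InsufficientDataError("field frequency must be positive")
    n_periods = int(np.floor(traj.duration / period + 1e-9)) - skip_periods
    if n_periods < min_periods:
        raise InsufficientDataError(
            f"trajectory spans {traj.duration:.3g}s < "
            f"{min_periods + skip_periods} period(s)")
    spine = pattern.spine if pattern is not None and pattern.spine is not None \
        else np.array([[0.0, 0.0], [1.0, 0.0]])
    t0 = skip_periods * period
    t_end = (skip_periods + n_periods) * period
    i0 = min(int(np.searchsorted(traj.times, t0 - 1e-9)), len(traj.times) - 1)
    idx = min(int(np.searchsorted(traj.times, t_end - 1e-9)), len(traj.times) - 1)
    s = spine_progress(traj.positions[[i0, idx], :2], spine)
    return float((s[1] - s[0]) / (traj.times[idx] - traj.times[i0]))


def pole_seed_position(pattern: MagnetPattern, ext: ExternalField,
                       film: FilmResponse, fluid: FluidEnv,
                       particle: Particle, magnet_index: int = 0,
                       t: float = 0.0, clearance: float = 0.3) -> np.ndarray:
    """Energy-minimum seed point for a bead near one magnet at time ``t``.

    Samples the energy on the magnet outline offset outward by
    ``clearance`` um and returns the minimizing point at the flight height.
    """
    poly = pattern.polygons[magnet_index]
    c = poly.mean(axis=0)
    out = poly - c
    norm = np.linalg.norm(out, axis=1, keepdims=True)
    ring = poly + out / np.maximum(norm, 1e-12) * clearance
    z = particle.flight_height
    pts = np.concatenate([ring, np.full((len(ring), 1), z)], axis=1)
    en = LandscapeEnergy(pattern, ext, film, fluid, particle)
    u = en(pts, t)
    return pts[int(np.argmin(u))]


def run_track_simulation(particle: Particle, pattern: MagnetPattern,
                         ext: ExternalField, n_periods: int = 5,
                         film: FilmResponse | None = None,
                         fluid: FluidEnv | None = None,
                         config: SimConfig | None = None,
                         settle_periods: float = 0.0) -> Trajectory:
    """Seed a bead at the first magnet's pole and run ``n_periods`` rotations."""
    film = film or FilmResponse()
    fluid = fluid or FluidEnv()
    p0 = pole_seed_position(pattern, ext, film, fluid, particle)
    particle = replace(particle, position=p0)
    base = config or SimConfig()
    cfg = replace(base, duration=(n_periods + settle_periods) * ext.period)
    return simulate([particle], pattern, ext, cfg, film=film, fluid=fluid)[0]


def critical_frequency(particle: Particle, pattern: MagnetPattern,
                       ext_template: ExternalField, f_grid,
                       n_periods: int = 5,
                       film: FilmResponse | None = None,
                       fluid: FluidEnv | None = None,
                       config: SimConfig | None = None):
    """Frequency of maximal mean speed over an ascending frequency grid.

    Returns ``(f_peak_hz, table)`` where ``table`` is a DataFrame with
    columns ``frequency_hz`` and ``mean_speed_um_s``.  Below the critical
    frequency the bead is phase-locked and speed grows as ``lambda * f``;
    above it the bead slips and the speed drops, so the grid maximum sits
    at the critical frequency.
    """
    f_grid = np.asarray(list(f_grid), dtype=float)
    if len(f_grid) < 3 or np.any(np.diff(f_grid) <= 0):
        raise InvalidArgumentError("f_grid must be ascending with >= 3 points")
    rows = []
    for f in f_grid:
        ext = ext_template.with_frequency(float(f))
        traj = run_track_simulation(particle, pattern, ext,
                                    n_periods=n_periods + 2, film=film,
                                    fluid=fluid, config=config)
        v = mean_speed(traj, pattern, ext, min_periods=1, skip_periods=2)
        rows.append({"frequency_hz": float(f), "mean_speed_um_s": v})
    table = pd.DataFrame(rows)
    if table["mean_speed_um_s"].max() <= 0:
        raise NoTransportError("no frequency produced forward transport")
    f_peak = float(table.loc[table["mean_speed_um_s"].idxmax(), "frequency_hz"])
    return f_peak, table
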