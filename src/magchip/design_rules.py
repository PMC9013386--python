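"""Transport design rules for drop-shape tracks and bends.

Operationalizes "appropriate particle transport": a run is *locked* when the
bead crosses at least three consecutive inter-magnet gaps while advancing
one spatial period per field rotation (sync ratio > 0.98).  Parameter sweeps
recover the two dimensionless thresholds — the smallest workable
diameter-to-gap ratio beta* and the largest workable diameter-to-neck ratio
gamma* — and bends are validated by the forward/backward energy-barrier
analysis, cross-checked against full trajectory simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    InvalidPatternError,
    UnbracketedThresholdError,
)
from .field_energy import (
    ExternalField,
    FilmResponse,
    FluidEnv,
    energy_profile,
    normalize_profiles,
)
from .geometry import BendSpec, MagnetPattern, TrackSpec, make_bend, make_drop_track
from .transport import (
    LandscapeEnergy,
    Particle,
    SimConfig,
    Trajectory,
    mean_speed,
    run_track_simulation,
    spine_progress,
)

#: normalized-energy barrier below which a path counts as unobstructed;
#: chosen above grid/sampling noise at the default 0.2-um resolution
BARRIER_TOL = 0.05

SYNC_LOCKED = 0.98
MIN_GAPS_LOCKED = 3


@dataclass(frozen=True)
class TransportVerdict:
    status: str                # locked | slipped | stuck
    gaps_crossed: int
    sync_ratio: float


@dataclass(frozen=True)
class BendReport:
    style: str
    forward_barrier: float     # normalized energy height above departure
    backward_barrier: float
    verdict: str               # pass | fail

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


# ---------------------------------------------------------------------------
# transport classification
# ---------------------------------------------------------------------------

def classify_transport(traj: Trajectory, pattern: MagnetPattern,
                       ext: ExternalField, min_periods: int = 3,
                       skip_periods: int = 2) -> TransportVerdict:
    """Classify a trajectory as locked / slipped / stuck.

    Counts distinct gap midlines crossed (track patterns) or, for patterns
    without per-gap metadata, full periods of spine progress; computes the
    mean progress per field period relative to the spatial period.  The
    first ``skip_periods`` rotations (seeding transient) are excluded from
    the sync ratio.
    """
    period_t = ext.period
    n_periods = int(np.floor(traj.duration / period_t + 1e-9)) - skip_periods
    if n_periods < min_periods:
        raise InsufficientDataError(
            f"trajectory spans {n_periods} < {min_periods} field periods "
            f"after the settle window")
    spine = pattern.spine
    if spine is None:
        raise InvalidPatternError("pattern has no spine to measure progress on")
    s = spine_progress(traj.positions[:, :2], spine)
    lam = pattern.metadata.get("period")
    if lam is None:
        raise InvalidPatternError("pattern metadata lacks spatial period")
    i0 = min(int(np.searchsorted(traj.times, skip_periods * period_t - 1e-9)),
             len(s) - 1)
    t_end = (skip_periods + n_periods) * period_t
    idx = min(int(np.searchsorted(traj.times, t_end - 1e-9)), len(s) - 1)
    progress = s[idx] - s[i0]
    sync = progress / (n_periods * lam)
    sync = float(np.clip(sync, 0.0, 1.05))

    gap_centers = pattern.metadata.get("gap_centers")
    if gap_centers is not None:
        s0 = s[i0]
        crossed = 0
        run = 0
        for gc in sorted(gap_centers):
            if gc < s0:
                continue
            if np.any(s[i0:idx + 1] > gc):
                run += 1
                crossed = max(crossed, run)
            else:
                run = 0
        gaps = crossed
    else:
        gaps = int(progress // lam)

    if gaps >= MIN_GAPS_LOCKED and sync > SYNC_LOCKED:
        status = "locked"
    elif sync <= 0.1:
        status = "stuck"
    else:
        status = "slipped"
    return TransportVerdict(status=status, gaps_crossed=int(gaps),
                            sync_ratio=sync)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepSettings:
    """Common settings for the design-rule sweeps."""

    ext: ExternalField = None
    film: FilmResponse = None
    fluid: FluidEnv = None
    chi_p: float = None
    n_periods: int = 5
    config: SimConfig = None

    def resolved(self):
        from .transport import DEFAULT_CHI_P
        return (self.ext or ExternalField(),
                self.film or FilmResponse(),
                self.fluid or FluidEnv(),
                self.chi_p if self.chi_p is not None else DEFAULT_CHI_P,
                self.config or SimConfig())


def _locked(diameter: float, track: TrackSpec, settings: SweepSettings) -> bool:
    ext, film, fluid, chi_p, cfg = settings.resolved()
    # the track must outlast the run: one unit per rotation plus margin
    if track.n_units < settings.n_periods + 4:
        track = TrackSpec(drop_length=track.drop_length,
                          drop_width=track.drop_width, neck=track.neck,
                          gap=track.gap, n_units=settings.n_periods + 4,
                          orientation=track.orientation)
    pattern = make_drop_track(track)
    particle = Particle(radius_um=diameter / 2.0, chi_p=chi_p)
    traj = run_track_simulation(particle, pattern, ext,
                                n_periods=settings.n_periods,
                                film=film, fluid=fluid, config=cfg)
    verdict = classify_transport(traj, pattern, ext,
                                 min_periods=min(3, settings.n_periods - 2))
    return verdict.status == "locked"


def sweep_beta(G: float, diameters, settings: SweepSettings | None = None,
               track: TrackSpec | None = None, refine_to: float = 0.01):
    """Smallest locked diameter/gap ratio beta*, bisection-refined.

    Sweeps ascending bead ``diameters`` on a track with gap ``G``; requires
    the sweep to straddle the stuck->locked transition.  Returns
    ``(beta_star, table)``.
    """
    settings = settings or SweepSettings()
    base = track or TrackSpec()
    track = TrackSpec(drop_length=base.drop_length, drop_width=base.drop_width,
                      neck=base.neck, gap=G,
                      n_units=base.n_units, orientation=base.orientation)
    diameters = sorted(float(d) for d in diameters)
    rows = []
    for d in diameters:
        ok = _locked(d, track, settings)
        rows.append({"d_P": d, "G": G, "N": track.neck, "beta": d / G,
                     "gamma": d / track.neck,
                     "status": "locked" if ok else "stuck"})
    table = pd.DataFrame(rows)
    locked = table[table.status == "locked"]
    failed = table[table.status != "locked"]
    if locked.empty or failed.empty or locked.d_P.min() < failed.d_P.max():
        if locked.empty or failed.empty:
            raise UnbracketedThresholdError(
                "diameter sweep does not bracket the transport threshold")
    lo = float(failed.d_P.max())
    hi = float(locked.d_P.min())
    while (hi - lo) / G > refine_to:
        mid = 0.5 * (lo + hi)
        if _locked(mid, track, settings):
            hi = mid
        else:
            lo = mid
        rows.append({"d_P": mid, "G": G, "N": track.neck, "beta": mid / G,
                     "gamma": mid / track.neck,
                     "status": "locked" if hi == mid else "stuck"})
    return hi / G, pd.DataFrame(rows)


def sweep_gamma(neck_values, d_P: float, settings: SweepSettings | None = None,
                track: TrackSpec | None = None, refine_to: float = 0.05):
    """Largest locked diameter/neck ratio gamma*, bisection-refined.

    Sweeps drop neck widths downward at fixed bead diameter; returns
    ``(gamma_star, table)``.
    """
    settings = settings or SweepSettings()
    base = track or TrackSpec()
    necks = sorted((float(n) for n in neck_values), reverse=True)

    def locked_at(n):
        tr = TrackSpec(drop_length=base.drop_length, drop_width=base.drop_width,
                       neck=n, gap=base.gap, n_units=base.n_units,
                       orientation=base.orientation)
        return _locked(d_P, tr, settings)

    rows = []
    for n in necks:
        ok = locked_at(n)
        rows.append({"d_P": d_P, "G": base.gap, "N": n, "beta": d_P / base.gap,
                     "gamma": d_P / n, "status": "locked" if ok else "stuck"})
    table = pd.DataFrame(rows)
    locked = table[table.status == "locked"]
    failed = table[table.status != "locked"]
    if locked.empty or failed.empty:
        raise UnbracketedThresholdError(
            "neck sweep does not bracket the transport threshold")
    n_ok = float(locked.N.min())    # narrowest neck that still works
    n_bad = float(failed.N.max())   # widest neck that fails
    lo, hi = n_bad, n_ok            # lo fails, hi locks, lo < hi
    while abs(d_P / lo - d_P / hi) > refine_to:
        mid = 0.5 * (lo + hi)
        if locked_at(mid):
            hi = mid
        else:
            lo = mid
        rows.append({"d_P": d_P, "G": base.gap, "N": mid,
                     "beta": d_P / base.gap, "gamma": d_P / mid,
                     "status": "locked" if hi == mid else "stuck"})
    return d_P / hi, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bend validation
# ---------------------------------------------------------------------------

def _labelled(pattern: MagnetPattern, name: str) -> np.ndarray:
    if name not in pattern.labels:
        raise InvalidPatternError(f"pattern lacks a magnet labelled {name!r}")
    return pattern.polygons[pattern.labels.index(name)]


def _offset_ring(poly: np.ndarray, clearance: float,
                 spacing: float = 0.8) -> np.ndarray:
    """Dense ring of points offset outward from a polygon boundary."""
    closed = np.vstack([poly, poly[:1]])
    pts = []
    c = poly.mean(axis=0)
    for a, b in zip(closed[:-1], closed[1:]):
        seg = b - a
        n = max(1, int(np.ceil(np.hypot(*seg) / spacing)))
        for f in np.arange(n) / n:
            pts.append(a + f * seg)
    ring = np.asarray(pts)
    out = ring - c
    out /= np.maximum(np.linalg.norm(out, axis=1, keepdims=True), 1e-12)
    return ring + out * clearance


def _ring_local_minima(e: np.ndarray) -> np.ndarray:
    """Indices of circular local minima of a 1D energy array."""
    left = np.roll(e, 1)
    right = np.roll(e, -1)
    return np.flatnonzero((e <= left) & (e <= right))


def _descend(en_ph, xy, z, step_um: float = 0.2, max_steps: int = 600,
             keep_path: bool = False):
    """Quasi-static steepest descent to the local energy minimum.

    Returns the minimizing (x, y); with ``keep_path`` also the list of
    visited points (the roll path of an overdamped bead at frozen phase).
    """
    from .transport import magnetic_force
    p = np.array([xy[0], xy[1], z])
    e = float(en_ph(p[None, :], 0.0)[0])
    path = [p[:2].copy()]
    for _ in range(max_steps):
        F = magnetic_force(lambda q: en_ph(q, 0.0), p, 0.05)
        fmag = float(np.hypot(F[0], F[1]))
        if fmag == 0.0:
            break
        q = p + np.array([F[0] / fmag, F[1] / fmag, 0.0]) * step_um
        eq = float(en_ph(q[None, :], 0.0)[0])
        if eq >= e:
            break
        p, e = q, eq
        if keep_path:
            path.append(p[:2].copy())
    if keep_path:
        return p[:2], path
    return p[:2]


def _nearest_magnet(pattern: MagnetPattern, xy) -> int:
    from shapely.geometry import Point
    pt = Point(*xy)
    d = [sh.distance(pt) for sh in pattern.shapely_polygons()]
    return int(np.argmin(d))


def switching_phase(pattern: MagnetPattern, particle: Particle,
                    ext: ExternalField, film: FilmResponse | None = None,
                    fluid: FluidEnv | None = None,
                    dwell_steps: int = 8):
    """Phase at which the bead's well leaves the corner magnet.

    The bead is seeded at the corner magnet's pole and integrated for up
    to three rotations at the operating frequency; the switching phase is
    the drive phase at the moment the bead departs ``magnet2`` for good
    (its well has destabilized and drained to a neighbouring magnet, and
    the bead was fast enough to follow).  Returns
    ``(phase_rad, p_before, target_label, roll_path)`` where ``p_before``
    is the last position on the corner magnet, ``target_label`` names the
    capturing magnet and ``roll_path`` is the simulated departure path.
    """
    from .transport import pole_seed_position, simulate
    from dataclasses import replace as dc_replace

    film = film or FilmResponse()
    fluid = fluid or FluidEnv()
    i2 = pattern.labels.index("magnet2")
    # seed upstream of the corner so the bead arrives at magnet2 in its
    # naturally phase-locked state (a bead seeded on magnet2 itself hops
    # backwards during the settle transient)
    seed_index = max(0, pattern.labels.index("magnet1") - 1)
    ext_run = ExternalField(ext.h_inplane_oe, ext.h_vertical_oe,
                            ext.frequency_hz or 0.2, phase0=0.0, sense="ccw")
    p0 = pole_seed_position(pattern, ext_run, film, fluid, particle,
                            magnet_index=seed_index)
    particle = dc_replace(particle, position=p0)
    cfg = SimConfig(duration=7.0 * ext_run.period, record_every=1)
    traj = simulate([particle], pattern, ext_run, cfg, film=film,
                    fluid=fluid)[0]
    near = np.array([_nearest_magnet(pattern, xy)
                     for xy in traj.positions[:, :2]])
    on_m2 = np.flatnonzero(near == i2)
    # arrival: first sustained residence on magnet2
    arrived = None
    for k in on_m2:
        if k + dwell_steps <= len(near) and np.all(near[k:k + dwell_steps] == i2):
            arrived = k
            break
    if arrived is None:
        raise InvalidPatternError(
            "bead never arrives at the corner magnet (upstream blockage)")
    k = arrived
    while k < len(near) - dwell_steps:
        if near[k] != i2 and np.all(near[k:k + dwell_steps] != i2):
            target = pattern.labels[int(near[k + dwell_steps - 1])]
            ph = ext_run.phase_at(traj.times[k])
            p_before = traj.positions[max(0, k - 1), :2]
            roll = traj.positions[max(0, k - 1):k + dwell_steps * 4, :2]
            return ph, p_before, target, roll
        k += 1
    raise InvalidPatternError(
        "corner well never destabilizes (no hand-off after arrival)")


def validate_bend(pattern: MagnetPattern, particle: Particle,
                  ext: ExternalField,
                  film: FilmResponse | None = None,
                  fluid: FluidEnv | None = None,
                  samples_per_segment: int = 160) -> BendReport:
    """Forward/backward energy-barrier analysis of a bend.

    At the numerically detected switching phase — where the bead's well on
    the corner magnet annihilates — the energy is sampled along the forward
    path (last well position ``p`` -> well ``q2`` on the next magnet along
    the particle path) and the backward path (``p`` -> well ``q1`` on the
    previous magnet),
    jointly min-max normalized.  The bend passes when the forward path has
    no interior barrier above the departure point (<= 0.05 normalized)
    while the backward path does: the released bead rolls forward and
    cannot return.
    """
    film = film or FilmResponse()
    fluid = fluid or FluidEnv()
    for lbl in ("magnet1", "magnet2", "magnet3"):
        _labelled(pattern, lbl)
    try:
        ph, p, target, roll = switching_phase(pattern, particle, ext, film,
                                              fluid)
    except InvalidPatternError:
        # the corner traps the bead in a closed orbit: maximal barriers
        return BendReport(style=pattern.metadata.get("style", "unknown"),
                          forward_barrier=1.0, backward_barrier=1.0,
                          verdict="fail")
    order = {lbl: i for i, lbl in enumerate(pattern.labels)}
    went_forward = order[target] > order["magnet2"]
    z = particle.flight_height
    ext_ph = ExternalField(ext.h_inplane_oe, ext.h_vertical_oe, 0.0,
                           phase0=ph, sense="ccw")
    en = LandscapeEnergy(pattern, ext_ph, film, fluid, particle)

    def ring_min(label):
        ring = _offset_ring(_labelled(pattern, label), clearance=0.3)
        pts3 = np.concatenate([ring, np.full((len(ring), 1), z)], axis=1)
        return ring[int(np.argmin(en(pts3, 0.0)))]

    i2 = pattern.labels.index("magnet2")
    q1 = ring_min(pattern.labels[max(0, i2 - 1)])
    q2 = ring_min(pattern.labels[min(len(pattern.labels) - 1, i2 + 1)])
    # forward path: the bead's actual roll path when the hand-off succeeds
    # (a straight chord can cross ridges the rolling bead goes around);
    # otherwise the chord from the released position to the next well
    if went_forward and len(roll) > 3:
        fwd_path = np.vstack([roll, q2[None, :]])
    else:
        fwd_path = np.stack([p, q2])
    bwd_path = np.vstack([roll, q1[None, :]]) if (not went_forward and
                                                  len(roll) > 3) \
        else np.stack([p, q1])
    prof_f = energy_profile(pattern, ext_ph, film, fluid,
                            particle.volume_um3, particle.chi_p,
                            fwd_path, z, 0.0,
                            max(2, samples_per_segment // max(1, len(fwd_path) - 1)),
                            labels=("p", "q2"))
    prof_b = energy_profile(pattern, ext_ph, film, fluid,
                            particle.volume_um3, particle.chi_p,
                            bwd_path, z, 0.0,
                            max(2, samples_per_segment // max(1, len(bwd_path) - 1)),
                            labels=("p", "q1"))
    nf, nb = normalize_profiles([prof_f, prof_b])
    fwd = _interior_barrier(nf)
    bwd = _interior_barrier(nb)
    verdict = "pass" if (fwd <= BARRIER_TOL and bwd > BARRIER_TOL) else "fail"
    return BendReport(style=pattern.metadata.get("style", "unknown"),
                      forward_barrier=fwd, backward_barrier=bwd,
                      verdict=verdict)


def _interior_barrier(profile) -> float:
    """Highest normalized energy above the departure value along the path."""
    e = profile.energy
    return float(max(0.0, np.max(e) - e[0]))


def simulate_bend_transport(spec: BendSpec, particle: Particle,
                            ext: ExternalField,
                            film: FilmResponse | None = None,
                            fluid: FluidEnv | None = None,
                            n_periods: int | None = None,
                            config: SimConfig | None = None):
    """Full trajectory check of a bend: does the bead reach the second arm?

    Returns ``(passed, trajectory, pattern)``.  The bead is seeded on the
    incoming arm just before the corner and must progress past the corner
    element within the allotted rotations.
    """
    pattern = make_bend(spec)
    film = film or FilmResponse()
    fluid = fluid or FluidEnv()
    # seed two drops before the corner; allow enough rotations to clear it
    seed_index = max(0, pattern.labels.index("magnet1") - 1)
    n_corner = pattern.labels.index("magnet3") - seed_index + 1
    n_periods = n_periods or (n_corner + 3)
    from .transport import pole_seed_position, simulate
    p0 = pole_seed_position(pattern, ext, film, fluid, particle,
                            magnet_index=seed_index)
    particle = replace(particle, position=p0)
    cfg = config or SimConfig()
    cfg = replace(cfg, duration=n_periods * ext.period)
    traj = simulate([particle], pattern, ext, cfg, film=film, fluid=fluid)[0]
    spine = pattern.spine
    s = spine_progress(traj.positions[:, :2], spine)
    m3 = _labelled(pattern, "magnet3").mean(axis=0)
    s_goal = spine_progress(np.atleast_2d(m3), spine)[0]
    passed = bool(np.max(s) >= s_goal)
    return passed, traj, pattern
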