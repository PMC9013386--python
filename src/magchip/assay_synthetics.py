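"""Synthetic data for the bead-pair assay pipeline.

Two generators feed the downstream stages:

* chamber micrographs of singlet beads and touching bead pairs with known
  ground truth, Gaussian read noise and optional Poisson shot noise, for
  exercising the detector;
* stochastic pair-formation datasets in which the probability that a bead
  encounter yields a persistent pair rises with analyte concentration from
  a field-mode-dependent background, following a saturating (Langmuir-type)
  binding curve::

      p(c) = p_bg + (p_max - p_bg) * c / (c + K)

  with ``p_bg`` the spontaneous (zero-analyte) pairing probability — high
  for a purely in-plane (2D) drive where rotating dipoles attract, low for
  the conical (3D) drive where the time-averaged pair force is repulsive —
  ``p_max`` the saturation probability and ``K`` the half-saturation
  concentration in the same relative units as the assay axes (~1e-13..1e-9).

A physics-based alternative to the phenomenological background is
:func:`simulate_background_encounters`, which integrates unlinked beads
with dipolar pair forces and thermal kicks under either drive mode and
counts spontaneously touching pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import minimize
from scipy.stats import binom

from .errors import (
    FitFailureError,
    InvalidArgumentError,
    InvalidModelError,
    InvalidSceneError,
    PackingError,
)
from .field_energy import ExternalField, FluidEnv
from .pair_detection import DEFAULT_SCALE_UM_PER_PX, PairSummary
from .transport import Particle, SimConfig, simulate


@dataclass(frozen=True)
class BindingModel:
    """Saturating pair-formation probability versus analyte concentration."""

    p_bg_2d: float = 0.15
    p_bg_3d: float = 0.02
    p_max: float = 0.8
    K: float = 1.0e-11

    def __post_init__(self):
        if not (0.0 <= self.p_bg_3d < self.p_bg_2d <= 1.0):
            raise InvalidModelError("need 0 <= p_bg_3d < p_bg_2d <= 1")
        if not (0.0 < self.p_max <= 1.0):
            raise InvalidModelError("need 0 < p_max <= 1")
        if not self.K > 0:
            raise InvalidModelError("half-saturation K must be positive")

    def p_bg(self, field_mode: str) -> float:
        if field_mode not in ("2D", "3D"):
            raise InvalidModelError("field_mode must be '2D' or '3D'")
        return self.p_bg_2d if field_mode == "2D" else self.p_bg_3d

    def pair_probability(self, concentration: float, field_mode: str) -> float:
        if concentration < 0:
            raise InvalidArgumentError("concentration must be >= 0")
        p0 = self.p_bg(field_mode)
        return p0 + (self.p_max - p0) * concentration / (concentration + self.K)


@dataclass
class ChamberScene:
    """Ground-truth layout of beads in one chamber image."""

    positions_um: np.ndarray          # (n, 2)
    radii_um: np.ndarray              # (n,)
    pair_links: list                  # list of (i, j)
    extent_um: tuple = (100.0, 100.0)
    scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX
    snr: float = np.inf
    background: float = 0.2
    seed: int = 0


# ---------------------------------------------------------------------------
# binding simulation
# ---------------------------------------------------------------------------

def simulate_binding(concentration: float, model: BindingModel, n_beads: int,
                     field_mode: str = "3D", seed: int = 0):
    """Draw ``(n_pairs, n_singles)`` for one chamber.

    Beads are paired into ``n_beads // 2`` candidate encounters; each forms
    a persistent pair with probability ``p(c)``; all other beads remain
    singles.
    """
    if n_beads < 2:
        raise InvalidArgumentError("need at least 2 beads")
    p = model.pair_probability(concentration, field_mode)
    rng = np.random.default_rng(seed)
    n_enc = n_beads // 2
    n_pairs = int(rng.binomial(n_enc, p))
    n_singles = n_beads - 2 * n_pairs
    return n_pairs, n_singles


def generate_dose_series(concentrations, model: BindingModel, n_beads: int,
                         replicates: int, field_mode: str = "3D",
                         seed: int = 0) -> pd.DataFrame:
    """Per-chamber pair/single counts across a concentration series.

    Fully reproducible: chamber ``(i, j)`` uses seed ``seed + i*1000 + j``.
    """
    conc = [float(c) for c in concentrations]
    if any(b > a for a, b in zip(conc[1:], conc[:-1])):
        raise InvalidArgumentError("concentrations must be ascending")
    rows = []
    for i, c in enumerate(conc):
        for j in range(replicates):
            s = seed + i * 1000 + j
            n_pairs, n_singles = simulate_binding(c, model, n_beads,
                                                  field_mode, seed=s)
            rows.append({"concentration": c, "replicate": j, "seed": s,
                         "n_beads": n_beads, "n_pairs": n_pairs,
                         "n_singles": n_singles,
                         "pair_percentage": PairSummary(n_singles, n_pairs).pair_percentage})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# physics-based background encounters
# ---------------------------------------------------------------------------

def random_nonoverlapping(n: int, radii, extent, rng, min_gap: float = 0.05,
                          max_tries: int = 20000) -> np.ndarray:
    """Random non-overlapping in-plane positions inside ``extent`` (um).

    ``min_gap`` is the minimum surface-to-surface distance between any two
    beads (and 0.05 um at least, so nothing starts in contact).
    """
    radii = np.broadcast_to(np.asarray(radii, float), (n,))
    W, Hgt = extent
    gap = max(min_gap, 0.05)
    pos = []
    for i in range(n):
        for _ in range(max_tries):
            p = rng.uniform([radii[i], radii[i]], [W - radii[i], Hgt - radii[i]])
            if all(np.hypot(*(p - q)) >= radii[i] + radii[j] + gap
                   for j, q in enumerate(pos)):
                pos.append(p)
                break
        else:
            raise PackingError(f"could not place bead {i} of {n}")
    return np.asarray(pos)


def simulate_background_encounters(n_beads: int = 50, mode: str = "3D",
                                   duration: float = 60.0, seed: int = 0,
                                   bead_radius_um: float = 1.4,
                                   chi_p: float | None = None,
                                   area_fraction: float = 0.02,
                                   frequency_hz: float = 0.2,
                                   amplitude_oe: float = 70.0,
                                   contact_gap_um: float = 0.1,
                                   min_start_gap_um: float = 4.0,
                                   dt: float | None = None):
    """Count spontaneously touching bead pairs after ``duration`` seconds.

    Unlinked beads are placed at random non-overlapping positions at the
    stated area fraction and integrated with pairwise dipolar forces and
    thermal kicks.  The placement keeps a minimum surface gap
    (``min_start_gap_um``, default 4 um) between beads: the chambers are
    loaded bead-by-bead under the repulsive conical drive, so the
    suspension starts dispersed, with nothing already in contact.
    ``mode='2D'`` drives with the in-plane rotating field only
    (time-averaged attraction -> agglomeration); ``mode='3D'`` adds an
    equal vertical bias (45-degree cone, above the dipolar magic angle ->
    time-averaged repulsion).  Returns ``(n_touching_pairs, summary)``:
    the number of bead pairs in mutual contact (surface gap <
    ``contact_gap_um``) at the end, plus the component breakdown
    (singles / isolated pairs / larger clusters).
    """
    if n_beads < 2:
        raise InvalidArgumentError("need at least 2 beads")
    if mode not in ("2D", "3D"):
        raise InvalidArgumentError("mode must be '2D' or '3D'")
    if chi_p is None:
        from .transport import DEFAULT_CHI_P
        chi_p = DEFAULT_CHI_P
    rng = np.random.default_rng(seed)
    # box side from the target area fraction
    area = n_beads * math.pi * bead_radius_um**2 / area_fraction
    side = math.sqrt(area)
    pos2 = random_nonoverlapping(n_beads, bead_radius_um, (side, side), rng,
                                 min_gap=min_start_gap_um)
    z = bead_radius_um + 0.5
    particles = [Particle(radius_um=bead_radius_um, chi_p=chi_p,
                          position=np.array([x, y, z]), id=i)
                 for i, (x, y) in enumerate(pos2)]
    ext = ExternalField(h_inplane_oe=amplitude_oe,
                        h_vertical_oe=amplitude_oe if mode == "3D" else 0.0,
                        frequency_hz=frequency_hz)
    cfg = SimConfig(dt=dt if dt is not None else ext.period / 200.0,
                    duration=duration, thermal=True, seed=seed,
                    max_disp_um=0.5, record_every=10**9)
    trajs = simulate(particles, None, ext, cfg, fluid=FluidEnv(), box=(0, 0, side, side))
    final = np.stack([t.positions[-1] for t in trajs])
    return _count_touching_pairs(final, np.full(n_beads, bead_radius_um),
                                 contact_gap_um)


def _count_touching_pairs(positions, radii, contact_gap_um):
    """Count touching bead pairs (contacts) and component structure.

    Returns ``(n_contacts, summary)``: ``n_contacts`` is the number of bead
    pairs in mutual contact (surface gap < ``contact_gap_um``); the summary
    groups the touch graph into singles / isolated pairs / larger clusters.
    """
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    n_contacts = 0
    for i in range(n):
        for j in range(i + 1, n):
            gap = np.linalg.norm(positions[i] - positions[j]) - radii[i] - radii[j]
            if gap < contact_gap_um:
                n_contacts += 1
                parent[find(i)] = find(j)
    sizes = {}
    for i in range(n):
        r = find(i)
        sizes[r] = sizes.get(r, 0) + 1
    n_pairs = sum(1 for s in sizes.values() if s == 2)
    big = [s for s in sizes.values() if s > 2]
    summary = PairSummary(n_singles=sum(1 for s in sizes.values() if s == 1),
                          n_pairs=n_pairs, n_clusters_gt2=len(big),
                          n_cluster_beads=sum(big))
    return n_contacts, summary


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def random_scene(n_singles: int, n_pairs: int, bead_radius_um: float = 1.4,
                 extent_um=(100.0, 100.0), snr: float = np.inf,
                 seed: int = 0, **kw) -> ChamberScene:
    """Scene with well-separated singles and touching pairs, known truth."""
    rng = np.random.default_rng(seed)
    r = bead_radius_um
    # place "sites": singles plus pair centroids, separated by 6 radii
    n_sites = n_singles + n_pairs
    sites = random_nonoverlapping(n_sites, 3.0 * r, extent_um, rng)
    positions, radii, links = [], [], []
    for k in range(n_singles):
        positions.append(sites[k])
        radii.append(r)
    for k in range(n_pairs):
        c = sites[n_singles + k]
        ang = rng.uniform(0, 2 * math.pi)
        d = np.array([math.cos(ang), math.sin(ang)]) * r
        i0 = len(positions)
        positions += [c - d, c + d]
        radii += [r, r]
        links.append((i0, i0 + 1))
    return ChamberScene(positions_um=np.asarray(positions, float).reshape(-1, 2),
                        radii_um=np.asarray(radii, float),
                        pair_links=links, extent_um=extent_um, snr=snr,
                        seed=seed, **kw)


def render_chamber_image(scene: ChamberScene):
    """Render a scene to a float image in [0, 1] plus ground truth.

    Beads are bright disks with Gaussian-blurred edges on a noisy
    background.  Deterministic for a fixed scene seed.

    Returns ``(image, truth)`` where ``truth`` is a dict with pixel-space
    centers (row, col), radii and pair links.
    """
    s = scene.scale_um_per_px
    W = int(round(scene.extent_um[0] / s))
    Hgt = int(round(scene.extent_um[1] / s))
    if len(scene.positions_um) != len(scene.radii_um):
        raise InvalidSceneError("positions and radii length mismatch")
    img = np.full((Hgt, W), scene.background, dtype=float)
    amp = 0.7
    for (x, y), r in zip(scene.positions_um, scene.radii_um):
        if not (0 <= x <= scene.extent_um[0] and 0 <= y <= scene.extent_um[1]):
            raise InvalidSceneError(f"bead at ({x:.1f}, {y:.1f}) outside frame")
        col = x / s
        row = y / s
        rpx = r / s
        r0, r1 = int(max(0, row - rpx - 3)), int(min(Hgt, row + rpx + 4))
        c0, c1 = int(max(0, col - rpx - 3)), int(min(W, col + rpx + 4))
        rr, cc = np.mgrid[r0:r1, c0:c1]
        mask = (rr - row)**2 + (cc - col)**2 <= rpx**2
        img[r0:r1, c0:c1][mask] = scene.background + amp
    img = gaussian_filter(img, sigma=1.0)
    if np.isfinite(scene.snr) and scene.snr > 0:
        rng = np.random.default_rng(scene.seed)
        img = img + rng.normal(scale=amp / scene.snr, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    truth = {
        "centers_rowcol_px": [(y / s, x / s) for x, y in scene.positions_um],
        "radii_px": list(scene.radii_um / s),
        "pair_links": list(scene.pair_links),
        "scale_um_per_px": s,
    }
    return img, truth


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

def recover_binding_params(dataset: pd.DataFrame, field_mode: str = "3D",
                           n_bootstrap: int = 200, seed: int = 0):
    """Maximum-likelihood fit of (p_bg, p_max, K) to a dose series.

    ``dataset`` needs columns ``concentration``, ``n_pairs``, ``n_beads``.
    The likelihood is binomial over ``n_beads // 2`` encounters per chamber.
    Returns a dict with point estimates and bootstrap percentile intervals.
    """
    req = {"concentration", "n_pairs", "n_beads"}
    if not req.issubset(dataset.columns):
        raise InvalidArgumentError(f"dataset needs columns {sorted(req)}")
    if dataset["concentration"].nunique() < 4:
        raise FitFailureError("need >= 4 distinct concentrations")
    if dataset["n_pairs"].sum() == 0:
        raise FitFailureError("all-zero pair counts; binding model unidentifiable")

    c = dataset["concentration"].to_numpy(float)
    k = dataset["n_pairs"].to_numpy(int)
    n = (dataset["n_beads"].to_numpy(int)) // 2
    pos_c = c[c > 0]
    log_k0 = math.log(np.median(pos_c)) if len(pos_c) else math.log(1e-11)

    def unpack(theta):
        a, b, lk = theta
        p_bg = 1.0 / (1.0 + math.exp(-a))
        p_max = p_bg + (1.0 - p_bg) / (1.0 + math.exp(-b))
        return p_bg, p_max, math.exp(lk)

    def nll(theta, cc, kk, nn):
        p_bg, p_max, K = unpack(theta)
        p = p_bg + (p_max - p_bg) * cc / (cc + K)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -np.sum(binom.logpmf(kk, nn, p))

    x0 = np.array([-2.0, 0.5, log_k0])
    res = minimize(nll, x0, args=(c, k, n), method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    if not np.isfinite(res.fun):
        raise FitFailureError("likelihood optimization failed")
    p_bg, p_max, K = unpack(res.x)

    rng = np.random.default_rng(seed)
    boots = []
    idx = np.arange(len(c))
    for _ in range(n_bootstrap):
        bi = rng.choice(idx, size=len(idx), replace=True)
        if k[bi].sum() == 0:
            continue
        rb = minimize(nll, res.x, args=(c[bi], k[bi], n[bi]),
                      method="Nelder-Mead", options={"maxiter": 1000})
        boots.append(unpack(rb.x))
    boots = np.asarray(boots) if boots else np.empty((0, 3))

    def ci(col):
        if len(boots) == 0:
            return (float("nan"), float("nan"))
        return tuple(np.percentile(boots[:, col], [2.5, 97.5]))

    return {
        "p_bg": p_bg, "p_max": p_max, "K": K,
        "p_bg_ci": ci(0), "p_max_ci": ci(1), "K_ci": ci(2),
        "n_bootstrap": len(boots),
    }
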