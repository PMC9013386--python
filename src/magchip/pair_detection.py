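"""Bead detection and pair counting in chamber micrographs.

The assay readout is the fraction of beads that sit in two-bead pairs after
the unlink/relink field protocol: an analyte molecule bridges two
ligand-coated beads, so the pair count reports the analyte concentration.
Detection is multiscale Laplacian-of-Gaussian blob detection on
background-subtracted intensity; two detections form a pair when their
centre distance is at most ``(r1 + r2) * (1 + tolerance)``.

Conventions (the reference image-processing method):

* ``pair_percentage = 100 * 2 * n_pairs / (2 * n_pairs + n_singles)`` —
  the percent of beads that are members of a pair;
* clusters of more than two beads are reported separately and excluded
  from the percentage (the conical drive is designed to prevent them);
* images are grayscale, origin top-left, row-major.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.feature import blob_log

from .errors import InsufficientDataError, InvalidArgumentError, InvalidInputError

DEFAULT_SCALE_UM_PER_PX = 0.2
DEFAULT_TOUCH_TOLERANCE = 0.2


@dataclass(frozen=True)
class BeadDetection:
    """One detected bead: centre (row, col) and radius in pixels."""

    row: float
    col: float
    radius: float
    score: float = 1.0


@dataclass(frozen=True)
class PairSummary:
    """Per-chamber single/pair/cluster counts."""

    n_singles: int
    n_pairs: int
    n_clusters_gt2: int = 0
    n_cluster_beads: int = 0

    @property
    def pair_percentage(self) -> float:
        denom = 2 * self.n_pairs + self.n_singles
        if denom == 0:
            return float("nan")
        return 100.0 * (2 * self.n_pairs) / denom

    @property
    def total_beads(self) -> int:
        return self.n_singles + 2 * self.n_pairs + self.n_cluster_beads


@dataclass(frozen=True)
class DoseResponsePoint:
    concentration: float
    median: float
    q1: float
    q3: float
    stdev: float
    n_replicates: int


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_beads(image: np.ndarray, radius_range_px=(5.0, 20.0),
                 threshold: float = 0.08,
                 background_sigma_factor: float = 4.0):
    """Detect bright beads in a grayscale image.

    Background is estimated by a wide Gaussian blur and subtracted; blobs
    are found by multiscale Laplacian of Gaussian within the expected
    radius range; duplicates within one radius are suppressed (handled by
    LoG maxima plus an explicit pass).

    Returns a list of :class:`BeadDetection`.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise InvalidInputError("image must be a non-empty 2D grayscale array")
    rmin, rmax = radius_range_px
    if rmin <= 0 or rmax <= rmin:
        raise InvalidArgumentError("radius range must satisfy 0 < rmin < rmax")

    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        return []
    bg = gaussian_filter(img, sigma=background_sigma_factor * rmax)
    work = np.clip(img - bg, 0.0, None)

    blobs = blob_log(work, min_sigma=rmin / math.sqrt(2.0),
                     max_sigma=rmax / math.sqrt(2.0), num_sigma=8,
                     threshold=threshold, overlap=0.3)
    dets = []
    for row, col, sigma in blobs:
        r = sigma * math.sqrt(2.0)
        if 0 <= row < img.shape[0] and 0 <= col < img.shape[1]:
            dets.append(BeadDetection(row=float(row), col=float(col),
                                      radius=float(r),
                                      score=float(min(1.0, work[int(row), int(col)]))))
    return _suppress_duplicates(dets)


def _suppress_duplicates(dets):
    """Drop detections whose centre lies within one radius of a stronger one."""
    dets = sorted(dets, key=lambda d: -d.score)
    kept = []
    for d in dets:
        dup = any(math.hypot(d.row - k.row, d.col - k.col) < max(d.radius, k.radius)
                  for k in kept)
        if not dup:
            kept.append(d)
    return kept


# ---------------------------------------------------------------------------
# pair classification
# ---------------------------------------------------------------------------

def classify_pairs(detections, touch_tolerance: float = DEFAULT_TOUCH_TOLERANCE
                   ) -> PairSummary:
    """Group detections into singles / pairs / larger clusters.

    Two beads touch when their centre distance is <= (r1 + r2) * (1 + tol);
    connected components of the touch graph of size 1 are singles, size 2
    pairs, larger ones clusters (reported, excluded from the percentage).
    """
    if touch_tolerance < 0:
        raise InvalidArgumentError("touch tolerance must be >= 0")
    n = len(detections)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            di, dj = detections[i], detections[j]
            lim = (di.radius + dj.radius) * (1.0 + touch_tolerance)
            if math.hypot(di.row - dj.row, di.col - dj.col) <= lim + 1e-12:
                parent[find(i)] = find(j)

    sizes = {}
    for i in range(n):
        r = find(i)
        sizes[r] = sizes.get(r, 0) + 1
    n_singles = sum(1 for s in sizes.values() if s == 1)
    n_pairs = sum(1 for s in sizes.values() if s == 2)
    big = [s for s in sizes.values() if s > 2]
    return PairSummary(n_singles=n_singles, n_pairs=n_pairs,
                       n_clusters_gt2=len(big), n_cluster_beads=sum(big))


# ---------------------------------------------------------------------------
# assay statistics
# ---------------------------------------------------------------------------

def dose_response(points) -> pd.DataFrame:
    """Aggregate per-chamber summaries into a dose-response table.

    ``points``: iterable of ``(concentration, PairSummary)``.  Returns a
    DataFrame with per-concentration median, quartiles, stdev and replicate
    count of the pair percentage, sorted by concentration.
    """
    rows = [(float(c), s.pair_percentage) for c, s in points]
    if not rows:
        raise InsufficientDataError("no dose-response data")
    df = pd.DataFrame(rows, columns=["concentration", "pair_percentage"])
    g = df.groupby("concentration")["pair_percentage"]
    out = pd.DataFrame({
        "median": g.median(),
        "q1": g.quantile(0.25),
        "q3": g.quantile(0.75),
        "stdev": g.std(ddof=1).fillna(0.0),
        "n_replicates": g.count(),
    }).reset_index()
    return out.sort_values("concentration").reset_index(drop=True)


def field_mode_ratio(background_2d, background_3d) -> float:
    """Fold change of zero-analyte pair counts, 2D over 3D drive.

    Means are taken over chambers; returns ``inf`` when the 3D mean is zero
    (complete suppression).
    """
    if not background_2d or not background_3d:
        raise InsufficientDataError("both field modes need at least one chamber")
    m2 = float(np.mean([s.n_pairs for s in background_2d]))
    m3 = float(np.mean([s.n_pairs for s in background_3d]))
    if m3 == 0.0:
        return float("inf")
    return m2 / m3
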