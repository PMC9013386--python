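# Model and methods

`magchip` models a magnetophoretic lab-on-a-chip: superparamagnetic beads
are carried along patterned permalloy micromagnet tracks by a rotating
*conical* magnetic field (an in-plane rotating component plus a static
vertical bias), and the same chip doubles as an agglutination sensor in
which an analyte links two ligand-coated beads into a pair that the
vertical bias cannot break apart, while unlinked beads are kept separated
by the time-averaged dipolar repulsion.

## Magnetostatics

The 100-nm Ni80Fe20 film is soft: its in-plane magnetization follows the
in-plane drive direction and saturates at `Ms = 8.6e5 A/m` (at 70 Oe the
film is always saturated in-plane); the out-of-plane response is suppressed
by the thin-film demagnetizing factor (`Nz = 1`), leaving `M_z ~ H_z`
(~5.6e3 A/m, two orders below `Ms`).

The stray field of each uniformly magnetized thin polygon is evaluated
analytically in the thin-film limit:

* in-plane magnetization → magnetic surface charge on the polygon side
  walls, collapsed to *line charges* `lambda = (M . n) t` on the edges,
  placed on the film mid-plane `z = t/2`; the field of a finite uniformly
  charged segment has a closed form;
* perpendicular magnetization → a uniform dipole sheet of moment density
  `M_z t`, equivalent by Ampère's theorem to a boundary current loop
  `I = M_z t` (closed-form Biot–Savart of straight segments).

Against a brute-force 3D surface-charge quadrature of a 4-um square magnet
the closed forms agree to better than 0.3 % for `z >= 2 um`.  The mid-plane
placement matters: line charges at `z = 0` bias the field by ~3 % at
`z = 2.5 um`.

A bead of volume `V_p` and susceptibility `chi_p` in water has dipolar
energy

    U(r) = -(1/2) mu0 V_p (chi_p - chi_f) |H(r)|^2

so beads are attracted to field maxima ("energy wells" at magnet poles).
With the in-plane field alone a magnetized disk carries two pole wells;
adding a vertical bias of equal amplitude turns the pole whose stray
z-component opposes the bias into a hill, which the landscape code
reproduces (two minima → one minimum below a 0.2 normalized threshold).

## Drop geometry

The track is a periodic row of teardrop magnets: a circular head (width
`W`), a *concave* fillet tail, and a rounded tip whose width is the neck
`N`; consecutive drops are separated by the gap `G`.  The concave tail is
load-bearing: on a fully convex island the energy well circulates smoothly
with the drive phase and the bead orbits in place (the disk failure mode).
The concave section makes the normal direction non-monotone along the
boundary, so once per rotation the occupied well annihilates in a
saddle-node event and the released bead rolls forward across the gap to
the next head — one spatial period of progress per field rotation.

The canonical template is `drop_length 30 um`, `head width 16 um`,
`neck 15 um`, `gap 15 um` (period 45 um), tail fillet radius
`0.5 x drop_length`.  Only `G = 15 um` and the ratio pairs
`beta = gamma` are fixed by the bench chips; the remaining dimensions were
chosen once so that (i) the spatial period matches the observed ~9 um/s at
0.2 Hz, and (ii) the saddle-node hand-off carries both the 5–6 um and the
8–10 um bead sets.  Head widths of 20 um carry the small set but strand
the 9-um set (the released bead falls back to its own head); 16 um carries
both.

## Transport integration

Overdamped dynamics: `v = F / (6 pi eta_f R_p)` with forward-difference
updates `r_i = r_{i-1} + v_{i-1} dt`, `dt = period/400` by default and an
adaptive substep that caps any displacement at 0.25 um (the hand-off is
fast compared to the rotation).  Motion is confined to the flight plane
`z = R_p + 0.5 um` (bead resting just above the non-fouling layer);
vertical force balance, friction and Brownian motion are neglected in the
deterministic transport runs.  The landscape force is the central finite
difference of `U` (step 0.05 um); pairwise bead interactions use the
point-dipole force with moments `m = 4 pi R_p^3 chi_p H_ext / 3` set by the
external drive only.  Hard-sphere overlaps are resolved by minimal
symmetric projection.

A seeded bead needs up to two rotations to fall into phase lock, so all
speed and synchrony measurements discard the first two periods.

## Calibration

The bead susceptibility is the one free parameter the chip data cannot
fix a priori.  A single bead-family value `chi_p = 0.2` is calibrated so
the simulated critical frequency of a 5.5-um bead on the canonical track
falls at the observed ~0.6 Hz; the 8–9.9-um set uses `1.2 x chi_p`,
reflecting that set's higher per-volume magnetization, which places its
critical frequency near the observed ~0.8 Hz.  At 0.2 Hz both sets are
phase-locked and the transport speed is exactly `lambda f = 9 um/s`
(a locking property, independent of the calibration).

With this calibration the model's workable bead-size window on the
canonical track is roughly 4.4–10 um diameter.  Beads below ~4.4 um are
not handed across the gap (the release event strands them on their own
drop at any susceptibility — a geometric property of the reconstructed
shape), which puts the simulated diameter-to-gap threshold at
`beta* ~ 0.29`, about twice the value the bench chips exhibit; 14–20-um
beads fly too high above the 16-um-wide drops to feel the hand-off
structure at all.  Both ends are stated limitations of the reconstructed
geometry (the fabricated drop dimensions are not published), not of the
integrator: within the window, the neck sweep reproduces a
diameter-to-neck threshold `gamma* ~ 1.2`, close to the bench rule
(< 1.4).

## Bend validation

A bend joins two straight arms through a corner element: several small
rotated drops, a single large corner drop (two variants), an inside-corner
drop, or the deliberately flawed construction whose corner gaps are simply
enlarged (2 G).  All corner magnets are themselves teardrops — a
rotationally symmetric corner (disk) would trap the bead in orbit.

Bend verdicts use the forward/backward energy-barrier analysis: the
switching phase is detected by simulating a bead arriving at the corner
magnet at the operating frequency and noting the drive phase at which it
departs; the energy is then sampled at that frozen phase along the forward
path (departure point → well on the next magnet, following the bead's
actual roll path, since a straight chord can cross ridges the rolling bead
goes around) and along the backward chord to the previous magnet's well,
jointly min-max normalized.  A bend passes when the forward path has no
interior barrier above the departure point (tolerance 0.05 normalized,
chosen above grid noise at the default 0.2-um sampling) and the backward
path does.  Corners that never release the bead, or whose upstream gap
already blocks arrival, fail with saturated barriers.

## Pair assay synthetics

Chamber micrographs are rendered as bright anti-aliased disks on a noisy
background (Gaussian read noise at a stated SNR); ground truth (centres,
radii, pair links) is kept alongside.  Detection is multiscale
Laplacian-of-Gaussian blob detection on background-subtracted intensity in
a narrow scale band (0.7–1.3 of the known bead radius — a wide band makes
a touching pair look like one large blob).  Two detections pair when their
centre distance is within `(r1+r2)(1+0.2)`; connected components larger
than two are reported as clusters and excluded from the pair percentage
`100 * 2 n_pairs / (2 n_pairs + n_singles)`.

Pair formation versus analyte concentration follows a saturating
(Langmuir-type) curve `p(c) = p_bg + (p_max - p_bg) c/(c + K)` with
defaults `p_bg_2D = 0.15`, `p_bg_3D = 0.02`, `p_max = 0.8`, `K = 1e-11`
(relative concentration units, matching the assay's 1e-13..1e-9 axes).
The form is the simplest one reproducing the observed flat background →
rising → saturating shape; `K` sits at the response midpoint and the
background ratio mirrors the >= 7-fold suppression of spontaneous pairs
under the conical drive.  Parameters are recovered from count data by
binomial maximum likelihood with bootstrap intervals.

The physics-based background alternative integrates 50 unlinked 2.8-um
beads (2 % area fraction) with dipolar pair forces and Stokes–Einstein
thermal kicks for 60 s.  Placement keeps a minimum surface gap of 4 um:
chambers are loaded bead-by-bead under the repulsive conical drive, so
nothing starts in contact.  Under the in-plane-only drive the
rotation-averaged pair force is attractive (elevation below the dipolar
magic angle `arctan(1/sqrt 2)`) and beads agglomerate; under the 45-degree
cone it is repulsive and only rare thermal crossings of the repulsive
barrier produce contacts.  "Touching pairs" are counted as bead pairs in
mutual contact (surface gap < 100 nm), which includes contacts inside
larger clusters; isolated-pair/cluster breakdowns are also reported.  A
caveat: once two beads do touch, the model dimer co-rotates with the
in-plane field component and remains bound even at 45 degrees — the
suppression in this model operates by preventing approach, not by breaking
formed dimers.

## What the synthetic data do not capture

Rendered chambers have uniform illumination, monodisperse beads and no
debris; real micrographs need the background subtraction to earn its keep.
The binding model has no kinetics (incubation time, washing) and the
encounter simulation no electrostatics, wall friction, mutual dipolar
induction at contact, or out-of-plane chaining.  Passing tests therefore
demonstrate internal consistency of the pipeline and agreement with the
published operating points, not instrument-grade prediction of a real
chip.

## Problem sizes

Default test and acceptance runs use 5–7 field rotations per transport
measurement, 11–16 track units, frequency grids of 0.1 Hz spacing (coarser
in the test suite), 8–20 random seeds for the encounter comparison, and
200-bead, 10-replicate dose series — sizes at which every headline number
is stable to well within the tolerances quoted alongside it.
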