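# Methods

This note documents the models, estimators, and calibrated defaults behind
`dominoarray`, and what the synthetic data can and cannot say about real
measurements.

## The system

A reconfigurable DNA origami "domino" array is a small lattice of
anti-junctions, four-way motifs with two stable stacked conformations
(*untransformed* and *transformed*) connected through an unstable open
intermediate. Adding trigger strands that hybridise to edge anti-junctions
biases those junctions toward the transformed conformation; the bias then
propagates junction by junction through the array as a diagonal cascade. The
assay follows single surface-immobilised arrays by dual-colour time-lapse
TIRF microscopy: each of two monitored anti-junctions carries a turn-on
probe (fluorophore plus dark quencher) that lights up when its junction
transforms, so a structure's two transients report the transformation times
of two specific positions in the same cascade.

## Lattice model of the cascade

Each anti-junction is a two-state variable on a 2-D occupancy-masked grid.
The configuration energy is

```
E(s) = J * (number of discordant adjacent pairs)
       - sum over active trigger sites i of h_i * s_i
```

Discordant adjacent pairs — neighbouring junctions in opposite
conformations — stand in for the open, strained junctions of transformation
intermediates: the more of them a configuration has, the less stable it is.
Deleted junctions (designs with staples left out) are removed from the
adjacency. Dynamics are continuous-time kinetic Monte Carlo over single-site
flips with Metropolis barriers,

```
k = k0 * exp(-(max(dE, 0) + lock)/RT),
```

where the `lock` term is an extra activation barrier charged only to moves
that take a locked site out of the untransformed conformation (the locking
duplex must be opened first). With no locks and no field the rates satisfy
detailed balance exactly; the test suite verifies the stationary occupancies
of a 2x2 array against Boltzmann weights over 10^6 events. Lock barriers are
purely kinetic: they do not change the energy of either end state, matching
the barrier-engineering reading of the locking mechanism.

### Scenario embedding

All presets share one 14-site staircase mask on a 4x5 grid
(rows `{0-4}, {1-4}, {1-3}, {2,3}`), the package's concrete embedding of the
5 x 2.5-junction array. The five triggers occupy the top row. Monitored
positions are `P1=(1,4)`, `P2=(1,1)`, `P3=(3,3)`, `P4=(2,2)`, `P5=(0,0)`;
the exact coordinates of the experimentally probed positions are not
published, so this map is a documented assumption chosen to reproduce the
observed orderings.

Three structural motifs carry the physics:

* **Start corner** `(0,4)` has a stronger trigger field. Nucleation there is
  the rate-limiting step (barrier `2J - h4`); afterwards the sweep advances
  by interface-neutral or downhill moves at ~`k0`, so positions transform in
  a reproducible order (`P1` first) and quasi-simultaneously at the 1 s
  frame period.
* **Pendant corner** `(0,0)` is the lattice's only coordination-1 site and
  carries the fifth trigger. With the trigger present its transformed state
  is pinned (`J + h_p` to re-open); dropping the trigger (the four-trigger
  condition) leaves it held by a single interface bond (`J`), so it re-opens
  roughly once per 25 min movie — the reversible fluctuations of the
  four-trigger regime. Its closing move is the one flip in the lattice with
  no neighbour assistance, so the open-intermediate barrier is charged
  explicitly (3.5 kcal/mol) rather than absorbed into `k0`; this keeps its
  dark dwells on the ~10 s scale the assay can see.
* **Probe block** `{(2,2),(2,3),(3,2),(3,3)}` is a four-cycle holding `P3`.
  In the unmodified design it fills at `k0` through its two feeder
  junctions. Design 2 adds a lock barrier at `P3` (delay ~150 s). Design 3
  deletes one feeder, gating entry behind a `+J` step (delay several hundred
  seconds, mostly uncoupled). Design 4 deletes all three feeders; every
  flip inside the isolated block then costs at least `2J` ~ 21 RT, so the
  downstream probe never transforms within the observation.

### Calibrated defaults

| parameter | value | role |
|---|---|---|
| `J` | 6.4 kcal/mol | interface penalty per discordant pair |
| `k0` | 20 1/s | attempt rate of neighbour-assisted flips |
| `h` | 7.0 kcal/mol | per-trigger stabilisation (row-0 sites) |
| `h` at `(0,4)` | 7.8 kcal/mol | start-corner bias (asymmetric trigger design) |
| `h` at `(0,0)` | 4.2 kcal/mol | pendant trigger |
| pendant closing barrier | 3.5 kcal/mol | unassisted corner flip |
| design-2 lock | 4.93 kcal/mol | ~150 s lag at `P3` |
| `T` | 310.15 K | measurement temperature (37 C) |

These were calibrated once, before the analysis pipeline was tested, to
realise the study conditions: five-trigger cascades complete with >= 99%
probability inside the 25 min window with median first-position
transformation around three minutes; the four-trigger pendant shows of order
one reversal per movie; the design series orders its fully-coupled fractions
1 > 2 > 3 > 4 with design 4 at zero. `k0 = 20/s` puts the sub-steps of the
sweep well below the 1 s frame period, so transient excursions at the moving
front are invisible at the camera's sampling — matching the clean
single-step transients of the driven regime — while the nucleation barrier
carries the observable timescale.

## Movie rendering

Probes are rendered as pixel-integrated 2-D Gaussians (error-function
photometry) with Poisson photon statistics on a Poisson background, one
16-bit stack per colour. The acquisition geometry follows the experiment:
100 ms exposure, 1 s period per colour, green 0.5 s after red, 25 min total;
a frame's timestamp is the start of its exposure and a frame reports the
conformation at that instant (sub-exposure state changes are not
fractionally integrated). Defaults (180 photons/frame on-state, background
20 photons/px, PSF sigma 1.15/1.05 px) put the peak-pixel amplitude at five
background noise sigmas — the "SNR 5" condition — and the transient-level
separation near six sigmas. Photobleaching is single-step and exponential in
cumulative illuminated on-time (mean 90 s of on-exposure, i.e. ~900 frames);
quencher photobleaching is not simulated. Always-on fiducials, linear stage
drift with optional white jitter, and a translation (optionally affine)
chromatic offset between channels complete the scene. One master seed feeds
a `SeedSequence` tree, so datasets are reproducible bit for bit.

Features of real data deliberately not emulated: dye blinking and
photophysical shot-to-shot brightness variation, non-rigid or
field-dependent chromatic aberration, camera read noise and gain texture,
partial-frame intensity levels at state changes, and surface heterogeneity.
Passing the end-to-end tests therefore shows the pipeline is correct and
well-conditioned at realistic photon budgets, not that it is robust to every
artefact of a real microscope.

## Image analysis

Drift is estimated by re-localising fiducials (band-pass detection on the
temporal median projection, persistence in >= 95% of frames including frame
0, iterative Gaussian-weighted centroids) frame by frame, taking the median
displacement across fiducials, and smoothing with a 9-frame moving average.
Shifts are applied to extraction coordinates; frames are never resampled.
Channel registration is a least-squares affine (translation-only below three
non-collinear pairs) from matched fiducial pairs. Appearing spots are found
by difference-of-Gaussians detection on the pixelwise maximum of time-block
means minus the early-baseline mean — the block maximum keeps spots that
photobleach mid-movie — with candidates already bright in the baseline
(fiducials, pre-transformed structures) excluded; the detection threshold is
5 robust noise sigmas. Transients are disk sums (radius 3 px) minus disk
area times a 3-sigma-clipped annulus mean (5-8 px); the clipped mean is as
robust to neighbour bleed-through as an annulus median but avoids the
median's discreteness bias on integer counts. Red and green spots are paired
by mutual nearest neighbours within 1.5 px after mapping green into red
coordinates.

## Transient analysis

Each transient is fitted separately with a two-state Gaussian-emission HMM
(EM, initialised from a two-means split, tolerance 1e-4 on the
log-likelihood, at most 500 iterations, fixed seed) and decoded by Viterbi;
states are ordered by emission mean. Two guards handle the failure modes of
per-trace EM: a fit whose level separation is below two frame-difference
noise sigmas is declared single-state (EM will happily carve a spurious
~1.5-sigma split out of structureless noise), and transition probabilities
are floored at 0.01 before decoding so a near-static fitted transition
matrix cannot smooth over genuine single-frame excursions.

Rules applied to decoded paths:

* **Transformation time** — the timestamp of the first frame of the first
  dark-to-bright transition followed by at least 10 s of uninterrupted
  bright occupancy (record end counts as occupancy). Single-state paths
  never yield a time.
* **Photobleach** — a terminal bright-to-dark drop persisting to the end of
  the record truncates the path there, so bleaching is never counted as a
  reversal; a drop followed by recovery is a reversal. Bleach truncation
  precedes fluctuation classification.
* **Fluctuating** — at least one bright-to-dark reversal surviving
  truncation.
* **Dual-on filter** — only structures in which both colours turn on enter
  the timing and coupling statistics; the excluded fraction is reported.

## Coupling and timing statistics

The coupling parameter is `C = same / (same + differing)` counted over the
shared frame grid of the two decoded channels, truncated at the earlier
photobleach, after excluding — in either channel — the frame directly before
and directly after every decoded jump (the half-period interleave otherwise
converts every shared jump into one spuriously differing frame). The window
is the full shared record; C is only reported for records containing a
transition. `C > 0.95` is full coupling. Time differences are green minus
red on the common frame grid with the 0.5 s acquisition lag removed, so
simultaneous transformations give exactly zero. Gaussian fits of time
differences are maximum likelihood on the raw values (mean, MLE sigma,
SE = sigma/sqrt(n)), with optional exclusion of exact zeros for designs
where most structures show a delay. Population fractions carry binomial
standard errors; the transformation yield is the percentage of reference
structures whose probes turned on, with a Wilson interval.

## Lock energies and transport efficiency

Lock duplex stabilities are unified nearest-neighbour free energies at 37 C
and 1 M NaCl (stacked-pair terms, per-terminal initiation, self-
complementarity correction; no salt correction). The generator maps a
duplex of stability `|dG|` to a lock barrier `max(0, |dG| - 9.8)` kcal/mol:
the offset is the stability the transformation step can pay, set once so
the simulated 50% transport-efficiency crossing of a 25 min observation
falls near 16 kcal/mol. The transport-efficiency analysis simulates the
lock-design scenario across a ladder of lock sequences, records the
fraction of structures transforming at the downstream position within the
window, and fits a two-parameter falling logistic in `|dG|`; fits are
refused when the data do not bracket the 50% crossing.

## Numerical conventions and edge cases

* Coordinates are 0-based, `x` = column, `y` = row, pixel centres at
  integers; subpixel positions are continuous.
* `t = 0` is trigger addition and the first red frame; green frames are
  offset +0.5 s. Ground-truth comparisons of recovered transformation times
  are made against the dwell rule applied to the *sampled* true
  conformation series, frame for frame, because a sub-frame excursion
  abutting the transformation makes the continuous event time unknowable to
  any decoder of the sampled record.
* Trajectory-level fluctuation counts use reversals occurring *after* the
  qualifying transformation, excluding sub-frame toggles of the advancing
  front that no camera-rate record can show.
* Degenerate inputs raise typed errors (`LatticeConfigError`,
  `OpticsConfigError`, `HmmError`, `CouplingError`, `ScenarioError`) rather
  than returning silent defaults; losing all fiducials or all registration
  pairs degrades to identity transforms with a logged warning.
* Identical run configurations and seeds produce byte-identical outputs;
  every summary embeds a hash of the analysis-relevant configuration.

## Problem sizes

The shipped tests and the acceptance script run the study at desk scale:
50-structure rendered movies (96 x 96 px, 1500 frames per colour) for the
end-to-end recovery, 200 trajectories per preset for the design orderings,
10^6 events for detailed balance, 10^4 runs for the first-passage check,
and 40-60 simulations per point for the transport-efficiency sweep. These
sizes give the comparisons standard errors comfortably inside the asserted
margins while keeping a full run in minutes on one CPU.

## Known limitations

* The lattice is a minimal two-state embedding: no strand-level mechanics,
  no base-pair-resolution opening, no trigger-binding kinetics (the field
  switches on at t = 0; an exponential binding delay can be emulated by
  `trigger_on_time`).
* The position map and the staircase mask are assumptions; only the
  orderings and regimes they produce, not their coordinates, are compared
  with the source experiments.
* The pendant's intrinsic closing barrier is a modelling device for the
  unassisted corner flip; with a single global `J` and pure Metropolis
  barriers, frame-visible corner fluctuations and a thermally pinned
  isolated block cannot otherwise coexist.
* Experimental headline numbers that depend on the deposited raw movies
  (absolute yields, the 198 s position-1-to-3 delay, the printed
  fully-coupled percentages) are mirrored only qualitatively by the
  synthetic presets.
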