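# dominoarray

Single-molecule analysis of allosteric transformation cascades in
reconfigurable DNA origami arrays — from dual-colour turn-on fluorescence
movies to per-structure transformation times, time differences, and the
mechanochemical coupling parameter *C* — together with a physics-based
synthetic-data generator so the whole chain can be exercised end to end with
known ground truth.

## The problem

A DNA origami "domino" array is a lattice of anti-junctions, each switchable
between two stable stacked conformations. Trigger strands bound at one edge
bias the edge junctions toward the transformed conformation, and the change
then propagates junction by junction through the array — an artificial
allosteric cascade. Two turn-on FRET probes (fluorophore + dark quencher) at
chosen positions light up at the moment their junction transforms, so
time-lapse TIRF imaging of single arrays yields, per structure, the
transformation times of two specific cascade steps.

The quantities of interest are, per structure and per design:

* the transformation time of each probed position — the first
  dark-to-bright transition of the HMM-decoded transient that is followed by
  at least 10 s of uninterrupted bright occupancy;
* the time difference `Δt = t_green − t_red` between the two probed
  positions, and Gaussian fits of its distribution per design;
* the coupling parameter
  `C = (frames in the same conformation) / (same + differing)` over the
  shared two-colour record (frames flanking decoded jumps excluded;
  `C > 0.95` counts as fully coupled);
* population fractions (fluctuating structures, fully coupled structures,
  transformation yield) with binomial standard errors;
* for lock-modified designs, the transport efficiency versus lock duplex
  stability (unified nearest-neighbour ΔG°₃₇) and its logistic 50% midpoint.

The package implements this pipeline (drift correction from fiducials,
channel registration, turn-on spot detection, aperture photometry, two-state
HMM dwell analysis, coupling statistics) and a kinetic Monte Carlo lattice
model of the cascade plus a TIRF movie renderer that generate realistic
datasets for every studied condition: five-trigger driven cascades,
the reversible four-trigger regime, and the lock/deletion design series.

## Worked example

Simulate, render, and analyse 20 five-trigger structures:

```
$ domino analyze --preset five_trigger --seed 1 --n-structures 20 --out results_demo
{
 "config_hash": "62859b876acb30ac",
 "counts": {
  "colocalized": 14,
  "coupling_defined": 14,
  "detected_green": 15,
  "detected_red": 15,
  "dual_on_kept": 14,
  "fluctuating": 0,
  "structures_true": 20,
  "transformed_both": 14
 },
 "delta_t_mean_s": 0.42857142857142855,
 "delta_t_se_s": 0.16642353500306215,
 "fluctuating_fraction": 0.0,
 "fluctuating_se": 0.0,
 "fully_coupled_fraction": 1.0,
 "fully_coupled_se": 0.0,
 "preset": "five_trigger",
 "warnings": [],
 "yield_percent": 70.0
}
```

Reading the output: of 20 simulated structures, 15 turned on per colour and
were detected (the rest transformed before a detection baseline existed,
never transformed, or bleached within seconds), 14 red/green spot pairs
colocalized within 1.5 px and had both colours turn on. All kept structures
transformed in both colours with a mean green−red delay of 0.43 ± 0.17 s —
the driven cascade reaches both probed positions quasi-simultaneously at the
1 s frame period — every structure is fully coupled (C > 0.95), and none
fluctuates: the five-trigger transformation is a single irreversible step.
Running the same command with `--preset four_trigger` instead shows a
nonzero fluctuating fraction, and the lock designs
(`lock_design_1` … `lock_design_4`) show growing delays and falling coupling
until design 4, whose downstream position never transforms.

`structures.csv` (per-structure times, Δt, C, fluctuation flags) and
`summary.json` are written to `--out`; `domino render` writes the raw TIFF
stacks plus ground truth, and `domino simulate` the bare cascade
trajectories.

The models, estimators, calibrated defaults, and their limitations are
documented in [`docs/methods.md`](docs/methods.md).

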