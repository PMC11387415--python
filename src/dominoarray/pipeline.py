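"""Run orchestration: simulate -> render -> analyze -> couple -> report.

A :class:`RunConfig` fully determines a run; identical configurations and
seeds produce byte-identical CSV/JSON outputs.  Every analysis output embeds
the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coupling import (
    coupling,
    delta_t,
    fit_gaussian,
    fraction_fluctuating,
    fraction_fully_coupled,
    transformation_yield,
)
from .hmm import analyze_transient, filter_dual_on
from .imaging import (
    DriftTrace,
    detect_appearing_spots,
    detect_fiducials,
    estimate_drift,
    extract_transient,
    pair_colocalized,
    register_channels,
)
from .optics import SyntheticDataset
from .scenarios import PRESETS, ScenarioError, generate_dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    preset: str = "five_trigger"
    seed: int = 0
    n_structures: int = 50
    min_dwell_s: float = 10.0
    colocalization_radius_px: float = 1.5
    detection_nsigma: float = 5.0
    exclude_zero_delta_t: bool = False
    out_dir: str = "results"
    version: str = __version__

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ScenarioError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (I/O paths excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class StructureResult:
    """Per-structure timing, coupling, and fluctuation summary."""

    structure_id: int
    t_red_s: float | None
    t_green_s: float | None
    delta_t_s: float | None
    C: float | None
    fluctuating_red: bool
    fluctuating_green: bool
    kept: bool


@dataclass
class RunReport:
    """Aggregated per-run statistics and filter-chain accounting."""

    preset: str
    config_hash: str
    counts: dict[str, int]
    structures: pd.DataFrame
    delta_t_mean: float | None
    delta_t_se: float | None
    fully_coupled_fraction: float | None
    fully_coupled_se: float | None
    fluctuating_fraction: float | None
    fluctuating_se: float | None
    yield_percent: float | None
    warnings: list[str] = field(default_factory=list)
    hmm_calls: pd.DataFrame | None = None
    spots: pd.DataFrame | None = None
    drift: dict[str, "DriftTrace"] = field(default_factory=dict)

    def summary_dict(self) -> dict:
        return {
            "preset": self.preset,
            "config_hash": self.config_hash,
            "counts": self.counts,
            "delta_t_mean_s": self.delta_t_mean,
            "delta_t_se_s": self.delta_t_se,
            "fully_coupled_fraction": self.fully_coupled_fraction,
            "fully_coupled_se": self.fully_coupled_se,
            "fluctuating_fraction": self.fluctuating_fraction,
            "fluctuating_se": self.fluctuating_se,
            "yield_percent": self.yield_percent,
            "warnings": self.warnings,
        }


def analyze_dataset(dataset: SyntheticDataset, config: RunConfig) -> RunReport:
    """Run the full image-to-statistics chain on one rendered dataset."""
    return analyze_movies(
        dataset.movies,
        inter_channel_lag=dataset.optics.inter_channel_lag,
        config=config,
        scenario=dataset.scenario,
        n_reference=len(dataset.ground_truth),
    )


def analyze_movies(
    movies: dict,
    inter_channel_lag: float,
    config: RunConfig,
    scenario: str = "",
    n_reference: int | None = None,
) -> RunReport:
    """Image-to-statistics chain on a two-channel movie dictionary.

    ``n_reference`` (e.g. the number of reference-dye localised structures,
    or the ground-truth count for synthetic data) enables the
    transformation-yield estimate.
    """
    warnings_log: list[str] = []
    lag = inter_channel_lag

    fiducials = {}
    drift = {}
    for channel, movie in movies.items():
        fids = detect_fiducials(movie, nsigma=config.detection_nsigma)
        if not fids:
            warnings_log.append(f"no fiducials in {channel}; identity drift")
            drift[channel] = DriftTrace.identity(movie.n_frames)
        else:
            drift[channel] = estimate_drift(movie, fids)
        fiducials[channel] = fids

    transform = register_channels(fiducials["red"], fiducials["green"])

    spots = {
        channel: detect_appearing_spots(
            movies[channel], drift[channel], nsigma=config.detection_nsigma
        )
        for channel in movies
    }
    pairs, unpaired_red, unpaired_green = pair_colocalized(
        spots["red"], spots["green"], transform, radius_px=config.colocalization_radius_px
    )

    results: list[StructureResult] = []
    c_values = []
    dts = []
    hmm_rows = []
    for i, (spot_r, spot_g) in enumerate(pairs):
        tr_r = extract_transient(movies["red"], drift["red"], spot_r)
        tr_g = extract_transient(movies["green"], drift["green"], spot_g)
        path_r, call_r, fluct_r = analyze_transient(tr_r, seed=config.seed, min_dwell=config.min_dwell_s)
        path_g, call_g, fluct_g = analyze_transient(tr_g, seed=config.seed, min_dwell=config.min_dwell_s)
        for channel, path, call, fluct in (
            ("red", path_r, call_r, fluct_r),
            ("green", path_g, call_g, fluct_g),
        ):
            hmm_rows.append(
                {
                    "spot_id": i,
                    "channel": channel,
                    "t_transform_s": call.time_s,
                    "fluctuating": fluct,
                    "n_transitions": len(path.transitions()),
                    "bleach_frame": path.truncation_frame,
                    "level_low": path.level_means[0],
                    "level_high": path.level_means[1],
                    "loglik": path.log_likelihood,
                }
            )
        kept = filter_dual_on(tr_r, tr_g, path_r, path_g)
        dt = delta_t(call_r, call_g, green_lag=lag) if kept else None
        cres = coupling(path_r, path_g) if kept else None
        c_val = cres.C if cres is not None else None
        results.append(
            StructureResult(
                structure_id=i,
                t_red_s=call_r.time_s if kept else None,
                t_green_s=call_g.time_s if kept else None,
                delta_t_s=dt,
                C=c_val,
                fluctuating_red=fluct_r if kept else False,
                fluctuating_green=fluct_g if kept else False,
                kept=kept,
            )
        )
        if kept and c_val is not None:
            c_values.append(c_val)
        if dt is not None:
            dts.append(dt)

    kept_results = [r for r in results if r.kept]
    counts = {
        "structures_true": int(n_reference) if n_reference is not None else 0,
        "detected_red": len(spots["red"]),
        "detected_green": len(spots["green"]),
        "colocalized": len(pairs),
        "dual_on_kept": len(kept_results),
        "transformed_both": sum(1 for r in kept_results if r.delta_t_s is not None),
        "fluctuating": sum(
            1 for r in kept_results if r.fluctuating_red or r.fluctuating_green
        ),
        "coupling_defined": len(c_values),
    }

    gfit = fit_gaussian(dts, exclude_zero=config.exclude_zero_delta_t)
    coupled = fraction_fully_coupled(c_values) if c_values else (None, None)
    fluct = (
        fraction_fluctuating(
            [r.fluctuating_red or r.fluctuating_green for r in kept_results]
        )
        if kept_results
        else (None, None)
    )
    yld = (
        transformation_yield(counts["dual_on_kept"], counts["structures_true"])[0]
        if counts["structures_true"]
        else None
    )

    structures_df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    all_spots = [f for ch in fiducials for f in fiducials[ch]] + [
        s for ch in spots for s in spots[ch]
    ]
    spots_df = pd.DataFrame(
        {
            "spot_id": range(len(all_spots)),
            "channel": [s.channel for s in all_spots],
            "x": [s.x for s in all_spots],
            "y": [s.y for s in all_spots],
            "first_frame": [s.first_frame for s in all_spots],
            "is_fiducial": [s.is_fiducial for s in all_spots],
        }
    )
    return RunReport(
        preset=scenario or config.preset,
        config_hash=config.config_hash(),
        counts=counts,
        structures=structures_df,
        delta_t_mean=gfit.mean if gfit else None,
        delta_t_se=gfit.se if gfit else None,
        fully_coupled_fraction=coupled[0],
        fully_coupled_se=coupled[1],
        fluctuating_fraction=fluct[0],
        fluctuating_se=fluct[1],
        yield_percent=yld,
        warnings=warnings_log,
        hmm_calls=pd.DataFrame(hmm_rows),
        spots=spots_df,
        drift=drift,
    )


def run_end_to_end(config: RunConfig, write_outputs: bool = True) -> RunReport:
    """Simulate, render, and analyze one preset; optionally write outputs."""
    if config.preset not in PRESETS:
        raise ScenarioError(f"unknown preset {config.preset!r}")
    dataset = generate_dataset(config.preset, seed=config.seed, n_structures=config.n_structures)
    report = analyze_dataset(dataset, config)
    if write_outputs:
        write_report(report, config.out_dir)
    return report


def write_report(report: RunReport, out_dir: str | Path) -> None:
    """Write the fixed file contract: structures, HMM calls, spots, drift."""
    from .io import write_drift

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.structures.to_csv(out / "structures.csv", index=False, float_format="%.4f")
    if report.hmm_calls is not None:
        report.hmm_calls.to_csv(out / "hmm_calls.csv", index=False, float_format="%.4f")
    if report.spots is not None:
        report.spots.to_csv(out / "spots.csv", index=False, float_format="%.4f")
    for channel, trace in report.drift.items():
        write_drift(trace, out / f"drift_{channel}.csv")
    (out / "summary.json").write_text(
        json.dumps(report.summary_dict(), sort_keys=True, indent=1)
    )


def transport_efficiency_sweep(
    n_per_point: int = 60,
    seed: int = 0,
    duration: float = 1500.0,
) -> tuple[float, float, pd.DataFrame]:
    """Transport efficiency versus lock hybridisation energy.

    For each lock duplex in the ladder, the lock-design model is simulated
    ``n_per_point`` times and the fraction of structures transforming at the
    downstream probe within the observation window is recorded against the
    duplex nearest-neighbour free energy (magnitude).  Returns the logistic
    50% midpoint, its fit standard error, and the point table.
    """
    from .coupling import nn_hybridization_energy, transport_efficiency_fit
    from .lattice import simulate_cascade, transformation_time_true
    from .scenarios import LOCK_SEQUENCES, POSITIONS, lock_energy_sweep_model

    ss = np.random.SeedSequence((seed, 0xBEEF))
    rows = []
    for seq, child in zip(LOCK_SEQUENCES, ss.spawn(len(LOCK_SEQUENCES))):
        dg = abs(nn_hybridization_energy(seq))
        model = lock_energy_sweep_model(dg)
        seeds = child.generate_state(n_per_point)
        n_ok = sum(
            transformation_time_true(
                simulate_cascade(model, duration, int(s) % (2**31 - 1)),
                POSITIONS["P3"],
            )
            is not None
            for s in seeds
        )
        rows.append({"sequence": seq, "dg_kcal": dg, "fraction": n_ok / n_per_point})
    table = pd.DataFrame(rows).sort_values("dg_kcal").reset_index(drop=True)
    mid, se = transport_efficiency_fit(table[["dg_kcal", "fraction"]].to_numpy())
    return mid, se, table


def compare_designs(reports: list[RunReport]) -> pd.DataFrame:
    """Aligned per-design table of timing and coupling metrics."""
    if not reports:
        raise PipelineError("need at least one report to compare")
    rows = []
    for r in reports:
        rows.append(
            {
                "preset": r.preset,
                "n_kept": r.counts.get("dual_on_kept", np.nan),
                "delta_t_mean_s": r.delta_t_mean,
                "delta_t_se_s": r.delta_t_se,
                "fully_coupled_fraction": r.fully_coupled_fraction,
                "fully_coupled_se": r.fully_coupled_se,
                "fluctuating_fraction": r.fluctuating_fraction,
            }
        )
    return pd.DataFrame(rows)
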