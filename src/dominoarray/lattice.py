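"""Energy-landscape model of a reconfigurable DNA origami anti-junction array.

The array is modelled as a small 2-D lattice of two-state units.  Each site
represents one anti-junction that is either *untransformed* (0) or
*transformed* (1).  Neighbouring anti-junctions that disagree form a strained
interface: the instability of a transformation intermediate grows with the
number of such discordant pairs, which plays the role of the number of open
anti-junctions in the cascade.  Trigger strands bound at edge sites act as a
static field stabilising the transformed conformation of those sites.

Dynamics are continuous-time kinetic Monte Carlo over single-site flips with
Metropolis-style barriers, ``k = k0 * exp(-(max(dE, 0) + lock)/RT)``, where the
lock term is an extra activation barrier charged only to moves that take a
locked site out of the untransformed conformation (a hybridised locking
duplex must be opened first).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

UNTRANSFORMED = 0
TRANSFORMED = 1

#: Gas constant in kcal/(mol*K).
R_KCAL = 1.987204259e-3

Site = tuple[int, int]


class LatticeConfigError(ValueError):
    """Raised for inconsistent lattice model definitions."""


def default_grid_mask(n_rows: int = 3, n_cols: int = 5) -> np.ndarray:
    """Occupancy mask for the default array (5 x 2.5 anti-junctions).

    Rows 0 and 1 are full; the trailing half row keeps its central sites so
    the mask is left-right symmetric.
    """
    mask = np.ones((n_rows, n_cols), dtype=bool)
    if n_rows >= 2:
        mask[n_rows - 1, :] = False
        n_half = n_cols // 2 + 1  # 3 of 5
        lo = (n_cols - n_half) // 2
        mask[n_rows - 1, lo : lo + n_half] = True
    return mask


@dataclass(frozen=True)
class LatticeModel:
    """Energetic and kinetic description of the anti-junction array.

    Parameters
    ----------
    grid:
        Boolean occupancy mask, shape ``(n_rows, n_cols)``.  ``True`` marks a
        site that exists in the design (before deletions).
    J:
        Interface penalty per discordant adjacent pair, kcal/mol.
    trigger_sites:
        Edge sites carrying the trigger bias field.
    h:
        Per-trigger stabilisation of the transformed conformation, kcal/mol.
        ``trigger_h`` may override the value at individual sites (the
        asymmetric trigger design uses a stronger field at the start corner).
    trigger_on_time:
        Time (s) at which the trigger field switches on.
    lock_barriers:
        Extra activation barrier (kcal/mol) charged to moves flipping the
        keyed site out of the untransformed conformation.
    removed_sites:
        Deleted anti-junctions (staples left out); excluded from adjacency.
    k0:
        Attempt rate, 1/s.
    temperature:
        K.
    """

    grid: np.ndarray
    J: float
    trigger_sites: tuple[Site, ...] = ()
    h: float = 0.0
    trigger_h: Mapping[Site, float] = field(default_factory=dict)
    trigger_on_time: float = 0.0
    lock_barriers: Mapping[Site, float] = field(default_factory=dict)
    removed_sites: frozenset[Site] = frozenset()
    k0: float = 1.0
    temperature: float = 310.15

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=bool)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "trigger_sites", tuple(tuple(s) for s in self.trigger_sites))
        object.__setattr__(self, "removed_sites", frozenset(tuple(s) for s in self.removed_sites))
        object.__setattr__(self, "trigger_h", {tuple(k): float(v) for k, v in dict(self.trigger_h).items()})
        object.__setattr__(self, "lock_barriers", {tuple(k): float(v) for k, v in dict(self.lock_barriers).items()})
        if grid.ndim != 2:
            raise LatticeConfigError("grid mask must be 2-D")
        if self.J < 0:
            raise LatticeConfigError("interface penalty J must be >= 0")
        if self.k0 <= 0:
            raise LatticeConfigError("attempt rate k0 must be > 0")
        if self.temperature <= 0:
            raise LatticeConfigError("temperature must be > 0")
        for s in self.trigger_sites:
            if not self._in_grid(s):
                raise LatticeConfigError(f"trigger site {s} is not on the grid")
        if self.removed_sites & set(self.trigger_sites):
            raise LatticeConfigError("removed sites may not carry triggers")
        for s in self.removed_sites:
            if not self._in_grid(s):
                raise LatticeConfigError(f"removed site {s} is not on the grid")
        for s, b in self.lock_barriers.items():
            if b < 0:
                raise LatticeConfigError("lock barriers must be >= 0")
            if not self._in_grid(s):
                raise LatticeConfigError(f"locked site {s} is not on the grid")

    # -- geometry -----------------------------------------------------------

    def _in_grid(self, site: Site) -> bool:
        r, c = site
        return 0 <= r < self.grid.shape[0] and 0 <= c < self.grid.shape[1] and bool(self.grid[r, c])

    @property
    def active_sites(self) -> tuple[Site, ...]:
        """Sites that exist and were not deleted, row-major order."""
        return tuple(
            (r, c)
            for r in range(self.grid.shape[0])
            for c in range(self.grid.shape[1])
            if self.grid[r, c] and (r, c) not in self.removed_sites
        )

    def neighbors(self, site: Site) -> tuple[Site, ...]:
        r, c = site
        out = []
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if self._in_grid((rr, cc)) and (rr, cc) not in self.removed_sites:
                out.append((rr, cc))
        return tuple(out)

    @property
    def rt(self) -> float:
        """Thermal energy RT in kcal/mol."""
        return R_KCAL * self.temperature

    def field_at(self, site: Site) -> float:
        """Trigger stabilisation (kcal/mol) of the transformed state at *site*."""
        if site not in set(self.trigger_sites):
            return 0.0
        return self.trigger_h.get(site, self.h)


@dataclass(frozen=True)
class LatticeTrajectory:
    """Event record of one kinetic Monte Carlo run.

    ``events`` is an ordered list of ``(time_s, site, new_state)``; the run
    starts from the all-untransformed configuration.
    """

    events: tuple[tuple[float, Site, int], ...]
    duration: float
    seed: int
    model: LatticeModel

    def __post_init__(self):
        times = [e[0] for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise LatticeConfigError("event times must be strictly increasing")

    def state_at(self, t: float) -> dict[Site, int]:
        """Configuration after all events with time <= t."""
        state = {s: UNTRANSFORMED for s in self.model.active_sites}
        for et, site, new in self.events:
            if et > t:
                break
            state[site] = new
        return state

    def final_state(self) -> dict[Site, int]:
        return self.state_at(self.duration)


def _check_state(model: LatticeModel, state: np.ndarray) -> np.ndarray:
    arr = np.asarray(state)
    if arr.shape != model.grid.shape:
        raise LatticeConfigError(
            f"state shape {arr.shape} does not match grid {model.grid.shape}"
        )
    return arr


def configuration_energy(model: LatticeModel, state: np.ndarray, field_on: bool = True) -> float:
    """Energy (kcal/mol) of a configuration.

    ``J`` times the number of discordant adjacent pairs (adjacency excluding
    removed sites), minus the trigger stabilisation of every trigger site in
    the transformed conformation while the field is active.
    """
    arr = _check_state(model, state)
    energy = 0.0
    seen = set()
    for site in model.active_sites:
        for nb in model.neighbors(site):
            pair = (site, nb) if site < nb else (nb, site)
            if pair in seen:
                continue
            seen.add(pair)
            if arr[site] != arr[nb]:
                energy += model.J
    if field_on:
        for site in model.trigger_sites:
            if arr[site] == TRANSFORMED:
                energy -= model.field_at(site)
    return energy


def flip_rate(model: LatticeModel, state: np.ndarray, site: Site, field_on: bool = True) -> float:
    """Rate of flipping *site* in *state* under the Metropolis barrier rule."""
    arr = _check_state(model, state)
    if site not in set(model.active_sites):
        raise LatticeConfigError(f"site {site} is removed or outside the grid")
    spin = arr[site]
    n_agree = sum(1 for nb in model.neighbors(site) if arr[nb] == spin)
    n_disagree = len(model.neighbors(site)) - n_agree
    d_e = model.J * (n_agree - n_disagree)
    if field_on and site in set(model.trigger_sites):
        d_e += model.field_at(site) if spin == TRANSFORMED else -model.field_at(site)
    barrier = max(d_e, 0.0)
    if spin == UNTRANSFORMED and site in model.lock_barriers:
        barrier += model.lock_barriers[site]
    rate = model.k0 * np.exp(-barrier / model.rt)
    if not np.isfinite(rate):
        raise LatticeConfigError("non-finite flip rate; check model parameters")
    return float(rate)


def simulate_cascade(
    model: LatticeModel,
    duration: float,
    seed: int,
    max_events: int = 2_000_000,
) -> LatticeTrajectory:
    """Continuous-time kinetic Monte Carlo over single-site flips.

    The trigger field is off before ``model.trigger_on_time`` and on after.
    Reproducible from *seed*.
    """
    if duration <= 0:
        raise LatticeConfigError("duration must be > 0")
    rng = np.random.default_rng(seed)
    sites = model.active_sites
    index = {s: i for i, s in enumerate(sites)}
    nbs = [tuple(index[n] for n in model.neighbors(s)) for s in sites]
    spins = np.zeros(len(sites), dtype=np.int8)
    h_vec = np.array([model.field_at(s) for s in sites])
    lock_vec = np.array([model.lock_barriers.get(s, 0.0) for s in sites])
    j = model.J
    rt = model.rt
    k0 = model.k0

    def rate_of(i: int, field_on: bool) -> float:
        spin = spins[i]
        n_agree = sum(1 for n in nbs[i] if spins[n] == spin)
        d_e = j * (2 * n_agree - len(nbs[i]))
        if field_on and h_vec[i] != 0.0:
            d_e += h_vec[i] if spin == TRANSFORMED else -h_vec[i]
        barrier = max(d_e, 0.0)
        if spin == UNTRANSFORMED:
            barrier += lock_vec[i]
        return k0 * np.exp(-barrier / rt)

    t = 0.0
    field_on = model.trigger_on_time <= 0.0
    rates = np.array([rate_of(i, field_on) for i in range(len(sites))])
    events: list[tuple[float, Site, int]] = []
    while t < duration and len(events) < max_events:
        total = rates.sum()
        if not np.isfinite(total):
            raise LatticeConfigError("non-finite total rate during simulation")
        if total <= 0.0:
            if not field_on:
                t = model.trigger_on_time
                field_on = True
                rates = np.array([rate_of(i, True) for i in range(len(sites))])
                continue
            break
        dt = rng.exponential(1.0 / total)
        if not field_on and t + dt >= model.trigger_on_time:
            t = model.trigger_on_time
            field_on = True
            rates = np.array([rate_of(i, True) for i in range(len(sites))])
            continue
        t = t + dt
        if t >= duration:
            break
        i = rng.choice(len(sites), p=rates / total)
        spins[i] = 1 - spins[i]
        events.append((t, sites[i], int(spins[i])))
        rates[i] = rate_of(i, field_on)
        for n in nbs[i]:
            rates[n] = rate_of(n, field_on)
    return LatticeTrajectory(events=tuple(events), duration=duration, seed=seed, model=model)


def junction_state_series(
    traj: LatticeTrajectory,
    site: Site,
    frame_times: Sequence[float],
) -> np.ndarray:
    """Piecewise-constant sampling of one site's conformation at frame times.

    A frame at time ``t`` reflects every event with time <= ``t``.
    """
    site = tuple(site)
    if site in traj.model.removed_sites or not traj.model._in_grid(site):
        raise LatticeConfigError(f"site {site} is removed or outside the grid")
    times = np.asarray(frame_times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise LatticeConfigError("frame_times must be sorted")
    ev = [(t, new) for t, s, new in traj.events if s == site]
    out = np.full(times.shape, UNTRANSFORMED, dtype=np.int8)
    state = UNTRANSFORMED
    k = 0
    for idx, ft in enumerate(times):
        while k < len(ev) and ev[k][0] <= ft:
            state = ev[k][1]
            k += 1
        out[idx] = state
    return out


def transformation_time_true(
    traj: LatticeTrajectory,
    site: Site,
    min_dwell: float = 10.0,
) -> float | None:
    """Ground-truth transformation time of *site*.

    First untransformed->transformed event followed by at least ``min_dwell``
    seconds of uninterrupted transformed occupancy (the record end counts as
    occupancy), mirroring the dwell rule applied to measured state paths.
    """
    site = tuple(site)
    ev = [(t, new) for t, s, new in traj.events if s == site]
    for i, (t, new) in enumerate(ev):
        if new != TRANSFORMED:
            continue
        t_next = ev[i + 1][0] if i + 1 < len(ev) else traj.duration
        if t_next - t >= min_dwell:
            return t
    return None


def n_reversals(traj: LatticeTrajectory, site: Site) -> int:
    """Number of transformed->untransformed events at *site*."""
    site = tuple(site)
    return sum(1 for _, s, new in traj.events if s == site and new == UNTRANSFORMED)


def n_reversals_after_transform(
    traj: LatticeTrajectory,
    site: Site,
    min_dwell: float = 10.0,
) -> int:
    """Reversals of *site* after its qualifying transformation.

    Counts transformed->untransformed events later than the ground-truth
    transformation time (dwell rule as in
    :func:`transformation_time_true`); returns 0 when the site never
    qualifies.  Sub-second excursions before the transformation proper are
    thereby excluded, mirroring what a fluctuation call on a measured
    transient can see.
    """
    t0 = transformation_time_true(traj, site, min_dwell=min_dwell)
    if t0 is None:
        return 0
    site = tuple(site)
    return sum(
        1 for t, s, new in traj.events if s == site and new == UNTRANSFORMED and t > t0
    )


def mean_first_passage_to_full(
    model: LatticeModel,
    n_runs: int,
    seed: int,
    t_max: float,
) -> np.ndarray:
    """First-passage times to the all-transformed configuration.

    Returns an array of length ``n_runs``; censored runs carry ``np.inf``.
    """
    out = np.full(n_runs, np.inf)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_runs)
    n_sites = len(model.active_sites)
    for i in range(n_runs):
        traj = simulate_cascade(model, t_max, int(seeds[i]) % (2**31 - 1))
        n_up = 0
        for t, _, new in traj.events:
            n_up += 1 if new == TRANSFORMED else -1
            if n_up == n_sites:
                out[i] = t
                break
    return out
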