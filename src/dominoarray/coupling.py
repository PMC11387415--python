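"""Coupling parameter C, transformation-time differences, and population
statistics.

The coupling parameter compares the time two monitored anti-junctions spend
in the same conformation with the time they spend in differing
conformations: ``C = same / (same + differing)`` over the frames of the
shared two-colour record, truncated at the earlier photobleach.  Because
the two colours are acquired with a half-period lag, the frame directly
before and directly after every decoded intensity jump is excluded in both
channels so that interleaving alone cannot weaken the coupling.  C = 1 is a
maximally coupled pair; structures with C above 0.95 are considered fully
coupled.

Also here: Gaussian fits of time-difference distributions (maximum
likelihood on the raw values, not histogram least squares), binomial
population fractions, the transformation yield, unified nearest-neighbour
duplex free energies for the lock-strength analysis, and the logistic
transport-efficiency fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .hmm import StatePath, TransformationCall

FULL_COUPLING_THRESHOLD = 0.95


class CouplingError(ValueError):
    pass


@dataclass(frozen=True)
class CouplingResult:
    C: float
    n_same: int
    n_differing: int
    n_excluded: int
    window_s: float

    def __post_init__(self):
        if not (0.0 <= self.C <= 1.0):
            raise CouplingError("C must lie in [0, 1]")

    @property
    def n_window(self) -> int:
        return self.n_same + self.n_differing + self.n_excluded


@dataclass(frozen=True)
class GaussianFit:
    mean: float
    sigma: float
    se: float
    n: int
    degenerate: bool = False
    zero_excluded: bool = False


def _jump_exclusion(states: np.ndarray) -> np.ndarray:
    """Mask of frames flanking any transition (last old + first new frame)."""
    s = np.asarray(states, dtype=int)
    excl = np.zeros(len(s), dtype=bool)
    jumps = np.flatnonzero(np.diff(s) != 0)
    excl[jumps] = True          # last frame of the old level
    excl[jumps + 1] = True      # first frame of the new level
    return excl


def coupling(path_red: StatePath, path_green: StatePath) -> CouplingResult | None:
    """Coupling parameter for one structure's two decoded channels.

    Channels are aligned on the shared frame grid (the green frame acquired
    half a period after red frame *i* pairs with red frame *i*).  Both paths
    are truncated at the earlier photobleach; frames flanking any transition
    in either channel are excluded.  Returns ``None`` (structure dropped,
    e.g. from coupling histograms) when no counted frame remains.
    """
    s_r = path_red.effective_states.astype(int)
    s_g = path_green.effective_states.astype(int)
    n = min(len(s_r), len(s_g))
    if n == 0:
        return None
    s_r, s_g = s_r[:n], s_g[:n]
    excl = _jump_exclusion(s_r)[:n] | _jump_exclusion(s_g)[:n]
    same = int(np.sum((s_r == s_g) & ~excl))
    diff = int(np.sum((s_r != s_g) & ~excl))
    t = path_red.effective_times[:n]
    window = float(t[-1] - t[0]) if n > 1 else 0.0
    if same + diff == 0:
        return None
    return CouplingResult(
        C=same / (same + diff),
        n_same=same,
        n_differing=diff,
        n_excluded=int(excl.sum()),
        window_s=window,
    )


def fraction_fully_coupled(
    c_values, threshold: float = FULL_COUPLING_THRESHOLD
) -> tuple[float, float]:
    """Fraction of structures with C > threshold, with binomial SE."""
    c = np.asarray([v for v in c_values if v is not None], dtype=float)
    if len(c) == 0:
        raise CouplingError("need at least one defined C value")
    p = float(np.mean(c > threshold))
    se = float(np.sqrt(p * (1 - p) / len(c)))
    return p, se


def delta_t(
    call_red: TransformationCall,
    call_green: TransformationCall,
    green_lag: float = 0.0,
) -> float | None:
    """Signed time difference green minus red on the shared frame grid.

    ``green_lag`` removes the inter-channel acquisition offset so that
    simultaneous transformations give exactly zero.  ``None`` when either
    channel has no transformation call (the structure is then counted in
    the no-transformation tally, not in the time-difference statistics).
    """
    if call_red.time_s is None or call_green.time_s is None:
        return None
    return float((call_green.time_s - green_lag) - call_red.time_s)


def fit_gaussian(values, exclude_zero: bool = False) -> GaussianFit | None:
    """Maximum-likelihood Gaussian fit (sample mean and sigma, SE = sigma/sqrt(n)).

    With ``exclude_zero`` set, exact zeros (perfectly coupled structures)
    are removed first, as done for designs where most structures show a
    time delay.  Returns ``None`` when fewer than two values remain.
    """
    v = np.asarray([x for x in values if x is not None], dtype=float)
    if exclude_zero:
        v = v[v != 0.0]
    if len(v) < 2:
        return None
    mean = float(np.mean(v))
    sigma = float(np.std(v))  # MLE (ddof=0)
    return GaussianFit(
        mean=mean,
        sigma=sigma,
        se=sigma / np.sqrt(len(v)),
        n=len(v),
        degenerate=sigma == 0.0,
        zero_excluded=exclude_zero,
    )


def fraction_fluctuating(flags) -> tuple[float, float]:
    """Fraction of fluctuating structures with binomial standard error."""
    f = np.asarray(list(flags), dtype=bool)
    if len(f) == 0:
        raise CouplingError("need at least one structure")
    p = float(np.mean(f))
    return p, float(np.sqrt(p * (1 - p) / len(f)))


def transformation_yield(
    n_turned_on_colocalized: int, n_reference: int, z: float = 1.96
) -> tuple[float, tuple[float, float]]:
    """Transformation yield in percent with a binomial (Wilson) CI."""
    if n_reference <= 0:
        raise CouplingError("reference count must be positive")
    if n_turned_on_colocalized > n_reference:
        raise CouplingError("turned-on count cannot exceed the reference count")
    p = n_turned_on_colocalized / n_reference
    denom = 1 + z**2 / n_reference
    centre = (p + z**2 / (2 * n_reference)) / denom
    half = (
        z
        * np.sqrt(p * (1 - p) / n_reference + z**2 / (4 * n_reference**2))
        / denom
    )
    return 100.0 * p, (100.0 * (centre - half), 100.0 * (centre + half))


# --- nearest-neighbour duplex thermodynamics -------------------------------

#: Unified nearest-neighbour free energies dG(37 C) in kcal/mol at 1 M NaCl,
#: keyed by the 5'->3' top-strand dinucleotide.
NN_DG37 = {
    "AA": -1.00, "TT": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45, "TG": -1.45,
    "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28,
    "GA": -1.30, "TC": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84, "CC": -1.84,
}
#: Duplex initiation per terminal base pair.
NN_INIT_GC = 0.98
NN_INIT_AT = 1.03
#: Symmetry correction for self-complementary duplexes.
NN_SYMMETRY = 0.43

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def nn_hybridization_energy(sequence: str) -> float:
    """Unified nearest-neighbour duplex dG(37 C) in kcal/mol.

    Sum of stacked-pair parameters plus one initiation term per terminal
    base pair plus the symmetry correction for self-complementary duplexes.
    Parameters are the unified set at 1 M NaCl; no salt correction is
    applied.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise CouplingError("duplex must be at least two bases long")
    if set(seq) - set("ACGT"):
        raise CouplingError(f"non-ACGT characters in sequence {sequence!r}")
    dg = sum(NN_DG37[seq[i : i + 2]] for i in range(len(seq) - 1))
    for base in (seq[0], seq[-1]):
        dg += NN_INIT_GC if base in "GC" else NN_INIT_AT
    if seq == _revcomp(seq):
        dg += NN_SYMMETRY
    return float(dg)


def transport_efficiency_fit(points) -> tuple[float, float]:
    """Midpoint of a two-parameter logistic through (dG, transformed fraction).

    ``points`` is an iterable of ``(dG_kcal, fraction)``; the fraction of
    structures transforming downstream falls with increasing lock
    hybridisation energy.  Returns the 50% efficiency energy and its fit
    standard error.  Points must bracket the 50% crossing; extrapolation is
    refused.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise CouplingError("need at least three (dG, fraction) points")
    x, y = pts[:, 0], pts[:, 1]
    if not (y.min() < 0.5 < y.max()):
        raise CouplingError("fractions do not bracket 50%; refusing to extrapolate")

    def logistic(xx, x0, w):
        return 1.0 / (1.0 + np.exp((xx - x0) / w))

    x0_guess = float(x[np.argmin(np.abs(y - 0.5))])
    popt, pcov = curve_fit(
        logistic, x, y, p0=[x0_guess, 1.0], maxfev=10000
    )
    se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.nan
    return float(popt[0]), se
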