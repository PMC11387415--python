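"""Two-level hidden Markov analysis of turn-on fluorescence transients.

Each background-subtracted transient is fitted per-trace with a two-state
Gaussian-emission HMM (expectation-maximisation, initialised from a
two-means split of the intensities) and decoded by Viterbi.  The low state
is the quenched/untransformed level, the high state the transformed level.
Downstream calls implement the dwell rules: the transformation time is the
first low-to-high transition followed by an uninterrupted high dwell of at
least ``min_dwell`` seconds, a terminal high-to-low drop that persists to
the end of the record is photobleaching (the path is truncated there so
bleaching never counts as a reversal), and a structure is fluctuating if
any high-to-low reversal survives truncation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .imaging import Transient

logger = logging.getLogger(__name__)

UNTRANSFORMED = 0
TRANSFORMED = 1

#: EM convergence tolerance on the log-likelihood and iteration cap.
EM_TOL = 1e-4
EM_MAX_ITER = 500
#: Levels closer than this many noise sigmas are a degenerate fit.  The
#: noise sigma comes from frame-to-frame differences (insensitive to steps);
#: two sigmas are required because expectation-maximisation happily carves a
#: spurious ~1.5-sigma split out of structureless noise.
MIN_SEPARATION_SIGMA = 2.0
#: Transition probabilities are floored before decoding so that a fitted
#: near-static transition matrix cannot smooth over genuine single-frame
#: level changes.
TRANSITION_FLOOR = 0.01


class HmmError(ValueError):
    pass


@dataclass(frozen=True)
class StatePath:
    """Viterbi-decoded two-level trajectory for one transient."""

    times: np.ndarray
    states: np.ndarray            # 0 = untransformed/dark, 1 = transformed
    level_means: tuple[float, float]
    level_vars: tuple[float, float]
    log_likelihood: float
    degenerate: bool = False
    truncation_frame: int | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=np.int8)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)
        if len(t) != len(s):
            raise HmmError("times and states must have equal length")

    @property
    def effective_states(self) -> np.ndarray:
        """States up to the photobleach truncation."""
        if self.truncation_frame is None:
            return self.states
        return self.states[: self.truncation_frame]

    @property
    def effective_times(self) -> np.ndarray:
        if self.truncation_frame is None:
            return self.times
        return self.times[: self.truncation_frame]

    def transitions(self) -> list[int]:
        """Frame indices that are the first frame of a new level."""
        s = self.states
        return [int(i) for i in np.flatnonzero(np.diff(s.astype(int)) != 0) + 1]


@dataclass(frozen=True)
class TransformationCall:
    """The dwell-qualified transformation time of one channel, if any."""

    time_s: float | None
    dwell_s: float | None
    channel: str


def robust_noise_sigma(values: np.ndarray) -> float:
    """Per-frame noise level from first differences, insensitive to steps."""
    d = np.diff(np.asarray(values, dtype=float))
    mad = 1.4826 * float(np.median(np.abs(d - np.median(d))))
    return mad / np.sqrt(2.0) if mad > 0 else float(np.std(d) / np.sqrt(2.0) or 1.0)


def _two_means_split(values: np.ndarray) -> tuple[float, float]:
    """Initial level means from a two-means split of the intensities."""
    lo, hi = np.min(values), np.max(values)
    if lo == hi:
        return float(lo), float(hi + 1.0)
    c = np.array([lo, hi], dtype=float)
    for _ in range(50):
        assign = np.abs(values[:, None] - c[None, :]).argmin(axis=1)
        new = np.array(
            [values[assign == k].mean() if np.any(assign == k) else c[k] for k in (0, 1)]
        )
        if np.allclose(new, c):
            break
        c = new
    return float(c[0]), float(c[1])


def fit_two_state_hmm(transient: Transient, seed: int = 0) -> StatePath:
    """Fit and Viterbi-decode the two-level model for one transient.

    States are ordered by emission mean.  A fit whose level separation falls
    below :data:`MIN_SEPARATION_SIGMA` frame-difference noise sigmas is
    declared single-state at the dominant level and flagged degenerate.
    """
    y = np.asarray(transient.intensities, dtype=float)
    if len(y) < 10:
        raise HmmError("need at least 10 frames to fit the two-state model")
    if not np.all(np.isfinite(y)):
        raise HmmError("transient intensities must be finite")
    m_lo, m_hi = _two_means_split(y)
    spread = np.var(y[y <= (m_lo + m_hi) / 2]) + np.var(y[y > (m_lo + m_hi) / 2])
    var0 = max(spread / 2, 1e-6 * max(1.0, (m_hi - m_lo) ** 2), 1e-12)
    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        n_iter=EM_MAX_ITER,
        tol=EM_TOL,
        init_params="",
        params="stmc",
        random_state=seed,
        min_covar=1e-8,
    )
    model.startprob_ = np.array([0.95, 0.05])
    model.transmat_ = np.array([[0.99, 0.01], [0.01, 0.99]])
    model.means_ = np.array([[m_lo], [m_hi]])
    model.covars_ = np.array([[var0], [var0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(y[:, None])
        tm = np.clip(model.transmat_, TRANSITION_FLOOR, None)
        model.transmat_ = tm / tm.sum(axis=1, keepdims=True)
        loglik, states = model.decode(y[:, None])
    means = model.means_.ravel()
    variances = model.covars_.ravel()
    order = np.argsort(means)
    states = np.argsort(order)[states]
    means = means[order]
    variances = variances[order]
    sigma = robust_noise_sigma(y)
    if means[1] - means[0] < MIN_SEPARATION_SIGMA * sigma:
        occupancy = np.bincount(states, minlength=2)
        dominant = int(np.argmax(occupancy))
        return StatePath(
            times=transient.times,
            states=np.full(len(y), dominant, dtype=np.int8),
            level_means=(float(means[0]), float(means[1])),
            level_vars=(float(variances[0]), float(variances[1])),
            log_likelihood=float(loglik),
            degenerate=True,
        )
    return StatePath(
        times=transient.times,
        states=states.astype(np.int8),
        level_means=(float(means[0]), float(means[1])),
        level_vars=(float(variances[0]), float(variances[1])),
        log_likelihood=float(loglik),
    )


def viterbi_path(
    observations: np.ndarray,
    startprob: np.ndarray,
    transmat: np.ndarray,
    means: np.ndarray,
    variances: np.ndarray,
) -> np.ndarray:
    """Viterbi decoding for fixed two-state Gaussian-emission parameters.

    Convenience wrapper used to compare against exhaustive enumeration.
    """
    model = GaussianHMM(n_components=2, covariance_type="diag", init_params="", params="")
    model.startprob_ = np.asarray(startprob, dtype=float)
    model.transmat_ = np.asarray(transmat, dtype=float)
    model.means_ = np.asarray(means, dtype=float).reshape(2, 1)
    model.covars_ = np.asarray(variances, dtype=float).reshape(2, 1)
    _, states = model.decode(np.asarray(observations, dtype=float).reshape(-1, 1))
    return states


def transformation_time(path: StatePath, min_dwell: float = 10.0) -> TransformationCall:
    """First low-to-high transition followed by >= ``min_dwell`` s high dwell.

    The transition frame is the first frame at the new level and its time is
    that frame's timestamp.  Dwell occupancy must be uninterrupted; the end
    of the (truncated) record counts as continuing occupancy.  Single-state
    paths never yield a transformation time.
    """
    if path.degenerate:
        return TransformationCall(time_s=None, dwell_s=None, channel="")
    s = path.effective_states.astype(int)
    t = path.effective_times
    if len(s) == 0:
        return TransformationCall(time_s=None, dwell_s=None, channel="")
    end_time = t[-1] + (t[-1] - t[-2] if len(t) > 1 else 0.0)
    i = 0
    while i < len(s):
        if s[i] == TRANSFORMED and (i == 0 or s[i - 1] == UNTRANSFORMED):
            j = i
            while j < len(s) and s[j] == TRANSFORMED:
                j += 1
            dwell = (t[j] if j < len(s) else end_time) - t[i]
            if i > 0 and dwell >= min_dwell:
                return TransformationCall(time_s=float(t[i]), dwell_s=float(dwell), channel="")
            i = j
        else:
            i += 1
    return TransformationCall(time_s=None, dwell_s=None, channel="")


def detect_bleach(transient: Transient, path: StatePath, min_dark: int = 5) -> int | None:
    """Photobleach truncation frame, if the record ends dark.

    A terminal drop from the high level to the low level that persists to
    the end of the record (at least ``min_dark`` frames) is labelled
    photobleaching; a drop followed by recovery is a reversal, not bleach.
    """
    s = path.states.astype(int)
    if len(s) == 0 or s[-1] != UNTRANSFORMED:
        return None
    i = len(s)
    while i > 0 and s[i - 1] == UNTRANSFORMED:
        i -= 1
    if i == 0:
        return None  # never turned on
    if len(s) - i < min_dark:
        return None
    return int(i)


def truncate_at_bleach(transient: Transient, path: StatePath) -> StatePath:
    """Apply the photobleach rule, returning a possibly truncated path."""
    frame = detect_bleach(transient, path)
    if frame is None:
        return path
    return replace(path, truncation_frame=frame)


def classify_fluctuating(path: StatePath) -> bool:
    """True iff at least one high-to-low reversal survives truncation."""
    s = path.effective_states.astype(int)
    return bool(np.any((s[:-1] == TRANSFORMED) & (s[1:] == UNTRANSFORMED)))


def filter_dual_on(
    transient_red: Transient,
    transient_green: Transient,
    path_red: StatePath,
    path_green: StatePath,
) -> bool:
    """Keep only structures in which both fluorophores turned on."""

    def turned_on(p: StatePath) -> bool:
        s = p.states.astype(int)
        return bool(np.any((s[:-1] == UNTRANSFORMED) & (s[1:] == TRANSFORMED)))

    return turned_on(path_red) and turned_on(path_green)


def analyze_transient(
    transient: Transient, seed: int = 0, min_dwell: float = 10.0
) -> tuple[StatePath, TransformationCall, bool]:
    """Fit, bleach-truncate, and call one transient.

    Returns ``(path, transformation call, fluctuating flag)``.
    """
    path = fit_two_state_hmm(transient, seed=seed)
    path = truncate_at_bleach(transient, path)
    call = transformation_time(path, min_dwell=min_dwell)
    call = TransformationCall(call.time_s, call.dwell_s, transient.channel)
    return path, call, classify_fluctuating(path)
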