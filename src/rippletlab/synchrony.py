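"""Jitter-Based Synchrony Index (JBSI) with analytic chance correction.

Given two simultaneously recorded spike trains, synchrony S is the fraction
of spikes in the sparser train that fall within a synchrony window SW of a
spike in the denser train. Chance synchrony <S_J> is the synchrony expected
after jittering each spike of the sparser train by a random offset drawn
uniformly from [-J, +J]; it is computed analytically as, per spike, the
Lebesgue measure of the intersection of the union of target windows
[b - SW, b + SW] with the jitter range [a - J, a + J], divided by 2J
(overlapping windows are merged, never double-counted). The index is

    JBSI = beta * (S - <S_J>),      here with J = 2*SW and beta = 2,

which bounds the index to [-1, 1]: with J = 2*SW every truly synchronous
spike has chance probability >= 1/2, so beta = 2 maps perfect synchrony to 1.

Trials are processed independently and pooled by counts; spikes are never
matched across trial boundaries. A Monte-Carlo estimate of <S_J> is provided
as an independent validation oracle for the analytic path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ValidationError, get_logger

__all__ = [
    "JBSIParams",
    "JBSIMatrix",
    "jbsi",
    "jbsi_matrix",
    "precision_and_lag",
    "chance_synchrony_mc",
    "default_sw_grid",
    "default_lag_grid",
]

log = get_logger(__name__)


@dataclass(frozen=True)
class JBSIParams:
    """Synchrony window SW, jitter half-range J = 2*SW, beta = 2, virtual lag."""

    sw: float
    j: float | None = None
    beta: float = 2.0
    lag: float = 0.0

    def __post_init__(self) -> None:
        if self.sw <= 0:
            raise ValidationError("synchrony window must be > 0")
        if self.j is None:
            object.__setattr__(self, "j", 2.0 * self.sw)
        if self.j <= 0:
            raise ValidationError("jitter half-range must be > 0")


def default_sw_grid() -> np.ndarray:
    return np.round(np.arange(0.1, 1.0 + 1e-9, 0.1), 10)


def default_lag_grid() -> np.ndarray:
    return np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)


def _as_trials(train) -> list[np.ndarray]:
    return [np.sort(np.asarray(tr, float)) for tr in train]


def _pick_jittered(a_trials, b_trials):
    """The train with fewer total spikes is jittered; ties jitter the first."""
    na = sum(tr.size for tr in a_trials)
    nb = sum(tr.size for tr in b_trials)
    if na <= nb:
        return a_trials, b_trials, na
    return b_trials, a_trials, nb


def _merged_windows(b: np.ndarray, sw: float) -> np.ndarray:
    """Union of [b - sw, b + sw] as merged disjoint intervals, shape (k, 2)."""
    if b.size == 0:
        return np.empty((0, 2))
    starts, ends = b - sw, b + sw
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged)


def _overlap(intervals: np.ndarray, lo: float, hi: float) -> float:
    """Measure of (union of intervals) intersected with [lo, hi]."""
    if intervals.size == 0:
        return 0.0
    left = np.maximum(intervals[:, 0], lo)
    right = np.minimum(intervals[:, 1], hi)
    return float(np.sum(np.maximum(right - left, 0.0)))


def _counts_one_trial(a: np.ndarray, b: np.ndarray, sw: float, j: float
                      ) -> tuple[int, float]:
    """(observed synchronous count, summed chance probability) for one trial."""
    if a.size == 0:
        return 0, 0.0
    if b.size == 0:
        return 0, 0.0
    # observed: nearest-neighbour distance <= sw
    pos = np.searchsorted(b, a)
    prev_gap = np.where(pos > 0, a - b[np.clip(pos - 1, 0, b.size - 1)], np.inf)
    next_gap = np.where(pos < b.size, b[np.clip(pos, 0, b.size - 1)] - a, np.inf)
    observed = int(np.sum(np.minimum(prev_gap, next_gap) <= sw))
    # analytic chance: interval-union overlap with each spike's jitter range
    win = _merged_windows(b, sw)
    chance = sum(_overlap(win, ai - j, ai + j) for ai in a) / (2.0 * j)
    return observed, chance


def jbsi(train_a, train_b, params: JBSIParams) -> float:
    """JBSI of two per-trial spike-time lists at one (SW, lag) setting.

    The sparser train is shifted by ``+lag`` and jittered. Returns NaN
    (flagged undefined) when either train is empty overall.
    """
    a_trials = _as_trials(train_a)
    b_trials = _as_trials(train_b)
    if len(a_trials) != len(b_trials):
        raise ValidationError("trains must have matching trial counts")
    jit, ref, n_jit = _pick_jittered(a_trials, b_trials)
    n_ref = sum(tr.size for tr in ref)
    if n_jit == 0 or n_ref == 0:
        log.warning("empty spike train; JBSI undefined")
        return math.nan
    observed = 0
    chance = 0.0
    for a, b in zip(jit, ref):
        o, c = _counts_one_trial(a + params.lag, b, params.sw, params.j)
        observed += o
        chance += c
    s = observed / n_jit
    s_j = chance / n_jit
    return params.beta * (s - s_j)


def chance_synchrony_mc(train_a, train_b, params: JBSIParams,
                        n_reps: int, seed: int) -> float:
    """Monte-Carlo estimate of the chance synchrony <S_J>.

    Each repetition jitters every spike of the sparser (lag-shifted) train
    independently by Uniform(-J, +J) and measures the synchronous fraction;
    the mean over repetitions estimates what the analytic path computes
    exactly. Validation oracle only.
    """
    if n_reps < 100:
        raise ValidationError("n_reps must be >= 100")
    a_trials = _as_trials(train_a)
    b_trials = _as_trials(train_b)
    jit, ref, n_jit = _pick_jittered(a_trials, b_trials)
    if n_jit == 0 or sum(tr.size for tr in ref) == 0:
        return math.nan
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(n_reps):
        count = 0
        for a, b in zip(jit, ref):
            if a.size == 0 or b.size == 0:
                continue
            aj = np.sort(a + params.lag + rng.uniform(-params.j, params.j, a.size))
            pos = np.searchsorted(b, aj)
            prev_gap = np.where(pos > 0, aj - b[np.clip(pos - 1, 0, b.size - 1)],
                                np.inf)
            next_gap = np.where(pos < b.size, b[np.clip(pos, 0, b.size - 1)] - aj,
                                np.inf)
            count += int(np.sum(np.minimum(prev_gap, next_gap) <= params.sw))
        total += count / n_jit
    return total / n_reps


@dataclass
class JBSIMatrix:
    """JBSI over an SW x virtual-lag grid with derived precision and lag."""

    sw_grid: np.ndarray
    lag_grid: np.ndarray
    values: np.ndarray                  # shape (len(sw_grid), len(lag_grid))
    precision: float | None = None      # smallest SW with max-over-lag JBSI > 0.5
    lag_at_precision: float | None = None

    def to_dict(self) -> dict:
        return {
            "sw_grid_ms": list(map(float, self.sw_grid)),
            "lag_grid_ms": list(map(float, self.lag_grid)),
            "values": [[None if math.isnan(v) else float(v) for v in row]
                       for row in self.values],
            "precision_ms": self.precision,
            "lag_at_precision_ms": self.lag_at_precision,
        }


def jbsi_matrix(train_a, train_b, sw_grid=None, lag_grid=None) -> JBSIMatrix:
    """Compute the full JBSI matrix and its pairwise precision and lag."""
    sw_grid = default_sw_grid() if sw_grid is None else np.asarray(sw_grid, float)
    lag_grid = default_lag_grid() if lag_grid is None else np.asarray(lag_grid, float)
    if sw_grid.size == 0 or lag_grid.size == 0:
        raise ValidationError("grids must be nonempty")
    values = np.empty((sw_grid.size, lag_grid.size))
    for i, sw in enumerate(sw_grid):
        for k, lag in enumerate(lag_grid):
            values[i, k] = jbsi(train_a, train_b, JBSIParams(sw=sw, lag=lag))
    m = JBSIMatrix(sw_grid=sw_grid, lag_grid=lag_grid, values=values)
    m.precision, m.lag_at_precision = precision_and_lag(m)
    return m


def precision_and_lag(m: JBSIMatrix) -> tuple[float | None, float | None]:
    """Pairwise precision (smallest SW whose best-lag JBSI exceeds 0.5) and
    the virtual lag maximizing the JBSI in that row; (None, None) when no
    row qualifies."""
    for i, sw in enumerate(m.sw_grid):
        row = m.values[i]
        if np.all(np.isnan(row)):
            continue
        if np.nanmax(row) > 0.5:
            return float(sw), float(m.lag_grid[int(np.nanargmax(row))])
    log.info("no SW row with JBSI > 0.5; pairwise precision undefined")
    return None, None
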