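"""Event segmentation and normalization of raw nanopore current.

The pore emits a regular stream of picoamp measurements.  Translocation of
one nucleotide corresponds, ideally, to one contiguous stretch of samples at
a roughly constant level — an *event*, summarized by its mean current e_c
and dwell time e_t (sample count).  Boundaries between events are located
with two rolling Welch t-statistic traces (a short and a long window, in the
style of the Scrappie segmenter): a significant t-statistic peak marks a
level change.

Event means are then normalized per read onto the pore-model scale:

    norm(e_c) = (e_c - mu_read) / sigma_read * model_std + model_mean

with mu_read / sigma_read maintained incrementally (Welford, population
variance) so that chunked acquisition can update the estimate as more of the
read arrives.  Statistics are never shared across reads: pore-to-pore offset
and drift are read-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

logger = logging.getLogger(__name__)

#: capped t-statistic assigned where the pooled variance is exactly zero but
#: the window means differ (an infinitely significant step)
T_STAT_CAP = 1e12

#: default chunk size in raw samples (~1 s of sequencing on R9.4 pores)
DEFAULT_CHUNK_SIZE = 4000


@dataclass(frozen=True)
class RawSignal:
    """One read's raw current trace."""

    read_id: str
    samples: np.ndarray

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.size == 0:
            raise ValueError(f"read {self.read_id}: empty signal")
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"read {self.read_id}: non-finite samples")
        object.__setattr__(self, "samples", samples)


@dataclass(frozen=True)
class EventSequence:
    """Segmented signal: per-event mean current, dwell, and start offset."""

    means: np.ndarray
    dwells: np.ndarray
    start_indices: np.ndarray
    low_confidence: bool = False

    def __post_init__(self):
        means = np.asarray(self.means, dtype=np.float64)
        dwells = np.asarray(self.dwells, dtype=np.int64)
        starts = np.asarray(self.start_indices, dtype=np.int64)
        if not (len(means) == len(dwells) == len(starts)):
            raise ValueError("means, dwells and start_indices must align")
        if len(dwells) and dwells.min() < 1:
            raise ValueError("dwells must be >= 1")
        if len(starts) > 1 and np.any(np.diff(starts) <= 0):
            raise ValueError("start_indices must be strictly increasing")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "dwells", dwells)
        object.__setattr__(self, "start_indices", starts)

    def __len__(self) -> int:
        return len(self.means)


@dataclass(frozen=True)
class EventDetectionParams:
    """Rolling t-test segmentation parameters.

    The numeric defaults are this package's documented settings for ~9
    samples/base R9.4-like signal, chosen to balance stay and skip errors:
    3/6-sample windows with peak thresholds 4.30265 / 2.57058 (the two-sided
    t critical values used by the Sigmap-style segmenter) and a minimum peak
    prominence of 0.2.  All are overridable and logged on every CLI run.
    """

    window_short: int = 3
    window_long: int = 6
    tstat_threshold_short: float = 4.30265
    tstat_threshold_long: float = 2.57058
    peak_height: float = 0.2

    def __post_init__(self):
        if not self.window_short < self.window_long:
            raise ValueError("window_short must be < window_long")
        if self.tstat_threshold_short <= 0 or self.tstat_threshold_long <= 0:
            raise ValueError("t-statistic thresholds must be positive")


def rolling_tstat(samples: np.ndarray, window: int) -> np.ndarray:
    """Welch t-statistic comparing the `window` samples before and after
    each position.

    Position i compares samples[i-window:i] against samples[i:i+window].
    Incomplete windows (trace edges) are defined as 0 so read ends never
    produce spurious boundaries.  A zero pooled variance with unequal means
    (a noiseless step) is capped at T_STAT_CAP.
    """
    n = len(samples)
    t = np.zeros(n, dtype=np.float64)
    if n < 2 * window:
        return t
    c1 = np.concatenate(([0.0], np.cumsum(samples)))
    c2 = np.concatenate(([0.0], np.cumsum(samples**2)))

    # candidate boundary positions with both windows complete
    pos = np.arange(window, n - window + 1)
    s1 = c1[pos] - c1[pos - window]
    q1 = c2[pos] - c2[pos - window]
    s2 = c1[pos + window] - c1[pos]
    q2 = c2[pos + window] - c2[pos]
    m1 = s1 / window
    m2 = s2 / window
    # sample variance (ddof=1) per window
    v1 = np.maximum(q1 - window * m1**2, 0.0) / (window - 1)
    v2 = np.maximum(q2 - window * m2**2, 0.0) / (window - 1)
    denom = np.sqrt(v1 / window + v2 / window)
    diff = np.abs(m1 - m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = diff / denom
    # zero pooled variance: an exact step is infinitely significant, but a
    # mean difference at float-cancellation scale is no step at all
    zero = denom == 0.0
    tol = 1e-9 * (1.0 + np.abs(m1[zero]) + np.abs(m2[zero]))
    stat[zero] = np.where(diff[zero] > tol, T_STAT_CAP, 0.0)
    t[pos] = stat
    return t


def detect_events(
    signal: RawSignal, params: EventDetectionParams | None = None
) -> EventSequence:
    """Segment a raw trace into events.

    Boundaries are local maxima of the short-window t-statistic trace that
    exceed the short threshold (with minimum prominence `peak_height`) and
    are corroborated by the long-window trace exceeding its own threshold —
    the short trace proposes, the long trace gates.  Every sample is
    assigned to exactly one event; the event mean is the arithmetic mean of
    its samples.

    A trace shorter than ``2 * window_long`` cannot support a single
    complete window pair and is returned as one low-confidence event.
    """
    params = params or EventDetectionParams()
    x = signal.samples
    n = len(x)
    if n < 2 * params.window_long:
        return EventSequence(
            means=np.array([x.mean()]),
            dwells=np.array([n]),
            start_indices=np.array([0]),
            low_confidence=True,
        )
    t_short = rolling_tstat(x, params.window_short)
    t_long = rolling_tstat(x, params.window_long)
    peaks, _ = _scipy_find_peaks(
        t_short,
        height=params.tstat_threshold_short,
        prominence=params.peak_height,
    )
    # gate: require long-window support near the candidate boundary
    w = params.window_short
    gated = []
    for p in peaks:
        lo = max(0, p - w)
        hi = min(n, p + w + 1)
        if np.max(t_long[lo:hi]) >= params.tstat_threshold_long:
            gated.append(p)
    boundaries = np.asarray(gated, dtype=np.int64)
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    csum = np.concatenate(([0.0], np.cumsum(x)))
    means = (csum[ends] - csum[starts]) / (ends - starts)
    return EventSequence(means=means, dwells=ends - starts, start_indices=starts)


# ---------------------------------------------------------------------------
# Normalization (Welford running statistics)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormState:
    """Running per-read event-mean statistics (Welford)."""

    n: int = 0
    mean: float = 0.0
    m2: float = 0.0

    def update(self, values: np.ndarray) -> "NormState":
        n, mean, m2 = self.n, self.mean, self.m2
        for v in np.asarray(values, dtype=np.float64):
            n += 1
            delta = v - mean
            mean += delta / n
            m2 += delta * (v - mean)
        return NormState(n=n, mean=mean, m2=m2)

    @property
    def std(self) -> float:
        """Population (divide-by-N) standard deviation."""
        return float(np.sqrt(self.m2 / self.n)) if self.n else 0.0


def apply_normalization(events: EventSequence, model, state: NormState) -> EventSequence:
    """Affinely map event means onto the model scale using fixed statistics."""
    sigma = state.std
    if sigma == 0.0:
        logger.warning("constant read (sigma_read = 0); mapping all events to model_mean")
        means = np.full(len(events), model.model_mean)
    else:
        means = (events.means - state.mean) / sigma * model.model_std + model.model_mean
    return replace(events, means=means)


def normalize_events(
    events: EventSequence, model, state: NormState | None = None
) -> tuple[EventSequence, NormState]:
    """Normalize event means onto the pore-model scale.

    The running statistics are first updated with the new events, then the
    *passed* events are normalized with the updated cumulative statistics.
    In chunked acquisition the estimate sharpens as chunks arrive; the
    returned state lets the caller re-apply the final affine map to earlier
    chunks (`apply_normalization`), which reproduces the whole-read result
    exactly because the Welford update is associative.
    """
    if len(events) == 0:
        raise ValueError("cannot normalize an empty event sequence")
    state = (state or NormState()).update(events.means)
    return apply_normalization(events, model, state), state


# ---------------------------------------------------------------------------
# Signal TSV container
# ---------------------------------------------------------------------------


def write_signal_tsv(reads: list[RawSignal], path) -> None:
    """One read per line: `read_id<TAB>comma-separated floats`."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(read.read_id)
            fh.write("\t")
            fh.write(",".join(repr(float(v)) for v in read.samples))
            fh.write("\n")


def read_signal_tsv(path) -> list[RawSignal]:
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                read_id, payload = line.split("\t", 1)
                samples = np.array([float(v) for v in payload.split(",")])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed signal line") from exc
            reads.append(RawSignal(read_id=read_id, samples=samples))
    if not reads:
        return []
    return reads


def iter_chunks(signal: RawSignal, chunk_size: int = DEFAULT_CHUNK_SIZE):
    """Yield fixed-size sample blocks of a read (last block may be short)."""
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    for start in range(0, len(signal.samples), chunk_size):
        yield signal.samples[start : start + chunk_size]
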