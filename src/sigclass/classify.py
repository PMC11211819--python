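"""Read classification from PML profiles: complexity-weighted peak vote.

Within one exact match the PML decrements by 1 per position, so a position
where the PML does *not* decrease relative to its predecessor marks the
start of a new match — a "peak".  Counting only peaks stops long matches
from voting once per covered position.  Each shred d accumulates

    score(d) = sum over peaks i with D[i] = d of  P[i] * C_d

where C_d is the shred's normalized substring complexity (down-weighting
low-complexity regions whose long matches arise by coincidence); the read is
assigned the class of the arg-max shred.  In binary mode the top positive-
class shred score is compared to the top null-class shred score and the read
is called positive when their ratio exceeds the spike-ratio threshold
(strictly greater; default 1.0, appropriate for roughly balanced mixtures —
`calibrate_threshold` estimates a quantile threshold for skewed ones).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .quantize import BinSequence, BinningConfig, bin_events, hpc_compress
from .rindex import (
    PMLProfile,
    ReferenceIndex,
    compute_pmls,
    shred_delta,
    shred_entropy,
)
from .signal_events import EventDetectionParams, RawSignal, detect_events, normalize_events

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassificationConfig:
    spike_ratio_threshold: float = 1.0
    complexity_correction: bool = True

    def __post_init__(self):
        if self.spike_ratio_threshold <= 0:
            raise ValueError("spike_ratio_threshold must be > 0")


@dataclass(frozen=True)
class ClassificationResult:
    read_id: str
    mode: str  # "multi" | "binary"
    predicted_class: str
    top_shred: int
    top_score: float
    null_score: float  # NaN in multiclass mode
    spike_ratio: float  # NaN in multiclass mode
    n_peaks: int
    flags: tuple[str, ...] = ()
    shred_scores: np.ndarray | None = field(default=None, repr=False, compare=False)


def find_peaks(P: np.ndarray) -> np.ndarray:
    """Peak positions of a PML vector: position 0 by convention, and every
    i >= 1 with P[i] >= P[i-1] (a non-decrease starts a new match)."""
    P = np.asarray(P)
    if len(P) == 0:
        return np.empty(0, dtype=np.int64)
    peaks = np.flatnonzero(np.concatenate(([True], P[1:] >= P[:-1])))
    return peaks.astype(np.int64)


def shred_complexity(shred: BinSequence, metric: str = "delta", max_k: int = 12) -> float:
    """Un-normalized complexity of one shred.

    `delta` is substring complexity (max over k of distinct k-substrings/k);
    `entropy` is order-0 empirical entropy in bits.  The index builder
    normalizes across the collection to (0, 1] by the maximum shred value.
    """
    if metric == "delta":
        return shred_delta(shred.symbols, max_k=max_k)
    if metric == "entropy":
        return shred_entropy(shred.symbols)
    raise ValueError(f"unknown complexity metric {metric!r}")


def score_documents(
    profile: PMLProfile, index: ReferenceIndex, cfg: ClassificationConfig
) -> np.ndarray:
    """Per-shred weighted peak-PML sums (the vote terms, evaluated exactly)."""
    scores = np.zeros(len(index.shred_classes), dtype=np.float64)
    peaks = find_peaks(profile.P)
    if len(peaks) == 0:
        return scores
    weights = profile.P[peaks].astype(np.float64)
    docs = profile.D[peaks]
    np.add.at(scores, docs, weights)
    if cfg.complexity_correction:
        scores *= index.shred_complexity
    return scores


def classify_multiclass(
    scores: np.ndarray, index: ReferenceIndex, read_id: str = "", n_peaks: int = 0
) -> ClassificationResult:
    """Assign the class of the arg-max shred (ties -> lowest shred id,
    flagged).  Every read receives a label; an all-zero profile is flagged
    as zero-signal."""
    flags = []
    top = int(np.argmax(scores))  # argmax returns the lowest index on ties
    if np.count_nonzero(scores == scores[top]) > 1:
        flags.append("tie")
    if scores[top] == 0.0:
        flags.append("zero_signal")
    cid = int(index.shred_classes[top])
    return ClassificationResult(
        read_id=read_id,
        mode="multi",
        predicted_class=index.class_table[cid][0],
        top_shred=top,
        top_score=float(scores[top]),
        null_score=math.nan,
        spike_ratio=math.nan,
        n_peaks=n_peaks,
        flags=tuple(flags),
        shred_scores=scores,
    )


def _polarity_mask(index: ReferenceIndex, polarity: str) -> np.ndarray:
    wanted = {
        cid for cid, (_, pol) in index.class_table.items() if pol == polarity
    }
    return np.isin(index.shred_classes, list(wanted))


def classify_binary(
    scores: np.ndarray,
    index: ReferenceIndex,
    cfg: ClassificationConfig,
    read_id: str = "",
    n_peaks: int = 0,
) -> ClassificationResult:
    """Spike-ratio rule: top positive shred vs top null shred."""
    pos_mask = _polarity_mask(index, "positive")
    null_mask = _polarity_mask(index, "null")
    if not pos_mask.any() or not null_mask.any():
        raise ValueError("binary mode needs >= 1 positive and >= 1 null class")
    flags = []
    pos_idx = np.flatnonzero(pos_mask)
    null_idx = np.flatnonzero(null_mask)
    top_pos = int(pos_idx[np.argmax(scores[pos_mask])])
    top_null = int(null_idx[np.argmax(scores[null_mask])])
    pos_score = float(scores[top_pos])
    null_score = float(scores[top_null])
    if null_score > 0.0:
        ratio = pos_score / null_score
        positive = ratio > cfg.spike_ratio_threshold
    elif pos_score > 0.0:
        ratio = math.inf
        positive = True
    else:
        ratio = math.nan
        positive = False
        flags.append("zero_signal")
    winner = top_pos if positive else top_null
    cid = int(index.shred_classes[winner])
    return ClassificationResult(
        read_id=read_id,
        mode="binary",
        predicted_class=index.class_table[cid][0],
        top_shred=winner,
        top_score=pos_score,
        null_score=null_score,
        spike_ratio=ratio,
        n_peaks=n_peaks,
        flags=tuple(flags),
        shred_scores=scores,
    )


def classify_profile(
    profile: PMLProfile,
    index: ReferenceIndex,
    cfg: ClassificationConfig | None = None,
    mode: str = "multi",
) -> ClassificationResult:
    cfg = cfg or ClassificationConfig()
    scores = score_documents(profile, index, cfg)
    n_peaks = len(find_peaks(profile.P))
    if mode == "multi":
        return classify_multiclass(scores, index, profile.read_id, n_peaks)
    if mode == "binary":
        return classify_binary(scores, index, cfg, profile.read_id, n_peaks)
    raise ValueError(f"unknown mode {mode!r}")


def calibrate_threshold(
    results: list[ClassificationResult], expected_positive_fraction: float
) -> float:
    """Spike-ratio threshold from a burn-in sample.

    Returns the (linearly interpolated) 1-q quantile of the burn-in spike
    ratios, q the expected positive fraction, so that approximately that
    fraction of burn-in reads lies above the threshold.
    """
    if not 0.0 < expected_positive_fraction <= 1.0:
        raise ValueError("expected_positive_fraction must be in (0, 1]")
    ratios = np.array(
        [r.spike_ratio for r in results if not math.isnan(r.spike_ratio)]
    )
    if len(ratios) == 0:
        raise ValueError("no usable spike ratios in the burn-in sample")
    if len(ratios) < 50:
        logger.warning("burn-in of %d reads is small; threshold may be unstable", len(ratios))
    if np.all(ratios == ratios[0]):
        logger.warning("degenerate burn-in: all spike ratios equal %g", ratios[0])
        return float(ratios[0])
    finite = ratios[np.isfinite(ratios)]
    if len(finite) < len(ratios):
        # infinite ratios sit above any threshold; quantile over the rest
        q = 1.0 - expected_positive_fraction
        frac_inf = 1.0 - len(finite) / len(ratios)
        if expected_positive_fraction <= frac_inf:
            return float(finite.max()) if len(finite) else math.inf
        q = 1.0 - (expected_positive_fraction - frac_inf) / (len(finite) / len(ratios))
        return float(np.quantile(finite, q))
    return float(np.quantile(ratios, 1.0 - expected_positive_fraction))


# ---------------------------------------------------------------------------
# Whole-read pipeline
# ---------------------------------------------------------------------------


def classify_signal(
    signal: RawSignal,
    index: ReferenceIndex,
    model,
    cfg: ClassificationConfig | None = None,
    event_params: EventDetectionParams | None = None,
    mode: str = "multi",
    normalize: bool = True,
) -> ClassificationResult:
    """Raw samples -> events -> (normalize) -> bins -> HPC -> PMLs -> vote.

    `model` needs `model_mean`/`model_std` (normalization targets) and
    `min_p`/`max_p` (bin range); a full PoreModel or stored index metadata
    both qualify.
    """
    bins = signal_to_binseq(
        signal, model, index.n_bins, event_params=event_params, normalize=normalize
    )
    profile, _ = compute_pmls(index, bins)
    profile = PMLProfile(P=profile.P, D=profile.D, read_id=signal.read_id)
    return classify_profile(profile, index, cfg, mode=mode)


def signal_to_binseq(
    signal: RawSignal,
    model,
    n_bins: int,
    event_params: EventDetectionParams | None = None,
    normalize: bool = True,
) -> BinSequence:
    """The read-side quantization pipeline shared by every entry point."""
    events = detect_events(signal, event_params)
    if normalize:
        events, _ = normalize_events(events, model)
    bin_cfg = BinningConfig(n_bins=n_bins, min_p=model.min_p, max_p=model.max_p)
    return hpc_compress(bin_events(events, bin_cfg))
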