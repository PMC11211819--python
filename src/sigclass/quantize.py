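"""Quantization of current values into a small picoamp-bin alphabet.

Both the normalized read events and the model-projected reference are
discretized into ``n_bins`` equal-width picoamp ranges spanning the pore
model's expected-level range [min_p, max_p]:

    s_p = (max_p - min_p) / n_bins
    b(e_c) = 0                      if e_c < min_p
           = n_bins - 1             if e_c > max_p
           = floor((e_c - min_p) / s_p)   otherwise, clamped at the top

Bins are half-open [min_p + i*s_p, min_p + (i+1)*s_p) except the top bin,
which is closed, making b a total monotone function of the current.  Wider
(fewer) bins trade match specificity for robustness to amplitude noise; an
alphabet of 6 is the default.

Runs of identical symbols are then homopolymer-compressed (HPC).  Over-
segmentation ("stays") re-emits the same level in consecutive events, which
appears as a same-symbol run; compressing runs on *both* the read and the
reference absorbs stays while keeping genuine reference repeats queryable.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .pore_model import PoreModel, expected_signal
from .signal_events import EventSequence

#: symbol -> printable character map: digits then letters (alphabets <= 62)
_ALPHABET = string.digits + string.ascii_lowercase + string.ascii_uppercase
_CHAR_TO_SYM = {c: i for i, c in enumerate(_ALPHABET)}

DEFAULT_N_BINS = 6


@dataclass(frozen=True)
class BinningConfig:
    """Picoamp-range alphabet: size and range, with derived bin width s_p."""

    n_bins: int
    min_p: float
    max_p: float

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not self.max_p > self.min_p:
            raise ValueError("max_p must exceed min_p")

    @property
    def s_p(self) -> float:
        return (self.max_p - self.min_p) / self.n_bins

    @classmethod
    def from_model(cls, model: PoreModel, n_bins: int = DEFAULT_N_BINS) -> "BinningConfig":
        """Range bounds come from the pore model, not from observed data."""
        return cls(n_bins=n_bins, min_p=model.min_p, max_p=model.max_p)


@dataclass(frozen=True)
class BinSequence:
    """A string over the bin alphabet {0 .. n_bins-1}."""

    symbols: np.ndarray
    n_bins: int
    hpc: bool = False
    source: str = "read"

    def __post_init__(self):
        symbols = np.asarray(self.symbols, dtype=np.int32)
        if symbols.size and (symbols.min() < 0 or symbols.max() >= self.n_bins):
            raise ValueError("symbols out of range for n_bins")
        if self.hpc and symbols.size > 1 and np.any(np.diff(symbols) == 0):
            raise ValueError("hpc sequence has equal adjacent symbols")
        object.__setattr__(self, "symbols", symbols)

    def __len__(self) -> int:
        return len(self.symbols)


def bin_value(e_c: float, cfg: BinningConfig) -> int:
    """Quantize one current value; total on finite floats."""
    if e_c < cfg.min_p:
        return 0
    if e_c > cfg.max_p:
        return cfg.n_bins - 1
    return min(int((e_c - cfg.min_p) // cfg.s_p), cfg.n_bins - 1)


def bin_values(values: np.ndarray, cfg: BinningConfig) -> np.ndarray:
    """Vectorized `bin_value`."""
    values = np.asarray(values, dtype=np.float64)
    b = np.floor((values - cfg.min_p) / cfg.s_p).astype(np.int32)
    return np.clip(b, 0, cfg.n_bins - 1)


def bin_events(events: EventSequence, cfg: BinningConfig) -> BinSequence:
    """Quantize normalized event means; dwell is carried by the events but
    plays no role in binning (diagnostics only)."""
    return BinSequence(symbols=bin_values(events.means, cfg), n_bins=cfg.n_bins)


def hpc_compress(bins: BinSequence) -> BinSequence:
    """Collapse maximal same-symbol runs to a single symbol (idempotent)."""
    s = bins.symbols
    if len(s) == 0:
        return BinSequence(symbols=s, n_bins=bins.n_bins, hpc=True, source=bins.source)
    keep = np.concatenate(([True], np.diff(s) != 0))
    return BinSequence(symbols=s[keep], n_bins=bins.n_bins, hpc=True, source=bins.source)


def reference_to_binseq(seq: str, model: PoreModel, cfg: BinningConfig) -> BinSequence:
    """Project a nucleotide reference into the HPC bin alphabet.

    expected_signal -> bin per value -> HPC; the read pipeline ends in HPC
    too, so noiseless signal of `seq` quantizes to exactly this sequence.
    """
    levels = expected_signal(model, seq)
    raw = BinSequence(symbols=bin_values(levels, cfg), n_bins=cfg.n_bins, source="reference")
    return hpc_compress(raw)


def encode_ascii(bins: BinSequence) -> str:
    """Encode symbols as printable characters: '0'..'9' then letters."""
    if bins.n_bins > len(_ALPHABET):
        raise ValueError(f"n_bins={bins.n_bins} exceeds printable alphabet size")
    return "".join(_ALPHABET[s] for s in bins.symbols)


def decode_ascii(text: str, n_bins: int, hpc: bool = False, source: str = "read") -> BinSequence:
    symbols = np.empty(len(text), dtype=np.int32)
    for i, ch in enumerate(text):
        sym = _CHAR_TO_SYM.get(ch)
        if sym is None or sym >= n_bins:
            raise ValueError(f"character {ch!r} outside the {n_bins}-symbol alphabet")
        symbols[i] = sym
    return BinSequence(symbols=symbols, n_bins=n_bins, hpc=hpc, source=source)


def write_binned_fasta(records: list[tuple[str, BinSequence]], path) -> None:
    """Multi-FASTA of ASCII-encoded bin sequences.

    Headers carry `<source_name>|<segment_index>`, one record per reference
    segment, as consumed by the index builder.
    """
    with open(path, "w") as fh:
        for name, bins in records:
            fh.write(f">{name}\n{encode_ascii(bins)}\n")
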