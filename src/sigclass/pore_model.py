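"""Pore models: k-mer -> expected picoamp level tables.

A nanopore emits a current that depends on the k nucleotides occupying the
pore at a given instant.  A *pore model* tabulates, for every k-mer, the
expected current level in picoamps (pA).  It serves two roles here: it
projects nucleotide references into expected-current space prior to
quantization, and it supplies the global level range and moments used for
signal normalization and bin construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_to_rank(kmer: str) -> int:
    """Map an ACGT k-mer to its lexicographic rank in [0, 4^k)."""
    r = 0
    for b in kmer:
        r = (r << 2) | _BASE_CODE[b]
    return r


def rank_to_kmer(rank: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[rank & 3])
        rank >>= 2
    return "".join(reversed(out))


@dataclass(frozen=True)
class PoreModel:
    """Expected-current table over all 4^k k-mers.

    Attributes
    ----------
    k : int
        K-mer length of the pore chemistry being modelled.
    levels : numpy.ndarray
        Expected current in pA, indexed by lexicographic k-mer rank
        (A=0, C=1, G=2, T=3 per position); length 4**k.
    min_p, max_p : float
        Extreme expected levels over the whole table; these bound the
        quantization range.
    model_mean, model_std : float
        Mean and population standard deviation of all levels; targets of
        per-read signal normalization.
    """

    k: int
    levels: np.ndarray = field(repr=False)
    min_p: float = 0.0
    max_p: float = 0.0
    model_mean: float = 0.0
    model_std: float = 0.0

    @classmethod
    def from_levels(cls, k: int, levels: np.ndarray) -> "PoreModel":
        levels = np.asarray(levels, dtype=np.float64)
        if levels.shape != (4**k,):
            raise ValueError(
                f"pore model for k={k} needs {4**k} levels, got {levels.shape}"
            )
        if not np.all(np.isfinite(levels)):
            raise ValueError("pore model levels must be finite")
        if np.any(levels <= 0):
            raise ValueError("pore model levels must be positive pA values")
        min_p = float(levels.min())
        max_p = float(levels.max())
        if not min_p < max_p:
            raise ValueError("degenerate pore model: min_p == max_p")
        return cls(
            k=k,
            levels=levels,
            min_p=min_p,
            max_p=max_p,
            model_mean=float(levels.mean()),
            model_std=float(levels.std()),  # population convention
        )

    def level(self, kmer: str) -> float:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {kmer!r}")
        return float(self.levels[kmer_to_rank(kmer)])


def load_pore_model(path, k: int) -> PoreModel:
    """Read a pore model from a TSV with (at least) kmer and level_mean columns.

    The dialect is a compatible superset of vendor k-mer model tables:
    tab-separated with a header row; extra columns are ignored.  All 4^k
    uppercase-ACGT k-mers must be present exactly once.
    """
    levels = np.full(4**k, np.nan)
    seen = np.zeros(4**k, dtype=bool)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "kmer" not in reader.fieldnames:
            raise ValueError(f"{path}: missing header with a 'kmer' column")
        if "level_mean" not in reader.fieldnames:
            raise ValueError(f"{path}: missing 'level_mean' column")
        for row in reader:
            kmer = row["kmer"].strip()
            if len(kmer) != k or any(b not in _BASE_CODE for b in kmer):
                raise ValueError(f"{path}: bad k-mer {kmer!r} for k={k}")
            rank = kmer_to_rank(kmer)
            if seen[rank]:
                raise ValueError(f"{path}: duplicate k-mer {kmer!r}")
            try:
                levels[rank] = float(row["level_mean"])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric level for {kmer!r}: {row['level_mean']!r}"
                ) from exc
            seen[rank] = True
    n_missing = int((~seen).sum())
    if n_missing:
        raise ValueError(f"{path}: {n_missing} of {4**k} k-mers missing")
    return PoreModel.from_levels(k, levels)


def write_pore_model(model: PoreModel, path) -> None:
    """Write the model as `kmer<TAB>level_mean` with full float precision."""
    with open(path, "w") as fh:
        fh.write("kmer\tlevel_mean\n")
        for rank, lv in enumerate(model.levels):
            fh.write(f"{rank_to_kmer(rank, model.k)}\t{float(lv)!r}\n")


def generate_pore_model(
    k: int, level_range: tuple[float, float] = (60.0, 120.0), seed: int = 0
) -> PoreModel:
    """Synthesize a pore model with i.i.d. uniform levels.

    Stands in for chemistry-specific tables in tests and simulations;
    deterministic for a fixed seed.
    """
    if not 2 <= k <= 8:
        raise ValueError(f"k={k} outside supported range [2, 8]")
    low, high = level_range
    if not low < high:
        raise ValueError("level_range must satisfy low < high")
    rng = np.random.default_rng(seed)
    levels = rng.uniform(low, high, size=4**k)
    return PoreModel.from_levels(k, levels)


def _encode_acgt(seq: str) -> np.ndarray:
    """Encode an ACGT string as integer codes; raises on other characters."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    if np.any(codes < 0):
        bad = chr(int(arr[codes < 0][0]))
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def expected_signal(model: PoreModel, seq: str) -> np.ndarray:
    """Project a nucleotide sequence into expected current space.

    Output position i is the model level of seq[i:i+k]; length is
    len(seq) - k + 1.
    """
    k = model.k
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} shorter than k={k}")
    codes = _encode_acgt(seq)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    ranks = windows @ weights
    return model.levels[ranks]


def split_on_ambiguity(seq: str) -> list[tuple[int, str]]:
    """Split a sequence at non-ACGT characters into (offset, segment) pairs.

    Ambiguity codes never receive a fabricated level; each contiguous ACGT
    stretch is projected independently.
    """
    segments: list[tuple[int, str]] = []
    start = None
    upper = seq.upper()
    for i, ch in enumerate(upper):
        if ch in _BASE_CODE:
            if start is None:
                start = i
        else:
            if start is not None:
                segments.append((start, upper[start:i]))
                start = None
    if start is not None:
        segments.append((start, upper[start:]))
    return segments


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA as a list of (description, sequence) pairs."""
    records = [(rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[tuple[str, str]], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
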