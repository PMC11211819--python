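"""Run-length-compressed BWT index with thresholds and a shredded sampled
document array; single-pass pseudo-matching-length (PML) queries.

The binned, HPC-compressed reference collection is cut into fixed-size
"shreds" (default 100 000 symbols), each carrying its own document label, so
that matches localize to a specific reference region without storing a
suffix array.  The shreds are concatenated, each followed by a shared
terminator symbol that orders before every bin symbol; queries consist only
of bin symbols, so no match can span a shred boundary.

Over that text the index keeps, in O(r)-flavoured per-run arrays:

* the run-length encoded BWT (symbol + length per run, run count r);
* one *threshold* per run: between two consecutive runs of the same symbol,
  the BWT row of minimum LCP — the split point deciding, during a mismatch,
  whether to jump up to the earlier run or down to the later one;
* a sampled document array: the shred label of the suffix at the first and
  last row of every run.

PMLs are truncated matching statistics.  The matcher walks the query right
to left holding a single (row, length, shred) state: while the BWT symbol at
the current row equals the next query symbol the match grows by one and the
label is carried unchanged (an LF step stays inside the same shred because
the prepended character is a bin symbol); on a mismatch the matcher jumps —
via the threshold — to the nearest run of the needed symbol, resets the
length, and picks up the exact label sampled at that run boundary.  The
per-position label therefore always names a shred that truly contains the
matched substring.

Construction is desk-scale: a full suffix array (in-repo prefix doubling)
and Kasai LCP are built once and discarded; the serialized index keeps only
the per-run and per-shred arrays.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .quantize import BinSequence

logger = logging.getLogger(__name__)

INDEX_FORMAT_VERSION = 1
DEFAULT_SHRED_SIZE = 100_000

#: polarity values a class may take in the class table
POLARITIES = ("positive", "null", "plain")


# ---------------------------------------------------------------------------
# Document collection and shredding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShredInfo:
    shred_id: int
    class_id: int
    source_name: str
    offset: int  # symbol offset of the shred within its source bin sequence


@dataclass
class DocumentCollection:
    """Shredded, binned reference collection."""

    shreds: list[tuple[ShredInfo, BinSequence]]
    shred_size: int
    class_table: dict[int, tuple[str, str]]  # class_id -> (name, polarity)
    n_bins: int

    def class_of_shred(self, shred_id: int) -> int:
        return self.shreds[shred_id][0].class_id

    @property
    def n_shreds(self) -> int:
        return len(self.shreds)


def shred_collection(
    docs: list[tuple[str, str, BinSequence]],
    shred_size: int = DEFAULT_SHRED_SIZE,
    class_polarity: dict[str, str] | None = None,
) -> DocumentCollection:
    """Split each (name, class_name, BinSequence) document into consecutive
    shreds of `shred_size` symbols; a final partial shred is kept.

    Equal-size shreds prevent long references from dominating the vote, and
    give match labels sub-reference resolution.
    """
    if shred_size < 2:
        raise ValueError("shred_size must be >= 2")
    if not docs:
        raise ValueError("empty document collection")
    class_polarity = class_polarity or {}
    class_ids: dict[str, int] = {}
    class_table: dict[int, tuple[str, str]] = {}
    shreds: list[tuple[ShredInfo, BinSequence]] = []
    n_bins = None
    for name, class_name, bins in docs:
        if len(bins) == 0:
            logger.warning("document %s is empty; skipped", name)
            continue
        if n_bins is None:
            n_bins = bins.n_bins
        elif bins.n_bins != n_bins:
            raise ValueError("documents disagree on n_bins")
        if class_name not in class_ids:
            cid = len(class_ids)
            class_ids[class_name] = cid
            class_table[cid] = (class_name, class_polarity.get(class_name, "plain"))
        cid = class_ids[class_name]
        for off in range(0, len(bins), shred_size):
            piece = BinSequence(
                symbols=bins.symbols[off : off + shred_size],
                n_bins=bins.n_bins,
                hpc=bins.hpc,
                source="reference",
            )
            shreds.append(
                (ShredInfo(len(shreds), cid, name, off), piece)
            )
    if not shreds:
        raise ValueError("all documents empty after shredding")
    return DocumentCollection(
        shreds=shreds, shred_size=shred_size, class_table=class_table, n_bins=n_bins
    )


# ---------------------------------------------------------------------------
# Suffix array / LCP (construction only; discarded after the build)
# ---------------------------------------------------------------------------


def suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy-vectorized)."""
    n = len(text)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    # dense initial ranks from the raw symbols
    rank = np.unique(text, return_inverse=True)[1].astype(np.int64)
    sa = np.arange(n, dtype=np.int64)
    k = 1
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        new_rank = np.empty(n, dtype=np.int64)
        key_r = rank[order]
        key_s = second[order]
        changed = np.concatenate(
            ([False], (np.diff(key_r) != 0) | (np.diff(key_s) != 0))
        )
        new_rank[order] = np.cumsum(changed)
        rank = new_rank
        sa = order
        if rank[order[-1]] == n - 1:
            break
        k *= 2
    return sa


def lcp_array(text: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai LCP: lcp[i] = lcp(suffix sa[i-1], suffix sa[i]); lcp[0] = 0."""
    n = len(sa)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    t = text
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            maxl = n - max(i, j)
            while h < maxl and t[i + h] == t[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


# ---------------------------------------------------------------------------
# Reference index
# ---------------------------------------------------------------------------


@dataclass
class ReferenceIndex:
    """RLEBWT + thresholds + sampled document array over shredded references.

    Alphabet layout: 0 is the shared terminator; bin symbol b maps to b + 1.
    All row/threshold quantities live in BWT row space.
    """

    text_length: int
    n_bins: int
    shred_size: int
    run_symbols: np.ndarray  # (r,) int32, internal alphabet
    run_lengths: np.ndarray  # (r,) int64
    thresholds: np.ndarray  # (r,) int64; first run of a symbol: its start row
    doc_first: np.ndarray  # (r,) int32 shred id at first row of run
    doc_last: np.ndarray  # (r,) int32 shred id at last row of run
    shred_complexity: np.ndarray  # (S,) float64, normalized delta in (0, 1]
    class_table: dict[int, tuple[str, str]]
    shred_classes: np.ndarray  # (S,) int32
    shred_sources: list[str]
    shred_offsets: np.ndarray  # (S,) int64
    #: free-form build metadata (e.g. pore-model stats so that classification
    #: can run from the index directory alone); serialized in the manifest
    meta: dict = field(default_factory=dict)

    # derived (rebuilt on load, not serialized)
    run_starts: np.ndarray = field(default=None, repr=False)
    _c_table: np.ndarray = field(default=None, repr=False)
    _occ_before: np.ndarray = field(default=None, repr=False)
    _runs_by_symbol: dict = field(default=None, repr=False)

    @property
    def r(self) -> int:
        return len(self.run_symbols)

    @property
    def n(self) -> int:
        return self.text_length

    @property
    def n_over_r(self) -> float:
        return self.text_length / self.r

    def finalize(self) -> "ReferenceIndex":
        """(Re)build LF-mapping support from the run-length encoding."""
        r = self.r
        self.run_starts = np.concatenate(
            ([0], np.cumsum(self.run_lengths[:-1]))
        ).astype(np.int64)
        sigma = self.n_bins + 1
        counts = np.zeros(sigma, dtype=np.int64)
        occ_before = np.zeros(r, dtype=np.int64)
        for j in range(r):
            c = self.run_symbols[j]
            occ_before[j] = counts[c]
            counts[c] += self.run_lengths[j]
        self._c_table = np.concatenate(([0], np.cumsum(counts)))[:-1]
        self._occ_before = occ_before
        runs_by_symbol: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        sym = np.asarray(self.run_symbols)
        for c in np.unique(sym):
            idx = np.flatnonzero(sym == c).astype(np.int64)
            lens = self.run_lengths[idx]
            runs_by_symbol[int(c)] = (
                self.run_starts[idx],
                idx,
                lens,
                np.cumsum(lens),
            )
        self._runs_by_symbol = runs_by_symbol
        return self

    def rank(self, c: int, row: int) -> int:
        """Occurrences of symbol c in BWT rows [0, row)."""
        entry = self._runs_by_symbol.get(c)
        if entry is None:
            return 0
        starts_c, _, lens_c, cum_c = entry
        t = int(np.searchsorted(starts_c, row, side="right"))
        if t == 0:
            return 0
        head = int(cum_c[t - 2]) if t >= 2 else 0
        inside = min(int(lens_c[t - 1]), row - int(starts_c[t - 1]))
        return head + inside

    # -- row-level helpers -------------------------------------------------

    def run_of_row(self, row: int) -> int:
        return int(np.searchsorted(self.run_starts, row, side="right")) - 1

    def run_end(self, j: int) -> int:
        return int(self.run_starts[j] + self.run_lengths[j] - 1)

    def lf(self, row: int) -> int:
        j = self.run_of_row(row)
        c = int(self.run_symbols[j])
        return int(self._c_table[c] + self._occ_before[j] + (row - self.run_starts[j]))

    def doc_of_row(self, row: int) -> int:
        """Sampled-document-array access: exact at run boundaries, nearer
        sampled boundary when the row is mid-run."""
        j = self.run_of_row(row)
        start = int(self.run_starts[j])
        end = self.run_end(j)
        if row - start <= end - row:
            return int(self.doc_first[j])
        return int(self.doc_last[j])


def shred_delta(symbols: np.ndarray, max_k: int = 12) -> float:
    """Substring complexity delta = max_k (#distinct k-substrings / k).

    For small alphabets the argmax occurs at small k; k is capped (default
    12) to keep the build linear-time.
    """
    m = len(symbols)
    if m == 0:
        raise ValueError("empty shred")
    data = np.asarray(symbols, dtype=np.uint8).tobytes()
    best = 0.0
    for k in range(1, min(max_k, m) + 1):
        distinct = len({data[i : i + k] for i in range(m - k + 1)})
        best = max(best, distinct / k)
    return best


def shred_entropy(symbols: np.ndarray) -> float:
    """Order-0 empirical entropy (bits/symbol); complexity alternative."""
    if len(symbols) == 0:
        raise ValueError("empty shred")
    _, counts = np.unique(np.asarray(symbols), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def build_index(
    coll: DocumentCollection, complexity_metric: str = "delta"
) -> ReferenceIndex:
    """Build the RLEBWT, thresholds, document samples, and per-shred
    complexity weights for a shredded collection.

    `complexity_metric` selects the per-shred complexity C_d: substring
    complexity `delta` (default) or order-0 empirical `entropy`."""
    if coll.n_shreds == 0:
        raise ValueError("empty collection")
    sigma = coll.n_bins + 1
    if sigma > np.iinfo(np.int32).max:
        raise ValueError("alphabet exceeds encoding width")

    pieces = []
    doc_of_pos = []
    for info, bins in coll.shreds:
        pieces.append(bins.symbols.astype(np.int64) + 1)  # bins shift past terminator
        pieces.append(np.zeros(1, dtype=np.int64))  # shared terminator
        doc_of_pos.append(np.full(len(bins) + 1, info.shred_id, dtype=np.int32))
    text = np.concatenate(pieces)
    doc_of_pos = np.concatenate(doc_of_pos)
    n = len(text)

    sa = suffix_array(text)
    lcp = lcp_array(text, sa)
    bwt = text[(sa - 1) % n]

    # run-length encoding
    breaks = np.flatnonzero(np.diff(bwt) != 0) + 1
    run_starts = np.concatenate(([0], breaks))
    run_ends_excl = np.concatenate((breaks, [n]))
    run_symbols = bwt[run_starts].astype(np.int32)
    run_lengths = (run_ends_excl - run_starts).astype(np.int64)
    r = len(run_symbols)

    # document samples at run boundaries
    doc_first = doc_of_pos[sa[run_starts]].astype(np.int32)
    doc_last = doc_of_pos[sa[run_ends_excl - 1]].astype(np.int32)

    # thresholds: for each pair of consecutive same-symbol runs, the row of
    # minimum LCP strictly after the earlier run and up to the start of the
    # later one (smallest row on ties).  First run of a symbol: its start.
    thresholds = run_starts.copy().astype(np.int64)
    last_run_of_symbol: dict[int, int] = {}
    for j in range(r):
        c = int(run_symbols[j])
        if c in last_run_of_symbol:
            p = last_run_of_symbol[c]
            lo = int(run_starts[p] + run_lengths[p])  # first row after run p
            hi = int(run_starts[j])  # start row of run j
            window = lcp[lo : hi + 1]
            thresholds[j] = lo + int(np.argmin(window))
        last_run_of_symbol[c] = j

    # per-shred complexity, normalized to (0, 1] by the collection maximum
    measure = {"delta": shred_delta, "entropy": shred_entropy}.get(complexity_metric)
    if measure is None:
        raise ValueError(f"unknown complexity metric {complexity_metric!r}")
    deltas = np.array([measure(bins.symbols) for _, bins in coll.shreds])
    if deltas.max() <= 0:
        deltas = np.ones_like(deltas)
    complexity = deltas / deltas.max()

    index = ReferenceIndex(
        text_length=n,
        n_bins=coll.n_bins,
        shred_size=coll.shred_size,
        run_symbols=run_symbols,
        run_lengths=run_lengths,
        thresholds=thresholds,
        doc_first=doc_first,
        doc_last=doc_last,
        shred_complexity=complexity,
        class_table=dict(coll.class_table),
        shred_classes=np.array([i.class_id for i, _ in coll.shreds], dtype=np.int32),
        shred_sources=[i.source_name for i, _ in coll.shreds],
        shred_offsets=np.array([i.offset for i, _ in coll.shreds], dtype=np.int64),
    )
    return index.finalize()


# ---------------------------------------------------------------------------
# PML computation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatcherState:
    """Resumable matcher state: the backward-search interval [s, e] of the
    current match, one concrete row within it whose shred label is known
    exactly, the current match length, and that label."""

    row: int
    length: int
    doc: int
    s: int = 0
    e: int = -1  # e < s encodes "no active match interval"


@dataclass(frozen=True)
class PMLProfile:
    """Per-position pseudo-matching lengths and shred labels."""

    P: np.ndarray
    D: np.ndarray
    read_id: str = ""

    def __post_init__(self):
        P = np.asarray(self.P, dtype=np.int64)
        D = np.asarray(self.D, dtype=np.int32)
        if len(P) != len(D):
            raise ValueError("P and D must align")
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "D", D)

    def __len__(self) -> int:
        return len(self.P)


def initial_state(index: ReferenceIndex) -> MatcherState:
    """Cold start: the last BWT row (a run boundary, so its label is exact),
    zero match length."""
    row = index.text_length - 1
    return MatcherState(row=row, length=0, doc=int(index.doc_last[index.r - 1]))


def compute_pmls(
    index: ReferenceIndex,
    query: BinSequence,
    state: MatcherState | None = None,
) -> tuple[PMLProfile, MatcherState]:
    """Single right-to-left pass computing PMLs with shred labels.

    The matcher carries the backward-search interval [s, e] of the current
    match together with one concrete row p inside it whose shred label is
    known exactly.  At each query symbol c (right to left):

    * if c can extend the match anywhere (the interval step is non-empty),
      the length grows by one; p follows by an LF step when BWT[p] = c, and
      otherwise hops to a c-run boundary *inside* [s, e] — one always exists
      in this case — picking up that boundary's exact document sample;
    * otherwise the match resets: p jumps through the thresholds structure
      to the nearest run of c (the boundary with the longer common context),
      the interval becomes all occurrences of c, and the length restarts at
      1 (the jumped-to occurrence itself);
    * a symbol absent from the reference scores 0 and leaves p in place.

    Hence P decreases by exactly 1 per position within one match, an exact
    substring of a shred scores [m, m-1, ..., 1], and D[i] always names a
    shred that genuinely contains query[i : i+P[i]].

    Matches are start-anchored, so the pass runs right to left and the
    returned state resumes computation *leftward*: feed the last chunk of a
    query first, then earlier chunks through the returned state, and the
    concatenated profile equals the one-shot result exactly.
    """
    if query.symbols.size and query.symbols.max() >= index.n_bins:
        raise ValueError("query symbol out of range for the index alphabet")
    st = state or initial_state(index)
    row, length, doc, s, e = st.row, st.length, st.doc, st.s, st.e
    m = len(query)
    P = np.zeros(m, dtype=np.int64)
    D = np.zeros(m, dtype=np.int32)

    run_starts = index.run_starts
    run_symbols = index.run_symbols
    run_lengths = index.run_lengths
    runs_by_symbol = index._runs_by_symbol
    thresholds = index.thresholds
    c_table = index._c_table
    occ_before = index._occ_before
    doc_first = index.doc_first
    doc_last = index.doc_last
    searchsorted = np.searchsorted

    def lf_from(j: int, r: int) -> int:
        return int(c_table[run_symbols[j]] + occ_before[j] + (r - run_starts[j]))

    q = query.symbols
    for i in range(m - 1, -1, -1):
        c = int(q[i]) + 1  # internal alphabet shift past the terminator
        entry = runs_by_symbol.get(c)
        if entry is None:
            length = 0
            s, e = 0, -1
            P[i] = 0
            D[i] = doc
            continue  # symbol absent from the reference; matcher stays put
        starts_c, idx_c, lens_c, cum_c = entry
        total_c = int(cum_c[-1])

        extended = False
        if length > 0 and e >= s:
            ns = c_table[c] + index.rank(c, s)
            ne = c_table[c] + index.rank(c, e + 1) - 1
            if ns <= ne:
                # the match extends somewhere within the interval
                j = int(searchsorted(run_starts, row, side="right")) - 1
                if int(run_symbols[j]) == c:
                    row = lf_from(j, row)
                else:
                    # a c-run boundary provably lies inside [s, e]
                    t = int(searchsorted(starts_c, s, side="left"))
                    if t < len(starts_c) and starts_c[t] <= e:
                        j = int(idx_c[t])
                        b = int(starts_c[t])
                        doc = int(doc_first[j])
                    else:
                        j = int(idx_c[t - 1])
                        b = int(starts_c[t - 1] + lens_c[t - 1] - 1)
                        doc = int(doc_last[j])
                    row = lf_from(j, b)
                s, e = int(ns), int(ne)
                length += 1
                extended = True
        if not extended:
            # reset: relocate through the thresholds structure
            pos = int(searchsorted(starts_c, row, side="right"))
            pred = int(idx_c[pos - 1]) if pos > 0 else -1
            succ = int(idx_c[pos]) if pos < len(idx_c) else -1
            j = int(searchsorted(run_starts, row, side="right")) - 1
            if int(run_symbols[j]) == c:
                b = row  # already standing on a c-row; doc is already exact
            elif pred >= 0 and succ >= 0:
                j = succ if row >= thresholds[succ] else pred
                if j == succ:
                    b = int(run_starts[j])
                    doc = int(doc_first[j])
                else:
                    b = int(run_starts[j] + run_lengths[j] - 1)
                    doc = int(doc_last[j])
            else:
                j = succ if pred < 0 else pred
                if j == succ:
                    b = int(run_starts[j])
                    doc = int(doc_first[j])
                else:
                    b = int(run_starts[j] + run_lengths[j] - 1)
                    doc = int(doc_last[j])
            row = lf_from(j, b)
            s = int(c_table[c])
            e = int(c_table[c]) + total_c - 1
            length = 1
        P[i] = length
        D[i] = doc
    return (
        PMLProfile(P=P, D=D, read_id=""),
        MatcherState(row=row, length=length, doc=doc, s=s, e=e),
    )


# ---------------------------------------------------------------------------
# Test oracles
# ---------------------------------------------------------------------------


def matching_statistics_oracle(
    query: BinSequence, coll: DocumentCollection
) -> np.ndarray:
    """Naive matching statistics: MS[i] = longest exact match of
    query[i:i+l] inside any single shred.  Test-scale only."""
    shred_bytes = [
        np.asarray(bins.symbols, dtype=np.uint8).tobytes() for _, bins in coll.shreds
    ]
    q = np.asarray(query.symbols, dtype=np.uint8).tobytes()
    m = len(q)
    ms = np.zeros(m, dtype=np.int64)
    for i in range(m):
        l = int(ms[i - 1] - 1) if i > 0 else 0  # MS can drop by at most 1
        l = max(l, 0)
        while i + l < m and any(q[i : i + l + 1] in s for s in shred_bytes):
            l += 1
        ms[i] = l
    return ms


def label_validity_check(
    profile: PMLProfile, query: BinSequence, coll: DocumentCollection
) -> bool:
    """Soundness: every labeled match substring occurs within its labeled
    shred.  Logs the first violation and returns False if any."""
    q = np.asarray(query.symbols, dtype=np.uint8).tobytes()
    shred_bytes = {
        info.shred_id: np.asarray(bins.symbols, dtype=np.uint8).tobytes()
        for info, bins in coll.shreds
    }
    for i in range(len(profile)):
        p = int(profile.P[i])
        if p <= 0:
            continue
        sub = q[i : i + p]
        d = int(profile.D[i])
        if sub not in shred_bytes[d]:
            logger.error(
                "label violation at %d: match of length %d not in shred %d", i, p, d
            )
            return False
    return True


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_ARRAY_FILES = {
    # file name -> (attribute(s), dtype)  — little-endian packed arrays
    "bwt.rle": (("run_symbols", "<i4"), ("run_lengths", "<i8")),
    "thresholds.bin": (("thresholds", "<i8"),),
    "docs.bin": (("doc_first", "<i4"), ("doc_last", "<i4")),
    "complexity.bin": (("shred_complexity", "<f8"),),
    "shreds.bin": (("shred_classes", "<i4"), ("shred_offsets", "<i8")),
}


def _pack(index: ReferenceIndex, specs) -> bytes:
    return b"".join(
        np.ascontiguousarray(getattr(index, attr)).astype(dtype).tobytes()
        for attr, dtype in specs
    )


def serialize_index(index: ReferenceIndex, directory) -> None:
    """Write the index as manifest.json plus packed little-endian arrays,
    with per-file SHA-256 checksums."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for fname, specs in _ARRAY_FILES.items():
        payload = _pack(index, specs)
        (directory / fname).write_bytes(payload)
        checksums[fname] = hashlib.sha256(payload).hexdigest()
    manifest = {
        "format_version": INDEX_FORMAT_VERSION,
        "n": int(index.text_length),
        "r": int(index.r),
        "n_over_r": index.n_over_r,
        "n_bins": int(index.n_bins),
        "shred_size": int(index.shred_size),
        "n_shreds": int(len(index.shred_classes)),
        "class_table": {str(k): list(v) for k, v in index.class_table.items()},
        "shred_sources": index.shred_sources,
        "meta": index.meta,
        "checksums": checksums,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_index(directory) -> ReferenceIndex:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{directory}: no manifest.json")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format_version") != INDEX_FORMAT_VERSION:
        raise ValueError(
            f"index format version {manifest.get('format_version')} unsupported"
        )
    arrays = {}
    for fname, specs in _ARRAY_FILES.items():
        payload = (directory / fname).read_bytes()
        if hashlib.sha256(payload).hexdigest() != manifest["checksums"][fname]:
            raise ValueError(f"{fname}: checksum mismatch (corrupt index)")
        counts = {"bwt.rle": "r", "thresholds.bin": "r", "docs.bin": "r"}.get(fname)
        count = manifest[counts] if counts else manifest["n_shreds"]
        offset = 0
        for attr, dtype in specs:
            width = np.dtype(dtype).itemsize
            arrays[attr] = np.frombuffer(
                payload, dtype=dtype, count=count, offset=offset
            ).copy()
            offset += count * width
        if offset != len(payload):
            raise ValueError(f"{fname}: unexpected file size")
    index = ReferenceIndex(
        text_length=manifest["n"],
        n_bins=manifest["n_bins"],
        shred_size=manifest["shred_size"],
        run_symbols=arrays["run_symbols"].astype(np.int32),
        run_lengths=arrays["run_lengths"].astype(np.int64),
        thresholds=arrays["thresholds"].astype(np.int64),
        doc_first=arrays["doc_first"].astype(np.int32),
        doc_last=arrays["doc_last"].astype(np.int32),
        shred_complexity=arrays["shred_complexity"].astype(np.float64),
        class_table={
            int(k): tuple(v) for k, v in manifest["class_table"].items()
        },
        shred_classes=arrays["shred_classes"].astype(np.int32),
        shred_sources=list(manifest["shred_sources"]),
        shred_offsets=arrays["shred_offsets"].astype(np.int64),
        meta=manifest.get("meta", {}),
    )
    return index.finalize()
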