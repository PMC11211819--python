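"""Synthetic raw-signal generator and classification metrics.

The simulator emulates an R9.4-style pore at ~9 samples/base: it samples a
read substring (random strand), walks its k-mers, and for each emits one
event of `dwell` samples at the k-mer's expected level plus Gaussian
amplitude noise.  Controlled distortions:

* dwell time ~ truncated normal(dwell_mean, dwell_sd), >= 1 sample — large
  dwell spread yields 1–2-sample events the segmenter cannot resolve,
  producing natural skip errors;
* amplitude noise sd = amp_noise_sd_factor * 1.0 pA (the base sd is fixed at
  1 pA so the factor reads directly as a pA standard deviation);
* optional explicit stay (re-emit the current level) and skip (advance two
  k-mers for one event) probabilities, for isolating HPC behaviour in tests.

Defaults follow the read-simulation settings used throughout: mean read
length 10 000 bases (geometric, truncated to the reference), amplitude noise
factor 2.0, dwell sd 8.0 around a 9-sample mean.  Explicit stay/skip default
to 0 because those errors already emerge from dwell variability and noise.

Every read carries machine-readable truth (source, class, strand, start,
per-sample originating k-mer index) so end-to-end accuracy is measurable
without external data.  `evaluate` computes confusion-matrix metrics from a
report/truth table pair, optionally weighting each read by its base length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .pore_model import BASES, PoreModel, expected_signal, revcomp
from .signal_events import RawSignal

logger = logging.getLogger(__name__)

#: base per-level amplitude noise sd in pA; amp_noise_sd_factor multiplies it
BASE_NOISE_SD = 1.0


@dataclass(frozen=True)
class SimParams:
    mean_read_length: int = 10_000  # bases
    amp_noise_sd_factor: float = 2.0
    dwell_mean: float = 9.0  # samples per base
    dwell_sd: float = 8.0
    p_stay: float = 0.0
    p_skip: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_stay < 1.0 and 0.0 <= self.p_skip < 1.0):
            raise ValueError("stay/skip probabilities must lie in [0, 1)")
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1 sample")
        if self.mean_read_length < 2:
            raise ValueError("mean_read_length must be >= 2")


@dataclass(frozen=True)
class SimulatedRead:
    signal: RawSignal
    source: str
    class_name: str
    strand: str  # '+' or '-'
    start: int  # 0-based start on the forward reference
    length: int  # bases drawn
    seq: str = field(repr=False)  # sampled substring, read orientation
    kmer_index: np.ndarray = field(repr=False)  # per-sample originating k-mer

    def __post_init__(self):
        idx = np.asarray(self.kmer_index, dtype=np.int64)
        if len(idx) != len(self.signal.samples):
            raise ValueError("kmer_index must label every sample")
        if len(idx) > 1 and np.any(np.diff(idx) < 0):
            raise ValueError("kmer_index must be non-decreasing")
        object.__setattr__(self, "kmer_index", idx)


def _draw_dwells(rng: np.random.Generator, params: SimParams, n: int) -> np.ndarray:
    """Integer dwell times, truncated normal >= 1 sample (one batched draw)."""
    if params.dwell_sd == 0.0:
        return np.full(n, max(1, int(round(params.dwell_mean))), dtype=np.int64)
    a = (1.0 - params.dwell_mean) / params.dwell_sd
    values = truncnorm.rvs(
        a, np.inf, loc=params.dwell_mean, scale=params.dwell_sd, size=n, random_state=rng
    )
    return np.maximum(1, np.round(values)).astype(np.int64)


def simulate_read(
    ref: str,
    model: PoreModel,
    params: SimParams,
    rng: np.random.Generator | None = None,
    read_id: str = "read",
    source: str = "ref",
    class_name: str = "",
) -> SimulatedRead:
    """Simulate one read from a nucleotide reference."""
    k = model.k
    if len(ref) < k + 1:
        raise ValueError(f"reference of length {len(ref)} shorter than k+1={k + 1}")
    rng = rng if rng is not None else np.random.default_rng(params.seed)

    # geometric read length with the stated mean, truncated to the reference
    length = int(rng.geometric(1.0 / params.mean_read_length))
    length = int(np.clip(length, k + 1, len(ref)))
    start = int(rng.integers(0, len(ref) - length + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    sub = ref[start : start + length]
    seq = sub if strand == "+" else revcomp(sub)

    levels = expected_signal(model, seq)
    noise_sd = params.amp_noise_sd_factor * BASE_NOISE_SD

    # 1) walk the k-mers, recording which one each *event* reports
    emitted: list[int] = []
    i = 0
    n_kmers = len(levels)
    while i < n_kmers:
        emitted.append(i)
        while rng.random() < params.p_stay:  # stay: re-emit this k-mer
            emitted.append(i)
        i += 2 if rng.random() < params.p_skip else 1  # skip: drop a k-mer
    emitted_arr = np.asarray(emitted, dtype=np.int64)

    # 2) one batched dwell draw per event, then expand to samples
    dwells = _draw_dwells(rng, params, len(emitted_arr))
    samples = np.repeat(levels[emitted_arr], dwells)
    if noise_sd > 0.0:
        samples = samples + rng.normal(0.0, noise_sd, size=len(samples))
    kmer_index = np.repeat(emitted_arr, dwells)

    return SimulatedRead(
        signal=RawSignal(read_id=read_id, samples=samples),
        source=source,
        class_name=class_name,
        strand=strand,
        start=start,
        length=length,
        seq=seq,
        kmer_index=kmer_index,
    )


def simulate_dataset(
    refs: list[tuple[str, str, str]],
    model: PoreModel,
    n_reads: int,
    params: SimParams,
    mixture: dict[str, float] | None = None,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Simulate `n_reads` reads from (name, class, sequence) references.

    Reads are drawn from classes per `mixture` (default: uniform over
    classes; weights not summing to 1 are renormalized with a warning) and
    uniformly over the references within a class.  Returns the reads and a
    truth table (read_id, class, source, strand, start, length_bases).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not refs:
        raise ValueError("empty reference list")
    rng = np.random.default_rng(params.seed)
    classes = sorted({c for _, c, _ in refs})
    by_class = {c: [(n, s) for n, cc, s in refs if cc == c] for c in classes}
    if mixture is None:
        weights = np.full(len(classes), 1.0 / len(classes))
    else:
        missing = set(mixture) - set(classes)
        if missing:
            raise ValueError(f"mixture names unknown classes: {sorted(missing)}")
        weights = np.array([mixture.get(c, 0.0) for c in classes], dtype=float)
        total = weights.sum()
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            logger.warning("mixture weights sum to %g; renormalizing", total)
        weights = weights / total

    reads = []
    rows = []
    for i in range(n_reads):
        cls = classes[int(rng.choice(len(classes), p=weights))]
        name, seq = by_class[cls][int(rng.integers(len(by_class[cls])))]
        read = simulate_read(
            seq,
            model=model,
            params=params,
            rng=rng,
            read_id=f"read_{i:05d}",
            source=name,
            class_name=cls,
        )
        reads.append(read)
        rows.append(
            {
                "read_id": read.signal.read_id,
                "class": cls,
                "source": name,
                "strand": read.strand,
                "start": read.start,
                "length_bases": read.length,
            }
        )
    truth = pd.DataFrame(rows)
    return reads, truth


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Reference generators
# ---------------------------------------------------------------------------


def random_reference(length: int, seed_or_rng=0) -> str:
    """Uniform i.i.d. ACGT string."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def de_bruijn_reference(k: int, seed_or_rng=0) -> str:
    """A sequence containing every ACGT k-mer exactly once (length 4^k+k-1).

    Sampled uniformly-ish by a random Eulerian circuit (Hierholzer with
    seeded edge shuffles) over the order-(k-1) de Bruijn graph.  Because a
    read covering the whole sequence samples every k-mer level exactly once,
    its event-mean statistics coincide with the pore model's, making
    per-read normalization an exact fixed point — the calibration-exactness
    condition used by the pipeline's noiseless identity checks.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    n_nodes = 4 ** (k - 1)
    # node = trailing (k-1)-mer, edges labelled by the appended base; every
    # node has in-degree = out-degree = 4, so an Eulerian circuit exists.
    edge_order = [list(rng.permutation(4)) for _ in range(n_nodes)]
    next_edge = [0] * n_nodes
    start = int(rng.integers(n_nodes))
    node_stack = [start]
    label_stack: list[int] = []
    circuit: list[int] = []  # edge labels, collected in reverse
    while node_stack:
        v = node_stack[-1]
        if next_edge[v] < 4:
            label = edge_order[v][next_edge[v]]
            next_edge[v] += 1
            node_stack.append((v * 4 + label) % n_nodes)
            label_stack.append(label)
        else:
            node_stack.pop()
            if label_stack:
                circuit.append(label_stack.pop())
    circuit.reverse()
    prefix = []
    v = start
    for _ in range(k - 1):
        prefix.append(v % 4)
        v //= 4
    prefix.reverse()
    return "".join(BASES[s] for s in prefix + circuit)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def evaluate(
    report: pd.DataFrame | str,
    truth: pd.DataFrame | str,
    positive_class: str | None = None,
) -> dict:
    """Confusion-matrix metrics for a classification report against truth.

    Returns accuracy, classification rate, and per-class precision/recall/F1
    in unweighted and read-length-weighted forms (each read weighted by its
    base length, prioritizing long reads).  When `positive_class` is given
    (or a single-positive report implies one), binary precision/recall/F1
    are reported for that class.  If the report carries an `n_chunks`
    column, a metrics dict is returned per chunk count under "by_chunks".
    """
    if not isinstance(report, pd.DataFrame):
        report = pd.read_csv(report, sep="\t")
    if not isinstance(truth, pd.DataFrame):
        truth = read_truth_tsv(truth)
    if len(truth) == 0:
        raise ValueError("empty truth table")

    if "n_chunks" in report.columns:
        by_chunks = {
            int(c): evaluate(grp.drop(columns=["n_chunks"]), truth, positive_class)
            for c, grp in report.groupby("n_chunks")
        }
        final = by_chunks[max(by_chunks)]
        final["by_chunks"] = by_chunks
        return final

    merged = report.merge(truth, on="read_id", how="outer", indicator=True)
    bad = merged.loc[merged["_merge"] != "both", "read_id"].tolist()
    if bad:
        raise ValueError(f"read_id mismatch between report and truth: {bad[:10]}")
    pred = merged["predicted_class"].fillna("").astype(str)
    true = merged["class"].astype(str)
    weights = merged["length_bases"].astype(float).to_numpy()
    correct = (pred == true).to_numpy()
    classified = (pred != "").to_numpy()

    out = {
        "n_reads": int(len(merged)),
        "classification_rate": float(classified.mean()),
        "accuracy": float(correct.mean()),
        "accuracy_weighted": float((correct * weights).sum() / weights.sum()),
        "per_class": {},
    }
    for cls in sorted(true.unique()):
        t = (true == cls).to_numpy()
        p = (pred == cls).to_numpy()
        tp, fp, fn = (t & p).sum(), (~t & p).sum(), (t & ~p).sum()
        precision, recall, f1 = _prf(tp, fp, fn)
        wtp = weights[t & p].sum()
        wfp = weights[~t & p].sum()
        wfn = weights[t & ~p].sum()
        wprecision, wrecall, wf1 = _prf(wtp, wfp, wfn)
        out["per_class"][cls] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "precision_weighted": wprecision,
            "recall_weighted": wrecall,
            "f1_weighted": wf1,
        }
    if positive_class is not None:
        if positive_class not in out["per_class"]:
            raise ValueError(f"positive class {positive_class!r} absent from truth")
        for key, value in out["per_class"][positive_class].items():
            out[key] = value
    return out
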