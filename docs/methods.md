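# Methods

This note records the model behind `sigclass`, the parameters that matter,
the numerical conventions that were fixed where several were defensible, and
what the synthetic benchmarks do and do not demonstrate.

## Signal model and segmentation

The pore reports current at a fixed sample rate while DNA translocates at a
roughly constant base rate, so one nucleotide step corresponds to a plateau
of ~9 samples (R9.4-like) whose level is determined by the k-mer occupying
the pore. Segmentation computes two rolling Welch t-statistic traces,
comparing the `w` samples before and after each candidate boundary for
`w ∈ {window_short, window_long}`. Boundaries are local maxima of the short
trace above its threshold (with a minimum prominence) that are corroborated
by the long trace exceeding its own threshold within ±window_short. The
defaults — windows 3/6, thresholds 4.30265/2.57058, prominence 0.2 — are
the package's documented settings for ~9 samples/base chemistry, chosen to
balance stay errors (over-segmentation) against skip errors (missed
boundaries); they are plain config values, logged on every run, and should
be re-examined for chemistries with very different dwell statistics.

Numerical conventions: the t-statistic is defined as 0 wherever a window is
incomplete (so read ends never produce cuts), and a zero pooled variance is
treated as an infinite statistic only when the window means differ by more
than a scale-relative tolerance (1e-9·(1+|m₁|+|m₂|)) — with cumulative-sum
arithmetic, exactly constant stretches otherwise produce mean differences at
float-cancellation scale and would spuriously register as steps.

## Normalization

Reads arrive with pore-specific offset and gain, so event means are
z-scored per read and rescaled to the pore model's global mean and
*population* standard deviation. Statistics are kept as a Welford state
`(n, mean, M2)` that can be updated chunk by chunk; a batch call normalizes
its events with the statistics including those events. Because the update is
associative, the state after chunked processing equals the whole-read state
exactly, and `apply_normalization` re-maps earlier chunks with the final
state to reproduce the one-shot result bit for bit. Early chunks normalized
with immature statistics are therefore *provisional* — the real-time
classifier (below) re-evaluates prefixes rather than trusting them. A
constant read (σ = 0) maps to the model mean with a logged warning.

Normalization targets the model's global level distribution, while the
reference is binned on raw expected levels. For a read sampling an arbitrary
substring the two scales differ by the substring-versus-model
level-statistics gap (O(σ/√N_events) in the shift), which occasionally flips
symbols adjacent to bin boundaries. This is intrinsic to read-statistics
normalization, not an implementation artifact. The pipeline-identity tests
are therefore split: the chain *without* normalization is exact on arbitrary
random references, and the chain *with* normalization is exercised on reads
that cover a reference containing every k-mer exactly once (a random-Euler-
tour de Bruijn sequence, provided by the simulator), where the read's event
statistics coincide with the model's and normalization is an exact fixed
point. Passing both shows segmentation, quantization, HPC and the
normalization formula are mutually consistent; neither quantifies the
residual normalization error on biological references.

## Quantization

Bin width is `s_p = (max_p − min_p)/n_bins` with `min_p`/`max_p` taken from
the pore model (never from observed data). Bins are half-open with a closed
top bin; currents below/above the range clamp to the extreme bins, making
quantization a total, monotone function. `n_bins = 6` is the default:
wider bins absorb amplitude noise, narrower bins buy match specificity.
Homopolymer compression is applied to reads and references alike so
stay errors collapse while genuine reference repeats remain queryable.
Dwell times are carried for diagnostics but never influence binning.

## Index

Shreds (default 100 000 symbols; the last shred of a source may be short)
give match labels sub-reference resolution and stop long references from
dominating votes. Both strands of every reference segment are projected and
indexed; since binning does not commute with reverse complement, the two
strands are separate shreds of the same source and class (a read matches
coherently against the shreds of its own strand, and classification
aggregates at class level).

All shreds are concatenated, each followed by a single shared terminator
symbol ordered before every bin symbol. Queries contain only bin symbols, so
no match can cross a shred boundary; sharing one terminator (rather than one
per shred) keeps the BWT run count from growing linearly with shred count,
which is what makes index growth additive when near-duplicate references are
added — the property the compressed index exists for. Construction is
desk-scale by design: a full suffix array (in-repo numpy prefix doubling)
and a Kasai LCP array are built once, used to derive the run-length BWT, the
per-run-pair minimum-LCP thresholds (smallest row on ties), and the document
samples at run boundaries, then discarded. The serialized index holds only
per-run and per-shred arrays plus a JSON manifest with checksums.

## PML computation

Pseudo-matching lengths are truncated matching statistics computed in one
right-to-left pass. The matcher state is the backward-search interval of the
current match, one concrete row inside it, the match length, and the shred
label of that row. While the next query symbol extends the match anywhere in
the interval, the length grows by 1; the row follows by an LF step when its
own BWT symbol matches, otherwise it hops to a run boundary of the needed
symbol *inside* the interval (one provably exists in that case), picking up
that boundary's exact document sample. Only when the match extends nowhere
does the length reset, relocating through the thresholds structure to the
nearest-context run of the needed symbol. Consequences, all tested exactly:
P decrements by 1 inside a match, an exact substring of a shred scores
`[m, m−1, …, 1]`, `0 ≤ P[i] ≤ MS[i]` against a brute-force matching-
statistics oracle, and every labeled substring truly occurs in its labeled
shred. A symbol absent from the reference scores 0 and leaves the matcher in
place. Cold start is the last BWT row (a run boundary, so its label is
exact) with length 0.

Matches are start-anchored, so the resumable state continues *leftward*:
feeding the last chunk of a query first and earlier chunks afterwards
reproduces the one-shot profile exactly. Real-time chunk arrival is
left-to-right, so the CLI's chunk mode instead re-evaluates increasing-
length signal prefixes (which also refreshes normalization); at full length
this is identical to whole-read classification by construction, and it is
what the chunked evaluation protocol measures.

## Classification

Peaks (`P[i] ≥ P[i−1]`, plus position 0 by convention, so a match beginning
at the first position is representable) each contribute `P[i]·C_d` to shred
`d = D[i]`. `C_d` is substring complexity δ = max_k (#distinct
k-substrings)/k, computed per shred at build time with k capped at 12 (for
these alphabet sizes the argmax occurs at small k) and normalized to (0, 1]
by the collection maximum; order-0 empirical entropy is available as a
build-time alternative with the same contract. Low-complexity shreds attract
long coincidental matches, and the weight discounts them.

Multiclass: the read takes the class of the arg-max shred; exact ties go to
the lowest shred id and are flagged; an all-zero profile is flagged
`zero_signal` but still labeled — every read receives a decision. Binary:
the top positive-class shred score over the top null-class shred score must
*strictly* exceed the spike-ratio threshold; a zero null score with a
positive signal counts as an infinite ratio (positive call), two zero scores
fall to the null class with a flag. Threshold 1.0 suits roughly balanced
mixtures; `calibrate_threshold` returns the linearly interpolated
(1 − q)-quantile of burn-in spike ratios for an expected positive fraction
q, warning below 50 reads or on degenerate ratios.

## Simulator

The generator emulates an R9.4-like pore: a geometric read length with the
stated mean (default 10 000 bases, truncated to the reference), uniform
strand, per-event dwell from a truncated normal ≥ 1 sample (mean 9, sd 8 by
default), and i.i.d. Gaussian amplitude noise with sd =
`amp_noise_sd_factor` × 1 pA (factor 2.0 by default, so the knob reads
directly in pA). Explicit stay/skip probabilities default to 0: in this
dwell regime segmentation errors already emerge naturally (a sd-8 dwell
distribution yields many 1–2-sample events the detector cannot resolve),
and the explicit knobs exist to isolate HPC behaviour in unit tests. The
simulator does not model adapter/stall artifacts, DAC quantization, pore
drift within a read, or level-dependent noise; synthetic accuracy numbers
therefore bound what the algorithm can do under its own assumptions rather
than predict accuracy on biological signal.

Every read carries truth (source, class, strand, start, per-sample k-mer
index), and `evaluate` computes confusion-matrix metrics, optionally
weighting reads by base length.

## Problem sizes used in the checks

The acceptance script and test suite run at desk scale, chosen so the whole
suite completes in a couple of minutes: brute-force BWT/threshold agreement
on random texts up to ~500 symbols over alphabets ≤ 7; PML/label properties
on 200 random query/collection pairs; a parameter-recovery study with two
random 50 kb references and 200 reads at the default noise settings
(accuracy and F1 ≥ 0.95 expected); duplication scaling with 3×400-symbol
shred sets copied 1–8×; chunked-versus-whole-read agreement on 20 reads.
Random references at 50 kb are far less repetitive than real genomes, so the
n/r ratios printed by these runs (~1.25) are a floor, not typical of
pangenome collections, where redundancy drives n/r up by orders of
magnitude.

## Known limitations

- Native FAST5/SLOW5/POD5 parsing and DAC calibration are out of scope; the
  signal container is a plain TSV.
- Thresholds are built from a full SA/LCP pass, bounding reference size by
  memory (fine at desk scale; O(r)-space constructions exist but are not
  implemented here).
- No null model: binary mode requires an indexed null class.
- Single-threaded; the per-read independence of the PML loop is the natural
  parallelization seam.
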