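import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

import sigclass as sc


NOISELESS = dict(amp_noise_sd_factor=0.0, dwell_mean=9.0, dwell_sd=0.0)


def read_pipeline(read, model, cfg, normalize=False):
    events = sc.detect_events(read.signal)
    if normalize:
        events, _ = sc.normalize_events(events, model)
    return sc.hpc_compress(sc.bin_events(events, cfg))


def test_noiseless_identity_keystone(model3, bin_cfg):
    # zero noise, zero stay/skip, constant dwell: the read pipeline output
    # equals the reference projection of the sampled substring exactly
    for seed in range(8):
        rng = np.random.default_rng(seed)
        ref = sc.random_reference(2500, rng)
        params = sc.SimParams(mean_read_length=1200, seed=seed, **NOISELESS)
        read = sc.simulate_read(ref, model3, params, rng=rng)
        got = read_pipeline(read, model3, bin_cfg)
        want = sc.reference_to_binseq(read.seq, model3, bin_cfg)
        assert np.array_equal(got.symbols, want.symbols), seed


def test_noiseless_identity_with_normalization(model3, bin_cfg):
    # over a reference containing every k-mer exactly once, a full-coverage
    # read's event statistics equal the model's, so normalization is an
    # exact fixed point and the identity holds through the full chain
    for seed in range(8):
        rng = np.random.default_rng(300 + seed)
        ref = sc.de_bruijn_reference(3, rng)
        params = sc.SimParams(mean_read_length=10**7, seed=seed, **NOISELESS)
        read = sc.simulate_read(ref, model3, params, rng=rng)
        assert read.length == len(ref)
        got = read_pipeline(read, model3, bin_cfg, normalize=True)
        want = sc.reference_to_binseq(read.seq, model3, bin_cfg)
        assert np.array_equal(got.symbols, want.symbols), seed


def test_stays_collapse_under_hpc(model3, bin_cfg):
    rng = np.random.default_rng(7)
    ref = sc.random_reference(2000, rng)
    params = sc.SimParams(mean_read_length=900, p_stay=0.5, seed=7, **NOISELESS)
    read = sc.simulate_read(ref, model3, params, rng=rng)
    got = read_pipeline(read, model3, bin_cfg)
    want = sc.reference_to_binseq(read.seq, model3, bin_cfg)
    assert np.array_equal(got.symbols, want.symbols)


def test_same_seed_identical_samples(model3):
    ref = sc.random_reference(1000, 4)
    params = sc.SimParams(seed=9)
    a = sc.simulate_read(ref, model3, params, rng=np.random.default_rng(9))
    b = sc.simulate_read(ref, model3, params, rng=np.random.default_rng(9))
    assert np.array_equal(a.signal.samples, b.signal.samples)
    assert a.strand == b.strand and a.start == b.start


def test_truth_indices_non_decreasing_and_tiled(model3):
    rng = np.random.default_rng(11)
    ref = sc.random_reference(1500, rng)
    params = sc.SimParams(mean_read_length=700, p_stay=0.2, p_skip=0.2, seed=11)
    read = sc.simulate_read(ref, model3, params, rng=rng)
    assert len(read.kmer_index) == len(read.signal.samples)
    assert np.all(np.diff(read.kmer_index) >= 0)


def test_read_too_short_reference(model3):
    with pytest.raises(ValueError):
        sc.simulate_read("ACG", model3, sc.SimParams(seed=0))


def test_de_bruijn_covers_every_kmer_once():
    for k in (2, 3, 4):
        for seed in (0, 1):
            seq = sc.de_bruijn_reference(k, seed)
            assert len(seq) == 4**k + k - 1
            kmers = [seq[i : i + k] for i in range(len(seq) - k + 1)]
            assert len(set(kmers)) == 4**k == len(kmers)


def test_dataset_mixture_within_binomial_bounds(model3):
    refs = [("A", "classA", sc.random_reference(800, 1)), ("B", "classB", sc.random_reference(800, 2))]
    params = sc.SimParams(mean_read_length=200, seed=5, **NOISELESS)
    reads, truth = sc.simulate_dataset(refs, model3, 200, params, {"classA": 0.5, "classB": 0.5})
    nA = int((truth["class"] == "classA").sum())
    lo, hi = binom.ppf([0.005, 0.995], 200, 0.5)
    assert lo <= nA <= hi
    assert len(reads) == 200 and len(truth) == 200


def test_dataset_single_read_and_errors(model3):
    refs = [("A", "classA", sc.random_reference(500, 1))]
    reads, truth = sc.simulate_dataset(refs, model3, 1, sc.SimParams(seed=1))
    assert len(reads) == 1 and len(truth) == 1
    with pytest.raises(ValueError):
        sc.simulate_dataset([], model3, 5, sc.SimParams(seed=1))
    with pytest.raises(ValueError):
        sc.simulate_dataset(refs, model3, 0, sc.SimParams(seed=1))


def test_dataset_renormalizes_weights(model3, caplog):
    refs = [("A", "classA", sc.random_reference(500, 1)), ("B", "classB", sc.random_reference(500, 2))]
    with caplog.at_level("WARNING"):
        _, truth = sc.simulate_dataset(
            refs, model3, 20, sc.SimParams(mean_read_length=100, seed=2, **NOISELESS),
            {"classA": 2.0, "classB": 2.0},
        )
    assert "renormalizing" in caplog.text
    assert set(truth["class"]) <= {"classA", "classB"}


def test_evaluate_perfect_predictions():
    truth = pd.DataFrame(
        {"read_id": ["a", "b"], "class": ["x", "y"], "length_bases": [10, 20]}
    )
    report = pd.DataFrame({"read_id": ["a", "b"], "predicted_class": ["x", "y"]})
    m = sc.evaluate(report, truth)
    assert m["accuracy"] == 1.0 and m["accuracy_weighted"] == 1.0
    assert m["per_class"]["x"]["f1"] == 1.0


def test_evaluate_length_weighting_example():
    # TP=2 (lengths 10, 10), FP=1 (length 20), FN=0 for the positive class
    truth = pd.DataFrame(
        {
            "read_id": ["a", "b", "c"],
            "class": ["pos", "pos", "neg"],
            "length_bases": [10, 10, 20],
        }
    )
    report = pd.DataFrame(
        {"read_id": ["a", "b", "c"], "predicted_class": ["pos", "pos", "pos"]}
    )
    m = sc.evaluate(report, truth, positive_class="pos")
    assert m["precision"] == pytest.approx(2 / 3)
    assert m["precision_weighted"] == pytest.approx(0.5)
    assert m["recall"] == 1.0


def test_evaluate_errors():
    truth = pd.DataFrame({"read_id": ["a"], "class": ["x"], "length_bases": [5]})
    report = pd.DataFrame({"read_id": ["zzz"], "predicted_class": ["x"]})
    with pytest.raises(ValueError, match="read_id mismatch"):
        sc.evaluate(report, truth)
    with pytest.raises(ValueError, match="empty truth"):
        sc.evaluate(report, truth.iloc[:0])
    with pytest.raises(ValueError, match="absent"):
        sc.evaluate(
            pd.DataFrame({"read_id": ["a"], "predicted_class": ["x"]}),
            truth,
            positive_class="nope",
        )


def test_noise_degrades_accuracy_monotonically(model3, bin_cfg):
    # trend property: more amplitude noise, same or worse mean accuracy
    refA = sc.random_reference(6000, 31)
    refB = sc.random_reference(6000, 32)
    docs = []
    for name, cls, seq in (("A", "cA", refA), ("B", "cB", refB)):
        for strand, s in (("+", seq), ("-", sc.revcomp(seq))):
            docs.append((f"{name}|0|{strand}", cls, sc.reference_to_binseq(s, model3, bin_cfg)))
    idx = sc.build_index(sc.shred_collection(docs, shred_size=100000))
    refs = [("A", "cA", refA), ("B", "cB", refB)]
    accs = []
    for noise in (0.0, 3.0, 6.0, 12.0, 24.0):
        params = sc.SimParams(
            mean_read_length=1200, amp_noise_sd_factor=noise, dwell_mean=9.0,
            dwell_sd=2.0, seed=77,
        )
        reads, _ = sc.simulate_dataset(refs, model3, 24, params)
        ok = sum(
            sc.classify_signal(r.signal, idx, model3, mode="multi").predicted_class
            == r.class_name
            for r in reads
        )
        accs.append(ok / len(reads))
    assert accs[0] >= 0.9
    assert accs[0] - accs[-1] >= 0.2
    assert all(b <= a + 0.10 for a, b in zip(accs, accs[1:]))  # near-monotone
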