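import numpy as np
import pytest

import sigclass as sc
from sigclass.quantize import BinSequence
from sigclass.rindex import initial_state, shred_delta, shred_entropy

from oracles import assert_index_matches_brute_force


def make_coll(docs, shred_size=50, **kw):
    return sc.shred_collection(docs, shred_size, **kw)


def random_coll(rng, n_bins=None, n_docs=None, max_len=120):
    n_bins = n_bins or int(rng.integers(2, 7))
    n_docs = n_docs or int(rng.integers(1, 4))
    docs = []
    for d in range(n_docs):
        L = int(rng.integers(5, max_len))
        sym = rng.integers(0, n_bins, size=L).astype(np.int32)
        docs.append((f"doc{d}", f"C{d % 2}", BinSequence(symbols=sym, n_bins=n_bins)))
    return make_coll(docs)


# -- shredding ---------------------------------------------------------------


def test_shred_arithmetic():
    bins = BinSequence(symbols=np.zeros(250, np.int32), n_bins=2)
    coll = sc.shred_collection([("d", "C", bins)], shred_size=100)
    lengths = [len(b) for _, b in coll.shreds]
    assert lengths == [100, 100, 50]
    short = sc.shred_collection([("d", "C", BinSequence(symbols=[0, 1], n_bins=2))], 100)
    assert short.n_shreds == 1


def test_shred_count_matches_ceil(rng):
    docs = []
    expected = 0
    for d in range(5):
        L = int(rng.integers(1, 400))
        expected += -(-L // 75)
        docs.append(("d%d" % d, "C", BinSequence(symbols=rng.integers(0, 4, L), n_bins=4)))
    coll = sc.shred_collection(docs, shred_size=75)
    assert coll.n_shreds == expected
    ids = [info.shred_id for info, _ in coll.shreds]
    assert ids == list(range(expected))  # dense ids


def test_empty_collection_rejected():
    with pytest.raises(ValueError):
        sc.shred_collection([], 100)
    with pytest.raises(ValueError):
        sc.shred_collection(
            [("d", "C", BinSequence(symbols=[], n_bins=2))], 100
        )


# -- construction vs brute force --------------------------------------------


def test_index_matches_brute_force_randomized(rng):
    for _ in range(25):
        coll = random_coll(rng)
        assert_index_matches_brute_force(sc.build_index(coll), coll)


def test_alternating_string_run_count():
    bins = BinSequence(symbols=np.tile([0, 1], 100), n_bins=2)
    coll = make_coll([("d", "C", bins)], shred_size=500)
    idx = sc.build_index(coll)
    assert_index_matches_brute_force(idx, coll)
    assert idx.r <= 8  # an alternating string is maximally repetitive


def test_duplicate_shreds_bounded_r_growth(rng):
    for _ in range(5):
        n_bins = 6
        sym = rng.integers(0, n_bins, size=200).astype(np.int32)
        one = make_coll([("d", "C", BinSequence(symbols=sym, n_bins=n_bins))], 500)
        two = make_coll(
            [
                ("d", "C", BinSequence(symbols=sym, n_bins=n_bins)),
                ("d2", "C", BinSequence(symbols=sym, n_bins=n_bins)),
            ],
            500,
        )
        r1 = sc.build_index(one).r
        r2 = sc.build_index(two).r
        assert r2 <= r1 + 2 * (n_bins + 1)


# -- matching statistics oracle ---------------------------------------------


def test_ms_oracle_hand_example():
    coll = make_coll([("d", "C", BinSequence(symbols=[1, 2, 1, 3, 1, 2], n_bins=4))])
    q = BinSequence(symbols=[2, 1, 3, 1], n_bins=4)
    # "2131", "131", "31", "1" all occur in "121312"
    assert sc.matching_statistics_oracle(q, coll).tolist() == [4, 3, 2, 1]


def test_ms_oracle_absent_symbol_and_full_shred():
    coll = make_coll([("d", "C", BinSequence(symbols=[0, 1, 0, 1], n_bins=4))])
    q = BinSequence(symbols=[3, 0], n_bins=4)
    assert sc.matching_statistics_oracle(q, coll).tolist() == [0, 1]
    full = BinSequence(symbols=[0, 1, 0, 1], n_bins=4)
    assert sc.matching_statistics_oracle(full, coll)[0] == 4


# -- PML computation ----------------------------------------------------------


def test_exact_substring_pml_single_shred(model3, bin_cfg):
    bins = sc.reference_to_binseq(sc.random_reference(800, 21), model3, bin_cfg)
    coll = make_coll([("d", "C", bins)], shred_size=10**6)  # one shred
    idx = sc.build_index(coll)
    m = 40
    q = BinSequence(symbols=bins.symbols[200 : 200 + m], n_bins=6, hpc=True)
    prof, _ = sc.compute_pmls(idx, q)
    assert prof.P.tolist() == list(range(m, 0, -1))
    assert np.all(prof.D == 0)


def test_pml_truncation_and_soundness(rng):
    for _ in range(30):
        coll = random_coll(rng, n_bins=5)
        idx = sc.build_index(coll)
        q = BinSequence(symbols=rng.integers(0, 5, size=50), n_bins=5)
        prof, _ = sc.compute_pmls(idx, q)
        ms = sc.matching_statistics_oracle(q, coll)
        assert np.all(prof.P >= 0)
        assert np.all(prof.P <= ms)
        assert sc.label_validity_check(prof, q, coll)


def test_pml_decrements_within_matches(toy_index, rng):
    _, idx = toy_index
    q = BinSequence(symbols=rng.integers(0, 6, size=200), n_bins=6)
    prof, _ = sc.compute_pmls(idx, q)
    drops = np.diff(prof.P)
    # every position is either one step down inside a match or a new peak
    assert np.all((drops == -1) | (prof.P[1:] >= prof.P[:-1]))


def test_absent_symbol_scores_zero(model3):
    cfg = sc.BinningConfig.from_model(model3, 6)
    # restrict the reference to symbols {0,1,2} by construction
    sym = np.array([0, 1, 2, 1, 0, 2, 1] * 10, dtype=np.int32)
    coll = make_coll([("d", "C", BinSequence(symbols=sym, n_bins=6))])
    idx = sc.build_index(coll)
    q = BinSequence(symbols=[5, 5, 0], n_bins=6)
    prof, _ = sc.compute_pmls(idx, q)
    assert prof.P.tolist()[:2] == [0, 0]
    assert prof.P[2] == 1
    del cfg


def test_forged_label_fails_validity(toy_index, rng):
    coll, idx = toy_index
    q = BinSequence(symbols=rng.integers(0, 6, size=60), n_bins=6)
    prof, _ = sc.compute_pmls(idx, q)
    assert sc.label_validity_check(prof, q, coll)
    if prof.P.max() >= 3:
        i = int(np.argmax(prof.P))
        D = prof.D.copy()
        D[i] = (D[i] + 1) % coll.n_shreds
        forged = sc.PMLProfile(P=prof.P, D=D)
        # forging is only detectable if the substring is unique to its shred
        ms_single = sc.matching_statistics_oracle(
            BinSequence(symbols=q.symbols[i : i + prof.P[i]], n_bins=6),
            sc.shred_collection(
                [("only", "C", coll.shreds[D[i]][1])], shred_size=10**6
            ),
        )
        if ms_single[0] < prof.P[i]:
            assert not sc.label_validity_check(forged, q, coll)


def test_all_zero_profile_vacuously_valid(toy_index):
    coll, _ = toy_index
    q = BinSequence(symbols=[0, 1, 2], n_bins=6)
    prof = sc.PMLProfile(P=np.zeros(3, int), D=np.zeros(3, int))
    assert sc.label_validity_check(prof, q, coll)


def test_query_symbol_out_of_range(toy_index):
    _, idx = toy_index
    with pytest.raises(ValueError):
        sc.compute_pmls(idx, BinSequence(symbols=[7], n_bins=8))


def test_streaming_resume_equals_one_shot(toy_index, rng):
    _, idx = toy_index
    q = BinSequence(symbols=rng.integers(0, 6, size=120), n_bins=6)
    one, final_state = sc.compute_pmls(idx, q)
    # matches are start-anchored: resume leftward by feeding the last chunk
    # first, then earlier chunks through the returned state
    state = None
    parts = []
    for a in range(90, -1, -30):
        chunk = BinSequence(symbols=q.symbols[a : a + 30], n_bins=6)
        prof, state = sc.compute_pmls(idx, chunk, state)
        parts.insert(0, prof)
    assert np.array_equal(np.concatenate([p.P for p in parts]), one.P)
    assert np.array_equal(np.concatenate([p.D for p in parts]), one.D)
    assert state == final_state


def test_cold_start_state(toy_index):
    _, idx = toy_index
    st = initial_state(idx)
    assert st.row == idx.n - 1
    assert st.length == 0


# -- complexity measures ------------------------------------------------------


def test_shred_delta_examples():
    assert shred_delta(np.array([0, 0, 0, 0])) == 1.0
    assert shred_delta(np.array([0, 1, 0, 1, 0, 1])) == 2.0  # 2 distinct 1-mers
    rng = np.random.default_rng(8)
    repetitive = np.tile([0, 1, 2], 60)
    random_shred = rng.integers(0, 6, size=180)
    assert shred_delta(repetitive) < shred_delta(random_shred)


def test_shred_entropy_examples():
    assert shred_entropy(np.zeros(10, int)) == 0.0
    assert abs(shred_entropy(np.array([0, 1, 0, 1])) - 1.0) < 1e-12


# -- serialization ------------------------------------------------------------


def test_serialize_round_trip(tmp_path, toy_index):
    _, idx = toy_index
    sc.serialize_index(idx, tmp_path / "idx")
    back = sc.load_index(tmp_path / "idx")
    assert back.n == idx.n and back.r == idx.r
    for attr in (
        "run_symbols",
        "run_lengths",
        "thresholds",
        "doc_first",
        "doc_last",
        "shred_complexity",
        "shred_classes",
        "shred_offsets",
    ):
        assert np.array_equal(getattr(back, attr), getattr(idx, attr)), attr
    assert back.class_table == idx.class_table
    assert back.shred_sources == idx.shred_sources
    # loaded index answers queries identically
    q = sc.BinSequence(symbols=np.arange(6, dtype=np.int32), n_bins=6)
    p1, _ = sc.compute_pmls(idx, q)
    p2, _ = sc.compute_pmls(back, q)
    assert np.array_equal(p1.P, p2.P) and np.array_equal(p1.D, p2.D)


def test_corrupt_index_rejected(tmp_path, toy_index):
    _, idx = toy_index
    sc.serialize_index(idx, tmp_path / "idx")
    path = tmp_path / "idx" / "thresholds.bin"
    path.write_bytes(path.read_bytes()[:-8])  # truncate
    with pytest.raises(ValueError):
        sc.load_index(tmp_path / "idx")


def test_manifest_reports_sizes(tmp_path, toy_index):
    import json

    _, idx = toy_index
    sc.serialize_index(idx, tmp_path / "idx")
    manifest = json.loads((tmp_path / "idx" / "manifest.json").read_text())
    assert manifest["n"] == idx.n and manifest["r"] == idx.r
    assert abs(manifest["n_over_r"] - idx.n / idx.r) < 1e-12


# -- repetition sublinearity --------------------------------------------------


def test_repeated_collections_grow_r_additively(rng):
    n_bins = 6
    base = [
        (
            "d%d" % i,
            "C",
            BinSequence(symbols=rng.integers(0, n_bins, 300).astype(np.int32), n_bins=n_bins),
        )
        for i in range(2)
    ]
    r = {}
    nr = {}
    for t in (1, 2, 4, 8):
        docs = [(f"{n}_{c}", cls, b) for c in range(t) for n, cls, b in base]
        idx = sc.build_index(sc.shred_collection(docs, shred_size=1000))
        r[t], nr[t] = idx.r, idx.n_over_r
    for t in (2, 4, 8):
        assert r[t] - r[1] <= 2 * (n_bins + 1)
    assert nr[1] < nr[2] < nr[4] < nr[8]
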