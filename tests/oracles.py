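"""Independent brute-force constructions used to validate the index.

Everything here is deliberately naive (sorted suffix lists, quadratic LCP)
and shares no code with the package's construction path.
"""

import numpy as np


def brute_force_index(coll):
    """Rebuild runs/thresholds/doc samples for a DocumentCollection by
    sorting suffixes directly.  Returns a dict of plain-python structures."""
    text = []
    dpos = []
    for info, bins in coll.shreds:
        text.extend(int(s) + 1 for s in bins.symbols)
        text.append(0)
        dpos.extend([info.shred_id] * (len(bins) + 1))
    text = tuple(text)
    n = len(text)
    sa = sorted(range(n), key=lambda i: text[i:])
    bwt = [text[(i - 1) % n] for i in sa]

    runs = []  # [symbol, length]
    for ch in bwt:
        if runs and runs[-1][0] == ch:
            runs[-1][1] += 1
        else:
            runs.append([ch, 1])
    starts = [0]
    for _, l in runs[:-1]:
        starts.append(starts[-1] + l)

    def lcp(a, b):
        x, y = text[a:], text[b:]
        i = 0
        while i < min(len(x), len(y)) and x[i] == y[i]:
            i += 1
        return i

    LCP = [0] + [lcp(sa[i - 1], sa[i]) for i in range(1, n)]

    thresholds = []
    doc_first = []
    doc_last = []
    last_run_of = {}
    for j, (ch, l) in enumerate(runs):
        doc_first.append(dpos[sa[starts[j]]])
        doc_last.append(dpos[sa[starts[j] + l - 1]])
        if ch in last_run_of:
            p = last_run_of[ch]
            lo = starts[p] + runs[p][1]
            hi = starts[j]
            window = LCP[lo : hi + 1]
            thresholds.append(lo + int(np.argmin(window)))
        else:
            thresholds.append(starts[j])
        last_run_of[ch] = j
    return {
        "n": n,
        "r": len(runs),
        "run_symbols": [r[0] for r in runs],
        "run_lengths": [r[1] for r in runs],
        "thresholds": thresholds,
        "doc_first": doc_first,
        "doc_last": doc_last,
    }


def assert_index_matches_brute_force(index, coll):
    want = brute_force_index(coll)
    assert index.n == want["n"]
    assert index.r == want["r"]
    assert index.run_symbols.tolist() == want["run_symbols"]
    assert index.run_lengths.tolist() == want["run_lengths"]
    assert index.thresholds.tolist() == want["thresholds"]
    assert index.doc_first.tolist() == want["doc_first"]
    assert index.doc_last.tolist() == want["doc_last"]
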