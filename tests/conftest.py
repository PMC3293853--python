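import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def brute_force_scan(riw, spacer, sequence, threshold):
    """Independent per-window scorer used as the scan oracle.

    Deliberately naive: pure-python loops, its own complement table and
    its own tandem handling (score first box + last box), sharing no code
    with argbox.scan beyond the weight matrix values.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = riw.shape[0]
    width = 2 * L + spacer if spacer is not None else L

    def box_score(window):
        return sum(riw[l][idx[b]] for l, b in enumerate(window))

    def window_score(window):
        if any(b not in idx for b in window):
            return None
        if spacer is None:
            return box_score(window)
        return box_score(window[:L]) + box_score(window[-L:])

    hits = []
    n = len(sequence)
    for o in range(n - width + 1):
        w = sequence[o:o + width]
        s = window_score(w)
        if s is not None and s >= threshold:
            hits.append((o, "+", s))
        wrc = "".join(comp[b] for b in reversed(w)) if all(
            b in comp for b in w) else None
        if wrc is not None:
            s = window_score(wrc)
            if s is not None and s >= threshold:
                hits.append((o, "-", s))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def random_dna(rng, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
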