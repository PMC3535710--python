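"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from cpgmut.core import A, C, G, T
from cpgmut.synth import _background_probs, _cgi_block_seq


def make_island_structured_seq(rng: np.random.Generator, length: int = 2000) -> str:
    """A 2-kb sequence shaped like real genomic DNA: CpG-depleted AT-rich
    background with 0-2 planted GC/CpG-rich blocks of mixed strength (some
    above, some below the island thresholds)."""
    gc = rng.uniform(0.30, 0.50)
    arr = rng.choice(np.array([A, C, G, T], np.uint8), size=length,
                     p=_background_probs(gc))
    cg = np.flatnonzero((arr[:-1] == C) & (arr[1:] == G))
    kill = cg[rng.random(len(cg)) < 0.7]
    arr[kill + 1] = np.where(rng.random(len(kill)) < 0.5, A, T)
    if rng.random() < 0.7:
        for _ in range(rng.integers(1, 3)):
            ln = int(rng.uniform(300, 1200))
            st = int(rng.integers(0, length - ln))
            arr[st:st + ln] = _cgi_block_seq(
                ln, rng.uniform(0.50, 0.80), rng.uniform(0.05, 0.5), rng)
    return arr.tobytes().decode()


def exhaustive_maximal_islands(seq: str, min_length: int = 500,
                               min_gc: float = 0.55,
                               min_oe: float = 0.65) -> list[tuple[int, int]]:
    """Brute-force oracle: all maximal intervals (>= min_length) satisfying
    the GC and O/E thresholds, found by checking every window of every
    length via prefix sums. Independent of the package's scanner."""
    arr = np.frombuffer(seq.encode(), np.uint8)
    L = len(arr)
    is_c = arr == C
    is_g = arr == G
    is_cpg = np.zeros(L, bool)
    is_cpg[:-1] = is_c[:-1] & is_g[1:]
    z = np.zeros(1, np.int64)
    cum_c = np.concatenate([z, np.cumsum(is_c)])
    cum_g = np.concatenate([z, np.cumsum(is_g)])
    cum_p = np.concatenate([z, np.cumsum(is_cpg)])
    all_s, all_e = [], []
    for ln in range(min_length, L + 1):
        s = np.arange(0, L - ln + 1)
        e = s + ln
        n_c = cum_c[e] - cum_c[s]
        n_g = cum_g[e] - cum_g[s]
        n_p = cum_p[e - 1] - cum_p[s]
        gc = (n_c + n_g) / ln
        oe = np.where(n_c * n_g > 0, n_p * ln / np.maximum(n_c * n_g, 1), 0.0)
        ok = (gc >= min_gc) & (oe >= min_oe)
        if ok.any():
            all_s.append(s[ok])
            all_e.append(e[ok])
    if not all_s:
        return []
    S = np.concatenate(all_s)
    E = np.concatenate(all_e)
    order = np.lexsort((-E, S))
    S, E = S[order], E[order]
    out: list[tuple[int, int]] = []
    max_e = -1
    for s_, e_ in zip(S, E):  # an interval is maximal iff no earlier one covers it
        if e_ > max_e:
            out.append((int(s_), int(e_)))
            max_e = int(e_)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
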