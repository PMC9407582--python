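"""Independent oracles used by the test suite.

These deliberately re-derive results by the most transparent route
available (exhaustive dynamic programming, brute-force scans, textbook
eigendecomposition) and stay independent of the implementation paths they
check.
"""

from __future__ import annotations

import itertools

import numpy as np

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, length))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def gotoh_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> float:
    """Exhaustive affine-gap global alignment score (three-matrix Gotoh).

    Gap of length L costs gap_open + (L - 1) * gap_extend.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a base vs '-')
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(
                M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend, Y[i - 1, j] + gap_open
            )
            Y[i, j] = max(
                M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend, X[i, j - 1] + gap_open
            )
    return float(max(M[n, m], X[n, m], Y[n, m]))


def brute_force_primer_scan(template: str, primer: str, max_mismatch: int):
    """Position/strand/mismatch triples by direct character comparison."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[c] for c in reversed(primer))
    hits = []
    for strand, probe in (("+", primer), ("-", rc)):
        for start in range(len(template) - len(probe) + 1):
            mm = sum(1 for x, y in zip(template[start : start + len(probe)], probe) if x != y)
            if mm <= max_mismatch:
                hits.append((start + 1, strand, mm))
    hits.sort()
    return hits


def brute_force_complete_linkage(x: np.ndarray):
    """O(n^3) agglomeration under complete linkage / Euclidean distance.

    Returns the merge sequence as (frozenset_a, frozenset_b, height),
    breaking ties by the lowest involved row index.
    """
    clusters: list[frozenset] = [frozenset([i]) for i in range(len(x))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = max(
                float(np.linalg.norm(x[i] - x[j])) for i in a for j in b
            )
            key = (d, *sorted((min(a), min(b))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, *_), a, b = best
        merges.append((a, b, d))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges


def pca_eigen_oracle(x: np.ndarray, k: int):
    """PCA through the covariance eigendecomposition.

    Same conventions as the implementation under test: mean-centering,
    no scaling, each component's largest-magnitude loading positive.
    """
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(k):
        pivot = np.argmax(np.abs(evecs[:, j]))
        if evecs[pivot, j] < 0:
            evecs[:, j] *= -1
    scores = xc @ evecs[:, :k]
    var = evals / evals.sum()
    return scores, evecs[:, :k], var[:k]
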