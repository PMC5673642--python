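"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import numpy as np


def smith_waterman_score(a: str, b: str, match: int = 1, mismatch: int = -2,
                         gap_open: int = 5, gap_extend: int = 2) -> int:
    """Exhaustive affine-gap local alignment score (full DP matrix).

    A gap of length g costs gap_open + g * gap_extend, matching the
    production scoring convention.
    """
    n, m = len(a), len(b)
    NEG = -(10 ** 9)
    H_prev = [0] * (m + 1)
    F = [NEG] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        H_cur = [0] * (m + 1)
        E = NEG
        ai = a[i - 1]
        for j in range(1, m + 1):
            E = max(E - gap_extend, H_cur[j - 1] - gap_open - gap_extend)
            F[j] = max(F[j] - gap_extend, H_prev[j] - gap_open - gap_extend)
            sub = match if ai == b[j - 1] else mismatch
            h = H_prev[j - 1] + sub
            if E > h:
                h = E
            if F[j] > h:
                h = F[j]
            if h < 0:
                h = 0
            H_cur[j] = h
            if h > best:
                best = h
        H_prev = H_cur
    return best


def covariance_eigen_pca(X: np.ndarray, n_components: int):
    """PCA oracle: explicit covariance matrix eigendecomposition."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (X.shape[0] - 1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    comps = V[:, :n_components].T
    flip = np.sign(comps[np.arange(n_components), np.argmax(np.abs(comps), axis=1)])
    comps = comps * flip[:, None]
    scores = Xc @ comps.T
    return scores, comps, w / w.sum()


def canonical_tetramer_classes() -> int:
    """Brute-force count of strand-collapsed 4-mer classes."""
    bases = "ACGT"
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    seen = set()
    from itertools import product

    for kmer in product(bases, repeat=4):
        s = "".join(kmer)
        rc = "".join(comp[c] for c in reversed(s))
        seen.add(min(s, rc))
    return len(seen)
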