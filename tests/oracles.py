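"""Independent brute-force oracles for the summary statistics and ABC
primitives.  These deliberately use naive enumeration (per-site loops,
explicit haplotype pairs, string comparison) so they share no code path
with the package implementations they check."""

from __future__ import annotations

import math
from itertools import combinations, permutations

import numpy as np


def oracle_sfs_counts(mat: np.ndarray) -> tuple[int, int, int]:
    n = mat.shape[0]
    seg = sing = doub = 0
    for j in range(mat.shape[1]):
        col = [int(x) for x in mat[:, j]]
        ones = sum(col)
        if 0 < ones < n:
            seg += 1
        minor = min(ones, n - ones)
        if minor == 1:
            sing += 1
        elif minor == 2:
            doub += 1
    return seg, sing, doub


def oracle_pi(mat: np.ndarray) -> float:
    """Mean pairwise difference by explicit pair enumeration."""
    n = mat.shape[0]
    total = 0
    for i, j in combinations(range(n), 2):
        total += int(np.sum(mat[i] != mat[j]))
    return total / (n * (n - 1) / 2)


def oracle_tajimas_d(mat: np.ndarray) -> float:
    """Second, independent coding of the Tajima (1989) closed form."""
    n = mat.shape[0]
    seg, _, _ = oracle_sfs_counts(mat)
    if seg == 0:
        return math.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (oracle_pi(mat) - seg / a1) / math.sqrt(e1 * seg + e2 * seg * (seg - 1))


def oracle_haplotype_counts(mat: np.ndarray) -> tuple[int, int]:
    strings = ["".join(str(int(x)) for x in row) for row in mat]
    counts: dict[str, int] = {}
    for s in strings:
        counts[s] = counts.get(s, 0) + 1
    return len(counts), max(counts.values())


def oracle_shared_private(mat1: np.ndarray, mat2: np.ndarray) -> tuple[int, int, int]:
    s1 = {"".join(str(int(x)) for x in row) for row in mat1}
    s2 = {"".join(str(int(x)) for x in row) for row in mat2}
    return len(s1 & s2), len(s1 - s2), len(s2 - s1)


def oracle_hudson_fst(mat1: np.ndarray, mat2: np.ndarray) -> float:
    """Hudson FST by explicit within/between pairwise differences."""
    n1, n2 = mat1.shape[0], mat2.shape[0]
    hw = []
    hb = []
    for j in range(mat1.shape[1]):
        w1 = sum(int(mat1[i, j] != mat1[k, j]) for i, k in combinations(range(n1), 2))
        w2 = sum(int(mat2[i, j] != mat2[k, j]) for i, k in combinations(range(n2), 2))
        hw.append((w1 / (n1 * (n1 - 1) / 2) + w2 / (n2 * (n2 - 1) / 2)) / 2)
        b = sum(int(mat1[i, j] != mat2[k, j]) for i in range(n1) for k in range(n2))
        hb.append(b / (n1 * n2))
    if sum(hb) == 0:
        return math.nan
    return 1 - (sum(hw) / len(hw)) / (sum(hb) / len(hb))


def oracle_best_assignment(cand: np.ndarray, manifest: np.ndarray) -> float:
    """Minimal total |candidate - manifest| over all injective assignments."""
    best = math.inf
    for perm in permutations(range(len(cand)), len(manifest)):
        total = sum(abs(cand[p] - m) for p, m in zip(perm, manifest))
        best = min(best, total)
    return best
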