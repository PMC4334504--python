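"""Independent brute-force reference implementations.

These are written directly from the defining formulas, with plain Python
loops and no shared code paths with the package, so they can serve as
oracles in equivalence tests.
"""

from __future__ import annotations

import math
import re
from collections import Counter

import numpy as np
import pywt

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def distribution_oracle(seq: str) -> list:
    out = []
    for aa in AMINO_ACIDS:
        positions = [i for i, r in enumerate(seq) if r == aa]
        n = len(positions)
        if n < 2:
            out.append(0.0)
            continue
        dists = [p - positions[0] for p in positions]
        mean = sum(dists) / n
        out.append(sum((d - mean) ** 2 for d in dists) / n)
    return out


def transition_oracle(seq: str, groups) -> list:
    """groups: list of (name, member-set) in scheme order."""
    group_of = {aa: g for g, (_, members) in enumerate(groups) for aa in members}
    pair_counts = Counter()
    for a, b in zip(seq, seq[1:]):
        pair_counts[(group_of[a], group_of[b])] += 1
    out = []
    for i in range(10):
        for j in range(i + 1, 10):
            out.append((pair_counts[(i, j)] + pair_counts[(j, i)]) / len(seq))
    return out


def pseaac_oracle(seq: str, scales, eta: int = 20, w: float = 0.05) -> list:
    """scales: list of dicts amino acid -> standardized value."""

    def theta_pair(a, b):
        return sum((s[a] - s[b]) ** 2 for s in scales) / len(scales)

    L = len(seq)
    thetas = [
        sum(theta_pair(seq[j], seq[j + k]) for j in range(L - k)) / (L - k)
        for k in range(1, eta + 1)
    ]
    freqs = [seq.count(aa) / L for aa in AMINO_ACIDS]
    denom = 1.0 + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


def dwt_cascade_oracle(signal, wavelet: str = "db4", level: int = 4) -> list:
    """Multilevel DWT via explicit symmetric extension + convolve + downsample.

    Returns coefficients ordered [cA_level, cD_level, ..., cD_1], matching
    the layout of a multilevel decomposition.
    """
    w = pywt.Wavelet(wavelet)
    flen = w.dec_len
    cur = np.asarray(signal, dtype=float)
    details = []
    for _ in range(level):
        n_out = (len(cur) + flen - 1) // 2
        ext = np.concatenate([cur[flen - 2 :: -1], cur, cur[: -flen : -1]])
        ca = np.convolve(ext, w.dec_lo, mode="valid")[1::2][:n_out]
        cd = np.convolve(ext, w.dec_hi, mode="valid")[1::2][:n_out]
        details.append(cd)
        cur = ca
    return [cur] + details[::-1]


def pssm_theta_oracle(scores, lag_max: int = 4) -> list:
    """Nested-loop evaluation of the lagged squared-difference descriptor."""
    E = [[1.0 / (1.0 + math.exp(-x)) for x in row] for row in scores]
    L = len(E)
    out = []
    for k in range(1, lag_max + 1):
        for i in range(20):
            total = sum((E[j][i] - E[j + k][i]) ** 2 for j in range(L - k))
            out.append(total / (L - k))
    return out


def segment_stats_oracle(binary: str) -> dict:
    """Run statistics of a '1'/'0' string via regex, for both classes."""
    ones = [len(m) for m in re.findall(r"1+", binary)]
    zeros = [len(m) for m in re.findall(r"0+", binary)]
    return {
        "n_ones": len(ones),
        "n_zeros": len(zeros),
        "min_ones": min(ones) if ones else 0,
        "max_ones": max(ones) if ones else 0,
        "min_zeros": min(zeros) if zeros else 0,
        "max_zeros": max(zeros) if zeros else 0,
    }


def igr_oracle(codes, labels) -> float:
    """Dictionary-based evaluation of the gain-ratio definition."""

    def entropy(counter):
        total = sum(counter.values())
        return -sum(
            (c / total) * math.log2(c / total) for c in counter.values() if c > 0
        )

    n = len(labels)
    h_class = entropy(Counter(labels))
    h_feature = entropy(Counter(codes))
    if h_feature == 0:
        return 0.0
    h_cond = 0.0
    for value in set(codes):
        sub = [lab for c, lab in zip(codes, labels) if c == value]
        h_cond += (len(sub) / n) * entropy(Counter(sub))
    return (h_class - h_cond) / h_feature
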