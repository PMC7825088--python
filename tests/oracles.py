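"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and shares no code with the package
implementation paths it checks.
"""

from __future__ import annotations

import numpy as np


def components_brute_force(labels, values, cutoff):
    """Connected components by repeated full-matrix scanning."""
    n = len(labels)
    comp = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if i != j and values[i][j] <= cutoff:
                    new = min(comp[i], comp[j])
                    if comp[i] != new or comp[j] != new:
                        comp[i] = comp[j] = new
                        changed = True
    groups = {}
    for i, c in enumerate(comp):
        groups.setdefault(c, set()).add(labels[i])
    return sorted(frozenset(g) for g in groups.values())


def exhaustive_modified_cosine(a, b, tol):
    """Maximum one-to-one matching score by exhaustive enumeration.

    ``a``/``b`` are normalized Spectrum objects with few peaks.
    """
    shift = a.precursor_mz - b.precursor_mz
    pairs = []
    for i in range(a.n_peaks):
        for j in range(b.n_peaks):
            d = a.mz[i] - b.mz[j]
            if abs(d) <= tol or abs(d - shift) <= tol:
                pairs.append((i, j))
    best = [0.0, 0]

    def rec(k, used_a, used_b, score, matched):
        if k == len(pairs):
            if score > best[0] + 1e-15:
                best[0], best[1] = score, matched
            return
        rec(k + 1, used_a, used_b, score, matched)
        i, j = pairs[k]
        if i not in used_a and j not in used_b:
            rec(k + 1, used_a | {i}, used_b | {j},
                score + a.intensity[i] * b.intensity[j], matched + 1)

    rec(0, frozenset(), frozenset(), 0.0, 0)
    return best[0]


def exact_kmer_jaccard(seq_a: str, seq_b: str, k: int) -> float:
    """Exact Jaccard of canonical k-mer sets, by direct set construction."""
    comp = str.maketrans("ACGT", "TGCA")

    def canon_set(s):
        out = set()
        for i in range(len(s) - k + 1):
            kmer = s[i:i + k]
            if set(kmer) - set("ACGT"):
                continue
            rc = kmer.translate(comp)[::-1]
            out.add(min(kmer, rc))
        return out

    sa, sb = canon_set(seq_a), canon_set(seq_b)
    union = sa | sb
    return len(sa & sb) / len(union) if union else 0.0
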