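"""Pairwise distances between biosynthetic gene clusters.

A BGC is represented by its ordered protein-domain architecture plus one
sequence token per domain copy. The distance blends three ingredients,
mirroring the components of domain-based cluster comparison used in gene
cluster family networking:

* **Domain Jaccard (J)** — set overlap of domain families (copies collapsed).
* **Adjacency index (AI)** — Jaccard over the sets of *ordered* adjacent
  domain pairs, capturing synteny of the architectures.
* **Domain sequence similarity (DSS)** — over shared domain families, the
  mean normalized token identity under a greedy best pairing of the copies;
  unmatched copies score 0.

``distance = 1 - (wJ*J + wA*AI + wD*DSS)`` with default weights
``(0.2, 0.3, 0.5)``. The result is a symmetric premetric on [0,1] with zero
diagonal; the triangle inequality is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import ParameterError

#: Biosynthetic class vocabulary (gene cluster family histograms).
BGC_CLASSES = (
    "NRPS", "T1PKS", "T3PKS", "terpene", "bacteriocin",
    "cyanobactin", "hybrid", "CDPS", "hglE-KS", "other",
)


@dataclass(frozen=True)
class BGCRecord:
    """One biosynthetic gene cluster as an ordered domain architecture."""

    id: str
    genome_id: str
    class_label: str
    complete_flag: bool
    domains: tuple[str, ...]
    domain_seqs: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "domains", tuple(self.domains))
        object.__setattr__(self, "domain_seqs", tuple(self.domain_seqs))
        if len(self.domains) != len(self.domain_seqs):
            raise ValueError(
                f"BGC {self.id}: domains and domain_seqs lengths differ "
                f"({len(self.domains)} vs {len(self.domain_seqs)})")
        if len(self.domains) < 1:
            raise ValueError(f"BGC {self.id}: empty architecture")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with row/column labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match "
                             f"{n} labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric within 1e-12")
        if np.any(np.abs(np.diag(v)) > 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("distances must lie in [0,1]")
        self.values = v

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


def domain_jaccard(a: BGCRecord, b: BGCRecord) -> float:
    """Jaccard similarity of the two domain-family sets (copies collapsed)."""
    sa, sb = set(a.domains), set(b.domains)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def _adjacent_pairs(domains: Sequence[str]) -> set[tuple[str, str]]:
    return {(domains[i], domains[i + 1]) for i in range(len(domains) - 1)}


def adjacency_index(a: BGCRecord, b: BGCRecord) -> float:
    """Jaccard over ordered adjacent domain pairs; order-sensitive.

    Falls back to :func:`domain_jaccard` when either architecture has a
    single domain (no adjacent pairs exist).
    """
    if len(a.domains) < 2 or len(b.domains) < 2:
        return domain_jaccard(a, b)
    pa, pb = _adjacent_pairs(a.domains), _adjacent_pairs(b.domains)
    union = pa | pb
    if not union:
        return 0.0
    return len(pa & pb) / len(union)


def _token_identity(s: str, t: str) -> float:
    """Normalized identity of two tokens: matches / max length."""
    if not s and not t:
        return 1.0
    m = sum(c1 == c2 for c1, c2 in zip(s, t))
    return m / max(len(s), len(t))


def domain_seq_similarity(a: BGCRecord, b: BGCRecord) -> float:
    """Mean token identity over shared domain families.

    Within each shared family the copies of the two records are paired
    greedily by descending identity; unmatched copies contribute 0. Records
    sharing no domain family score 0.
    """
    fams_a: dict[str, list[str]] = {}
    for d, s in zip(a.domains, a.domain_seqs):
        fams_a.setdefault(d, []).append(s)
    fams_b: dict[str, list[str]] = {}
    for d, s in zip(b.domains, b.domain_seqs):
        fams_b.setdefault(d, []).append(s)
    shared = sorted(set(fams_a) & set(fams_b))
    if not shared:
        return 0.0
    total = 0.0
    n_slots = 0
    for fam in shared:
        toks_a, toks_b = fams_a[fam], fams_b[fam]
        pairs = sorted(
            ((_token_identity(s, t), i, j)
             for i, s in enumerate(toks_a) for j, t in enumerate(toks_b)),
            key=lambda x: (-x[0], x[1], x[2]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for ident, i, j in pairs:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            total += ident
        # unmatched copies (count difference) score 0 but occupy slots
        n_slots += max(len(toks_a), len(toks_b))
    return total / n_slots


DEFAULT_WEIGHTS = (0.2, 0.3, 0.5)


def bgc_distance(a: BGCRecord, b: BGCRecord,
                 weights: tuple[float, float, float] = DEFAULT_WEIGHTS) -> float:
    """Weighted distance ``1 - (wJ*J + wA*AI + wD*DSS)`` in [0,1]."""
    wj, wa, wd = weights
    if min(weights) < 0:
        raise ParameterError("weights: must be nonnegative")
    if abs(wj + wa + wd - 1.0) > 1e-9:
        raise ParameterError(f"weights: must sum to 1, got {wj + wa + wd}")
    sim = (wj * domain_jaccard(a, b)
           + wa * adjacency_index(a, b)
           + wd * domain_seq_similarity(a, b))
    return min(1.0, max(0.0, 1.0 - sim))


def pairwise_distances(bgcs: Sequence[BGCRecord],
                       weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
                       ) -> DistanceMatrix:
    """All-vs-all BGC distance matrix.

    Raises on duplicate ids; requires at least two records.
    """
    if len(bgcs) < 2:
        raise ValueError("need at least 2 BGCs for a pairwise matrix")
    ids = [b.id for b in bgcs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate BGC ids: {dupes}")
    n = len(bgcs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bgc_distance(bgcs[i], bgcs[j], weights)
    return DistanceMatrix(labels=list(ids), values=d)
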