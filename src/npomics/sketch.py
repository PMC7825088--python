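"""MinHash genome sketching and Mash-style distance.

Each genome is reduced to the ``s`` smallest 64-bit hash values of its
canonical k-mers (bottom-s MinHash). The Jaccard index of two k-mer sets is
estimated from the merged bottom-s sketch and converted to an evolutionary
distance proxy ``d = -ln(2j/(1+j))/k``. Significance of the observed sketch
overlap is a binomial tail probability under the null that the two genomes
share k-mers only by hash collision chance. A genome is a "rare" singleton
when no partner passes both the distance and the p-value thresholds.

Hashing is a seeded splitmix64-style 64-bit mixer over 2-bit packed k-mers,
so sketches are deterministic, portable across platforms, and comparable
only between equal ``k`` and equal hash seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .config import PipelineConfig

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# base -> 2-bit code; anything else marks the k-mer invalid
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass
class Sketch:
    """Bottom-s MinHash signature of a genome's canonical k-mer set."""

    genome_id: str
    k: int
    s: int
    hashes: np.ndarray        # sorted, strictly increasing uint64
    genome_kmer_count: int    # distinct canonical k-mers in the genome
    hash_seed: int = 42

    def __post_init__(self):
        h = np.asarray(self.hashes, dtype=np.uint64)
        if h.size > 1 and not (h[1:] > h[:-1]).all():
            raise ValueError("sketch hashes must be strictly increasing")
        if h.size > self.s:
            raise ValueError("sketch larger than declared size s")
        self.hashes = h


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer (uint64 in, uint64 out)."""
    x = x.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        x += np.uint64(0x9E3779B97F4A7C15)
        z = x
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
    return z


def _encode_kmers(sequence: str, k: int) -> np.ndarray:
    """2-bit pack every valid k-mer window into a uint64 (requires k<=32).

    Windows containing non-ACGT characters are skipped. Returns the
    canonical code per window: min(forward, reverse complement).
    """
    if k > 32:
        raise ValueError("k must be <= 32 for 64-bit packing")
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    # sliding windows of codes
    idx = np.arange(n)[:, None] + np.arange(k)[None, :]
    win = codes[idx]
    valid = (win >= 0).all(axis=1)
    win = win[valid].astype(np.uint64)
    if win.size == 0:
        return np.empty(0, dtype=np.uint64)
    weights_fwd = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd = win @ weights_fwd
    # reverse complement: complement code = 3 - code, reversed order
    rc_win = (np.uint64(3) - win)[:, ::-1]
    rev = rc_win @ weights_fwd
    return np.minimum(fwd, rev)


def sketch(sequence: str, genome_id: str = "", k: int = 21, s: int = 1000,
           hash_seed: int = 42) -> Sketch:
    """Bottom-s MinHash sketch of the canonical k-mer set of ``sequence``."""
    if len(sequence) < k:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than k={k}")
    kmers = np.unique(_encode_kmers(sequence, k))
    hashes = np.unique(_splitmix64(kmers ^ np.uint64(hash_seed & 0xFFFFFFFFFFFFFFFF)))
    bottom = hashes[:s] if hashes.size > s else hashes
    return Sketch(genome_id=genome_id, k=k, s=s, hashes=bottom,
                  genome_kmer_count=int(kmers.size), hash_seed=hash_seed)


def jaccard_estimate(a: Sketch, b: Sketch) -> tuple[float, int, int]:
    """Mash bottom-s merged Jaccard estimator.

    Merges the two hash lists, keeps the s smallest distinct values of the
    union, and returns ``(j, shared, union_sampled)`` where ``j`` is the
    fraction of those present in both sketches.
    """
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} vs {b.k}")
    if a.hash_seed != b.hash_seed:
        raise ValueError("hash seed mismatch; sketches not comparable")
    union = np.union1d(a.hashes, b.hashes)
    s = min(a.s, b.s)
    sampled = union[:s] if union.size > s else union
    if sampled.size == 0:
        return 0.0, 0, 0
    shared = int(np.intersect1d(sampled,
                                np.intersect1d(a.hashes, b.hashes)).size)
    return shared / sampled.size, shared, int(sampled.size)


def mash_distance(j: float, k: int) -> float:
    """Convert a Jaccard estimate to a mutation-distance proxy.

    ``d = -(1/k) * ln(2j / (1+j))`` for j > 0, capped at 1.0; j = 0 maps
    to the cap.
    """
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"jaccard must lie in [0,1], got {j}")
    if j == 0.0:
        return 1.0
    d = -np.log(2.0 * j / (1.0 + j)) / k
    return float(min(d, 1.0))


def mash_pvalue(shared: int, union_sampled: int,
                kmer_count_a: int, kmer_count_b: int,
                hash_space: float = 2.0 ** 64) -> float:
    """Binomial tail probability of observing >= ``shared`` matches by chance.

    The null per-draw match probability is
    ``r = wa*wb / (wa + wb - wa*wb)`` with ``w = kmer_count / hash_space``
    (the chance a random hash value belongs to both genomes given it
    belongs to at least one).
    """
    if kmer_count_a <= 0 or kmer_count_b <= 0:
        raise ValueError("genome k-mer counts must be positive")
    if shared == 0:
        return 1.0
    wa = kmer_count_a / hash_space
    wb = kmer_count_b / hash_space
    r = (wa * wb) / (wa + wb - wa * wb)
    # P(X >= shared), X ~ Binom(union_sampled, r)
    return float(binom.sf(shared - 1, union_sampled, r))


@dataclass
class MashPair:
    genome_a: str
    genome_b: str
    distance: float
    pvalue: float
    shared: int
    union_sampled: int


def mash_all_pairs(sketches: list[Sketch]) -> list[MashPair]:
    """Distance + p-value for every unordered pair of sketches."""
    pairs = []
    for i in range(len(sketches)):
        for jx in range(i + 1, len(sketches)):
            a, b = sketches[i], sketches[jx]
            jac, shared, union_sampled = jaccard_estimate(a, b)
            d = mash_distance(jac, a.k)
            p = (1.0 if union_sampled == 0 else
                 mash_pvalue(shared, union_sampled,
                             a.genome_kmer_count, b.genome_kmer_count))
            pairs.append(MashPair(a.genome_id, b.genome_id, d, p,
                                  shared, union_sampled))
    return pairs


def find_rare(sketches: list[Sketch], cfg: PipelineConfig,
              ) -> tuple[list[str], list[MashPair]]:
    """Identify singleton ("rare") genomes.

    A genome is rare iff it has no partner with distance <= cfg.mash_dist_max
    AND p-value <= cfg.mash_p_max. Returns (rare genome ids, all pairs).
    """
    pairs = mash_all_pairs(sketches)
    networked: set[str] = set()
    for p in pairs:
        if p.distance <= cfg.mash_dist_max and p.pvalue <= cfg.mash_p_max:
            networked.add(p.genome_a)
            networked.add(p.genome_b)
    rare = sorted(s.genome_id for s in sketches
                  if s.genome_id not in networked)
    return rare, pairs
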