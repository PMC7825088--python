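"""Genome prioritization by gene-cluster-family beta-diversity.

The similarity network is converted into a binary genome x GCF
presence/absence matrix (singleton BGCs are not families and do not count).
Pairwise dissimilarity between genomes — Bray-Curtis or Jaccard on the
binary rows — is averaged per genome; genomes whose average dissimilarity
exceeds a threshold (default strictly above 0.95) are classified as
high-diversity, the prioritization signal for natural-product discovery.
Classical PCoA ordination and a GCF rarefaction curve (with a
Michaelis-Menten/Clench saturation fit) complete the picture.

On presence/absence data Jaccard and Bray-Curtis are monotone transforms of
one another (J = 2BC/(1+BC)), so the high/low ranking is robust to the
metric choice even though the numeric scores differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import squareform

from .families import GCFPartition


@dataclass
class PresenceMatrix:
    """Binary genome x GCF incidence matrix."""

    genome_ids: list[str]
    gcf_ids: list[str]
    values: np.ndarray  # shape (n_genomes, n_gcfs), entries 0/1
    excluded_genomes: list[str] | None = None  # only singleton BGCs

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.size and not np.isin(v, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0/1")
        self.values = v.astype(np.int8).reshape(
            len(self.genome_ids), len(self.gcf_ids))
        if self.excluded_genomes is None:
            self.excluded_genomes = []

    def row(self, genome_id: str) -> np.ndarray:
        return self.values[self.genome_ids.index(genome_id)]


@dataclass
class DiversityResult:
    genome_ids: list[str]
    pairwise: np.ndarray
    average_per_genome: dict[str, float]
    classification: dict[str, str]  # genome -> "high" | "low"
    metric: str
    threshold: float


@dataclass
class PCoAResult:
    genome_ids: list[str]
    coordinates: np.ndarray          # genomes x positive axes
    eigenvalues: np.ndarray          # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues


@dataclass
class RarefactionCurve:
    depths: np.ndarray
    mean_gcf_count: np.ndarray
    sd: np.ndarray
    permutations: int
    seed: int


def presence_matrix(partition: GCFPartition,
                    genome_of: dict[str, str]) -> PresenceMatrix:
    """Build the genome x GCF incidence matrix from a partition.

    Entry (g, f) is 1 iff any member BGC of family f belongs to genome g.
    Genomes whose BGCs are all singletons end up with an all-zero row; they
    are excluded from the matrix and reported in ``excluded_genomes``.
    """
    for bgc_id in partition.all_ids():
        if bgc_id not in genome_of:
            raise ValueError(f"BGC {bgc_id!r} has no genome mapping")
    genomes = sorted({genome_of[b] for b in partition.all_ids()})
    gcf_ids = sorted(partition.families)
    gidx = {g: i for i, g in enumerate(genomes)}
    values = np.zeros((len(genomes), len(gcf_ids)), dtype=np.int8)
    for j, fid in enumerate(gcf_ids):
        for member in partition.families[fid]:
            values[gidx[genome_of[member]], j] = 1
    present = values.any(axis=1)
    excluded = [g for g, keep in zip(genomes, present) if not keep]
    kept = [g for g, keep in zip(genomes, present) if keep]
    return PresenceMatrix(genome_ids=kept, gcf_ids=gcf_ids,
                          values=values[present], excluded_genomes=excluded)


def beta_diversity(pm: PresenceMatrix, metric: str = "braycurtis",
                   ) -> np.ndarray:
    """Pairwise dissimilarity between genomes on binary GCF rows.

    jaccard: ``1 - |A&B| / |A|B|``; braycurtis: ``1 - 2|A&B| / (|A|+|B|)``.
    Two genomes with empty GCF sets are defined as identical (0); empty vs
    nonempty is maximally dissimilar (1).
    """
    if metric not in ("braycurtis", "jaccard"):
        raise ValueError(f"unknown metric {metric!r}")
    x = pm.values.astype(float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 genomes for beta-diversity")
    sizes = x.sum(axis=1)
    inter = x @ x.T
    d = np.zeros((n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        if metric == "jaccard":
            union = sizes[:, None] + sizes[None, :] - inter
            d = 1.0 - np.divide(inter, union, out=np.ones_like(inter,
                                dtype=float), where=union > 0)
        else:
            tot = sizes[:, None] + sizes[None, :]
            d = 1.0 - np.divide(2.0 * inter, tot, out=np.ones_like(inter,
                                dtype=float), where=tot > 0)
    # both-empty pairs: defined as 0
    empty = sizes == 0
    if empty.any():
        ee = np.outer(empty, empty)
        d[ee] = 0.0
    np.fill_diagonal(d, 0.0)
    return d


def average_and_classify(genome_ids: list[str], d: np.ndarray,
                         threshold: float = 0.95,
                         metric: str = "braycurtis") -> DiversityResult:
    """Per-genome mean off-diagonal dissimilarity, split at ``threshold``.

    A genome is ``high`` iff its average is strictly greater than the
    threshold.
    """
    d = np.asarray(d, dtype=float)
    n = len(genome_ids)
    if n < 2:
        raise ValueError("classification needs at least 2 genomes")
    if d.shape != (n, n):
        raise ValueError("matrix shape does not match genome ids")
    avg = (d.sum(axis=1)) / (n - 1)  # zero diagonal
    average = {g: float(a) for g, a in zip(genome_ids, avg)}
    classification = {g: ("high" if a > threshold else "low")
                      for g, a in average.items()}
    return DiversityResult(genome_ids=list(genome_ids), pairwise=d,
                           average_per_genome=average,
                           classification=classification,
                           metric=metric, threshold=threshold)


def pcoa(genome_ids: list[str], d: np.ndarray) -> PCoAResult:
    """Classical metric scaling (principal coordinate analysis).

    Double-centers ``-0.5 * D**2`` (Gower), eigendecomposes, and returns
    coordinates ``eigvec * sqrt(eigval)`` for the positive eigenvalues.
    Negative eigenvalues (non-Euclidean dissimilarities) are retained in
    the eigenvalue report but excluded from coordinates; proportions
    explained are computed over the positive eigenvalues.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("dissimilarity matrix must be square symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValueError("dissimilarity matrix must have zero diagonal")
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12, 1e-12 * abs(eigval).max(initial=1.0))
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pos_sum = eigval[pos].sum()
    prop = eigval[pos] / pos_sum if pos_sum > 0 else eigval[pos]
    return PCoAResult(genome_ids=list(genome_ids), coordinates=coords,
                      eigenvalues=eigval, proportion_explained=prop)


def rarefaction(pm: PresenceMatrix, permutations: int = 100,
                seed: int = 0) -> RarefactionCurve:
    """GCF accumulation over random genome orderings (no replacement).

    For each depth k the mean and SD of the number of distinct families
    seen in the first k genomes are taken over ``permutations`` shuffles.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    rng = np.random.default_rng(seed)
    n, _ = pm.values.shape
    counts = np.zeros((permutations, n))
    vals = pm.values.astype(bool)
    for p in range(permutations):
        order = rng.permutation(n)
        seen = np.zeros(vals.shape[1], dtype=bool)
        for depth, gi in enumerate(order, 1):
            seen |= vals[gi]
            counts[p, depth - 1] = seen.sum()
    return RarefactionCurve(
        depths=np.arange(1, n + 1),
        mean_gcf_count=counts.mean(axis=0),
        sd=counts.std(axis=0, ddof=0),
        permutations=permutations,
        seed=seed,
    )


def _clench(x, a, b):
    return a * x / (1.0 + b * x)


def fit_clench(curve: RarefactionCurve) -> tuple[float, float, float]:
    """Least-squares Clench (Michaelis-Menten) fit ``y = a*x/(1+b*x)``.

    Returns ``(a, b, slope_at_n)`` where the slope of the fitted curve at
    the deepest sampled depth n is ``a / (1+b*n)**2`` — a near-zero slope
    means additional genomes add few new families.
    """
    x = curve.depths.astype(float)
    y = curve.mean_gcf_count.astype(float)
    if len(x) < 2 or np.allclose(y, y[0]):
        # flat curve: asymptote = observed count, slope 0
        return float(y[-1]), 0.0 if y[-1] == 0 else float("inf"), 0.0
    a0 = max(y[-1], 1.0)
    b0 = 1.0 / max(x[-1], 1.0)
    (a, b), _ = curve_fit(_clench, x, y, p0=(a0, b0), maxfev=20000)
    n = x[-1]
    slope_at_n = a / (1.0 + b * n) ** 2
    return float(a), float(b), float(slope_at_n)
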