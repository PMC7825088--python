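"""Classical molecular networking of MS/MS spectra.

Spectra are square-root transformed and unit-normalized, pairwise scored
with the modified cosine (fragment matches allowed either directly or
shifted by the precursor mass difference, over a one-to-one peak matching),
and connected into molecular families: connected components of the network
whose edges pass both the cosine and the matched-peak-count thresholds.
Components below the minimum family size are singletons ("no match").
Library matching (dereplication) scores each query against a reference
library with the same modified cosine and reports the best hit passing the
thresholds.

The one-to-one matching is greedy in descending intensity-product order —
deterministic and near-optimal on sparse candidate sets; tests compare it
against exhaustive enumeration on small spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class Spectrum:
    """One MS/MS spectrum: precursor m/z, charge, and its peak list."""

    id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray          # peak m/z values, ascending
    intensity: np.ndarray   # nonnegative, parallel to mz

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.size == 0:
            raise ValueError(f"spectrum {self.id}: empty peak list")
        if mz.size != inten.size:
            raise ValueError(f"spectrum {self.id}: mz/intensity mismatch")
        if (inten < 0).any():
            raise ValueError(f"spectrum {self.id}: negative intensity")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


def normalize(spec: Spectrum) -> Spectrum:
    """Square-root transform intensities, then scale to unit Euclidean norm."""
    inten = np.sqrt(spec.intensity)
    norm = float(np.linalg.norm(inten))
    if norm == 0.0:
        raise ValueError(f"spectrum {spec.id}: all-zero intensities")
    return replace(spec, intensity=inten / norm)


def modified_cosine(a: Spectrum, b: Spectrum, fragment_tolerance: float = 0.02,
                    shift: float | None = None) -> tuple[float, int]:
    """Modified cosine score and matched peak count for two normalized spectra.

    Candidate pairs are peaks within ``fragment_tolerance`` either directly
    (|mz_a - mz_b| <= tol) or after shifting by the precursor mass
    difference (|mz_a - mz_b - shift| <= tol, default shift =
    a.precursor_mz - b.precursor_mz). The score is the sum of intensity
    products over a greedy one-to-one matching taken in descending product
    order; ties break on (mz_a, mz_b) for determinism.
    """
    if fragment_tolerance < 0:
        raise ValueError("fragment tolerance must be nonnegative")
    if shift is None:
        shift = a.precursor_mz - b.precursor_mz
    diff = a.mz[:, None] - b.mz[None, :]
    cand = (np.abs(diff) <= fragment_tolerance) | \
           (np.abs(diff - shift) <= fragment_tolerance)
    ii, jj = np.nonzero(cand)
    if ii.size == 0:
        return 0.0, 0
    products = a.intensity[ii] * b.intensity[jj]
    order = np.lexsort((b.mz[jj], a.mz[ii], -products))
    used_a = np.zeros(a.n_peaks, dtype=bool)
    used_b = np.zeros(b.n_peaks, dtype=bool)
    score = 0.0
    matched = 0
    for idx in order:
        i, j = ii[idx], jj[idx]
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        score += products[idx]
        matched += 1
    return float(min(score, 1.0)), matched


@dataclass
class Annotation:
    library_id: str
    score: float
    matched: int


@dataclass
class MolecularNetwork:
    """Spectral similarity network with molecular families."""

    nodes: list[str]
    edges: list[tuple[str, str, float, int]]  # (a, b, score, matched)
    families: dict[str, list[str]]            # family id -> member spectra
    singletons: list[str]                     # "no match" nodes
    annotations: dict[str, Annotation]


def build_network(spectra: list[Spectrum], cosine_min: float = 0.70,
                  min_matched_peaks: int = 4, min_family_size: int = 2,
                  fragment_tolerance: float = 0.02) -> MolecularNetwork:
    """Molecular network from all pairwise modified-cosine comparisons.

    Edges require score >= ``cosine_min`` AND matched >=
    ``min_matched_peaks``; families are connected components with at least
    ``min_family_size`` nodes, named after their lexicographically smallest
    member. Smaller components are singletons.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra to build a network")
    ids = [s.id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate spectrum ids")
    normed = [normalize(s) for s in spectra]
    edges = []
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(len(normed)):
        for j in range(i + 1, len(normed)):
            score, matched = modified_cosine(normed[i], normed[j],
                                             fragment_tolerance)
            if score >= cosine_min and matched >= min_matched_peaks:
                edges.append((ids[i], ids[j], score, matched))
                g.add_edge(ids[i], ids[j])
    families: dict[str, list[str]] = {}
    singletons: list[str] = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        if len(members) >= min_family_size:
            families[members[0]] = members
        else:
            singletons.extend(members)
    singletons.sort()
    return MolecularNetwork(nodes=list(ids), edges=edges, families=families,
                            singletons=singletons, annotations={})


def library_match(spectra: list[Spectrum], library_spectra: list[Spectrum],
                  cosine_min: float = 0.70, min_matched_peaks: int = 4,
                  fragment_tolerance: float = 0.02) -> dict[str, Annotation]:
    """Best-scoring library hit per query passing both thresholds."""
    if not library_spectra:
        raise ValueError("library is empty")
    lib = [normalize(s) for s in library_spectra]
    out: dict[str, Annotation] = {}
    for q in spectra:
        qn = normalize(q)
        best: Annotation | None = None
        for ref in lib:
            score, matched = modified_cosine(qn, ref, fragment_tolerance)
            if score >= cosine_min and matched >= min_matched_peaks:
                if best is None or score > best.score:
                    best = Annotation(ref.id, score, matched)
        if best is not None:
            out[q.id] = best
    return out


def annotation_rate(network: MolecularNetwork) -> tuple[int, int, float]:
    """(annotated nodes, total nodes, fraction annotated) over the network."""
    total = len(network.nodes)
    annotated = sum(1 for n in network.nodes if n in network.annotations)
    return annotated, total, (annotated / total if total else 0.0)
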