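"""Synthetic multi-omics data with planted, recoverable structure.

The generator emulates the data regimes the pipeline consumes, with ground
truth retained for parameter-recovery tests:

* **Archetypes** — gene-cluster prototypes: an ordered domain architecture,
  per-domain sequence tokens, a compound fingerprint prototype, a
  biosynthetic class label, a spectral fragment pool, and a base precursor
  mass. Some archetypes are shared by every genome, others are private to
  one genome (controlling planted beta-diversity).
* **BGC instances** — noisy copies of archetype architectures (each domain
  and token character resampled with probability ``domain_mutation_rate``).
  Private archetypes are instantiated twice in their genome so they form
  real two-member families rather than singletons.
* **Compounds** — one per BGC instance; its fingerprint is the archetype
  prototype with bits flipped at ``fingerprint_flip_rate``, so
  within-family Tanimoto far exceeds between-family Tanimoto.
* **DNA** — every genome shares one common segment of length
  ``shared_segment_fraction * genome_length`` (planting small Mash
  distances); one designated outlier genome shares nothing (the planted
  Mash singleton). The remainder is i.i.d. random sequence.
* **Spectra** — one per compound; 60% of peaks drawn from the archetype's
  fragment pool (shared within the family) and 40% uniform noise, pool
  peaks carrying higher intensity, with Gaussian m/z jitter. Chosen so the
  within-family modified cosine clears 0.7 at the default jitter.

A single root seed drives one ``SeedSequence``; sub-generators are spawned
per stage in a fixed order, so adding a later stage never perturbs earlier
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ParameterError, SimConfig
from .families import CompoundRecord
from .similarity import BGCRecord
from .specnet import Spectrum

#: classes sampled for archetypes (subset of the full vocabulary)
ARCHETYPE_CLASSES = ("NRPS", "T1PKS", "terpene", "bacteriocin", "hybrid",
                     "other")

_AA = "ACDEFGHIKLMNPQRSTVWY"
_TOKEN_LEN = 12
_FRAGMENT_POOL_SIZE = 20
_POOL_PEAK_FRACTION = 0.6  # fraction of peaks drawn from the family pool


@dataclass(frozen=True)
class Archetype:
    """A gene-cluster family prototype with its chemical counterparts."""

    id: str
    domains: tuple[str, ...]
    domain_seqs: tuple[str, ...]
    fingerprint: np.ndarray        # boolean prototype
    class_label: str
    fragment_pool: np.ndarray      # characteristic fragment m/z values
    base_precursor: float
    shared: bool                   # carried by every genome?
    owner_genome: str | None = None  # set for private archetypes


@dataclass
class SyntheticDataset:
    """Everything the downstream pipeline consumes, plus ground truth."""

    genome_ids: list[str]
    sequences: dict[str, str]            # genome id -> DNA
    bgcs: list[BGCRecord]
    compounds: list[CompoundRecord]
    spectra: list[Spectrum]
    archetypes: list[Archetype]
    truth_bgc: dict[str, str]            # bgc id -> archetype id
    truth_compound: dict[str, str]       # compound id -> archetype id
    truth_spectrum: dict[str, str]       # spectrum id -> archetype id
    outlier_genome: str
    private_counts: dict[str, int]       # genome id -> n private archetypes


def _rngs(cfg: SimConfig, n: int) -> list[np.random.Generator]:
    seqs = np.random.SeedSequence(cfg.seed).spawn(n)
    return [np.random.default_rng(s) for s in seqs]


def simulate_archetypes(cfg: SimConfig) -> list[Archetype]:
    """Generate shared and per-genome private archetypes.

    Archetype order is deterministic: shared first, then private archetypes
    grouped by owner genome. Only the first ``n_diverse_genomes`` genomes
    (all genomes when unset) receive private archetypes.
    """
    rng = _rngs(cfg, 5)[0]
    genome_ids = [f"g{i:03d}" for i in range(cfg.n_genomes)]
    n_diverse = (cfg.n_genomes if cfg.n_diverse_genomes is None
                 else cfg.n_diverse_genomes)
    archetypes: list[Archetype] = []

    def make(aid: str, shared: bool, owner: str | None) -> Archetype:
        length = int(rng.integers(cfg.architecture_length_range[0],
                                  cfg.architecture_length_range[1] + 1))
        domains = tuple(
            f"d{int(i):03d}"
            for i in rng.integers(0, cfg.domain_alphabet_size, size=length))
        tokens = tuple(
            "".join(_AA[int(c)] for c in rng.integers(0, len(_AA),
                                                      size=_TOKEN_LEN))
            for _ in range(length))
        fingerprint = rng.random(cfg.fingerprint_length) < 0.5
        class_label = str(rng.choice(ARCHETYPE_CLASSES))
        pool = np.sort(rng.uniform(100.0, 1000.0, size=_FRAGMENT_POOL_SIZE))
        base_precursor = float(rng.uniform(400.0, 1200.0))
        return Archetype(id=aid, domains=domains, domain_seqs=tokens,
                         fingerprint=fingerprint, class_label=class_label,
                         fragment_pool=pool, base_precursor=base_precursor,
                         shared=shared, owner_genome=owner)

    for i in range(cfg.n_shared_archetypes):
        archetypes.append(make(f"A_shared_{i:03d}", True, None))
    for g in genome_ids[:n_diverse]:
        for j in range(cfg.n_private_archetypes_per_genome):
            archetypes.append(make(f"A_{g}_{j:03d}", False, g))
    return archetypes


def _mutate_architecture(arch: Archetype, cfg: SimConfig,
                         rng: np.random.Generator,
                         ) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Noisy copy: resample each domain id and each token character with
    probability ``domain_mutation_rate``."""
    domains = list(arch.domains)
    tokens = [list(t) for t in arch.domain_seqs]
    for pos in range(len(domains)):
        if rng.random() < cfg.domain_mutation_rate:
            domains[pos] = f"d{int(rng.integers(0, cfg.domain_alphabet_size)):03d}"
        tok = tokens[pos]
        flips = rng.random(len(tok)) < cfg.domain_mutation_rate
        for ci in np.nonzero(flips)[0]:
            tok[ci] = _AA[int(rng.integers(0, len(_AA)))]
    return tuple(domains), tuple("".join(t) for t in tokens)


_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _make_spectrum(spec_id: str, arch: Archetype, cfg: SimConfig,
                   rng: np.random.Generator) -> Spectrum:
    n_peaks = int(rng.integers(cfg.spectrum_peaks_range[0],
                               cfg.spectrum_peaks_range[1] + 1))
    n_pool = max(1, int(round(_POOL_PEAK_FRACTION * n_peaks)))
    n_pool = min(n_pool, arch.fragment_pool.size)
    n_noise = n_peaks - n_pool
    pool_idx = rng.choice(arch.fragment_pool.size, size=n_pool, replace=False)
    pool_mz = arch.fragment_pool[np.sort(pool_idx)] + \
        rng.normal(0.0, cfg.mz_jitter, size=n_pool)
    pool_int = rng.uniform(50.0, 100.0, size=n_pool)
    noise_mz = rng.uniform(100.0, 1000.0, size=n_noise)
    noise_int = rng.uniform(5.0, 30.0, size=n_noise)
    mz = np.concatenate([pool_mz, noise_mz])
    inten = np.concatenate([pool_int, noise_int])
    precursor = arch.base_precursor + float(rng.uniform(-2.0, 2.0))
    return Spectrum(id=spec_id, precursor_mz=precursor, charge=1,
                    mz=mz, intensity=inten)


def simulate_genomes(cfg: SimConfig, archetypes: list[Archetype],
                     ) -> SyntheticDataset:
    """Instantiate genomes, BGCs, compounds, DNA, and spectra.

    Each genome carries one noisy BGC copy of every shared archetype and two
    copies of each of its private archetypes. The last genome is the planted
    Mash outlier: its DNA shares no segment with the others.
    """
    if not archetypes:
        raise ParameterError("archetypes: must be nonempty")
    _, rng_bgc, rng_fp, rng_dna, rng_spec = _rngs(cfg, 5)
    genome_ids = [f"g{i:03d}" for i in range(cfg.n_genomes)]
    outlier = genome_ids[-1]

    shared_archetypes = [a for a in archetypes if a.shared]
    private_of: dict[str, list[Archetype]] = {g: [] for g in genome_ids}
    for a in archetypes:
        if not a.shared:
            if a.owner_genome not in private_of:
                raise ParameterError(
                    f"archetypes: owner {a.owner_genome!r} not a genome id")
            private_of[a.owner_genome].append(a)

    bgcs: list[BGCRecord] = []
    truth_bgc: dict[str, str] = {}
    instances: list[tuple[str, Archetype]] = []  # (bgc id, archetype)
    counter = 0
    for g in genome_ids:
        carried = ([(a, 1) for a in shared_archetypes]
                   + [(a, 2) for a in private_of[g]])
        for arch, copies in carried:
            for _ in range(copies):
                bid = f"bgc{counter:05d}"
                counter += 1
                domains, tokens = _mutate_architecture(arch, cfg, rng_bgc)
                bgcs.append(BGCRecord(
                    id=bid, genome_id=g, class_label=arch.class_label,
                    complete_flag=bool(rng_bgc.random() < 0.8),
                    domains=domains, domain_seqs=tokens))
                truth_bgc[bid] = arch.id
                instances.append((bid, arch))

    compounds: list[CompoundRecord] = []
    truth_compound: dict[str, str] = {}
    for bid, arch in instances:
        flips = rng_fp.random(cfg.fingerprint_length) < cfg.fingerprint_flip_rate
        fp = np.logical_xor(arch.fingerprint, flips)
        cid = f"cmp_{bid}"
        compounds.append(CompoundRecord(compound_id=cid, bgc_id=bid,
                                        fingerprint=fp))
        truth_compound[cid] = arch.id

    shared_len = int(round(cfg.shared_segment_fraction * cfg.genome_length))
    shared_segment = _random_dna(rng_dna, shared_len)
    sequences: dict[str, str] = {}
    for g in genome_ids:
        if g == outlier or shared_len == 0:
            sequences[g] = _random_dna(rng_dna, cfg.genome_length)
        else:
            sequences[g] = shared_segment + _random_dna(
                rng_dna, cfg.genome_length - shared_len)

    spectra: list[Spectrum] = []
    truth_spectrum: dict[str, str] = {}
    for c in compounds:
        arch_id = truth_compound[c.compound_id]
        arch = next(a for a in archetypes if a.id == arch_id)
        sid = f"spec_{c.compound_id}"
        spectra.append(_make_spectrum(sid, arch, cfg, rng_spec))
        truth_spectrum[sid] = arch_id

    private_counts = {g: len(private_of[g]) for g in genome_ids}
    return SyntheticDataset(
        genome_ids=genome_ids, sequences=sequences, bgcs=bgcs,
        compounds=compounds, spectra=spectra, archetypes=list(archetypes),
        truth_bgc=truth_bgc, truth_compound=truth_compound,
        truth_spectrum=truth_spectrum, outlier_genome=outlier,
        private_counts=private_counts)


def simulate(cfg: SimConfig) -> SyntheticDataset:
    """Archetypes plus genomes in one call."""
    return simulate_genomes(cfg, simulate_archetypes(cfg))


def write_truth(ds: SyntheticDataset, path: str | Path) -> None:
    """Sidecar TSV of ground-truth labels for parameter-recovery tests."""
    rows = []
    for bid in sorted(ds.truth_bgc):
        rows.append(("bgc_archetype", bid, ds.truth_bgc[bid]))
    for cid in sorted(ds.truth_compound):
        rows.append(("compound_archetype", cid, ds.truth_compound[cid]))
    for sid in sorted(ds.truth_spectrum):
        rows.append(("spectrum_archetype", sid, ds.truth_spectrum[sid]))
    rows.append(("outlier_genome", ds.outlier_genome, "1"))
    for g in sorted(ds.private_counts):
        rows.append(("private_archetypes", g, str(ds.private_counts[g])))
    pd.DataFrame(rows, columns=["kind", "id", "value"]).to_csv(
        path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
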