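"""Pipeline and simulation configuration.

All numeric thresholds used across the pipeline live in
:class:`PipelineConfig`; the defaults are the study conditions
(GC binning cutoff, completeness/contig quality gates, the 0.30
gene-cluster network distance cutoff, the 95% beta-diversity
classification threshold, Mash significance thresholds, and the
molecular-networking parameters).

Config files are a flat ``key: value`` text format (a YAML subset);
unknown keys are a hard error so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


class ParameterError(ValueError):
    """A configuration field is outside its stated domain."""


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{name}: {msg}")


@dataclass
class PipelineConfig:
    """Thresholds and parameters for every pipeline stage.

    Attributes
    ----------
    gc_max
        Maximum GC fraction for a contig to be binned (inclusive).
    completeness_min
        Genome completeness must be strictly greater than this to pass QC.
    max_contigs
        Genome scaffold count must be strictly less than this to pass QC.
    cutoff_grid
        Ascending distance cutoffs scanned during family calibration.
    selected_cutoff
        Distance cutoff used to form gene cluster families.
    diversity_metric
        ``braycurtis`` or ``jaccard`` beta-diversity on presence/absence.
    diversity_threshold
        Average dissimilarity strictly above this classifies a genome as
        high-diversity.
    mash_k, mash_sketch_size
        k-mer size and bottom-sketch size for MinHash genome comparison.
    mash_dist_max, mash_p_max
        A genome pair "networks" when distance <= mash_dist_max AND
        p-value <= mash_p_max; a genome with no partner is a singleton.
    cosine_min, min_matched_peaks, min_family_size
        Molecular-networking edge and family thresholds.
    fragment_tolerance
        Fragment m/z matching tolerance in Da.
    rarefaction_permutations
        Number of random genome orderings in the rarefaction curve.
    seed
        Root seed for every stochastic stage.
    """

    gc_max: float = 0.58
    completeness_min: float = 0.90
    max_contigs: int = 500
    cutoff_grid: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(1, 19))
    selected_cutoff: float = 0.30
    diversity_metric: str = "braycurtis"
    diversity_threshold: float = 0.95
    mash_k: int = 21
    mash_sketch_size: int = 1000
    mash_dist_max: float = 0.05
    mash_p_max: float = 1e-10
    cosine_min: float = 0.70
    min_matched_peaks: int = 4
    min_family_size: int = 2
    fragment_tolerance: float = 0.02
    rarefaction_permutations: int = 100
    seed: int = 42

    def __post_init__(self) -> None:
        _check(0.0 <= self.gc_max <= 1.0, "gc_max", "must be a fraction in [0,1]")
        _check(0.0 <= self.completeness_min <= 1.0, "completeness_min",
               "must be a fraction in [0,1]")
        _check(self.max_contigs > 0, "max_contigs", "must be positive")
        grid = tuple(float(c) for c in self.cutoff_grid)
        _check(all(0.0 <= c <= 1.0 for c in grid), "cutoff_grid",
               "all cutoffs must lie in [0,1]")
        _check(all(a < b for a, b in zip(grid, grid[1:])), "cutoff_grid",
               "must be strictly ascending")
        self.cutoff_grid = grid
        _check(0.0 <= self.selected_cutoff <= 1.0, "selected_cutoff",
               "must lie in [0,1]")
        _check(self.diversity_metric in ("braycurtis", "jaccard"),
               "diversity_metric", "must be 'braycurtis' or 'jaccard'")
        _check(0.0 <= self.diversity_threshold <= 1.0, "diversity_threshold",
               "must be a fraction in [0,1]")
        _check(self.mash_k >= 1, "mash_k", "must be >= 1")
        _check(self.mash_sketch_size >= 1, "mash_sketch_size", "must be >= 1")
        _check(0.0 <= self.mash_dist_max <= 1.0, "mash_dist_max",
               "must lie in [0,1]")
        _check(0.0 <= self.mash_p_max <= 1.0, "mash_p_max", "must lie in [0,1]")
        _check(0.0 <= self.cosine_min <= 1.0, "cosine_min", "must lie in [0,1]")
        _check(self.min_matched_peaks >= 0, "min_matched_peaks",
               "must be nonnegative")
        _check(self.min_family_size >= 1, "min_family_size", "must be >= 1")
        _check(self.fragment_tolerance >= 0.0, "fragment_tolerance",
               "must be nonnegative")
        _check(self.rarefaction_permutations >= 1, "rarefaction_permutations",
               "must be >= 1")


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-omics data generator.

    The generator plants recoverable structure at every level: shared and
    genome-private gene-cluster archetypes (controls beta-diversity), noisy
    domain-architecture copies per archetype (controls within-family BGC
    distance), noisy fingerprint copies per archetype (controls within-family
    Tanimoto), genomes sharing a common DNA segment (controls Mash distance,
    with one planted outlier sharing nothing), and spectra drawing peaks from
    per-archetype fragment pools (controls modified-cosine recovery).
    """

    n_genomes: int = 25
    n_shared_archetypes: int = 5
    n_private_archetypes_per_genome: int = 3
    domain_alphabet_size: int = 40
    architecture_length_range: tuple[int, int] = (6, 12)
    domain_mutation_rate: float = 0.05
    fingerprint_length: int = 128
    fingerprint_flip_rate: float = 0.005
    genome_length: int = 20000
    shared_segment_fraction: float = 0.5
    spectrum_peaks_range: tuple[int, int] = (25, 35)
    mz_jitter: float = 0.005
    seed: int = 0
    # Only the first n_diverse_genomes receive private archetypes
    # (None = every genome does); lets a scenario plant clones vs
    # high-diversity genomes.
    n_diverse_genomes: int | None = None

    def __post_init__(self) -> None:
        _check(self.n_genomes >= 1, "n_genomes", "must be >= 1")
        _check(self.n_shared_archetypes >= 0, "n_shared_archetypes",
               "must be >= 0")
        _check(self.n_private_archetypes_per_genome >= 0,
               "n_private_archetypes_per_genome", "must be >= 0")
        _check(self.domain_alphabet_size >= 1, "domain_alphabet_size",
               "must be >= 1")
        lo, hi = self.architecture_length_range
        _check(lo >= 2, "architecture_length_range", "minimum must be >= 2")
        _check(hi >= lo, "architecture_length_range", "max must be >= min")
        _check(0.0 <= self.domain_mutation_rate <= 1.0, "domain_mutation_rate",
               "must be a probability in [0,1]")
        _check(self.fingerprint_length >= 1, "fingerprint_length",
               "must be >= 1")
        _check(0.0 <= self.fingerprint_flip_rate <= 1.0,
               "fingerprint_flip_rate", "must be a probability in [0,1]")
        _check(self.genome_length >= 1, "genome_length", "must be >= 1")
        _check(0.0 <= self.shared_segment_fraction <= 1.0,
               "shared_segment_fraction", "must be a fraction in [0,1]")
        plo, phi = self.spectrum_peaks_range
        _check(plo >= 1, "spectrum_peaks_range", "minimum must be >= 1")
        _check(phi >= plo, "spectrum_peaks_range", "max must be >= min")
        _check(self.mz_jitter >= 0.0, "mz_jitter", "must be nonnegative")
        if self.n_diverse_genomes is not None:
            _check(0 <= self.n_diverse_genomes <= self.n_genomes,
                   "n_diverse_genomes", "must be in [0, n_genomes]")


_CONFIG_CLASSES = {"pipeline": PipelineConfig, "sim": SimConfig}


def _parse_scalar(raw: str, target_type: type):
    raw = raw.strip()
    if target_type is bool:
        if raw.lower() in ("true", "yes", "1"):
            return True
        if raw.lower() in ("false", "no", "0"):
            return False
        raise ParameterError(f"cannot parse boolean from {raw!r}")
    if target_type is int:
        return int(raw)
    if target_type is float:
        return float(raw)
    return raw


def load_config(path: str | Path, kind: str = "pipeline"):
    """Load a flat ``key: value`` config file.

    Lists are comma-separated; tuples of two ints use ``lo,hi``. Unknown
    keys raise :class:`ParameterError` rather than being ignored.
    """
    cls = _CONFIG_CLASSES[kind]
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if ":" not in stripped:
            raise ParameterError(
                f"{path}:{lineno}: expected 'key: value', got {stripped!r}")
        key, _, raw = stripped.partition(":")
        key = key.strip()
        if key not in fields:
            raise ParameterError(f"{path}:{lineno}: unknown key {key!r}")
        f = fields[key]
        ftype = f.type if isinstance(f.type, type) else str(f.type)
        raw = raw.strip()
        if key in ("cutoff_grid",):
            kwargs[key] = tuple(float(x) for x in raw.split(","))
        elif key in ("architecture_length_range", "spectrum_peaks_range"):
            lo, hi = raw.split(",")
            kwargs[key] = (int(lo), int(hi))
        elif key == "n_diverse_genomes":
            kwargs[key] = None if raw.lower() in ("none", "") else int(raw)
        elif key == "diversity_metric":
            kwargs[key] = raw
        else:
            default = f.default
            if isinstance(default, bool):
                kwargs[key] = _parse_scalar(raw, bool)
            elif isinstance(default, int):
                kwargs[key] = _parse_scalar(raw, int)
            elif isinstance(default, float):
                kwargs[key] = _parse_scalar(raw, float)
            else:
                kwargs[key] = raw
    return cls(**kwargs)
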