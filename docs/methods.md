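# Methods

## Scope and model

`npomics` implements a prioritization workflow for natural-product
discovery in microbial genome collections. The core object is the **gene
cluster family (GCF)**: a connected component of a BGC similarity network
at a distance cutoff. Everything downstream — presence/absence
beta-diversity, genome classification, PCoA, rarefaction — treats the GCF
repertoire of a genome as its natural-product fingerprint. Two orthogonal
analyses complete the picture: MinHash whole-genome comparison flags
genomes that are unlike anything else in the collection, and spectral
molecular networking groups expressed metabolites into molecular
families.

## BGC distance

A BGC is an ordered list of protein-domain family identifiers plus one
sequence token per domain copy (inputs are assumed to come from an
upstream cluster-detection tool; strand orientation is resolved
upstream). The distance is

    d(a, b) = 1 − (wJ·J + wA·AI + wD·DSS),   (wJ, wA, wD) = (0.2, 0.3, 0.5)

* **J** — Jaccard similarity of the domain-family sets, copies collapsed.
* **AI** — Jaccard over *ordered* adjacent domain pairs; architectures
  with fewer than two domains fall back to J. Order sensitivity is
  deliberate: a reversed architecture is a different synteny.
* **DSS** — over shared domain families, the mean normalized token
  identity under a greedy highest-identity pairing of the copies;
  unmatched copies occupy slots and score 0; records sharing no family
  score 0.

This is a symmetric premetric on [0,1] with zero diagonal; the triangle
inequality is not claimed (single-linkage component formation never needs
it). The weights privilege sequence identity over composition, are
configurable, and sum to 1. Multi-copy domains are collapsed for J
(set semantics) and paired greedily for DSS; ties in the greedy pairing
break on copy order, making results order-deterministic.

## Family formation and chemistry calibration

Families are connected components (size ≥ 2) of the graph with an edge
wherever distance ≤ cutoff — single-linkage semantics that mirror how
similarity-network outputs are consumed in practice. Component ids are
the lexicographically smallest member id, so partitions are
deterministic. Raising the cutoff can only merge components
(nestedness), which the tests assert.

The cutoff is not a free parameter: it is calibrated against paired
BGC↔compound records. At each grid cutoff, all unordered pairs of
compounds whose BGCs share a family are scored with Tanimoto similarity
(bit-set intersection over union; two empty fingerprints define 1.0).
Only families with ≥ 2 compound-linked members contribute. The selected
cutoff is the **largest** one whose mean within-family Tanimoto is ≥ 0.95
— the loosest network that still groups chemically near-identical
products. The 0.95 floor reflects the observation that a well-chosen
cutoff corresponds to ~99% structural similarity among co-networked
characterized compounds; it is configurable. If no cutoff qualifies, the
smallest cutoff forming at least one family is returned with an explicit
fallback flag rather than silently.

Mean within-family Tanimoto is only guaranteed nonincreasing in the
cutoff **above** the point where all within-family pairs have merged;
below it, raising the cutoff can add chemically identical pairs and raise
the mean. The monotonicity test therefore restricts to that range.

## Beta-diversity prioritization

The presence/absence matrix has entry (g, f) = 1 iff any member of family
f belongs to genome g; singleton BGCs are not families and contribute
nothing. Genomes whose BGCs are all singletons would be all-zero rows;
they are excluded from the matrix and reported separately rather than
entering averages with an ill-defined dissimilarity.

On binary rows, Bray–Curtis is `1 − 2|A∩B|/(|A|+|B|)` and Jaccard is
`1 − |A∩B|/|A∪B|`; they are monotone transforms of each other
(J = 2BC/(1+BC)), so the high/low ranking is metric-robust. Both are
implemented; Bray–Curtis is the default. Conventions for degenerate
rows: empty vs empty = 0, empty vs nonempty = 1. The per-genome score is
the mean off-diagonal dissimilarity; classification is **strictly**
above the threshold (default 0.95) for "high".

PCoA is classical metric scaling: Gower-center −½D², eigendecompose,
scale eigenvectors by √eigenvalue. Negative eigenvalues (non-Euclidean
input) are retained in the report but excluded from coordinates, and
proportions explained are over positive eigenvalues only; no Lingoes or
Cailliez correction is applied.

Rarefaction samples genome orderings without replacement (default 100
permutations, seeded) and reports mean and SD of distinct GCFs at each
depth. The saturation fit is the Clench (Michaelis–Menten) form
`y = ax/(1+bx)` by least squares, with the slope at the deepest depth
`a/(1+bn)²` as the "how much is left" statistic; the functional form is a
package choice since richness-accumulation fits have no canonical form,
and a flat or single-point curve returns its plateau with slope 0 rather
than a degenerate fit.

## Genome sketching and rarity

Sketches are bottom-s MinHash over canonical k-mers (lexicographic min of
k-mer and reverse complement; windows containing non-ACGT characters are
skipped), with k = 21 and s = 1000 as defaults — the conventional
sketching parameters for bacterial genomes. Hashing is a seeded
splitmix64 finalizer over 2-bit-packed k-mers (k ≤ 32), so sketches are
platform-portable and comparable only between equal k and hash seed.

The Jaccard estimate merges two sketches and takes the fraction of the s
smallest union hashes present in both. Distance is
`d = −ln(2j/(1+j))/k`, capped at 1.0, with j = 0 mapping to the cap. The
p-value is the binomial tail P(X ≥ shared) with n = union_sampled draws
and null match probability `r = w_a·w_b/(w_a + w_b − w_a·w_b)`,
w = genome k-mer count / 2⁶⁴. A genome is a **rare singleton** iff it has
no partner passing *both* thresholds (d ≤ 0.05 and p ≤ 1e−10).

## Molecular networking

Spectra are square-root transformed and unit-normalized. The modified
cosine allows fragment pairs within tolerance either directly or after
shifting by the precursor mass difference, and scores the best one-to-one
matching. Matching is greedy in descending intensity-product order with
deterministic m/z tie-breaks. On high-resolution data (0.02 Da tolerance,
peaks spread over hundreds of Da) the candidate graph is sparse and
greedy equals the exhaustive optimum — asserted against brute-force
enumeration on 200 small fixtures. In adversarially dense candidate
graphs greedy is a lower bound on the optimum (deviations up to ~0.3 were
observed in synthetic stress fixtures with every peak within tolerance of
every other); the tests assert the bound. Network edges require
cosine ≥ 0.7 **and** ≥ 4 matched fragment ions; molecular families are
components of ≥ 2 nodes, smaller components being "no match" singletons.
The minimum-size-2 rule is applied to molecular families: inputs are
assumed to be one consensus spectrum per feature, so no raw-scan
consensus clustering is performed. Library matching uses the same scorer
and thresholds and keeps the best-scoring hit per query; analog search is
not performed.

## Synthetic data: what it emulates and what it does not

The generator plants one recoverable signal per pipeline stage:

* **Archetypes** (shared vs genome-private) define the true GCFs; each
  BGC instance resamples every domain id and token character with
  probability `domain_mutation_rate` (default 0.05). Private archetypes
  are instantiated **twice** in their genome so they form genuine
  two-member families rather than singletons; this is what lets private
  repertoires raise a genome's beta-diversity. An optional
  `n_diverse_genomes` restricts private archetypes to the first k
  genomes, enabling clone-vs-diverse classification scenarios.
* **Fingerprints** flip prototype bits at `fingerprint_flip_rate`
  (default 0.005, keeping within-family Tanimoto ≈ 0.98 against a
  between-family background near 1/3 for random half-density
  prototypes).
* **DNA**: all genomes share one common segment
  (`shared_segment_fraction`, default 0.5 of a 20 kb genome; at k = 21
  this plants Jaccard ≈ 1/3, Mash d ≈ 0.033, well inside the 0.05
  threshold); the last genome shares nothing and is the planted Mash
  outlier.
* **Spectra**: 60% of peaks come from a 20-fragment per-archetype pool at
  high intensity (50–100), 40% are uniform noise at low intensity (5–30),
  with Gaussian m/z jitter (default 0.005 Da). With sqrt-normalization
  this puts within-family modified cosines around 0.75–0.85, safely above
  the 0.7 edge threshold at default jitter.

One root seed drives a `SeedSequence`; per-stage generators are spawned
in fixed order so adding a stage never perturbs earlier outputs, and all
outputs are byte-identical across reruns.

Deliberately **not** emulated: nucleotide-level BGC sequences, read-level
sequencing error, assembly artifacts, isotope patterns/adducts/charge
states in spectra, abundance-weighted diversity, and realistic domain
vocabularies. Passing tests therefore demonstrate that the algorithms
recover the structures they are designed to detect under controlled
noise; they do not certify performance on real assemblies or real
LC-MS/MS data.

## Numerical and design choices

* Problem sizes in the tests and the acceptance script: 8–50 genomes,
  up to 1000 BGCs and 500 spectra — sizes at which exact oracles
  (brute-force components, exhaustive matchings, exact k-mer sets)
  remain computable for cross-checking.
* Boundary semantics follow the stated rules literally: GC filter
  inclusive (≤ 0.58); completeness and scaffold filters strict (> 0.90,
  < 500); diversity classification strict (> 0.95).
* GC content is computed over unambiguous bases only (ambiguity codes
  excluded from numerator and denominator).
* Reported means round half-up to one decimal, so a printed 21.1 means
  the exact mean is in [21.05, 21.15).
* The calibration scenario used for recovery checks has shared
  archetypes only: with uniform many-member families, the first
  above-gap merge mixes enough unrelated chemistry to break the 0.95
  homogeneity floor, making the selected cutoff land inside the planted
  within/between distance gap. With many tiny (two-member) families the
  first merge can be too small to move the mean — a genuine property of
  mean-based calibration, not an implementation artifact.
* Matrix writers order rows lexicographically and print floats at 12
  significant digits; round-trips are identity to 1e−9.
* Unknown configuration keys are hard errors (flat `key: value` format)
  to prevent silent typos.

## Known limitations

* The BGC distance is a documented simplification of domain-based
  cluster comparison; it preserves the Jaccard/adjacency/sequence
  ingredients but does not reproduce any external tool's exact scores or
  per-class weight presets.
* Single-linkage families chain: one intermediate BGC can merge two
  otherwise distinct families. The calibration guard detects the
  chemical consequences but cannot prevent chaining itself.
* The binomial Mash p-value treats hash draws as independent Bernoulli
  trials; for very small sketches or tiny genomes the approximation is
  crude (it is the standard one for this statistic).
* Greedy cosine matching is exact only on sparse candidate graphs; dense
  low-resolution data would need the Hungarian algorithm.
* The rarefaction fit assumes a saturating accumulation; richness that
  grows without bound would be better served by the power-law
  alternative, which is not the default.
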