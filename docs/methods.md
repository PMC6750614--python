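# Methods

## Data model and missingness

All quantities derive from protein-level tables: per species, one row per
protein accession with unique-peptide counts and summed MS1 precursor
areas per replicate. A missing abundance means *not detected* and is kept
as NaN throughout; a zero area is coerced to missing at construction,
because a detected precursor always has a positive peak area. No
imputation is performed anywhere: downstream rules (both-detected fold
changes, detected-replicate means, coverage sets) are defined directly on
the observed cells. Accessions are case-sensitive opaque strings; isoform
or homeolog suffixes (`.L`/`.S`) are never stripped implicitly, since
silently merging them would bias the ortholog averaging they feed into.

## Assembly

**Quantifiability.** A protein is quantifiable with ≥ 2 unique peptides
in every replicate, or ≥ 4 unique peptides in at least one replicate.
With a single replicate the rule degenerates to the ≥ 4 clause.

**Median normalization.** Each sample (species × replicate column) gets
one multiplicative factor so its median detected abundance equals the
grand median of all per-sample medians. Targeting the grand median rather
than 1 preserves the data's magnitude scale, which keeps downstream
complex scores interpretable as areas. Normalization happens per sample
*before* replicate averaging, so replicate-level scale differences are
removed rather than averaged in. A sample with no detected values is an
error: there is nothing to scale.

**Ortholog collapse.** Per species, each protein's abundance is the mean
over its *detected* replicates (missing replicates excluded, not
zero-filled); then all species-native entries mapping to one reference
accession are averaged arithmetically over the entries that carry a
value. This is the point where homeolog duplicates merge. Unmapped
accessions are dropped and counted in the run log. The operation is
idempotent under an identity map on an already-collapsed matrix.

**Fold changes** are ratios over proteins detected in both species only.
**Tryptic counting** cleaves after K/R, suppressed before proline
(configurable), with missed cleavages and a 7–30 aa length window by
default — the convention of proteomic-ruler-style peptide counting; all
four knobs are parameters because the counting convention varies between
tools. **PRM roll-up** performs exactly three steps: divide each peptide
area by its sample's mean MS1 intensity, scale each peptide to its mean
across runs (so every peptide averages 1 across samples — a tested fixed
point), and average a protein's peptides per sample. Peptides with zero
area in every sample carry no signal and are excluded with a warning
rather than poisoning the scaling with a division by zero.

## Complex inference

**Coverage** of a complex in a species is the detected fraction of its
*full catalogued membership* — members never observed in any species stay
in the denominator, because coverage is a statement about the known
complex, not about the observed part of it.

**Filter.** Complexes need ≥ 3 members; of those, complexes of ≤ 5
members must reach 40% coverage in at least one species and larger
complexes 20%. Both thresholds are inclusive ("less than 40%" is the
removal rule, so exactly 40% passes) and configurable via `FilterPolicy`.
Enlarging any species' detected set can only raise coverages, so the
passing set is monotone in detection (property-tested).

**Score.** `score(c, s) = mean(abundance of members detected in s) ×
coverage(c, s)`. The mean runs over the members detected *in that
species* — not all members, and not only members detected everywhere —
because the score must be able to differ between species and the coverage
weight is explicitly per species. The score is 0 exactly when coverage is
0, and never exceeds the largest detected member abundance (mean ≤ max,
coverage ≤ 1).

**Conserved subset.** "Low variance across species" is interpreted as a
coefficient of variation (population standard deviation / mean of the
per-species scores) below a threshold, default 0.20 — a CV is the only
unitless reading of a percentage variance bound on quantities with
arbitrary intensity units. Complexes with zero coverage in any species
are excluded first: an absent complex is not a conserved one. An all-zero
row is excluded, not an error.

**PPI expansion.** Binary interactions are expanded into candidate
complexes as all *maximal cliques* with ≥ 3 members. A clique requires
mutual association evidence among all members, which is the natural
reading of "maximum possible complexes" from binary data; connected
components were rejected because a single hub protein would chain
unrelated complexes together. Enumeration uses pivoting recursive search
(networkx's Bron–Kerbosch implementation); output is sorted by member
tuple, so ids and order are deterministic. Tests verify equivalence with
exhaustive subset enumeration on graphs of up to 12 vertices and
maximality of every emitted clique.

## Clustering and overview

Score rows are converted to relative profiles (row / row sum) before
clustering, matching the relative-abundance reading of cross-species heat
maps; raw-score clustering remains available by flag. Missing cells in
complex-score profiles are zeros (a zero score is meaningful absence),
whereas the protein-level k-means runs on proteins detected in all
species, so that missingness patterns do not masquerade as abundance
patterns.

Ward clustering uses the textbook criterion — each merge minimizes the
increase in within-cluster sum of squares on Euclidean distances
(scipy's `linkage(method="ward")`, the "ward.D2" contract) — and the
dendrogram is cut to exactly k clusters. The historical ambiguity between
ward.D and ward.D2 is resolved in favor of the textbook criterion. Default
cuts: k = 6 for the curated catalogue, k = 8 for the PPI-derived one,
k = 6 for shared-protein k-means and k = 4 for subset analyses; all are
plain parameters. k-means uses k-means++ initialization with n_init = 25
and a recorded seed, since no initialization convention is implied by the
analysis itself.

Pearson correlations are computed per species pair over the rows detected
in both; pairs with fewer than 3 shared rows are flagged undefined (NaN)
rather than reported from degenerate data. PCA is centered, on rows, with
variance-explained fractions non-increasing by construction. No log
transform is applied by default; the preprocessing behind any particular
published overview figure is not fixed by the pipeline, so numerical
agreement with external figures is not expected.

## Synthetic data

The generator emulates the study design the pipeline targets: 4 species ×
2 replicates, ~600 reference proteins by default. Each protein draws a
log-normal base abundance (median 1e6, sigma 1.0 — a realistic multi-decade
dynamic range) and one of six archetypes: enriched 5-fold in exactly one
species (four archetypes), enriched in both mammals, or uniform.
Replicate values multiply the archetype expectation by log-normal noise
(sigma 0.1, ≈ 10% CV, typical for MS1 label-free replicates); cells go
missing independently at probability 0.1. One designated allotetraploid
species emits `.L`/`.S` accession pairs for 40% of proteins — both map to
the same reference accession and share the base abundance with
independent noise, which makes the effect of homeolog averaging directly
measurable. Unique-peptide counts are a shifted Poisson (2 + Poisson(4))
for quantifiable rows; a configurable 10% of rows instead draw counts
capped at 1, which fails the quantifiability rule by construction.
Planted complexes draw members from a single archetype, so their score
profile inherits that archetype; decoy members (never expressed) can be
salted in to exercise the coverage filter. The PPI generator plants
vertex-disjoint cliques over an Erdős–Rényi background.

All randomness flows from one integer seed through labelled substreams
(`numpy.random.SeedSequence` spawn keys), so fixtures are bit-reproducible
and each table's stream is independent of the others.

What the generator does *not* emulate: peptide-level effects (shared
peptides, length bias, chromatography), intensity-dependent missingness
(cells vanish uniformly, not preferentially at low abundance), correlated
noise between replicates, and catalogue errors (wrong members rather than
unexpressed ones). Passing tests therefore demonstrate the correctness of
the computations and their behavior under the stated noise model, not
robustness to those real-data pathologies.

## Numerical choices and degenerate inputs

* Medians agree after normalization to 1e-12 relative tolerance
  (property-tested); the comparison tolerance reflects float64 rounding,
  not a method parameter.
* Complex scores are deterministic, pure arithmetic; the brute-force
  oracle reproduces them exactly (same summation order).
* Ties in Ward merges are resolved by scipy's deterministic ordering;
  cluster labels are arbitrary up to permutation and compared by adjusted
  Rand index.
* Degenerate inputs fail loudly with the offending record named: duplicate
  accessions, negative values (row number), empty subunit lists, malformed
  edge lines (line number), samples with no detected values, all-zero
  profile rows, k larger than the item count.
* Problem sizes in tests and the acceptance script (hundreds of proteins,
  up to 200 complexes, graphs ≤ 12 vertices for exhaustive enumeration)
  are chosen so independent oracles — brute-force enumeration in
  particular — remain exact and fast.

## Known limitations

* The ortholog map is consumed as given (top-hit quality, paralog
  ambiguity and mapping errors are upstream concerns).
* No statistical testing of score differences between species is
  included; the scores are descriptive.
* Homeolog-aware duplication *correction* is not implemented; the
  collapse merely averages and the run log flags reference accessions
  receiving more than one contributing entry, leaving any correction to
  the analyst.
* Clique expansion can emit overlapping candidate complexes; no
  overlap-merging or de-noising of the PPI graph is attempted.
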