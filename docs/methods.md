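# Methods

This note documents the models, conventions and numerical choices behind
`straitpop`, in the spirit of the methods documentation of coalescent and
statistical packages. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and missing-data policy

A `LocusAlignment` holds equal-length haplotype sequences over
`{A,C,G,T,-,N}` with stable sample ids; sequences are haplotypes
(amplicon- or clone-derived), so no diplotype phasing is attempted, and
inputs are assumed co-oriented by prior alignment (no reverse-complement
logic). Columns are 0-based internally; user-facing reports are 1-based.

`N` is missing data everywhere. For diversity and differentiation
statistics we use **complete deletion**: any column containing `-` or `N`
in any retained sequence is excluded, which keeps π, *S* and Tajima's *D*
internally consistent (the convention of the classical diversity
software). Indels therefore contribute nothing to those statistics; they
are scored only in the haplotype-network stage, via simple indel coding.

## Diversity and neutrality statistics

- π is the mean pairwise difference per usable site; *Hd* is the
  sample-size-corrected haplotype heterozygosity
  `n/(n-1) · (1 - Σ p_i²)` over haplotypes collapsed on the usable
  columns; Watterson's θ is reported **per sequence** (`S/a₁`,
  `a₁ = Σ_{i<n} 1/i`); the parsimony-informative fraction counts usable
  columns with at least two states each carried by at least two
  sequences.
- Tajima's *D* uses the 1989 normalising constants computed from *n*.
  Undefined statistics (e.g. *S* = 0) are reported as NaN, never 0, so a
  monomorphic sample is not mistaken for a "stable population" signal.
- Fu's *Fs* is `ln(S'/(1-S'))` with `S' = P(K ≥ k_obs)` under the Ewens
  sampling distribution at `θ̂ = k̄` (mean pairwise differences per
  sequence, the original estimator choice). Unsigned Stirling numbers of
  the first kind are built by the triangle recurrence entirely in log
  space; both tails of the logit are formed with `logsumexp`, so *Fs*
  stays finite and accurate even when `S'` is within 1e-16 of 0 or 1.
- Significance of both statistics comes from neutral constant-size
  coalescent replicates with *n* matched and θ = k̄ (1000 by default,
  matching the study's convention). *D* is tested two-tailed on |D|; *Fs*
  is reported lower-tailed (the expansion-sensitive headline) and
  upper-tailed. p-values carry the +1/(B+1) correction and are never
  exactly zero. The *D* null is computed by a replicate-vectorised
  coalescent (interval-wise Poisson mutation counts weighted by lineage
  leaf counts); the *Fs* null needs haplotype counts and uses an explicit
  per-replicate tree with zero-mutation edge contraction. The two null
  generators are cross-checked against each other in the test suite.

## AMOVA and Φ statistics

The three-level decomposition is Excoffier–Smouse–Quattro on squared
inter-haplotype distances. With the pairwise-difference metric the
squared distance is taken to be the difference count itself — the
haplotypic convention of the standard implementation — with `squared=True`
available. Negative variance components are reported as computed and
flagged, never truncated, so the Φ definitions remain exact identities.

Permutation schemes follow the standard hierarchy: Φ<sub>ST</sub> permutes
sequences among all populations; Φ<sub>SC</sub> permutes sequences among
populations within their group; Φ<sub>CT</sub> permutes intact populations
among groups with group sizes fixed. Ties count as extreme (≥), and when
the number of distinct whole-population reassignments is below the
requested permutation count, Φ<sub>CT</sub> switches to exhaustive
enumeration (flagged in the result). Default 10,000 permutations, the
study's setting.

Pairwise Φ<sub>ST</sub> is the one-level special case on each unit pair,
with sequence permutation between the two units.

## Net-divergence split times

`divergence_summary` reports d<sub>xy</sub>, Da = d<sub>xy</sub> −
(π<sub>a</sub>+π<sub>b</sub>)/2 and T̂ = Da/(2μ) — a **no-migration moment
estimator**, flagged as such in its output. It is a deliberate
simplification standing in for full isolation-with-migration posterior
inference, which is out of scope. The estimator assumes deme sizes
constant across the split; when extant sizes differ strongly from the
ancestral size the censoring of within-deme coalescence at the split
biases T̂ (the acceptance recovery experiment therefore uses equal sizes,
the assumption under which the estimator is meant to work). Negative Da
yields T̂ = NaN rather than a negative age. The reference rate is the
study's LFY anchor, μ = 3.7 × 10⁻⁹ /site/yr.

## Haplotype networks

Simple indel coding: every distinct contiguous gap run (start, end) seen
in the alignment is one binary character; a sequence whose own gap
strictly contains a shorter character's span scores *missing* for that
character; gap columns are then removed from the nucleotide matrix.
Haplotypes collapse on (nucleotide string, indel-character vector), with
deterministic numbering by first occurrence. Distances count nucleotide
differences (columns with `N` in either haplotype skipped pairwise) plus
one step per differing indel character, missing states skipped pairwise —
an indel weighs exactly as much as a substitution, a documented choice
the source material leaves open (configurable by simply ignoring the
indel characters).

The network is a minimum-spanning network: pairs are processed in
increasing step distance; within one distance class the component
structure is frozen at the class start, so every pair that joins two
(pre-class) components is added — this retains ties and produces the
loops/ambiguities of statistical parsimony. Pairs beyond the connection
limit are excluded, giving disconnected subnetworks. Each retained
d-step edge is rendered as d−1 hypothetical median nodes chained by
1-step edges (the hollow squares of the classical figures).

The 95% connection limit is the largest j whose estimated probability of
parsimony is ≥ 0.95. Published implementations of this estimator differ
numerically, so ours is documented and a fixed limit is first-class
(`network_connection_limit_mode = fixed:j`): we model substitutions
between two sequences as Poisson with mean anchored at the Jukes–Cantor
corrected substitution count for the observed difference fraction,
uniform over sites; parsimony holds when the substitution count equals
the number of changed sites, and the estimator is
`P(M = j | j distinct sites changed)` with the occupancy term computed
from Stirling numbers of the second kind in log space. The limit is at
least 1 (at confidence 1.0 only single steps are connectable), and it is
monotone in alignment length.

## McDonald–Kreitman test

Per codon triplet: polymorphisms are changes segregating within the
ingroup; fixed differences require strict ingroup monomorphism at the
codon (a codon both polymorphic and different from the outgroup counts as
polymorphism only). Changes are classified under the configured NCBI
genetic code (standard by default). Multi-hit codons are resolved by
pathway averaging over all orderings of the differing positions, with
stop-codon routes excluded when any stop-free route exists (the
Nei–Gojobori convention); with more than two ingroup codons the codon is
scored as a star from the most frequent codon (ties broken
lexicographically). Codons with gaps or `N` in any counted sequence are
excluded; internal ingroup stop codons are excluded with a warning.

The χ² is Pearson's on the 2×2 table **without** continuity correction —
the only convention that reproduces the published worked-example value
(χ² = 5.876 for Ps=9, Pn=41, Ds=20, Dn=30) — with a Fisher's-exact
fallback when a margin is zero. The neutrality index is
(Pn·Ds)/(Ps·Dn).

## The isolation-with-migration simulator

The generator is an event-driven structured coalescent over three extant
demes (HS, C, TI): per-deme pair coalescence at rate `1/(2·Ne·scale)` per
generation, deme merges C+TI→A1 at t₀ and HS+A1→A2 at t₁, optional
backward migration. Defaults are the study system's point estimates:
Ne_HS = 547,070, Ne_TI = 810,240, Ne_C = 122,784 diploid individuals,
t₀ = 0.75 Myr, t₁ = 1.14 Myr, μ = 3.7 × 10⁻⁹ /site/yr, migration 0
(the inferred gene-flow posteriors all peaked at zero). Choices the
source material leaves open:

- **Generation time** defaults to 1 year (parameters are scaled by a
  per-year rate and no generation time is stated); configurable.
- **Ancestral sizes** default to the mean of their daughter demes (their
  posteriors are flat and carry no usable point value); configurable.
- **Migration entries** are forward-in-time 2Nm of the receiving deme,
  converted internally to backward per-lineage hop rates.
- **Mutations** are infinite-sites by default (each mutation takes a
  fresh column; saturation raises an instructive error); a finite-sites
  Jukes–Cantor mode exists for robustness work, since real haplotype
  networks show occasional homoplasy. Ancestral bases are drawn uniformly
  per column.
- **Indels** (off by default) are deletions with geometric run length
  (mean 3), placed uniformly, at a per-site-per-year event rate.
- **Chloroplast loci** use `inheritance_scale = 0.25`, the effective-size
  ratio of a uniparental haploid genome in a diploid outcrosser.

The default simulated marker panel mirrors the study's: three nuclear
introns of 400/400/393 bp and one effectively smaller cpDNA locus. At the
default sizes a 400-bp nuclear locus has θ ≈ 3 per sequence, the
magnitude the study reports (geometric-mean θ = 3.2). What the generator
does **not** emulate: recombination within loci, selection,
sequencing/assembly error, and uneven real-world sampling; passing tests
therefore demonstrate correctness of the estimators and qualitative
recoverability of deep three-deme structure, not robustness to those
real-data features.

An independent msprime configuration of the same history serves as a
cross-check oracle in the test suite; it is never the implementation.

## Landscape stage

Suitability (ESRI ASCII grid, values in [0,1]) maps to conductance
`c = max(s, floor)` with floor 1e-6 — a pure reciprocal of 0 is undefined
— while NODATA/sea cells are hard barriers (c = 0), distinct from merely
unsuitable land. Edges take the mean of the two cell conductances
(averaging resistances instead is the other published convention; the
toggle is the `squared`-style option left to the caller by building the
graph from transformed conductances), divided by the inter-centre
distance: 1, √2 and √5 grid units for orthogonal, diagonal and knight
moves, or great-circle metres with `geo_correct`. Traversal cost is the
reciprocal; least-cost paths are Dijkstra on the sparse graph. Because
the 8-neighbourhood's edge set contains the 4-neighbourhood's and the
16-neighbourhood adds knight moves to the 8, least-cost distances are
monotone non-increasing in neighbourhood richness — a property the
acceptance suite verifies on random rasters. Populations snap to the
nearest passable cell within 3 cells (configurable); unreachable or
unplaceable pairs get infinite cost and an empty path.

The `islands` synthetic raster places two high-suitability patches
separated by a near-zero corridor, emulating the finding that the exposed
sea shelf at the Last Glacial Maximum offered no usable dispersal route.

## Morphology

Corolla lobe/tube ratios classify into the three published closed ranges
(Taiwan 1.853–3.105; Japan 1.053–1.575; China 0.339–0.37). Values in the
gaps are "unclassified": the source offers no nearest-range rule, and
inventing one would overstate the trait's resolution. Range disjointness
is asserted at import.

## Reproducibility and problem sizes

The pipeline expands one global seed into independent per-stage
substreams keyed by a CRC of the stage name, so adding a stage never
perturbs earlier stages' draws; a run manifest records config, seed and
SHA-256 content hashes of all inputs and outputs. Problem sizes used by
the acceptance computations — 1000 calibration datasets × 1000 null
replicates; 2000 closed-form replicates; 50 recovery replicates of 30
loci × 400 bp × 40 sequences per split time; 20 structure-recovery seeds
with 999 permutations; 100 random rasters — are chosen so Monte-Carlo
error is small relative to each check's tolerance while the whole suite
runs in minutes on one core.

## Known limitations

- The AMOVA is per locus (as in the study's tables); no joint
  multi-locus AMOVA is attempted.
- T̂ = Da/(2μ) is a point summary; no uncertainty interval is attached
  (full IM posterior inference is out of scope).
- The connection-limit estimator is one defensible operationalisation of
  statistical parsimony; analyses that must match a specific published
  tool should use the fixed-limit mode.
- The MK polymorphism count for codons with three or more segregating
  codon states depends on the star-from-majority convention; such codons
  are rare at intraspecific divergence levels.
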