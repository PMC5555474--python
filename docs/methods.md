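# Methods

This note documents the models, conventions and design choices behind
`rdnarip`, in the order data flows through the pipeline.

## The RIP model in the simulator

The simulator emulates a fungal genome carrying N copies of a 45S rDNA
unit, a subset of which has been inactivated by repeat-induced point
mutation. RIP is modelled as independent per-site transitions with
dinucleotide-context-specific probabilities:

* a C mutates to T with probability `context_rates[CpX]`, where X is its
  3′ neighbour;
* a G mutates to A with probability `context_rates[CpX']`, where X′ is the
  complement of its 5′ neighbour — the same class read on the minus strand
  (a TpG site is a CpA site on the other strand).

A C at the last position and a G at the first position have no defined
context and are ineligible. By default RIP is applied in a **single pass
against the original sequence**, so every logged mutation's context is
exactly recoverable from the input — this is what makes the context
classifier testable to the count. Real RIP acts over successive sexual
cycles and later rounds see already-mutated neighbours; a `rounds` knob
exposes that regime without asserting how many rounds acted in any real
genome, and the package makes no claim either way.

Background noise (sequencing/assembly error and rare non-RIP mutation) is
drawn uniformly over the ten substitution classes that are *not* C→T or
G→A, at `background_rate` per site (default 0.001, the empirical "<0.1 %"
level of non-transition changes in verified pseudogene sequences). Sites
already RIPped are not additionally perturbed, so the mutation log is a
bijection onto changed positions.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| unit layout | 18S 1800, ITS1 200, 5.8S 160, ITS2 200, 28S 3300, IGS 2000 bp | typical ascomycete subunit lengths, ~7.7 kb unit |
| subunit GC | 0.48 coding, 0.50 spacers | functional coding genes observed in a 46–53 % GC band |
| `context_rates` | CpA 0.75, CpC 0.18, CpG 0.22, CpT 0.18 | strong CpA/TpG preference; yields overall RIP rates of ~15–20 % of aligned sites, inside the 17–24 % band reported for rDNA pseudogenes, and a CpA count-dominance ratio ~1.3 |
| `pseudogene_fraction` | 0.8 | pseudogene copies outnumber functional ones in assemblies because RIP variation prevents their collapse during assembly |
| `complete_fraction` | 0.7 | mix of complete and partial repeats as seen in WGS repeat tables |
| `background_rate` | 0.001 | see above |

Functional copies are emitted as exact template replicas (functional rDNA
repeats are observed identical within a genome); truncated copies keep a
random contiguous 30–70 % window; each repeat is embedded in a contig with
random 400 bp non-rDNA flanks, on a random strand.

**What the simulator does not emulate:** unequal crossing-over/gene
conversion dynamics (concerted evolution is represented only by its end
state — identical functional copies), tandem arrays on a single contig
(one repeat per contig by default), real intron splice structure (introns
are random insertions), or assembly collapse of near-identical repeats.
Passing tests therefore demonstrate correctness of the *analysis* under
the stated mutational model, not robustness to assembly artefacts.

## Repeat mining

The search runs in rounds: round k uses every sequence recovered in rounds
< k as a query, and stops when a round contributes no new locus (or after
`max_rounds`, default 10). This matters because a copy decayed to ~64 %
identity to the functional gene is invisible at the 0.70 identity floor
but is recovered through an intermediate ~85 % copy.

The engine is self-contained: exact k-mer seeding (k = 12) locates
candidate loci; each locus is refined by local affine-gap alignment
(match +1, mismatch −1, gap open −5 including the first gapped column,
extend −1), clipped to the seeded extents plus a 200 bp margin. One seed
cluster can span several adjacent copies, so accepted loci are masked and
the window re-refined until nothing acceptable remains. Candidate loci
already >50 % covered by an accepted hit are skipped, and hits within
100 bp on the same contig and strand are merged (RIP decay can fragment
one repeat into several local matches). A hit's identity is the identity
at discovery; ambiguous (non-ACGT) columns are excluded from its
denominator. Defaults `min_identity` 0.70 and `min_hit_length` 200 bp are
declared, not derived: they must capture copies decayed by ~20–25 % RIP
with headroom under the ~80 % similarity floor of the RIP substrate
requirement.

Subunit annotation aligns each strand-normalised hit semi-globally to the
reference unit and projects the reference subunit intervals through the
alignment. A subunit is *present* at ≥0.9 reference coverage for coding
genes and ≥0.5 for spacers; a repeat is *complete* when all six subunits
are present with ≥0.95 coverage of the coding genes. Insertion runs of
≥ `min_insert` (50 bp) inside a subunit are excised as introns — the
threshold separates intron-like inserts from ordinary alignment gaps and
is a declared choice.

## Classification

GC content is computed over non-gap, unambiguous bases. Paralogs are split
into high/low GC groups at the **largest gap** in the sorted GC values; if
that gap is under `min_gap` (2.0 percentage points) the set is treated as
unimodal (all functional). Caveat: with very sparse sampling the largest
gap can fall inside the pseudogene band rather than at the
functional/pseudogene boundary; the downstream spectrum condition guards
against the resulting misgrouping.

The reference for mutation spectra is the single highest-GC complete
sequence of each subunit (ties broken lexicographically by id). Spectra
count directed substitutions per alignment column; columns gapped in
either sequence are tallied as indel columns and excluded from the
`aligned_sites` denominator, as are ambiguity codes. All rates in the
package — per-class transition rates and RIP rates alike — share this
denominator, which is what makes "RIP rate" equal "G→A rate + C→T rate"
to machine precision on the same alignment.

A paralog is called **pseudogene** iff it is in the low-GC group, carries
at least one G→A/C→T transition, and its count of *other* substitutions is
statistically consistent with the noise ceiling `max_other_rate` (0.001):
consistency is a one-sided binomial test at `alpha` = 0.001 rather than a
point comparison, because on a 160 bp subunit the observed other-rate
fluctuates around the true noise rate and a point threshold set *at* the
noise level would reject about half of genuine pseudogenes. Low-GC
paralogs failing the noise test are flagged `undetermined` for review, and
are excluded from the tree stage.

Discriminating primer windows require the pseudogene set to be unanimous
and gap-free across the window (20 columns), ≥2 differences against every
functional sequence, and ≥1 fixed difference in the 3 terminal 3′
positions. Windows with GC < 0.25 carry a `low_complexity` warning:
heavily RIPped targets force AT-rich primers that can fail in practice.
Candidates are discriminating windows, not thermodynamically validated
primers.

## RIP context profiling

Context is always read from the **consensus** (highest-GC sequence), never
from the mutated query, since the neighbouring base may itself be RIPped.
Across indels the nearest non-gap consensus column defines the neighbour;
a site whose neighbour does not exist is counted `unclassified`. The four
classes plus `unclassified` exactly partition the C→T/G→A differences, and
the whole profile is invariant under reverse complementation of both
sequences.

`dominance` is the CpA-class count over the summed other three classes,
with the denominator clamped at 1 (and flagged) when those classes are
empty. Note that this count ratio mixes the per-site rate bias with the
neighbour-base composition of the template: at context rates of 3:1
(CpA:each other) its expectation is only ~1.03 and varies ±5 % with
template composition, whereas at the package's default rates it is ~1.3.
Rate-level dominance questions should therefore be asked of the
per-context rate estimates (mutations over eligible sites per context),
which the validation suite checks directly.

Windowed tracks tile the alignment (window = step = 50 columns by
default, last window truncated) so that column sums over windows
reproduce the global class counts exactly; invariant and gap columns are
tallied separately for heat-map rendering.

## Structure impact

The pairing table is consumed as a two-column 1-based TSV or a dot-bracket
string (nested round brackets only; other bracket types would denote
pseudoknots and are rejected). A mutation at a paired position *disrupts*
the pair iff the post-mutation pair (DNA read as RNA) leaves
{AU, UA, GC, CG, GU, UG}; G·U wobble counts as valid per standard rRNA
helix conventions, with a strict Watson–Crick mode available. Compensatory
double mutations that restore a valid pair — including the common RIP
double hit G→A with C→T, which turns G:C into A:T — are counted as paired
but not disrupting. This is a declared operationalisation of
"structure-destroying": no folding or free-energy computation is
attempted.

## Distances, trees, bootstrap

p-distance is differences over comparable (gap-free, unambiguous) sites;
K2P is d = −½·ln(1−2P−Q) − ¼·ln(1−2Q) and is flagged saturated (NaN) when
a log argument is non-positive; K2P ≥ p-distance wherever defined.
Deletion policy is `pairwise` (per-pair comparable columns) or `complete`
(columns gap-free in every sequence); the pipeline picks `complete` when
all sequences in a set are complete and `pairwise` otherwise, and the
policy is exposed as a flag because mixed partial sets admit either
treatment.

Neighbor-joining is the canonical Saitou–Nei agglomeration. Determinism:
ties in the Q criterion (within 1e-12) are broken by the lexicographically
smallest pair of cluster keys, a cluster's key being its smallest leaf id.
Negative branch lengths are clamped to zero with the deficit moved to the
sister branch. Saturated or undefined entries abort tree construction with
the offending pairs named.

Bootstrap resamples alignment columns with replacement; support of an
internal edge is the percentage of successful replicate NJ trees
containing its bipartition (canonicalised to the side not holding the
lexicographically first leaf). Replicates with undefined distances are
dropped and counted, with a warning above 5 %. Supports are reported as
integers 0–100 and never used to collapse edges — hiding low supports is a
display decision, not a topology decision.

Clade purity scans every edge: the tree *separates* the classes when some
edge induces exactly the functional/pseudogene bipartition; otherwise the
minimum number of misplaced leaves over all edges is reported.

Multiple alignments inside the pipeline are reference-anchored: each
sequence is aligned pairwise to the highest-GC reference and merged on
reference coordinates. This is exact for the colinear, rearrangement-free
paralog sets the pipeline produces and keeps the whole path deterministic;
it is not a general progressive aligner.

## Problem sizes and reproducibility

The bundled experiments run at desk scale, chosen so the full suite and
the acceptance script each complete in minutes on one CPU: 10-paralog
assemblies for the end-to-end pipeline (bootstrap 100 replicates), 50
paralogs for RIP parameter recovery, 5 + 5 sequences of an 1800 bp gene
for the clade-separation experiment, 500 random pairs ≤12 bp for the
aligner-vs-DP oracle and 100 random additive matrices (n ≤ 10) for NJ
topology recovery. All randomness flows from a single seed through named
`numpy.random.Generator` instances; pipeline reruns with the same
configuration are byte-identical.

## Known limitations

* Genome-scale repeat counts from public assemblies depend on external
  data retrieval and the behaviour of the original search engine, and are
  out of scope; mining is validated against simulator truth tables
  instead. The `summarize_prealigned` entry point reproduces
  per-species/per-gene summary tables from externally supplied curated
  alignments.
* The largest-gap GC split assumes the two bands are better separated than
  any within-band gap; sparse or skewed sampling can violate this.
* The disruption rule is per-pair and ignores loop context, coaxial
  stacking and non-canonical pairs.
* NJ and K2P inherit the usual distance-method caveats under the strongly
  asymmetric RIP substitution process; the package deliberately does not
  fit a substitution model to RIPped data.
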