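# Methods

This note documents the models and procedures implemented in
`grntransfer`, the parameters that matter, the numerical conventions,
and what the synthetic test ecosystems do and do not establish about
real genomes.

## Regulatory-network transfer model

The core assumption is that orthologous TFs tend to regulate
orthologous target genes. A reference GRN is a directed graph of
TF→TG edges with an effect sign (activation, repression, dual,
unknown). Transfer assigns an edge to a target genome iff both
endpoints have orthologs there (guilt by association); nothing about
binding sites, promoter architecture, or expression is modelled. This
inference is known to break down under transcriptional rewiring —
binding-site turnover, horizontal acquisition, promoter restructuring —
so predicted edges are starting points for validation, not facts; the
evaluation machinery (below) quantifies exactly how far the assumption
carries between well-characterized genomes.

Self-loops (autoregulation) transfer like any other edge. Regulators
belonging to the basal transcription machinery can be excluded by
annotation substring match (default tokens: `sigma factor`,
`antiterminator`, `terminator`, `sensor`, case-insensitive on product
and gene name); the match is deliberately conservative — a regulator
absent from the annotation is kept.

## Orthology: reciprocal best hits

Pairwise similarity hits (BLAST outfmt-6 dialect, 12 columns, with
optional explicit coverage columns 13–14) are filtered on three
inclusive thresholds:

| parameter      | default | meaning                                      |
|----------------|---------|----------------------------------------------|
| `max_evalue`   | 1e-5    | alignment E-value upper bound                |
| `min_coverage` | 70 %    | required on **both** query and subject       |
| `min_identity` | 25 %    | percent identity lower bound                 |

These are the thresholds commonly used for bacterial TF ortholog
detection. When only the 12 standard columns are present, coverage is
computed as `100 × alignment_length / sequence_length` from supplied
length maps. Surviving hits are reduced to strict reciprocal best
hits; "best" is the highest bit score, with deterministic tie-breaking
(lower E-value, higher identity, lexicographically smaller subject id).
The result is a 1:1 map. Co-ortholog (1:many) groups, as a
graph-clustering orthology tool would emit, are intentionally not
modelled: the transfer rule consumes 1:1 correspondences, and strict
RBH is the reproducible core of such clusterings. Consequences: in
genomes with recent paralog expansions some true ortholog pairs are
dropped rather than guessed.

## Transcription-unit model

Genes are scanned in coordinate order per replicon (1-based inclusive
coordinates). Adjacent genes join one TU iff they share a strand and
`start(next) − end(prev) − 1 ≤ max_intergenic_gap` (default **50 bp**).
Abutting genes have gap 0; negative gaps (overlapping ORFs, common in
bacteria) join iff `allow_overlap` (default true). Replicon boundaries
always break TUs and circular replicons are treated as linear — at
most one operon per replicon can be split by this simplification.
A fixed distance threshold replaces the likelihood-based distance
models of dedicated operon predictors; it makes the rule explicit,
monotone (larger threshold ⇒ never more TUs) and testable, at the cost
of ignoring genome-specific intergenic-distance distributions.

The **first gene** of a TU is the promoter-proximal one in
transcription order: lowest coordinate on the + strand, highest on the
− strand. TU expansion applies only when a transferred target heads
its TU; a target landing mid-operon is *not* expanded and *not*
re-anchored to the TU head, matching the conservative reading of the
rule (the regulator demonstrably acts on that gene, not necessarily on
the whole operon's promoter). Expansion is a closure operator:
idempotent, extensive, monotone — property-tested on every fixture.

## Integration and provenance

Every edge carries a set of `(source organism, derivation)` pairs with
derivation ∈ {`direct`, `orthology`, `tu_expansion`}. Integration is
edge union keyed on (tf, tg); a duplicate keeps one record with merged
provenance, so per-source counts may sum to more than the number of
distinct new edges (an edge can be found via several references).
Conflicting effect signs integrate to `dual` rather than dropping the
edge — information-preserving and visible to the user. Per-source
contribution shares are **truncated** (not rounded) to two decimals,
matching the convention of published share tables of this kind.

## Evaluation

**Edge level.** TP = edges in both networks, FN = reference-only,
FP = prediction-only; TN is defined only against an explicit
possible-edge universe. For the randomization null the universe is
|union TFs| × |union genes|, so all four counts total the same universe
in every replicate.

**Graphlet level.** Instances are (unordered node triple, class) pairs
over the 13 weakly connected directed 3-node isomorphism classes,
named by the standard triad census (021D fan, 021C cascade, 030T
feed-forward loop, …). Enumeration walks edges and their endpoint
neighborhoods (every connected triple contains an edge touching the
third node), classifies each triple by a canonical 6-bit arc mask
minimized over the 6 node permutations, and ignores self-loops. The
implementation is verified against exhaustive per-triple classification
with networkx's independent triad-type routine. TN uses the universe
C(n, 3) × 13 over the union node set; this convention is stated in the
output because TN magnitudes are convention-dependent and other
choices are defensible.

**Metrics.** P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R). A
zero denominator yields 0 with a degenerate-input flag; the harmonic
identity F1 = 2TP/(2TP+FP+FN) holds exactly and is exercised in tests.
Metrics are printed to 4 decimals.

**Randomization null.** TF identity labels are permuted uniformly over
the TF positions (targets fixed), preserving edge count, TF count,
gene set and the TF out-degree sequence. Null-mean TP/FP/FN/TN over
`n_replicates` (default 10,000; 200 in the desk-scale tests and the
acceptance script, enough for the mean counts to stabilize at these
network sizes) feed a G-test: G = 2 Σ Oᵢ ln(Oᵢ/Eᵢ), terms with
Oᵢ = 0 contributing 0, p from χ² with k−1 df. The G statistic is
computed in-package because observed and null-mean counts need not sum
identically (TP varies across replicates), which standard
goodness-of-fit entry points reject; where sums do agree the
implementation is cross-checked against scipy's log-likelihood-ratio
power divergence.

**Consensus naming.** Cross-genome comparison requires a shared
namespace: ortholog groups are the connected components of the union
of all pairwise maps (transitive closure via union–find), and every
member is renamed to the lexicographically smallest identifier of its
group — deterministic and independent of map order.

## Synthetic ecosystems

The generator emulates the study conditions at desk scale: a reference
genome of **60 genes, 8 TFs, 80 edges** laid out in operonic runs
(TU sizes 1 + Poisson(mean−1), default mean 2; within-TU gaps ≤ 20 bp,
between-TU gaps ≥ 200 bp, straddling the 50 bp threshold with margin so
the planted TU partition is exactly recoverable), proteins of 60–120
random residues, and a derived target conserving a configurable gene
fraction (default 0.7) with 5 % per-residue substitution divergence
plus 5 unrelated novel genes. All-vs-all similarity hits use exact
head-to-head identity; unrelated sequences score at the ~5 % random
floor, far below every threshold, so RBH provably recovers the planted
map. The generator also emits the *expected* transferred and
TU-expanded networks via independent exhaustive scans, giving
planted-truth oracles for the whole pipeline.

What passing these tests shows: the algorithms implement their stated
rules exactly (recall equals the conserved-edge fraction by
construction, expansion is a fixpoint, the pipeline is deterministic).
What they do not show: performance on real genomes — the generator has
no paralogs, no domain-level homology, no gene fusions/fissions, no
compositional bias, and its networks are uniform rather than
scale-free, so real precision/recall will be substantially lower, as
the published cross-comparisons of the six model organisms (F1 between
0.05 and 0.59 at edge level) illustrate.

## Numerical and degenerate-input conventions

- Coordinates 1-based inclusive everywhere on disk; any half-open
  arithmetic is internal.
- Missing annotation text fields carry the literal `NODATA`; `NODATA`
  is never a legal edge endpoint or ortholog key.
- Fewer than 2 TFs makes the randomization the identity (warned, not
  an error).
- Hub calling: `top_fraction` (default top 5 % of TFs by out-degree,
  ties at the cutoff included, at least one hub) or
  `degree_threshold` (mean + k·sd). There is no canonical hub
  definition; the default is a common pragmatic choice.
- Co-regulation modules: single-linkage connected components of the
  regulator-pair Jaccard similarity graph at a threshold (default 0.5),
  on out-neighborhoods for regulators or in-neighborhoods for targets
  (both exposed, since common-neighbor similarity is meaningful on
  either side). This reduces a full profile-similarity/hierarchical
  module workflow to the one quantity it is built on; it recovers
  planted block structure but will merge chained modules that
  hierarchical merging could keep apart.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); reruns are byte-identical.

## Known limitations

- No binding-site scanning or expression integration; transfer
  fidelity is bounded by orthology alone.
- 1:1 orthology only (see above).
- The TU threshold is global; genomes with unusual intergenic spacing
  deserve a re-tuned `max_intergenic_gap`.
- Graphlet enumeration is exact but cubic in the worst case; intended
  for networks up to a few thousand nodes, not metagenome-scale graphs.
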