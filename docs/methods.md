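# Methods

## Evidence model

The unit of curation is the unordered protein pair, identified by canonical
Entrez gene IDs. Provider records arrive as PSI-MITAB 2.5 lines; the reader
keeps the first `database:accession` token of each identifier column,
extracts `MI:NNNN` codes from the parenthesized-term syntax, accepts files
with more than 15 columns (extended MITAB dialects) and rejects shorter
data lines with the offending line number. Records are restricted to the
association-like interaction categories (association MI:0914, physical
association MI:0915, direct interaction MI:0407, colocalization MI:0403);
when a method-ontology DAG is supplied, descendants of these codes are
accepted as well. Rows whose interactors do not both map to a positive
Entrez ID are discarded and tallied by cause, so
`kept + discarded = input rows` always holds.

Aggregation takes the union of studies, detection methods and interaction
types over all rows of a pair. "Duplicate" means an identical
(pair, study, method) triple — set semantics make duplicates vacuous —
while distinct studies or methods for the same pair are evidence, not
duplication. A missing field (`-`) contributes nothing rather than
invalidating its row. Self-interactions are retained: homodimer evidence is
legitimate, and the resulting self-loop counts once in a node's degree.
When two provider identifiers map to the same Entrez ID their rows merge,
since deduplication is defined at the Entrez level. Proteins exist in the
network only through interactions, so isolated nodes cannot arise by
construction. Interolog support (species in which homologs of the pair also
interact) is attached from a per-pair taxon table; the mouse taxon (10090)
is excluded defensively.

## Scoring

`S = w_s·s_s + w_o·s_o + w_t·s_t` with `s_i(n) = 2/(1+e^{−α_i n}) − 1`,
algebraically `tanh(α_i n/2)` — the identity the test suite uses as an
independent oracle. Defaults: weights 0.6/0.1/0.3 (must be nonnegative and
sum to 1 within 1e−9) and rates α = 1, 1.5, 0.5, chosen so that the study
sub-score saturates around three supporting studies, the interolog
sub-score around two species, and the technique sub-score once about two
mid-reliability techniques (summed reliability ≈ 10) have been applied.

Technique reliability is an expert-assigned 0–10 value per PSI-MI detection
method; each *distinct* method counts once regardless of how many studies
used it. The shipped default table carries the three anchor classes
(NMR and light scattering 10; two-hybrid and co-immunoprecipitation 5;
fluorescence microscopy and RNAi 1) plus a loader for full user tables.
Methods absent from the table default to reliability 1 — the lowest anchor
class, a deliberately conservative fallback — with a warning.

Scores are kept at full precision; the printed 0.53/0.6 thresholds are
2-decimal display values. Quartile confidence levels use the
linear-interpolation quantile (numpy's default), the most common
convention; the published medium/high constants (0.53/0.6) are exposed as
named presets rather than recomputed, because they summarize a specific
historical provider snapshot that no synthetic corpus reproduces.

## Annotation

Ontologies (a GO-slim-like DAG and a MeSH-tree-like hierarchy converted to
parent edges) are consumed as (child, parent, relation) triples; construction
rejects cycles. Descendant closure follows `is_a` and `part_of` by default
— slightly broader than "children" alone, matching common GO-slim practice
— and the relation set is configurable. Propagation is downward only: an
interaction carries a term when **both** partners are directly annotated
with the term or one of its descendants; ancestors are never inferred. A
homodimer needs only its single gene to qualify.

Presence calls are `TPM ≥ threshold` with threshold 1 TPM, inclusive
("at least one TPM"). An interaction's tissue set is the AND of its
partners' presence vectors; genes absent from the expression matrix are
present nowhere (conservative) rather than an error. Raising the threshold
can only shrink tissue sets — asserted as a property test.

## Queries

Identifier resolution accepts Entrez (all-digit strings), gene symbol, MGI
and UniProt accessions, in that precedence; an ambiguous symbol is an error
listing the candidates. Network queries take proteins and/or explicit pairs:
`layers=0` returns edges within the input set, `layers=1` adds first-level
neighbors, keeping a neighbor only if it interacts with at least
`min_connections` input proteins; edges among surviving neighbors are
included by default (toggleable — the choice is genuinely open, and this
variant keeps the subnetwork self-consistent). Confidence, interaction-type,
tissue and term filters are conjunctive. The confidence cutoff is
**inclusive** (score ≥ threshold), so a median-valued edge stays inside the
medium-confidence set. Explicitly queried pairs absent from the reference
get the sentinel pseudo-score −1; pseudo-rows are user-requested absences,
so they are exempt from confidence filtering and excluded from degree and
score statistics. Exports: TSV edge lists, PSI-MITAB 2.5 (round-trippable
through the package's own parser) and a node-link JSON graph standing in
for interactive visualization.

## Directionality

Sources default to receptors and sinks to transcription factors, both taken
from explicit role lists (never inferred); either set may be overridden.
For every (source, sink) pair all minimum-hop paths are enumerated and each
traversed edge is oriented in its direction of traversal; an edge traversed
in both directions across any retained paths is left undirected
("conflicting" is read as conflicting traversal directions, not regulatory
signs — regulatory signs enter only through the curated overlay). The
weighted variant keeps, per endpoint pair, only the minimum-hop path with
the highest summed confidence, breaking ties by lexicographically smallest
node sequence so runs are reproducible; a −log(score) Dijkstra weighting is
available behind `method="neglog"` but is not the default, since the
default semantics contrast hop-count shortest paths with a
confidence-based selection among them. Disconnected endpoint pairs
contribute nothing. Curated effect entries (activation/inhibition) override
inference; entries present in both orientations mark the edge undirected
with both effects attached, and entries for absent edges are ignored — the
overlay can never orient an edge outside the subnetwork.

## Synthetic fixtures

The corpus generator emulates a multi-provider snapshot: ~150 true pairs
over 80 proteins, one plus Poisson(1) studies per pair with one or two
techniques each drawn from an eight-method pool, 10% exact-duplicate rows,
10% rows with unmappable provider identifiers (split across A/B/both), 5%
rows in an off-category interaction type, 40% interolog coverage over five
taxa, an 8-tissue TPM matrix with 50% presence probability (present genes
1 + Exponential(20) TPM, absent genes uniform below 1), a 3-level/3-branch
random ontology, and random role/effect tables. These sizes exercise every
code path while keeping the default test suite and the acceptance script in
the seconds range. A ground-truth sidecar (true pairs, per-pair evidence,
row tallies) makes pipeline recovery an exact bookkeeping check, not a
statistical estimate. The generator does **not** emulate provider-specific
MITAB dialect quirks, realistic TPM distributions, correlated expression,
or biased study/technique co-occurrence — so green tests certify the
pipeline's bookkeeping and contracts, not performance on real snapshots.

The Hippo fixture is deterministic: six genes with synthetic Entrez IDs
(101–106) and real symbols, six cascade edges each carrying three studies,
NMR + two-hybrid evidence and one interolog species (score ≈ 0.906, above
the medium preset by design so confidence filtering never breaks the use
case), a trophoblast/stem-cell expression matrix in which only Tead4 drops
below 1 TPM in the stem-cell context, Tead4 flagged as a transcription
factor and Stk4 listed as a receptor — a fixture convenience so default
endpoint selection resolves (biologically Stk4 is a cytoplasmic kinase; the
modeled use case sets the source explicitly).

## Numerical notes and limitations

- `2/(1+e^{−x}) − 1` is mathematically below 1 for finite x but rounds to
  exactly 1.0 in binary64 beyond x ≈ 37; strict-monotonicity properties are
  therefore asserted on the unsaturated domain (αn ≲ 30).
- Weight-sum validation uses tolerance 1e−9; the score-identity invariant
  holds to 1e−12.
- Quantiles are linear-interpolation (type 7); other conventions shift the
  quartiles of small score multisets.
- Determinism: fixture generation uses a single seeded generator and sorted
  iteration everywhere sets are serialized; re-scoring sorts by pair;
  direction inference sorts endpoint sets and breaks path ties
  lexicographically.
- Screen annotation treats unresolvable identifiers like absent pairs
  (score −1) rather than erroring, since screening lists routinely contain
  genes outside the reference.
- The package does not parse full OBO/MeSH distributions, does not perform
  enrichment statistics, and does not query live provider services; all
  inputs are files in the documented TSV/MITAB formats.
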