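# ppiref

An evidence-aggregated reference of mouse protein–protein interactions
(PPIs), built as a library plus command-line tool. It covers the full life
cycle of a curated interactome resource: ingesting PSI-MITAB 2.5 snapshots
from molecular-interaction providers, collapsing redundant records into
per-pair evidence, scoring each interaction by the amount *and quality* of
its support, annotating interactions with ontology terms and tissues, and
answering context-specific network queries with shortest-path
directionality inference. It is aimed at systems biologists who need
reliable, tissue-aware mouse subnetworks as input to downstream analyses,
and at tool builders who want the scoring and query machinery without a web
stack. All inputs can be produced by the bundled synthetic-fixture
generator, so the whole pipeline runs offline.

## The confidence score

Every interaction receives

```
S = w_s · s_s + w_o · s_o + w_t · s_t,        w_s + w_o + w_t = 1
```

where each sub-score is the saturating function

```
s_i(n) = 2 / (1 + e^(−α_i n)) − 1  ∈ [0, 1)      (≡ tanh(α_i n / 2))
```

with `n` being, per component:

- **s_s** (weight 0.6, α = 1): the number of distinct studies reporting the
  interaction — saturating around three studies;
- **s_o** (weight 0.1, α = 1.5): the number of non-mouse species in which
  homologs of the pair also interact (interolog support) — saturating
  around two species;
- **s_t** (weight 0.3, α = 0.5): the sum of expert reliability values
  (0–10) over the distinct detection techniques used, e.g. NMR and light
  scattering 10, two-hybrid and co-immunoprecipitation 5, microscopy- and
  RNAi-based assays 1 — saturating once roughly two mid-reliability
  techniques agree.

Named confidence levels are quartiles of the reference score distribution;
the published constants (medium = 0.53, high = 0.6) ship as presets. All
parameters — weights, rates and the reliability table — are user-overridable
for re-scoring.

Context-specific networks use a 1-TPM presence call (a gene is present in a
tissue if expressed at ≥ 1 TPM; an interaction takes place where both
partners are present) and downward ontology propagation (an interaction
carries a term when both partners are annotated with the term or any of its
descendants). Directionality is inferred from minimum-hop paths between
sources (receptors by default) and sinks (transcription factors): edges
traversed by at least one shortest path are oriented source-to-sink-ward,
and edges traversed in both directions stay undirected.

## Worked example: a Hippo-pathway subnetwork

The packaged fixture is a miniature Hippo signaling cascade
(Stk4/Sav1 → Lats2 → Yap1/Wwtr1 → Tead4) with a two-context expression
matrix:

```
$ ppiref fixture --kind hippo --outdir hippo
$ ppiref build --mitab hippo/interactions.mitab --idmap hippo/idmap.tsv \
    --interologs hippo/interologs.tsv --reliability hippo/reliability.tsv \
    --out scored.tsv
scored 6 interactions from 18 rows (0 discarded: 0 unmapped A, 0 unmapped B, 0 both)

$ ppiref partners --scored scored.tsv --idmap hippo/idmap.tsv --protein Lats2
partner_entrez  partner_symbol  ...  score               publications                         techniques       interolog_species
101             Stk4            ...  0.9062721802434945  pubmed:9010|pubmed:9011|pubmed:9012  MI:0018|MI:0077  9606
104             Yap1            ...  0.9062721802434945  pubmed:9020|pubmed:9021|pubmed:9022  MI:0018|MI:0077  9606
105             Wwtr1           ...  0.9062721802434945  pubmed:9030|pubmed:9031|pubmed:9032  MI:0018|MI:0077  9606
```

Each edge is backed by three studies (s_s = tanh(1.5) ≈ 0.905), one
interolog species (s_o = tanh(0.75) ≈ 0.635) and two techniques summing to
reliability 15 (s_t = tanh(3.75) ≈ 0.999), hence
S = 0.6·0.905 + 0.1·0.635 + 0.3·0.999 ≈ 0.906 — comfortably above the
high-confidence preset. Restricting the query to the stem-cell context
drops the Yap1–Tead4 and Wwtr1–Tead4 edges (Tead4 is below 1 TPM there),
reproducing the biology in which Yap1 is kept out of the nucleus and cannot
activate Tead4:

```
$ ppiref query --scored scored.tsv --idmap hippo/idmap.tsv \
    --proteins "Stk4,Lats2,Tead4" --expression hippo/expression.tsv \
    --tissue "stem cell" --out_type browser
entrez_a  entrez_b  score
101       102       0.9062721802434945
101       103       0.9062721802434945
103       104       0.9062721802434945
103       105       0.9062721802434945
```

In the trophoblast context the full cascade survives, and
`ppiref direct --sources Stk4 --sinks Tead4 ...` orients it
Stk4 → Lats2 → {Yap1, Wwtr1} → Tead4 in the exported JSON graph.

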