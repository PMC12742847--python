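# Methods

`sdohkg` implements a pipeline that mines social-determinants-of-health
(SDoH) knowledge triplets from text and patient records, fuses them with a
biological knowledge graph (KG), and asks whether the SDoH augmentation
improves graph-embedding link prediction — with a differential-expression
stage that validates candidate genes in omics data. The production inputs of
such an analysis (credentialed EHR tables, a PubMed crawl, a full biomedical
KG, post-mortem proteomics and single-cell RNA-seq) are restricted or very
large, so the package ships a first-class synthetic-data module that emulates
each input with known ground truth. Everything below describes what the code
actually computes.

## Text mining

Text is cleaned by lowercasing, removing punctuation and special characters,
and collapsing whitespace; sentences are split on sentence-final punctuation
before cleaning. Entity recognition, SDoH classification, and relation
labelling are pluggable interfaces (the production analogue would call an
NER toolkit and an LLM); the shipped implementations are dictionary-backed
and deterministic. Classification is two-pass: pass 1 assigns each candidate
term one of the five Healthy People 2030 SDoH categories and drops everything
that fits none (a term fitting no category is unlikely to be a genuine social
determinant); pass 2 assigns subcategories. All terms are classified in one
batch so no per-record context leaks.

For a biomedical entity *b* and an SDoH entity *s* the co-occurrence score is
the sentence-level overlap coefficient

    score(b, s) = n_both / max(n_b, n_s)

where `n_both` counts sentences containing both and `n_b`, `n_s` count
sentences containing each. Pairs with score >= 0.5 become triplets. Two
readings of the denominator are possible ("the higher of the two numbers of
sentences in which only one of the two entities appears" could mean exclusive
counts); the exclusive reading can exceed 1 and is incompatible with a
frequency-style threshold, so the total-count (overlap-coefficient) reading
is used. The threshold comparison is inclusive — a pair sitting exactly at
0.5 is retained — and configurable.

## EHR population KG

The cohort is selected by ICD-9 codes (default: the AD/ADRD list 3310, 2900,
2901, 2902, 2903, 2904, 3311, 3312, 33182, 2941, 4380; any-match semantics).
Each patient contributes a typed entity set: one disease entity per diagnosis
code, one drug entity per prescription, one entity per demographic
attribute-value (age, ethnicity, religion, marital status, gender,
insurance — age bucketed into decades so the node set stays bounded), and the
SDoH terms the classifier chain accepts from the discharge-note text. The
population KG connects every unordered pair of entities co-assigned within a
patient, aggregated over patients: edge weight = number of patients carrying
both entities, and pairs seen in fewer than 10 patients are dropped. No
patient nodes appear; the graph is population-level by construction (the
per-patient star-graph alternative would put identifiable hubs in the graph).
Relation labels are the canonical ordered pair of endpoint types
(`disease_drug`, ...), since no EHR relation vocabulary exists.

## Fusion

Entities of shared types (drug, disease by default) are normalized to
concept identifiers (CUIs) through a static two-column mapping table — a
deliberate stand-in for a live terminology service, keeping runs
deterministic and free of licensed resources. Nodes with equal (type,
identifier) keys collapse; unmapped entities keep their original identifiers
so nothing is lost. Duplicate (head, relation, tail) edges after rewriting
deduplicate keeping the maximum weight and the union of provenance; parallel
edges with different relations stay distinct. Mirrored edges (both
directions of the same pair under the same relation) are collapsed to a
single canonical direction, lexicographically smaller id first.

## Link prediction

The encoder is a two-layer graph convolutional network: each layer computes
`H' = Â H W` with `Â = D^{-1/2}(A + I)D^{-1/2}` over the undirected,
homogeneous skeleton of the KG (relation labels are used only for split
bookkeeping and candidate typing — the method is a plain GCN, not a
relational one), with tanh between layers and a linear output layer. Input
and output dimensions are 50. Candidate edges are scored by cosine
similarity.

The training objective is not dictated by the scoring function, so the
package uses a logistic contrastive loss on temperature-scaled cosines
(temperature 0.1): observed edges are pushed toward score 1 and, per
positive, one uniformly tail-corrupted type-compatible non-edge (resampled
every epoch) toward 0. Optimization is full-batch Adam (learning rate 0.05)
for 250 epochs. The graphs carry no intrinsic node attributes, so input
features are free parameters: initialized i.i.d. normal with variance 1/dim
and optimized jointly with the layer weights (`learn_features=False` freezes
them). Forward and backward passes are written directly in numpy/scipy;
training internals run in float32 (the pair-gradient arrays are
memory-bound; the objective is insensitive to the precision at these
scales), and a ~2,000-node graph trains in a few seconds on one CPU. A
non-finite loss raises a training error naming the epoch.

Three experiment designs:

- **Random mask** — hold out floor(20%) of one relation's edges uniformly;
  train on the rest (all other relations intact).
- **Targeted mask** — hold out a gene's edges to a list of experimentally
  validated interaction partners (in production, a protein–protein
  association database export; in tests, synthetic ground truth).
- **Exploratory ranking** — enumerate absent SDoH–gene pairs, score by
  cosine, return the top fraction (the production default 1e-7 reads the
  study's "top 0.0001‰" literally; 1e-6 for the 0.0001% reading is a flag
  away). Ties break by canonical pair order so output is deterministic.

Evaluation: for each held-out positive, 100 type-compatible non-edges
sharing the positive's head are sampled (tail corruption only; corrupting
heads as well is a configuration choice the method leaves open), all 101
candidates are scored, and the positive's reciprocal rank is recorded with
mean ranks on ties (unbiased under score ties). MRR is the arithmetic mean.
Each experiment runs 15 times; base-vs-augmented comparisons are paired by
seed: the same run masks the same edges, uses the same initialization seed,
and samples the same evaluation negatives in both arms.

## Statistics

Per relation (or gene): mean ± SD (n−1 denominator) of the 15 MRRs, a
two-tailed paired t-test, and a two-tailed Wilcoxon signed-rank test, both
Bonferroni-adjusted over the experiment family (7 relations; 23 genes).
The Wilcoxon implementation drops zero differences, mid-ranks ties, takes
the smaller signed-rank sum as the statistic, and computes the exact
two-tailed p by dynamic programming over all 2^n sign assignments for
effective n <= 25 (15 runs always take this path), falling back to the
normal approximation with continuity and tie corrections above.
Benjamini–Hochberg is the step-up construction
`q_(i) = min_{j>=i} m p_(j) / j`, capped at 1, returned in input order.

## Omics validation

Differential abundance fits, per feature, ordinary least squares of
log-scale abundance on a case/control indicator plus nuisance covariates
(default design: one continuous age-like and one binary sex-like term,
mirroring standard post-mortem designs). The p-value comes from the
two-tailed t-statistic of the group coefficient; BH runs across features and
the significance flag is q <= 0.05. A rank-deficient design errors; a
constant feature gets p = 1 with a warning. Cross-dataset consensus is the
intersection of the two significant sets.

Per-cell-type DE: per (gene, cell type), the log fold change is the
difference of mean log-normalized expression (case − control) with a
two-sample t-test; BH runs over the full gene × cell-type grid (the
correction family is not dictated by the design; a per-cell-type alternative
is available). Fold changes are z-scored within each cell type, and genes
are clustered on their z-profiles with average-linkage hierarchical
clustering on Euclidean distance; the dendrogram leaf order is returned for
heatmap layout. Input expression is assumed already normalized and
log-transformed; a log1p convenience transform exists but is never applied
silently.

## Synthetic data: what it emulates, and what it does not

- **Corpus** — bag-of-entities sentences (no grammar; only sentence-level
  co-mention counts feed the score). A seed entity is drawn per sentence;
  linked partners co-occur with probability `p_link` (default 0.8),
  unrelated opposite-kind entities with `p_background` (default 0.05).
- **Patient tables** — six demographic attributes, diagnosis codes, drugs,
  SDoH terms embedded in generated note sentences, and planted entity
  co-assignment rules with configurable rates. No admission timelines and
  no realistic clinical language.
- **Biological KG** — ~1,900 nodes over the seven node types, seven relation
  classes each connecting its two designated types, and a latent block
  (community) structure: 8 blocks, within-block edge probability 0.03,
  between-block 0.003. SDoH nodes (50) attach to disease and gene nodes:
  with `aux_informative=true` they connect only within their own block
  (probability 0.12) and act as community anchors — the regime the
  augmentation hypothesis describes; with `aux_informative=false` they
  attach uniformly at the degree-matched rate 0.12/8 and carry no signal
  (negative control). The base/augmented comparison removes/retains the
  SDoH nodes of the same generated graph, so both arms share the evaluated
  relation's edges exactly. The regime was calibrated when the experiment
  was designed: the base graph carries weak-but-present community structure
  (headroom for informative SDoH edges to matter), and the SDoH edge budget
  (~660 edges, about 5% of training positives) is small enough that purely
  random attachment sits below the detection limit of the paired design —
  at several-fold larger budgets, uninformative edges measurably *hurt* the
  encoder (capacity spent fitting unfittable random edges), which would make
  the noise control a confound rather than a control.
- **Omics** — `value(s,f) = baseline(f) + effect(f)·group(s) + covariates +
  N(0, noise_sd)`; defaults: 50 cases / 50 controls, 1,000 features, 5%
  planted at 3× the noise SD.

All generators draw from a single seeded stream, so identical configs give
byte-identical outputs. Passing tests on these generators shows the pipeline
recovers planted structure under its stated model; it does not certify
performance on real corpora (where mentions are ambiguous), real EHR (where
SDoH language is noisy and demographics are missing-not-at-random), or real
omics (batch effects, missingness, non-Gaussian noise).

## Problem sizes and numerical choices

The augmentation experiment in the acceptance suite evaluates the
`disease_gene` relation — the relation whose endpoints carry the planted
SDoH signal — at the full synthetic scale (~2,000 nodes, 15 paired runs per
condition); evaluating all seven relations is a configuration change, not a
code change. The pipeline's scaled-down smoke configuration (`scale=0.12`,
40 epochs, 3 runs) exists to exercise orchestration and reproducibility, not
to measure effects. Cosine ties in ranking are resolved by mean rank;
candidate ties in the exploratory list by canonical pair order. Negative
sampling rejects existing edges for up to four redraw passes and then
accepts the (vanishingly rare on sparse graphs) leftovers. Degenerate
inputs: all-zero paired differences raise a degeneracy error in the tests
themselves but are flagged (NaN p) in the summary table, since identical
arms carry no evidence either way.

## Known limitations

- The GCN is homogeneous; relation types do not modulate message passing.
- Literature relation labels default to a single canonical label unless a
  relation extractor is plugged in; label quality is out of scope.
- The CUI mapping is a static table; no fuzzy matching or ontology-aware
  merging.
- Exact Wilcoxon is limited to effective n <= 25 (beyond that the normal
  approximation is used, which is standard at such n).
- The synthetic block model plants community structure only; degree
  heterogeneity, hubs, and relation-specific topology of real biomedical
  KGs are not modeled.
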