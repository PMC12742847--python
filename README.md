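# sdohkg

Social determinants of health (SDoH) — economic stability, education,
neighborhood, health-care access, social context — shape Alzheimer's disease
(AD) risk, but the knowledge connecting them to disease biology is scattered
across literature and electronic health records (EHR). `sdohkg` is a Python
package for researchers who want to mine that knowledge into a typed
knowledge graph (KG), fuse it with a biological KG, and test whether the
SDoH augmentation improves graph-embedding link prediction — with a
differential-expression stage that validates nominated genes in omics data.

The pipeline, end to end:

1. **Text mining** — clean text, recognize entities (pluggable NER /
   classifier interfaces with dictionary-backed implementations), keep
   (bio, SDoH) pairs whose sentence co-occurrence score
   `n_both / max(n_a, n_b) >= 0.5`, and emit knowledge triplets.
2. **EHR population KG** — select an AD/ADRD cohort by ICD-9 code, build
   per-patient entity sets (diagnoses, drugs, six demographics, SDoH terms
   from notes), connect co-assigned entity pairs, and drop pairs seen in
   fewer than 10 patients.
3. **Fusion** — align drug/disease entities across graphs by concept
   identifier (CUI), merge, and collapse mirrored edges.
4. **Link prediction** — train a 2-layer graph convolutional network
   (dimension 50, 250 epochs, logistic contrastive loss on
   temperature-scaled cosine scores; numpy implementation, CPU-fast at this
   scale), then run three experiments: random masking of 20% of a
   relation's edges, targeted masking of a gene's validated partners, and
   exploratory ranking of absent SDoH–gene pairs.
5. **Evaluation** — mean reciprocal rank (MRR) over 15 seed-paired runs per
   relation; two-tailed paired t and Wilcoxon signed-rank tests (exact
   distribution at n = 15), Bonferroni-adjusted over the experiment family.
6. **Omics validation** — per-feature OLS differential abundance with
   Benjamini–Hochberg correction at q <= 0.05, cross-dataset consensus, and
   per-cell-type differential expression with z-score profiles and
   hierarchical gene clustering.

The production inputs (MIMIC-style EHR tables, PubMed abstracts, a full
biomedical KG, AMP-AD/ROSMAP-style proteomics, single-cell RNA-seq) are
restricted or large, so the package includes a first-class synthetic-data
module generating structurally faithful stand-ins with known ground truth:
corpora with planted co-occurrence, patient tables with planted
co-assignment, a typed KG with latent block structure whose SDoH nodes
either carry community signal or are a degree-matched noise control, and
omics matrices with planted group effects. See `docs/methods.md` for the
model details and what passing tests do and do not show.

## Worked example

```python
from sdohkg import (KGConfig, generate_bio_kg, paired_augmentation_runs,
                    summarize_comparison)

# ~2,000-node synthetic KG; SDoH nodes attach within their latent block
kg, truth = generate_bio_kg(KGConfig(seed=0, aux_informative=True))

# 15 seed-paired runs: mask 20% of disease-gene edges, train a GCN on the
# base graph (SDoH removed) and the augmented graph, measure MRR
base, aug = paired_augmentation_runs(kg, "disease_gene", runs=15)

table = summarize_comparison({"disease_gene": base},
                             {"disease_gene": aug}, m_corrections=7)
print(table[["label", "mean_base", "mean_augmented",
             "t_p_bonferroni", "wilcoxon_p_bonferroni"]].to_string(index=False))
```

```
       label  mean_base  mean_augmented  t_p_bonferroni  wilcoxon_p_bonferroni
disease_gene   0.067524        0.091008        0.000256               0.000854
```

Read: with SDoH nodes that genuinely carry community signal, the augmented
graph lifts the MRR for held-out disease–gene edges by about a third
(0.068 → 0.091), and the improvement survives Bonferroni adjustment over the
seven-relation family under both the paired t-test and the Wilcoxon
signed-rank test. Re-running with `aux_informative=False` (SDoH attached
uniformly at the same expected degree) shows no significant difference —
the lift comes from the information in the SDoH edges, not from extra
connectivity per se.

The same machinery is exposed as a CLI:

```bash
sdoh-kg run --seed 0 --out artifacts/          # full synthetic pipeline
sdoh-kg mine-lit --corpus corpus.jsonl --threshold 0.5 --out triplets.tsv
sdoh-kg build-ehr --tables tables/ --min-freq 10 --out ehr_kg/
sdoh-kg fuse --kg-a lit_kg/ --kg-b ehr_kg/ --cui-map cui.tsv --out merged/
sdoh-kg eval-random-mask --kg merged/ --relation disease_gene --runs 15 --out runs.csv
sdoh-kg validate-omics --matrix omics/ --q 0.05 --out de.csv
```

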