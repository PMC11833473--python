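# ecclust

Clustering of clinical-trial **e**ligibility **c**riteria, with the
evaluation experiments that show what the clusters are worth.

Designing the eligibility section of a trial protocol means choosing dozens
of inclusion/exclusion rules under competing pressures (recruitment,
homogeneity, safety). Across a registry these rules are massively
repetitive: a limited set of semantic archetypes recurs with paraphrase
variation, and which archetypes a protocol uses tracks its phase, condition
and intervention. `ecclust` is for informaticians who want to exploit that
structure: it tokenizes registry eligibility sections into individual rules,
embeds and clusters them, and quantifies how much protocol-level information
the clusters retain.

## Method in brief

- **Tokenization.** Registry exports (CSV/JSON) are filtered to
  interventional, completed/terminated, phase 1–4 trials started 2000-01-01
  to 2024-06-01; eligibility sections are split into tagged rules by a
  versioned header/bullet dialect.
- **Clustering.** Criterion embeddings (pluggable encoder; deterministic
  hashing embedder by default) are reduced to 2-D with t-SNE and clustered
  with two-stage HDBSCAN: primary clusters large enough are re-clustered,
  and a sub-split is kept only when it converges. Hyperparameters θ maximize

  ```
  O(C | θ) = silhouette(assigned points) + N_assigned / N_total  ∈ [−1, 2]
  ```

  via seeded search (TPE when optuna is present). Medoids and prevalences
  are computed in the same 2-D space.
- **Experiment 1 — alignment.** Criteria are duplicated over their trial's
  phase × intervention × condition label combinations at three MeSH
  granularities; cluster/label agreement is adjusted mutual information
  (AMI), normalized by the ceiling attainable when labels live at the trial
  level. A 50-cluster × 20-criterion review sheet supports human coherence
  audits.
- **Experiment 2 — classification.** Trial outcomes (duration, enrollment,
  operational rate, phase) are predicted from cluster-count features vs raw
  mean embeddings vs random vectors with penalized linear classifiers on a
  70/10/20 split; paired t-tests with Bonferroni correction compare the
  modes.
- **Experiment 3 — generation.** For held-out trials, criteria are retrieved
  from similar trials (MeSH-level relaxation ladder), clustered, and a draft
  section is sampled from cluster medoids proportionally to prevalence;
  drafts are scored with self-implemented ROUGE-1/2/L and a greedy
  token-embedding match against the real section and a random-reference
  baseline.

A synthetic-registry generator with planted template structure and outcome
signal makes the whole pipeline testable end to end without external data.

## Worked example

```python
import ecclust

trials, truth = ecclust.generate_registry(n_trials=120, n_templates=8, seed=42)
criteria = ecclust.ingest.criteria_from_trials(trials)
X = ecclust.synthetic_embed(criteria, truth, separation=30, dim=48, seed=42)

solution = ecclust.cluster_pipeline(
    X, ecclust.ClusterParams(min_cluster_size=25, min_samples=10, perplexity=30),
    seed=42,
)
print(f"criteria: {len(criteria)}  clusters: {solution.n_clusters}  "
      f"assigned: {solution.n_assigned / len(criteria):.3f}  "
      f"objective: {solution.objective_value:.3f}")

planted = truth.template_labels(criteria)
fg = planted >= 0  # idiosyncratic background criteria have no template
ami = ecclust.adjusted_mutual_information(solution.assignments[fg], planted[fg])
print(f"AMI vs planted templates: {ami:.3f}")

labeled = ecclust.build_composite_labels(criteria, granularity=(2, 1))
result = ecclust.normalized_alignment(solution, labeled)
print(f"label AMI: {result['ami']:.4f}  ceiling: {result['ceiling_ami']:.4f}")
```

Output:

```
criteria: 3141  clusters: 9  assigned: 0.891  objective: 1.616
AMI vs planted templates: 0.999
label AMI: 0.1267  ceiling: 0.0136
```

The 120 synthetic trials yield 3 141 criteria; the pipeline recovers the 8
planted templates (plus one cluster of background criteria) almost exactly
(AMI 0.999 against the planted labels), assigning 89 % of criteria with a
composite objective of 1.616 out of 2. The cluster ids carry genuine
protocol information: their AMI with coarse phase–intervention–condition
labels (0.127) sits far above chance (AMI ≈ 0), and above the
one-criterion-per-trial ceiling (0.014) — on synthetic data templates repeat
within trials, so clusters can beat that reference point (see
`docs/methods.md`).

The same stages are scriptable from a shell:

```bash
ecclust synth   --output out --seed 42
ecclust ingest  --output out --seed 42
ecclust cluster --output out --seed 42
ecclust align   --output out --seed 42   # then: classify, generate, report
```

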