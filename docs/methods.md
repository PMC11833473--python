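# Methods

## Problem and pipeline

Eligibility sections of clinical-trial protocols are free text, but the
individual rules they contain are highly repetitive across trials: a modest
number of semantic archetypes ("age ≥ 18", "signed informed consent", "no
prior chemotherapy within N weeks", ...) recur with paraphrase-level
variation, and which archetypes a protocol uses depends on the trial's phase,
condition and intervention. `ecclust` groups tokenized criteria into such
archetype clusters and quantifies how much protocol-level information the
clusters retain, via three evaluations: label alignment, trial-level outcome
classification, and draft-section generation.

The pipeline runs in this order:

1. **Ingest.** Registry exports (CSV or JSON) are parsed into trial records;
   trials are kept when they are interventional, completed or terminated,
   carry at least one of phases 1–4, and started between 2000-01-01 and
   2024-06-01 (both ends inclusive). Eligibility sections are split into
   individual rules by a versioned header/bullet dialect (see below).
2. **Embedding.** Each criterion text becomes a fixed-length vector through a
   pluggable token encoder with `cls` (first position) or `mean_non_pad`
   (mean over unmasked tokens) pooling. The default desk-scale encoder is a
   deterministic hashing embedder: every word maps to a stable pseudo-random
   unit vector, texts are L2-normalized bags of word vectors. Transformer
   presets exist behind the same protocol but are never required.
3. **Clustering.** Embeddings are reduced to 2-D with t-SNE and clustered
   with HDBSCAN (noise allowed). Every primary cluster with at least twice
   the minimum cluster size is re-clustered by a second HDBSCAN restricted to
   its members; the split is kept only when the sub-run converges. Cluster
   hyperparameters maximize the composite objective

       O(C | θ) = silhouette(assigned points) + N_assigned / N_total ∈ [−1, 2].

4. **Evaluation.** Experiments on alignment, classification and generation,
   each reading only the clustering solution, the embeddings and the registry.

## Tokenizer dialect

Registry eligibility text has no canonical grammar, so the dialect is fixed
in code and versioned: case-insensitive `inclusion criteria` / `exclusion
criteria` headers (optional `key` prefix, optional trailing punctuation) set
the kind of subsequent rules; bullets are `-`, `*`, common bullet glyphs and
`1.` / `1)` / `(1)` numbering; non-bullet lines continue the open bullet
(wrapped lines merge); bullet-free prose splits at sentence boundaries
(terminal punctuation followed by an upper-case letter or digit); rules
shorter than 3 characters are dropped as tokenizer noise; rules outside any
header get kind `unknown` and are retained downstream. Dates parse as
ISO-8601 with month-precision values resolving to day 1.

MeSH tree numbers are dot-separated codes; *level n* means the first *n*
components, the root counting as level 1 (`C01` = level 1, `C01.925` =
level 2). Truncation is idempotent.

## Clustering details

- Distances for clustering, silhouette and medoids all live in the reduced
  2-D plane — the space the clusterer actually saw.
- The silhouette term is computed over assigned points only. When assigned
  points span fewer than two clusters (or are all singletons) it takes the
  sentinel value −1, so an all-noise clustering scores exactly −1.
- Secondary "did not converge", left open by the underlying method, is
  defined as any of: the sub-run raises; it yields fewer than two
  sub-clusters; it marks more than 50 % of the members noise. In those cases
  the primary cluster is kept intact; otherwise sub-noise becomes global
  noise and sub-clusters are renumbered globally. Primary noise is never
  revisited, and a secondary split can never merge criteria from different
  primary clusters.
- Medoid of a cluster = the member minimizing the summed Euclidean distance
  to all members, ties to the lowest index. Prevalence = fraction of
  *assigned* criteria in the cluster (noise excluded from both sides).
- Hyperparameter search: default ranges min_cluster_size 10–500, min_samples
  5–100, cluster-selection epsilon 0–1, perplexity 10–100 (all overridable).
  Candidates come from optuna's TPE sampler when optuna is importable and
  from seeded random search otherwise; a fully discrete space small enough to
  enumerate is searched exhaustively. The 2-D reduction is cached per
  distinct perplexity. All seeds are fixed and logged; both t-SNE and HDBSCAN
  carry intrinsic randomness, so stability is asserted at fixed seed only.

## Experiment 1 — alignment with protocol labels

Each criterion inherits its trial's phases, condition codes and intervention
codes and is duplicated once per unique `phase − intervention − condition`
combination, with condition/intervention codes truncated to one of three
granularity pairs: (4, 3), (3, 2), (2, 1) (condition level, intervention
level). Agreement between duplicated cluster ids and composite labels is
adjusted mutual information with the arithmetic-mean normalizer,
AMI = (MI − E[MI]) / (mean(H(u), H(v)) − E[MI]), with the hypergeometric
permutation-model expectation. Unassigned criteria are pooled as one shared
noise category by default (exclusion is a flag).

Labels live at the trial level while clusters live at the criterion level,
so AMI = 1 is unreachable. The reported score is normalized by a *ceiling*:
the AMI of an idealized assignment in which, per trial, one designated
criterion (first by index) joins the cluster of its own composite label and
every other criterion is a singleton. For multi-label trials each duplicated
row of the designated criterion joins its own row-label's cluster — the
per-duplicate reading of "assigned to the correct cluster" — which keeps the
ceiling strictly positive where the shared-id reading can dip below zero
under chance correction.

Two caveats the tests make explicit. First, when nearly every trial carries
a unique label (tiny corpora at fine granularity) the ceiling itself is
chance-level and normalization is undefined; the orchestration then reports
raw AMI with a degenerate-ceiling flag rather than a ratio. Second, the
ceiling's premise — every criterion of a trial in a different cluster — is a
property of real corpora with hundreds of clusters. The synthetic generator
plants a handful of templates reused many times within a trial, so planted
clusters can legitimately align better than the ceiling and the normalized
score can exceed 1 there; the quantity remains a consistent reference point,
not an upper bound, on synthetic data.

The expert-review export selects the 50 largest clusters (ties to the lower
id) and, within each, the 20 criteria nearest the medoid (ties to the lower
index), yielding a 1000-row sheet with a blank verdict column restricted to
`correct` / `not correct` / `unclear`. Scoring is `#correct / #rows`, with
`unclear` counting in the denominator. The verdicts themselves require a
human; the package only exports and scores the sheet.

## Experiment 2 — outcome classification

Trials are split 70 / 10 / 20 into train / validation / test at the trial
level (rounded fractions, remainder to train). Three feature modes share
identical splits: per-cluster criterion counts (length = number of clusters,
noise ignored), the mean of the trial's criterion embeddings (length = D),
and seeded uniform-random vectors (chance floor). Continuous outcomes —
study duration, enrollment count, and operational rate defined as
enrollment / duration — are median-split into binary labels, ties at the
median assigned alternately in trial-id order to keep the classes as even as
the ties allow; the phase task is multi-class over the trial's lowest listed
phase. Classifiers are penalized logistic regressions (L1 / L2 /
elastic-net, standing in for Lasso / Ridge / Elastic Net in a classification
setting), tuned by validation macro F1 over a seeded search with the penalty
family part of the search space, refit on train + validation, and scored by
test macro F1. Feature modes are compared with two-sided paired t-tests at
α = 0.05 and a Bonferroni threshold of α divided by the number of
comparisons.

## Experiment 3 — section generation

For a target trial, criteria are retrieved from all other trials sharing at
least one phase, one condition and one intervention, matched first at
granularity (4, 3); if fewer than the relaxation threshold of criteria are
found the ladder relaxes to (3, 2), then (2, 1); the broadest rung is
accepted when it reaches the acceptance floor, otherwise the target is
rejected and the sampler moves on. The API defaults are the full-corpus
thresholds (5 000 relax / 2 500 accept); desk-scale runs pass scaled
thresholds (400 / 120 in the acceptance script) because a few-thousand-
criterion synthetic registry cannot yield 5 000 retrieved criteria per
target after excluding the target itself.

The retrieved criteria are clustered per target, and a draft section is
assembled from cluster medoids: candidates ordered by descending prevalence
(ties to the lower cluster id), repeated passes over not-yet-included
candidates, each included with probability prevalence / max-prevalence (so
the most prevalent cluster always enters on the first pass), until the
per-condition target length (21 / 30 / 21 / 24 criteria for roots C01 / C04 /
C14 / C20, empirical registry mean otherwise) is reached or every cluster
has contributed once.

Drafts are scored with self-implemented metrics: ROUGE-1/2 (clipped n-gram
overlap) and ROUGE-L (document-level longest common subsequence over
lowercased alphanumeric tokens), and a BERTScore-style greedy cosine match
over token embeddings (harmonic-mean F, no idf weighting, no baseline
rescaling, pluggable token encoder — the hashing encoder in all tests). Each
draft is also scored against a seeded random reference section (the
lexical-similarity floor), and per-target silhouette is correlated with the
draft's score (Pearson r with two-sided p). The external generative-model
comparator is an abstract interface with a shuffle-echo stub for smoke tests
only; its scores carry no scientific meaning.

## Synthetic registry — what it emulates and what it does not

The generator is the package's test bed and defines its study conditions:

- **Templates.** `n_templates` latent criterion archetypes (default 20),
  each with a base text over a clinical-flavoured word pool, an
  inclusion/exclusion kind, and an affinity profile over
  (phase, condition root, intervention root) built as an outer product of
  Dirichlet weights. A trial samples its 10–40 criteria from templates
  weighted by its own context, then renders them as a bulleted
  inclusion/exclusion section that round-trips exactly through the
  tokenizer.
- **Paraphrase noise.** Word-level perturbations (synonym-like suffixing,
  drops, adjacent swaps) at rate `lexical_noise` (default 0.1) — the
  variation clusters are supposed to absorb. Each template additionally has
  3 sub-variants marked by a variant token.
- **Background criteria.** With probability `background_fraction` (default
  0.2) a criterion is an idiosyncratic one-off rule with a unique token and
  a latent severity scalar. These emulate the unassigned gray points real
  density clustering produces: they form no cluster, but their content
  carries trial-level information.
- **Outcomes.** log-duration and log-enrollment are linear in the trial's
  realized template mixture (coefficient `effect_size`, default 1), its
  variant mixture (half weight), and the mean background severity (equal
  weight, opposite sign for enrollment), plus Gaussian noise (σ = 0.35);
  enrollment is Poisson-distributed around its log-linear mean. Duration is
  thus lognormal, enrollment count-valued, and operational rate =
  enrollment / duration inherits both. The split between archetype-level
  and residual signal is what gives the three feature modes their expected
  ordering: cluster counts capture the template mixture but not the variant
  or background layers, which only the raw embeddings retain.
- **Embedding geometry.** The template-aware synthetic embedder places
  template centers uniformly on a sphere of radius `separation` (default
  30), variant offsets at radius separation/15 (below the unit-noise scale,
  so clustering sees templates, not variants), background criteria in a
  diffuse central cloud (spread 5) with severity encoded linearly along one
  fixed direction at scale separation/6, and unit Gaussian noise on every
  vector. `separation = 0` collapses everything into a single structureless
  cloud.
- **Seeding.** One global seed fans out to per-component generators through
  `numpy.random.SeedSequence.spawn`, so every artifact is reproducible from
  (config, seed).

The generator does **not** emulate: realistic clinical language or MeSH
semantics (codes are synthetic tree numbers), calibration to real registry
marginals, inter-trial correlation beyond the context-affinity coupling, or
free-text idiosyncrasies (tables, sub-headings, cross-references) beyond the
declared tokenizer dialect. Passing tests therefore demonstrate correctness
of the machinery and recoverability of planted structure under these
conditions — not performance on real registry text.

## Problem sizes and numerical choices

Desk-scale runs use registries of 100–300 trials (≈2 500–7 500 criteria):
planted-recovery runs 200 trials with 5 templates at separation 30 and a
20-trial hyperparameter search on cached 2-D coordinates; feature-mode
comparisons use 300 trials, three continuous tasks, three repeated splits
and a 12-point aggregate; generation uses 100 trials, up to three evaluation
targets per condition root and scaled retrieval thresholds, with the
per-target density floor and perplexity scaled to the retrieved-set size.
Embedding dimensions are 48–64. These sizes were chosen as the smallest at
which the planted effects are comfortably detectable.

Other numerical conventions: silhouette sentinel −1 on degenerate
partitions; all tie-breaks deterministic (lowest index / lowest cluster id /
trial-id order); binarization errors out when all outcome values are
identical; paired t-tests return an explicit zero-variance flag instead of a
statistic; texts are truncated at the encoder's max length with a logged
warning.

## Known limitations

- Normalized alignment is only meaningful when the label structure is rich
  relative to the corpus (see the ceiling caveats above).
- The expert-coherence accuracy cannot be reproduced without a human; only
  the sheet export and its scoring rule are implemented.
- The information-retention ratio between cluster counts and raw embeddings
  hovers near 100 % at desk scale and its sign can flip between seeds; the
  ordering against the random floor is the robust signal.
- t-SNE/HDBSCAN determinism holds per seed, not across library versions.
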