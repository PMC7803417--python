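# Methods

## The model

`hetpath` predicts which of a fixed vocabulary of metabolic pathway types
(11 KEGG top-level metabolism categories in the real task) a chemical or
enzyme belongs to, using nothing but the weighted interaction neighborhood
of the molecule in a heterogeneous network. The premise is that molecules
acting in the same pathway type interact — directly or through short
weighted paths — more than unrelated molecules do, so a node's diffusion
profile over the network is an informative, uniform feature representation
for both node kinds at once.

The pipeline has three stages.

**Network assembly.** Three links files (chemical–chemical,
chemical–protein, protein–protein; tab-separated `node1 node2 score` rows
with integer confidence scores in 1–999) are parsed, the scores are mapped
to edge weights by dividing by 1000 (so weights lie in (0, 1)), the three
layers are merged into one undirected network over the union of a chemical
roster and an enzyme roster, and degree-zero nodes are discarded. Duplicate
rows for the same unordered pair keep the maximum weight — deterministic,
order independent, and retaining the strongest evidence. Node ids are
opaque strings; kind comes only from the rosters. All matrix views use a
canonical order: chemicals sorted lexicographically, then enzymes.

**Embedding.** For every node i a random walk with restart is run: the
walker steps to a neighbor with probability proportional to edge weight and
returns to its seed with probability r each step. The fixed point of
p ← (1−r)·P·p + r·e_i (P the column-stochastic transition matrix) is node
i's diffusion state V_i. The n×n matrix V of all diffusion states is then
factorized into d-dimensional node features X_i and context vectors W_k by
fitting the softmax model V~_ik = exp(X_i·W_k)/Σ_k′ exp(X_i·W_k′) to the
columns of V, minimizing the mean KL divergence (1/n)·Σ_i D_KL(V_i ‖ V~_i).
X is the downstream feature representation.

**Classification.** RAKEL (random k-labelsets): draw M random size-k
subsets of the label vocabulary; for each subset fit one label-powerset
(LP) classifier whose multiclass target is the sample's label set
restricted to the subset (each observed combination is one class). At
prediction time each member's predicted combination expands to binary votes
on its subset's labels; a label is assigned when the average vote over the
members covering it strictly exceeds 0.5 (a tie is a negative decision —
the vote must be *larger than* the threshold). Binary relevance (one
independent binary classifier per label) is exactly the k = 1 case with a
full singleton cover, and the implementation is tested to be
prediction-identical to it. Base learners: SVM with polynomial or RBF
kernel (SMO-style solver, one-vs-one multiclass voting, via scikit-learn's
SVC) or a random forest; a 1-nearest-neighbour learner backs the
brute-force equivalence tests.

**Evaluation.** Four measures over true sets L_i and predictions L_i′:
per-sample Jaccard accuracy, exact match, hamming loss |L_i Δ L_i′|/m, and
the integrated score accuracy × exact match × (1 − hamming loss), the
single model-selection criterion. Metrics are pooled over the out-of-fold
predictions of a complete ten-fold pass (each sample tested exactly once),
never averaged per fold, because the measures are defined over all n
samples. Fold assignment is a plain seeded random partition (fold sizes
differing by at most one); multilabel stratification is deliberately not
applied by default since nothing in the task requires it, and the repeated
(e.g. 100×) cross-validation reports the spread instead.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| restart probability r | 0.5 | per-step probability of returning to the seed; the common convention of the reference diffusion-embedding implementation; larger r keeps diffusion more local |
| RWR tolerance / cap | 1e−8 L1 / 1000 iter | geometric convergence at rate (1−r); warns and flags if the cap is hit |
| embedding dimension d | 250 (grid 50–300 by 50) | the grid's optimum on the real task; toy fixtures use d ≤ n as required |
| k, M (RAKEL) | 11, 5 | labelset size and ensemble size; k = m makes every member the full LP problem, k = 1 with full cover is binary relevance |
| vote threshold | 0.5 | strict inequality: exact ties are negative decisions |
| SVM C, exponent E, RBF γ | 2, 1, 0.01 | grid values {1,2,3} × {1,2,3} × {0.01,0.02,0.03} |
| random-forest trees | 100 | grid 10–100 by 10 |
| feature scaling | off | diffusion-derived features share a scale; a standardization flag exists |

## Numerical choices

* **SVD route (default embedding).** Rank-d truncated SVD of log V with
  X = V_d√S_d, W = U_d√S_d. Softmax re-normalization absorbs any
  per-column additive shift of log V, so at d = n the model reconstructs V
  exactly; this deterministic factorization is the default. A pseudo-count
  ε is added inside the log **only when V contains zeros** (possible on
  disconnected networks; a connected network's RWR distributions are
  strictly positive). ε = 1/n, the scale of a uniform diffusion entry.
  Smoothing unconditionally would bias every reconstruction toward
  (V+ε)/(1+nε), which is why it is conditional.
* **Gradient route.** Full-batch gradient descent on the KL objective from
  a seeded uniform(−0.01, 0.01) init; step size starts at 0.1, grows 1.05×
  on every accepted step and halves when the objective would increase (the
  step is rejected), so the recorded trace is non-increasing and the whole
  path is a pure function of the seed. A non-finite objective raises,
  naming the iteration. On a full-rank toy instance it descends to the SVD
  optimum within 1e−3 in ≤ 2000 iterations.
* **Labelset draws.** Uniform without replacement among the C(m, k)
  distinct k-subsets when C(m, k) ≥ M (so the draw exhausts them when
  C(m, k) ≤ M), with replacement otherwise; when k·M ≥ m the draw is
  retried until every label is covered. Uncovered-but-present labels are
  warned about at fit time and can never be predicted.
* **Degenerate members.** An LP member whose training restriction has a
  single class becomes a constant predictor (with a warning) rather than an
  error; likewise a constant label column in binary relevance.
* **Ranking ties** in grid search break by accuracy, then lexicographic
  configuration — documented, deterministic.

## The synthetic benchmark

Real inputs require large third-party downloads, so the test bed is a
seeded generator emulating the data's structure: two node kinds, each node
carrying 1–2 of m = 5 labels (count uniform; the cap of 2 mirrors the real
data's ≈1.25–1.5 labels per node), and a label-conditioned planted
partition — pairs sharing a label are connected with probability p_intra,
others with p_inter, *identically within and across kinds*, so cross-kind
edges carry label signal and the combined-versus-separated comparisons are
meaningful. Shared-label edges draw weights from U(0.5, 0.999),
non-shared from U(0.001, 0.5), quantized to 3 decimals to round-trip the
integer score dialect exactly. Presets: easy (120 chemicals + 60 enzymes,
p_intra = 0.25, p_inter = 0.02), medium (0.15/0.04), hard (0.08/0.05).
Isolated nodes are rewired to one shared-label partner so pruning removes
nothing.

What the generator does **not** emulate: the real data's heavy-tailed
degree distribution, its label co-occurrence structure, evidence-channel
correlations in the confidence scores, and its scale (thousands of nodes).
Passing tests therefore demonstrate correctness of the machinery and
recoverability of a planted neighborhood-label signal at 180-node scale,
not the published real-data performance levels.

Benchmark scale in the test suite is kept small on purpose — embedding
dimension 32 at 180 nodes, ten-fold cross-validation, ten generator seeds
for the permutation-direction experiment — which completes the whole suite
in well under a minute while still exercising every stage end-to-end from
exported flat files.

## Known limitations

* RWR uses dense power iteration / dense linear algebra; adequate to a few
  thousand nodes, not engineered for very large networks.
* LP members can only predict label combinations observed in their
  training restriction; unseen combinations are unreachable by a single
  member (inherent to label powerset).
* With k = m every ensemble member solves the identical LP problem, so
  deterministic base learners make all M members identical; a per-member
  seed is possible via refitting with different seeds but members default
  to deterministic.
* The end-to-end exact-match level on the easy benchmark depends on the
  label/graph draw: the linear-kernel SVM typically reaches ≈0.62–0.72
  exact match across generator seeds, with occasional draws a few points
  lower, whereas tree ensembles on the same features are markedly stronger;
  the benchmark keeps the linear SVM because that is the configuration
  under study.
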