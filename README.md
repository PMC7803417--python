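# hetpath

Multilabel prediction of **metabolic pathway types for chemicals and
enzymes** from a weighted heterogeneous interaction network.

Chemicals and enzymes are the two working parts of every metabolic
pathway, and many molecules act in more than one of the 11 KEGG top-level
metabolism categories — so assigning pathway types is a multilabel
problem. `hetpath` solves it with network information alone: both node
kinds are placed in one network built from chemical–chemical,
chemical–protein and protein–protein interaction evidence (STITCH/STRING
links-file dialect, integer confidence scores 1–999 rescaled to edge
weights in (0, 1)), so that each kind's neighborhood informs the other's
predictions.

The method, in the field's standard notation:

1. **Diffusion.** For each node *v_i*, a random walk with restart
   (restart probability *r* = 0.5) yields the stationary distribution
   *V_i* of *p ← (1−r)·P·p + r·e_i*, with *P* the column-stochastic
   transition matrix of the weighted network.
2. **Embedding.** The diffusion matrix is compressed into *d*-dimensional
   feature vectors *X_i* and context vectors *W_k* minimizing
   (1/n)·Σ_i D_KL(V_i ‖ Ṽ_i), where Ṽ_ik = exp(X_iᵀW_k)/Σ_k′ exp(X_iᵀW_k′)
   — either exactly in closed form (truncated SVD of log V, the default)
   or by seeded gradient descent on the KL objective itself.
3. **Classification.** RAKEL: an ensemble of *M* label-powerset
   classifiers on random size-*k* labelsets over a pluggable base learner
   (polynomial/RBF-kernel SVM or random forest); labels are assigned by
   strict-majority average vote (> 0.5) over covering members. Binary
   relevance is the *k* = 1 special case.
4. **Evaluation.** Per-sample Jaccard accuracy, exact match, hamming loss
   and the integrated score *accuracy × exact match × (1 − hamming loss)*,
   pooled over the out-of-fold predictions of (optionally repeated)
   ten-fold cross-validation.

A seeded synthetic-benchmark module generates heterogeneous networks with
label-correlated planted connectivity in the exact input file dialects, so
the whole pipeline is testable without any downloads.

## Worked example

```sh
hetpath simulate --difficulty easy --seed 7 --out sim
hetpath build-net --cci sim/cci.tsv --cpi sim/cpi.tsv --ppi sim/ppi.tsv \
    --chemicals sim/chemicals.txt --enzymes sim/enzymes.txt --out net
hetpath embed --net net --dim 32 --seed 1 --out emb.tsv
hetpath cv --features emb.tsv --labels sim/labels.tsv \
    --k 5 --m-members 5 --base svm-poly --c 2 --e 1 --seed 1 --out cvout
```

prints

```
network: 180 nodes (120 chemicals, 60 enzymes), 1875 edges (cci=821, cpi=859, ppi=195); removed 0 isolated nodes
embedded 180 nodes at d=32 (svd) -> emb.tsv
                    min    max   mean  std
accuracy          0.774  0.774  0.774  NaN
exact_match       0.567  0.567  0.567  NaN
hamming_loss      0.098  0.098  0.098  NaN
integrated_score  0.396  0.396  0.396  NaN
```

Reading the numbers: on this 180-node synthetic benchmark the classifier's
predicted pathway-type sets overlap the true sets by 77.4% on average
(Jaccard), are exactly right for 56.7% of nodes, and disagree on 9.8% of
the individual label decisions; the integrated score multiplies the three
(0.774 × 0.567 × 0.902 ≈ 0.396). A single repeat leaves the spread columns
empty; `--repeats 100` fills them. Shuffling which node receives which
feature vector (`hetpath permute-test --mode all …`) collapses the
integrated score to ≈0.01, confirming the score is carried by the
feature–node correspondence, not by label frequencies. The same stages are
available as library functions (`hetpath.make_benchmark`,
`hetpath.diffusion_states`, `hetpath.mashup_embed`,
`hetpath.RakelStrategy`, `hetpath.cross_validate`), and `hetpath run
--config run.yaml` drives the whole pipeline with a manifest for exact
replay.

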