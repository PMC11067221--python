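# goltr

Multi-view, multi-label protein function prediction with **latent tensor
reconstruction (LTR)**, together with the Gene Ontology (GO) label-processing
pipeline, protein-centric CAFA evaluation metrics, frequency/homology
baselines, and a synthetic-data generator so the whole method runs at desk
scale with no downloads.

## The problem

Assigning GO terms to proteins is a hierarchical multi-label task: terms form
an is-a DAG across three subontologies (molecular function, cellular
component, biological process), and annotating a term implies annotating all
of its ancestors (the *true-path rule*). Modern predictors combine several
feature modalities per protein — sequence-embedding vectors from a protein
language model, binary InterPro domain fingerprints, PPI-network profiles —
and the question is how to model their *joint* interactions rather than
concatenating them.

## The model

Each protein is described by `n_d` views `x⁽¹⁾ … x⁽ⁿᵈ⁾`. LTR fits a degree-
`n_d` polynomial over the cross-view feature products whose weight tensor is
kept in CP (rank-one sum) form,

```
T = Σ_t λ_t  p_t⁽¹⁾ ⊗ … ⊗ p_t⁽ⁿᵈ⁾ ,      t = 1 … n_t,
```

so each polynomial coefficient is `w_{j₁…j_d} = Σ_t λ_t p_{j₁,t} ⋯ p_{j_d,t}`.
A second-level factorization `P⁽ᵈ⁾ = V⁽ᵈ⁾ U⁽ᵈ⁾ᵀ D⁽ᵈ⁾` (unit-norm rows of
`V⁽ᵈ⁾` and `U⁽ᵈ⁾`, diagonal per-feature scales `D⁽ᵈ⁾`) decouples per-feature
weights from the latent rank, multi-label output comes from a projection `Q`
with unit-norm columns, and ReLU activations can be inserted inside the
per-view maps:

```
π(x) = Q ( λ ⊙ Π_d  B( V⁽ᵈ⁾ A( U⁽ᵈ⁾ᵀ D⁽ᵈ⁾ x⁽ᵈ⁾ ) ) ).
```

Training minimises `(1/2mn_y)‖Y − Ŷ‖²_F + (C_λ/2n_t)‖λ‖²` by projected
mini-batch gradient descent (a gradient step, then renormalisation onto the
unit-norm constraints). Predicted scores are clipped to [0, 1] and
max-propagated up the DAG so every parent scores at least as high as its
children.

Evaluation follows the CAFA protein-centric protocol: `F_max` (maximum over
thresholds of the harmonic mean of precision and recall), its
information-content-weighted variant `WF_max`, the minimum semantic distance
`S_min = min_τ √(ru² + mi²)` in bits, AUPRC, micro-AUROC and coverage, with
per-term conditional information content `I(v) = −log₂ P(v | Pa(v))`.

## Worked example

Train the tensor model and the Naive (training-frequency) baseline on a
synthetic bundle — a toy ontology of 30 non-root terms, 1000 proteins with
two 20-dimensional views, labels generated by a planted rank-3 model, and a
cluster-grouped train/test split:

```python
from goltr.experiments import synthetic_benchmark
for k, v in synthetic_benchmark(seed=7).items():
    print(k, round(v, 4) if isinstance(v, float) else v)
```

```
ltr_fmax 0.7078
naive_fmax 0.5659
ltr_smin 3.5112
naive_smin 5.9151
ltr_auprc 0.7314
naive_auprc 0.5228
ltr_coverage 0.8718
n_test 117
n_labels 30
max_constraint_residual 0.0
```

The tensor model recovers most of the planted structure on the held-out
cluster split (`F_max` 0.71 vs 0.57 for Naive; `S_min` 3.5 bits vs 5.9 —
lower is better), and the norm constraints hold exactly after every epoch.

The same pipeline is scriptable from the shell:

```
goltr simulate --seed 7 --m 1000 --n-y 30 --out bundle/
goltr prepare  --obo bundle/ontology.obo --annotations bundle/annotations.tsv \
               --view bundle/view0.tsv --view bundle/view1.tsv \
               --clusters bundle/clusters.tsv --min-count 3 --out prep/
goltr train    --prepared prep/ --fold 0 --n-t 8 --out model.npz
goltr predict  --model model.npz --prepared prep/ --fold 0 --out pred.tsv
goltr evaluate --predictions pred.tsv --prepared prep/ --fold 0
goltr baseline --kind naive --prepared prep/ --fold 0 --out naive.tsv
```

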