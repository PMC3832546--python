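# isodiff

Detection of differential expression and differential splicing of genes
from multi-condition RNA-Seq data, at the level of full-length transcript
isoforms.

`isodiff` answers, for each annotated gene observed in K conditions, which
of three nested situations the data support:

* **model 0** — no differential expression: all conditions share one
  isoform abundance vector θ̃;
* **model 1** — differential expression *without* differential splicing:
  condition k has abundances θ_k = τ_k·θ̃, a common splicing profile scaled
  by a per-condition fold τ_k (identified by Σ_k τ_k = K);
* **model 2** — differential splicing: every condition has its own free
  abundance vector θ_k.

Read evidence is modeled with a linear Poisson model: the count of reads
of type j in condition k is Poisson with mean Σ_i a_kij·θ_ki, where the
sampling rate a_kij is constant over all read positions of an isoform
(uniform single-end sampling) and read types sharing an
isoform-compatibility pattern are collapsed into categories without
changing the maximum-likelihood problem. Each model's MLE is computed by
EM, and model selection uses a two-round hierarchical likelihood ratio
test (hLRT): model 0 vs 1 (χ², K−1 df) and model 0 vs 2 (χ², (K−1)·I df)
each at level α/2; if both reject, model 1 vs 2 (χ², (K−1)·(I−1) df) at
level α. Genes with fewer than 5 reads in every condition are filtered
out. Two-condition differential-splicing hits are ranked by

    T = ½ · ‖ θ̂₁/‖θ̂₁‖₁ − θ̂₂/‖θ̂₂‖₁ ‖₁  ∈ [0, 1],

which is 0 exactly for model-0/1 genes. A junction-count utility
estimates cassette-exon inclusion levels ψ = (UJC+DJC)/((UJC+DJC)+2·SJC)
and Δψ between conditions.

The intended users are statistical-genomics researchers comparing
transcript usage between conditions (e.g. a splicing-factor perturbation
vs control, or disease vs normal tissue) from mapped read counts and a
transcript annotation.

## Worked example

Simulate one gene under each generating model (the built-in cassette-exon
gene: a 60 bp skipping exon between shared 1200 bp and 600 bp exons, two
isoforms; depths 50M and 55M reads; total gene abundance G = 10
RPKM-like units) and classify:

```python
import numpy as np
from isodiff import (default_sim_gene, theta_from_scenario, simulate_counts,
                     run_all_genes)
from isodiff.io import results_to_frame

rng = np.random.default_rng(0)
gene = default_sim_gene()
dataset = []
for gid, model in [("null_gene", 0), ("fold_gene", 1), ("splice_gene", 2)]:
    theta = theta_from_scenario(model, G=10.0)
    dataset.append((gid, simulate_counts(theta, gene, (50e6, 55e6), 50, rng)))
res = run_all_genes(dataset, alpha=0.05)
print(results_to_frame(res)[["gene_id", "selected_model", "p01", "p02", "p12", "T"]])
```

prints

```
    gene_id  selected_model      p01       p02       p12      T
  null_gene               0   0.5845   0.04023       NaN      0
  fold_gene               1 2.99e-50 4.916e-49    0.6072      0
splice_gene               2  0.01944 1.393e-10 2.636e-10 0.6264
```

The null gene is kept as model 0 (neither first-round test rejects at
α/2 = 0.025), the proportional fold change is called model 1 (first-round
rejections but a non-significant second round, p12 = 0.61), and the
isoform switch is called model 2 with T = 0.63 — a large splicing shift.
Its fitted abundance matrix recovers the generating θ = (8,2)/(2,8):

```
[[7.487 2.994]
 [0.845 8.762]]
```

with per-parameter 95% Wald confidence intervals available from
`confidence_intervals`.

The same pipeline runs from the shell: `isodiff run` (annotation +
category-count TSV → per-gene result table), `isodiff simulate`
(type-I-error/power study), and `isodiff psi` (junction-count ψ/Δψ).

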