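# ssipred

Semi-supervised prediction of protein–protein interface residues from
evolutionary-conservation features.

## The problem

Most residues on protein surfaces cannot be labeled as interface or
non-interface because only a small fraction of protein–protein interactions
has been characterised experimentally.  Supervised classifiers trained on
the few labeled residues generalise poorly.  `ssipred` implements the
semi-supervised alternative: exploit the large pool of *unlabeled* surface
residues together with the labeled ones, under the cluster assumption that
a good decision boundary passes through low-density regions of feature
space.

The package is aimed at structural bioinformaticians who have, per chain:
a PDB structure (Cα coordinates), an HSSP-style conservation profile
(20-amino-acid frequencies, entropy, relative entropy, conservation
weight), and Rate4Site/ConSurf evolutionary rates.

## Definitions and features

* **Surface residue** — relative solvent accessibility
  ASA / maxASA(aa) > 16% (strict; Rost–Sander maximum-ASA scale by default).
* **Interface residue** — a surface residue whose Cα lies strictly within
  1.2 nm (12 Å) of any Cα of the partner chain.
* **Features** — per residue, 24 values: the 20-dim sequence profile p,
  its Shannon entropy H(p) = −Σᵢ pᵢ log₂ pᵢ, the relative entropy
  H(p)/log₂ 20, a conservation weight, and the evolutionary rate.  Each
  target residue is concatenated with its 10 spatially closest chain
  neighbours, giving an 11 × 24 = **264-dimensional** vector.

## Learners

* `svm` — soft-margin SVM baseline (dual solved to KKT tolerance).
* `means3vm-iter` / `means3vm-mkl` — label-mean S3VM: maximise the margin
  between the two class means of the unlabeled data,

      min_{d∈Δ} min_{w,b,ρ,ξ} ½‖w‖² + c₁ Σᵢ ξᵢ − c₂ ρ

  subject to the labeled margins, the two mean-margin constraints, and the
  equilibrium constraint Σᵢ∈ᵤ sgn f(xᵢ) = r, where d ∈ Δ assigns
  u₊ = (r+u)/2 unlabeled points to the positive mean.  Solved either by
  alternating optimisation with a ranking update (`iter`) or by
  cutting-plane multiple-kernel learning over the augmented mean-instance
  kernels (`mkl`).
* `s4vm` — safe S3VM: sample many large-margin low-density separators by
  seeded local search, compress them to diverse representatives with
  k-means, then output the labeling maximising the **worst-case gain** over
  the supervised baseline — so unlabeled data can help but is prevented
  from hurting.

Defaults follow the study conditions: c₁ = 1, c₂ = 0.1, at most 50
generations, 5-fold stratified cross-validation.  Evaluation reports
accuracy, sensitivity, precision, specificity, F-measure and MCC.

## Worked example

Everything runs on synthetic fixtures — no databases needed:

```bash
ssipred simulate --n-a 80 --n-b 30 --seed 3 --out-prefix /tmp/cx
# wrote complex /tmp/cx_* (64 surface residues, 20 interface)

ssipred extract-features \
    --structure /tmp/cx_A.pdb A /tmp/cx_B.pdb B \
    --hssp A /tmp/cx_A.hssp --rate A /tmp/cx_A.rate4site \
    --out /tmp/features.tsv
# wrote 64 feature rows to /tmp/features.tsv

ssipred evaluate --features /tmp/features.tsv --method s4vm --seed 0 \
    --out-metrics /tmp/metrics.tsv --out-stability /tmp/stability.tsv
# wrote 5 fold reports to /tmp/metrics.tsv
```

`/tmp/metrics.tsv` holds one row of the six metrics per fold;
`/tmp/stability.tsv` lists, per metric, the mean across folds and the
maximum/mean absolute deviation from that mean (the fold-stability
summary).  `train-predict` writes per-residue labels, and
`annotate-structure` encodes each residue's outcome (1=TP, 2=TN, 3=FP,
4=FN) in the B-factor column of a PDB file for colouring in a molecular
viewer.

In Python:

```python
import ssipred as sp

ds, truth = sp.make_two_gaussians(sp.ToySpec(sigma=0.1, seed=3))
model, labels = sp.means3vm_iter(ds)
print((labels == truth).mean())   # 1.0 on the separated toy
```

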