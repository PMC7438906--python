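# enacp

Identification of anticancer peptides (ACPs) from amino-acid sequence with
a two-stage stacked ensemble.

Anticancer peptides are short (typically 5–50 residue) sequences with
selective toxicity toward cancer cells; screening candidates
experimentally is slow and expensive, so sequence-based classifiers are
used to rank candidates first. `enacp` is aimed at bioinformaticians
building or benchmarking such classifiers: it provides the full feature
stack, the stacked model, the evaluation protocols, and a synthetic
benchmark generator so everything is testable without external downloads.

## Model

A peptide P = R₁R₂…R_L is encoded 19 ways across four families:

* **Composition** — k-mer frequencies (20^k), distance-based residue
  pairs DR (20 + 400·dmax), and distance pairs over a reduced alphabet
  (m + m²·dmax);
* **Autocorrelation** — auto/cross/auto-cross covariance of standardized
  physicochemical index signals, e.g.
  AC(u,d) = Σᵢ (Iᵤ(Rᵢ)−Īᵤ)(Iᵤ(Rᵢ₊d)−Īᵤ)/(L−d),
  plus the physicochemical distance transformation
  PDT(u,d) = Σᵢ (Iᵤ(Rᵢ)−Iᵤ(Rᵢ₊d))²/(L−d);
* **Pseudo amino acid composition** — composition augmented with λ
  sequence-order correlation factors θⱼ and jointly normalized,
  xᵤ = fᵤ/(Σfᵢ + wΣθⱼ), in parallel (squared property differences) and
  series (property products) flavors, plus General variants over
  arbitrary index panels;
* **Profile-based** — eight encoders over per-peptide position-specific
  scoring matrices (Top-n-gram, DT, PDT-Profile, AC/CC/ACC over profile
  columns, PSSM-DT, PSSM-RT). Profiles are optional; without them the
  bank reduces to the 11 sequence encoders.

Stage 1 fits one LightGBM classifier per encoding (library defaults) and
collects the positive-class probabilities into a k-dimensional
meta-feature vector; stage 2 fits an RBF-kernel SVM on the meta-features
with (C, γ) grid-searched under stratified 5-fold accuracy. Evaluation
follows the field's conventions: Sn, Sp, Acc, MCC, rank-based AUC,
repeated stratified 5-fold cross-validation, and DeLong comparison of
correlated ROC curves. See `docs/methods.md` for every convention and
design choice.

## Worked example

```python
from enacp import (SyntheticSpec, generate_peptide_dataset,
                   train_enacp, predict_enacp)

spec = SyntheticSpec(n_pos=100, n_neg=100, effect=0.3, seed=42)
dataset, truth = generate_peptide_dataset(spec)
model = train_enacp(dataset, seed=7)
print("bank size:", model.bank.k)

probe, _ = generate_peptide_dataset(
    SyntheticSpec(n_pos=3, n_neg=3, effect=0.3, seed=99))
for r in predict_enacp(model, probe.records):
    print(f"{r.id}\t{r.score:.4f}\t{'ACP' if r.label else 'non-ACP'}")
```

prints

```
bank size: 11
pos_0000	0.6674	ACP
pos_0001	0.7110	ACP
pos_0002	0.6924	ACP
neg_0000	0.3638	non-ACP
neg_0001	0.2760	non-ACP
neg_0002	0.3033	non-ACP
```

The generator planted a δ = 0.3 lysine-enrichment shift in the positive
class; with no PSSMs supplied the bank holds the 11 sequence encoders,
and the trained stack separates held-out positives (scores above the 0.5
threshold) from negatives. The score is the logistic-squashed,
spread-normalized SVM margin: 0.5 sits exactly on the decision boundary
and larger values mean a deeper positive margin.

The same workflow is available from the shell:

```sh
enacp simulate --n-pos 100 --n-neg 100 --effect 0.3 --seed 42 --out-dir sim/
enacp train --fasta-pos sim/positives.fasta --fasta-neg sim/negatives.fasta \
            --seed 7 --out model.bin
enacp predict --model model.bin --fasta sim/positives.fasta --out preds.tsv
enacp evaluate --fasta-pos sim/positives.fasta --fasta-neg sim/negatives.fasta \
               --folds 5 --repeats 30 --seed 1 --out-prefix eval
```

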