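# thermoseq

Sequence-based discrimination of thermophilic from non-thermophilic
proteins by multi-descriptor feature fusion.

Proteins from thermophilic organisms (optimal growth temperature above
~60 °C) resist heat denaturation and are prized in enzyme engineering.
Their sequences carry a detectable compositional signature — enrichment in
charged residues (K, E, D, Q) that form salt bridges and in hydrophobic
core-packing residues (I, V), against the small neutral residues (A, T, S,
G) that dominate mesophilic proteins.  `thermoseq` turns that signature
into a classifier for researchers screening candidate proteins before
committing to wet-lab thermostability assays.

## Method

Each sequence is encoded with seven descriptors:

| descriptor | meaning | dims |
|---|---|---|
| AAC | residue frequencies f(t) = N(t)/N | 20 |
| tPseAAC | AAC + λ tier correlation factors τ_k from hydrophobicity/hydrophilicity/side-chain mass | 20+λ |
| aPseAAC | AAC + 2λ amphiphilic (H1/H2) correlation factors | 20+2λ |
| CKSAAP | k-spaced residue-pair frequencies, k = 0..5 | 2400 |
| DC | dipeptide frequencies N(g,h)/(N−1) | 400 |
| DDE | dipeptide deviation (Dc−Tm)/√Tv from codon-usage expectation | 400 |
| CTD | polar/neutral/hydrophobic composition, transitions, distribution | 21 |

Per descriptor, features are ranked by the one-way ANOVA F statistic
F(m) = s²_b(m)/s²_w(m) between the two classes and pruned by sequential
backward elimination, scoring each subset with stratified cross-validated
AUC (CTD is kept whole).  The chosen subsets are fused by concatenation and
classified with a single-hidden-layer perceptron (100 ReLU units, logistic
output, mini-batch SGD with Nesterov momentum 0.8, batch 60, learning rate
0.001); RBF-SVM (γ = 1e-4, C = 900), random forest (500 trees) and KNN
(k = 6, p = 1) baselines share the interface.  Performance is reported as
Sn, Sp, Acc, MCC and rank-based AUC.

Because no benchmark corpus ships with the package, a seeded synthetic
generator produces two sequence classes whose compositional contrast (and
optional dipeptide structure) is controlled by an effect size δ ∈ [0, 1];
see `docs/methods.md` for what it does and does not emulate.

## Worked example

```python
from thermoseq import FusionPipeline, SynthConfig, generate, stratified_split
from thermoseq.pipeline import evaluate_pipeline

dataset = generate(SynthConfig(n_pos=200, n_neg=200, effect_size=0.8, seed=101))
train, test = stratified_split(dataset, train_fraction=0.8, seed=101)

pipe = FusionPipeline(epochs=200, random_state=101)
pipe.fit(list(train), train.labels())

print(len(pipe.feature_names_))
print({k: round(v, 4) for k, v in
       evaluate_pipeline(pipe, list(test), test.labels()).as_dict().items()})
```

prints

```
402
{'Sn': 0.975, 'Sp': 1.0, 'Acc': 0.9875, 'MCC': 0.9753, 'AUC': 1.0}
```

i.e. backward selection kept 402 of the 3,664 encoded features, and on the
80 held-out sequences the fused MLP recovers the planted class signal
almost perfectly: sensitivity 0.975 (one thermophile-like sequence missed),
specificity 1.0, and an AUC of 1.0 (every positive outscores every
negative).  At effect size 0 the same pipeline's held-out AUC stays near
0.5 — the pipeline finds signal only when there is one.

The same run is available from the shell:

```sh
thermoseq run-all --config my_config.yaml --out runs/demo
thermoseq predict --model runs/demo/model --fasta new_proteins.fasta --out calls.tsv
```

Every stage (`simulate`, `encode`, `select`, `train`, `evaluate`,
`predict`) can also be run separately over its predecessor's artifact
directory; manifests carry the config hash, and identical configs give
byte-identical manifests.

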