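# Methods

## Problem and model

`thermoseq` classifies protein sequences as thermophilic (from organisms
with optimal growth temperature above ~60 °C) or non-thermophilic, from the
amino acid sequence alone.  The model is a multi-descriptor fusion pipeline:

1. **Feature extraction.** Each sequence is mapped to seven descriptor
   vectors — amino acid composition (AAC, 20), traditional and amphiphilic
   pseudo amino acid composition (tPseAAC 20+λ, aPseAAC 20+2λ), composition
   of k-spaced amino acid pairs (CKSAAP, 400·(k_max+1)), dipeptide
   composition (DC, 400), dipeptide deviation from expected mean (DDE, 400)
   and composition/transition/distribution (CTD, 21).
2. **Feature selection.** Per descriptor, features are ranked by the
   two-group one-way ANOVA F statistic (between- over within-class variance,
   df_b = 1, df_w = N−2) and pruned by sequential backward elimination along
   that ranking, scoring each intermediate subset with stratified
   cross-validated AUC; the criterion-maximal subset wins, ties going to the
   smaller subset.  CTD is kept whole by default (selection degrades it).
3. **Fusion and classification.** The chosen subsets are concatenated in a
   fixed order (AAC, tPseAAC, aPseAAC, CKSAAP, DC, DDE, CTD) and fed to a
   single-hidden-layer perceptron (100 ReLU units, logistic output) trained
   by mini-batch SGD with Nesterov momentum; SVM (RBF), random forest and
   KNN baselines share the interface.

## Descriptor details and conventions

* **Feature order** is fixed — alphabetical residues, lexicographic residue
  pairs, gap blocks ascending in k — so matrices reproduce bit-for-bit.
* **CKSAAP** normalises each gap block by its own valid-pair count
  N_k = N−k−1, so every block is a probability vector even for short
  sequences.
* **DDE** standardises each dipeptide frequency by the codon-usage
  expectation Tm(g,h) = (Cg/CN)(Ch/CN) with CN = 61 sense codons, and scale
  sqrt(Tv), Tv = Tm(1−Tm)/(N−1).  The square-root scale follows the original
  definition of the descriptor.
* **PseAAC** uses the classic hydrophobicity / hydrophilicity / side-chain
  mass table (packaged under `thermoseq/data/`), each property standardised
  to zero mean and unit population SD over the 20 residues.  tPseAAC
  correlation factors are means of squared property differences (hence
  τ_k ≥ 0); aPseAAC uses lagged products of H1 and H2 separately,
  alternating per lag (values may be negative).  λ defaults to 4 with
  weight w = 0.05; λ = 0 or w = 0 reduces both variants to plain AAC.
* **CTD** uses the standard hydrophobicity partition polar {R,K,E,D,Q,N} /
  neutral {G,A,S,T,P,H,Y} / hydrophobic {C,L,V,I,M,F,W}; distribution
  percentiles use the index ceil(p · group count), reported 1-based as a
  percentage of sequence length, with 0 for an absent group.  Alternative
  partitions can be supplied as explicit mappings.

## Selection and training choices

* **ANOVA degrees of freedom.** We use the classical one-way df_w = N−K with
  K = 2 groups.  F is flagged infinite for a perfectly separated constant
  pair of groups and 0 for a feature with no between-class variance.
* **Backward-selection criterion.** Stratified k-fold (default 5)
  cross-validated AUC.  The inner classifier defaults to logistic regression
  — a deliberately cheap stand-in that tracks linear separability and keeps
  the 2400-dimensional CKSAAP trace tractable; a reduced-epoch MLP evaluator
  is available via `selection_classifier="mlp"`.  The elimination step
  defaults to 5% of the descriptor's features (minimum 1 per round).
* **MLP.** Batch 60, learning rate 0.001, momentum 0.8 (Nesterov), 1200
  epochs by default with no early stopping; the stated weight decay of 1e-8
  enters as an equally inert L2 penalty.  Loss is binary cross-entropy;
  weight initialisation is scikit-learn's seeded Glorot scheme.  Epoch
  counts are configurable, and tests use reduced epochs.
* **Scaling.** MLP/SVM/KNN inputs are z-scored with statistics fitted on
  training rows only (constant columns map to zero); the random forest sees
  raw features.
* **KNN** uses the stated Minkowski power p = 1 (Manhattan), k = 6, leaf
  size 2; per-dimension distance weights are uniform.
* **SVM** scores for AUC are Platt-calibrated probabilities.
* **MCC** is defined as 0 when its denominator vanishes; AUC uses the
  rank (Mann–Whitney) formulation with ties counted 1/2.
* **Permutation importance** is computed on held-out data (generalisable
  signal rather than memorised fit), with accuracy drop as the default
  metric and AUC drop available; values can be negative and are not clamped.

## Synthetic data: what it emulates and what it does not

The generator produces two sequence classes over a uniform residue
background.  The thermophile-like class tilts probability mass toward
charged and hydrophobic residues {K,E,D,Q,Y,I,V}; the mesophile-like class
toward small neutral residues {A,T,S,G}.  The effect size δ ∈ [0,1] scales
the tilt (each enriched residue's weight grows from 1 to 1+δ before
renormalisation); δ = 0 makes the classes statistically identical.  An
optional first-order coupling inserts class-preferred dipeptides (KE, LK,
EE, EK, KI, IK vs AA, LA) at a configurable rate, giving the
dipeptide-aware descriptors structure that composition alone cannot see.
Default conditions: 200 sequences per class, lengths uniform on [50, 400]
(globular-protein scale), δ = 0.8, coupling 0.

The generator reproduces the *compositional* contrast between thermophilic
and mesophilic proteomes, not real protein structure: there is no
phylogenetic correlation, no domain architecture, no SwissProt background
composition (a uniform background keeps analytic expectations trivial), and
no temperature labels.  Passing tests therefore demonstrate that the
pipeline recovers compositional class signal and is calibrated under the
null — not that it attains any particular accuracy on real proteomes.

## Verification design

Every encoder, the ANOVA decomposition, the confusion metrics and the AUC
are checked against independent brute-force oracles (naive dict-and-loop
implementations kept in the test suite), and against scipy/scikit-learn
where an external reference exists.  Pipeline-level checks run at desk
scale: signal recovery uses the default 200+200/δ=0.8 conditions with an
80:20 split and reduced MLP epochs; null calibration trains 20 seeded
pipelines at δ = 0 and measures each one's AUC on an independently generated
600-sequence probe set — at that probe size the null AUC standard deviation
is ≈ 0.024, so the [0.4, 0.6] acceptance band is a ≈ 4σ test, whereas an
80-sequence split would make the same band statistically meaningless
(σ ≈ 0.066).

## Numerical and degenerate-input conventions

* Encoders are pure; identical input yields bit-identical output.
* Sequence preconditions: AAC needs N ≥ 1, dipeptide descriptors N ≥ 2,
  CKSAAP N ≥ k_max+2, PseAAC N > λ; violations raise errors naming the
  record and descriptor.
* Ambiguous residues (B/J/O/U/X/Z) are rejected by default; `drop` and
  `strip-nonstandard` policies are offered for practical data.
* Stratified splitting rounds the per-class train size as
  floor(n·fraction + 0.5), clamped so neither side is empty; identical seeds
  give identical splits.
* Exact score ties in backward selection resolve to the smaller subset;
  exact F ties in ranking keep original column order.
* Manifests contain no timestamps, so identical configurations yield
  byte-identical artifacts.

## Known limitations

* The λ and property-table choices for PseAAC are conventions; other
  published tables shift tPseAAC/aPseAAC values.
* The backward-selection trace evaluates a coarse grid of subset sizes (one
  per elimination round), not every size.
* Training is CPU-only scikit-learn; very large epoch counts on wide fused
  matrices are slow.
* The CLI's staged artifacts are TSV/JSON for auditability; the model
  archive itself uses joblib and is not portable across library versions.
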