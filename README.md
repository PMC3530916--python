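# tispred

Prediction of translation initiation sites (TISs) in **plant genomic DNA**.

Most TIS predictors operate on mRNA or cDNA, where the first in-frame ATG
is already close to the answer. Recognising which ATG triplets in *genomic*
sequence are genuine start codons is much harder: introns, intergenic DNA
and untranslated regions are full of decoy ATGs. `tispred` classifies every
candidate ATG in genomic sequence using only the surrounding DNA context —
no expressed-sequence evidence — which makes it useful for annotating
newly assembled plant genomes. It is aimed at genome-annotation
bioinformaticians and at anyone studying the sequence determinants of
translation initiation.

## Method

Each candidate ATG is represented by a fixed 300-nt window read 5′→3′ on
its strand, with the codon at positions 150–152. The classifier has three
parts:

1. **Feature engineering.** A declarative catalogue maps a window to a
   numeric vector: a position-weight-matrix (PWM) log-odds score over the
   Kozak context [−10, +5] (scored as Σ log₂ p(b|i)/q(b) against the
   background composition q), base indicators at the classic −3 and +4
   positions, downstream open-reading-frame length and in-frame stop
   indicators, upstream ATG counts, and k-mer/G+C compositional summaries
   reaching up to ~150 bp from the codon. PWM, background and per-feature
   z-normalisation constants are estimated on a dedicated
   *feature-estimation* partition only.
2. **Wrapper feature selection.** A genetic algorithm evolves bit-vectors
   over the selectable features (a fixed, always-on subset carries the
   consensus TIS signals). Fitness of a bit-vector is the 3-fold
   cross-validated accuracy of the downstream network on the training
   partition; variation is single-point crossover plus 15 % per-bit
   mutation, with tournament selection and elitism.
3. **Classifier.** A single-hidden-layer feedforward network (31 logistic
   units by default) trained by backpropagation on cross-entropy, with
   early stopping: after each epoch the loss on a held-out validation
   partition is measured, training stops after 20 epochs without
   improvement, and the best-validation weights are restored.

Training data are built from a genome (FASTA) plus annotation (GFF3): one
positive window per protein-coding start, and an equal number of negative
ATG windows sampled with per-chromosome quotas proportional to chromosome
length, excluding annotated starts and any window sequence present in the
positive set. Per class, 65 % of windows go to training (subdivided into
feature-estimation, network-training and validation parts) and 35 % to
testing. Performance is reported as sensitivity Se = TP/(TP+FN) and
specificity Sp = TN/(TN+FP).

A synthetic-genome generator with a planted, tunable Kozak-like consensus
and downstream codon bias makes the whole pipeline testable without any
genome downloads; see `docs/methods.md` for the model and its limits.

## Worked example

Simulate a two-sequence genome with 120 planted genes, train on it, and
scan it:

```bash
tispred simulate --out-prefix synth --n-sequences 2 --length 30000 \
    --n-genes 120 --seed 3
# wrote synth.fasta / .gff3 / .truth.tsv (120 planted genes)

tispred train --genome synth.fasta --annotation synth.gff3 \
    --model-out model.json --feature-estimation 30 --validation 18 \
    --ga-population 10 --ga-generations 5 --seed 3
# model written to model.json
# test partition: Se=0.9286 Sp=0.9762 (TP=39 TN=41 FP=1 FN=3)

tispred predict --genome synth.fasta --model model.json \
    --out preds.gff3 --strands plus
# 960 candidates scored; 196 above threshold 0.5
```

The training report means: of the 42 held-out genuine starts, 39 were
recovered (Se = 0.93); of 42 held-out decoy ATGs, 41 were rejected
(Sp = 0.98). The prediction file is standard GFF3, one 3-nt `TIS` record
per candidate with the network probability in the score column:

```
##gff-version 3
synth1	tispred	TIS	184	186	0.522416	+	.	label=1
synth1	tispred	TIS	236	238	0.290127	+	.	label=0
```

`tispred select-features`, `tispred evaluate`, and the library API
(`WindowFeaturizer`, `GeneticFeatureSelector`, `NeuralNetClassifier`,
`train_from_genome`, `scan`) expose each stage separately; the estimators
follow scikit-learn conventions (`fit`/`transform`/`predict_proba`,
`get_params`).

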