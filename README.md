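# contactfold

Contact-assisted *de novo* protein structure prediction at desk scale:
coarse-grained fragment assembly under a knowledge-based energy function
extended with a predicted residue–residue contact pseudo-energy, plus the
model-selection and model-quality-assessment machinery needed to pick and
trust the resulting models.

## Who this is for

Predicted residue–residue contacts (e.g. from sparse-inverse-covariance
analysis of deep sequence alignments) carry strong constraints on a protein
domain's topology. `contactfold` is a compact, fully self-contained
implementation of the workflow that exploits them: it folds a target
sequence by fragment assembly with replica-exchange simulated annealing,
scores conformations with statistical potentials **plus** a contact
satisfaction term, and then assesses the resulting decoy ensembles without
ever seeing a native structure. Every input it needs (targets, natives,
secondary-structure predictions, PPV-scored contact lists, fragment-source
structures) can be produced by its own synthetic generator, so the whole
method is testable on a laptop with no downloads.

## The model

A chain is reduced to backbone N, CA, C, O plus an ideal Cβ, built from
per-residue (φ, ψ, ω) torsions with ideal bond geometry. The objective is

```
E_total = Σₖ Wₖ·Eₖ ,   k ∈ {SR, LR, SOLV, HB, COMPACT, STERIC, RR}
```

where SR/LR are inverse-Boltzmann pairwise potentials (sequence separation
5–10 / >10) trained from reference structures over a reduced 7-class
residue alphabet, SOLV/HB/COMPACT/STERIC are fixed-form burial,
secondary-structure, radius-of-gyration and clash terms, and RR is the
contact pseudo-energy. For one predicted contact with probability *P* and
current Cβ–Cβ distance *d* (Cα for glycine):

```
E_rr(d) = −P                                  d ≤ d_con
E_rr(d) = P·(1 − 2·exp(−(d − d_con)/τ))       d > d_con        d_con = 8 Å
```

a square well with exponentially decaying attraction whose violation
penalty is proportional to *P*. Weights Wₖ equalise each term's spread
against the SR term over an ensemble of random conformations of the target,
then multiply in user factors (1 everywhere except STERIC ×3, RR ×5).
Contacts can be active from the start (*all*), or introduced *sequentially*
from short-range (separation ≤ 9) to full range, linearly per annealing
cycle; the *combined* pool mixes both schedules.

Model assessment uses the length-normalised TM-score
(d₀ = 1.24·(L−15)^⅓ − 1.8). The ensemble-level quality scores are

```
MQA_LR = CON_LR · ln(1 + N_LR)            (top-L long-range contacts, sep > 23)
CS     = W_TM·⟨TM⟩_pairwise + W_LR·MQA_LR     W_TM = 7, W_LR = 1
```

with CS > 3.4 flagging a predicted-correct fold (TM ≥ 0.5 operating point).

## Worked example

Fold a synthetic 60-residue helix hairpin from its simulated contact
prediction (90% precision), using a fragment library cut from four other
toy structures (decontaminated against the target sequence):

```bash
contactfold synth --topology helix_hairpin --length 60 \
    --precision 0.9 --n-contacts 40 --seed 1 --out-prefix toy
contactfold synth --topology helix_hairpin     --length 50 --seed 4 --out-prefix src4
contactfold synth --topology three_helix_bundle --length 75 --seed 7 --out-prefix src7
contactfold synth --topology three_helix_bundle --length 75 --seed 8 --out-prefix src8
contactfold synth --topology three_helix_bundle --length 75 --seed 9 --out-prefix src9
contactfold build-fraglib --pdb src4.pdb --pdb src7.pdb --pdb src8.pdb \
    --pdb src9.pdb --exclude toy.fasta --out lib.jsonl
contactfold train-pairs  --pdb src4.pdb --pdb src7.pdb --pdb src8.pdb \
    --pdb src9.pdb --out pairs.tsv
contactfold fold --fasta toy.fasta --ss2 toy.ss2 --rr toy.rr \
    --fraglib lib.jsonl --pair-table pairs.tsv \
    --mode combined --n 6 --steps 50000 --seed 42 --out ensemble.pdb
contactfold assess --ensemble ensemble.pdb --rr toy.rr \
    --native toy.pdb --out qa.tsv
```

`qa.tsv` then reads (native column only because `--native` was given):

```
decoy_id  energy     rank  N_LR  CON_LR  mqa_lr  mean_pairwise_tm  cs      predicted_correct  tm_to_native
0         -568.6008  2     20    0.8500  2.5878  0.8983            8.8756  1                  0.9455
1         -567.2137  4     20    0.8500  2.5878  0.8983            8.8756  1                  0.9283
2         -566.5192  5     20    0.7500  2.2834  0.8983            8.5712  1                  0.9505
3         -580.9650  1     20    0.8000  2.4356  0.8983            8.7234  1                  0.9703
...
```

Reading: the lowest-energy model (decoy 3, rank 1) satisfies 80% of the 20
top-L long-range predicted contacts, the ensemble is tight (mean pairwise
TM-score 0.90), and the combined score 8.72 is far above the 3.4
threshold — the model is called correct, which the TM-score to the native
(0.97) confirms. Without the `--rr` contact term the same protocol
typically stalls near TM ≈ 0.5.

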