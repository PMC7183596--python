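# poorqa — single-model quality assessment for poor protein structure models

`poorqa` estimates the quality of a predicted protein structure without
reference to the native structure and without needing a large pool of
alternative models to compare against. It is aimed at the hard end of
structure prediction, where most candidate models are poor (GDT-TS well
below 50) and consensus methods break down.

## The model

Each candidate structure is reduced to six features:

- **E_dope**, **E_goap** — two knowledge-based statistical potentials,
  normalized per target to [0, 1];
- **E_ss_h**, **E_ss_e** — disagreement between the model's hydrogen-bond
  derived secondary structure and a sequence-based secondary-structure
  prediction, measured separately for the helix and strand channels as a
  per-residue binary XOR rate;
- **E_sa** — the same XOR disagreement between the model's relative
  solvent accessibility (buried/exposed at a 25% threshold) and a
  sequence-based accessibility prediction;
- **E_contact** — the fraction of the top-L predicted residue–residue
  contacts (L = chain length) not realized in the model at 8 Å between
  side-chain reference atoms.

These combine linearly into a single score

```
E = w₁·E_dope + w₂·E_goap + w₃·E_ss_h + w₄·E_ss_e + w₅·E_sa + w₆·E_contact
```

where lower E means a better model. The package ships a published weight
vector (`poorqa.PUBLISHED_WEIGHTS`) and two fitters for learning weights from
labelled decoy pools: pooled linear regression, and a three-round
range-refining random search that maximizes the summed per-target Pearson
correlation between −E and GDT-TS. A synthetic benchmark generator
produces decoy pools (and full on-disk fixture trees with PDB files and
prediction files) with a planted weight vector, so every stage can be
validated against a known ground truth.

## Worked example

`examples/evaluate_ranking.py` generates eight synthetic pools of 120
decoys each and evaluates the published weights:

```
target    corr(-E,GDT)  top1 GDT  best-of-5  Z(top1)
T000             0.965     50.48      51.09     2.05
T001             0.975     60.00      60.00     2.92
...
mean correlation: 0.971
mean top-1 GDT-TS: 59.22
Z-score sums: top1 20.40, best-of-5 20.52
```

`examples/fit_weights.py` recovers a planted weight direction from noisy
pools (regression cosine 0.99999 to the planted direction); and
`examples/score_decoys.py` builds a small fixture tree on disk and ranks
the decoys of one target — the native-derived decoy ranks first with all
four penalty features exactly zero.

The same pipeline is available as a command-line tool:

```
poorqa fixtures --targets 5 --decoys 20 --seed 3 --out tree/
poorqa score    --models tree/ --out ranking.tsv
poorqa fit      --features ranking.tsv --quality tree/ --method search --out weights.yaml
poorqa evaluate --features ranking.tsv --quality tree/ --weights weights.yaml --out report.tsv
```

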