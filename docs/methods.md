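# Methods

This document records the models implemented in `poorqa`, the parameter
choices, and the scope of the synthetic benchmark generator. It makes no
empirical claims beyond what the test suite and `scripts/acceptance.py`
compute.

## Score model

A candidate model receives the scalar score

E = w₁·E_dope + w₂·E_goap + w₃·E_ss_h + w₄·E_ss_e + w₅·E_sa + w₆·E_contact

with lower E better. All correlation-based metrics therefore use
corr(−E, quality). The shipped `PUBLISHED_WEIGHTS` are
dope 4.96, goap 0.4, ss_h 76.5, ss_e 65.5, sa 70.65, contact 168.16.

### Potential features (E_dope, E_goap)

Raw statistical-potential values are supplied externally per model. Within
a target they are min–max normalized to [0, 1] (`normalize_potential`); a
constant column normalizes to 0.5 for every model.

### Binary agreement features (E_ss_h, E_ss_e, E_sa)

Each is the per-residue XOR rate Σᵢ(xᵢ⊕pᵢ)/N between a binary string
derived from the model and one derived from a sequence-based prediction.

- Secondary structure is assigned from backbone geometry by hydrogen-bond
  analysis: an H-bond exists when the electrostatic energy
  0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) is below −0.5 kcal/mol,
  with the amide hydrogen reconstructed as N + unit(C_prev − O_prev).
  α-helices come from consecutive i→i+4 turns; strands from parallel and
  antiparallel bridge patterns; 3₁₀/π helices collapse to H and isolated
  bridges to E. Proline cannot donate; |i−j| ≤ 1 pairs are excluded; a
  9 Å Cα prefilter bounds the pair search. The helix channel binarizes
  H vs not-H, the strand channel E vs not-E, each XORed against the same
  binarization of the predicted string.
- Solvent accessibility uses a deterministic sphere-sampling surface
  (golden-spiral point set, 960 points by default in feature extraction,
  fewer where speed matters), probe radius 1.4 Å, van der Waals radii
  C 1.70 / N 1.55 / O 1.52 / S 1.80 Å. Per-residue areas are divided by
  theoretical maximum accessible areas; relative accessibility ≥ 0.25
  (inclusive) counts as exposed.

### Contact feature (E_contact)

Predicted contacts are sorted by confidence descending (ties broken by
ascending (i, j)). The top L usable pairs are taken, where L is the number
of residues present in the model; pairs touching absent residues are
skipped and do not consume a slot. A pair is realized when the Cβ–Cβ
distance (Cα for glycine or missing Cβ) is at most 8 Å. The penalty is
1 − realized/taken. If no pair is usable the feature fails.

### Fallbacks

If any feature cannot be computed (missing prediction file, malformed
input, no usable contacts), its value is set to 0.5 and the corresponding
entry of `fallback_mask` is set, so downstream consumers can distinguish
a genuine mid-range penalty from a placeholder.

## Weight fitting

**Linear regression.** Ordinary least squares of GDT-TS on the pooled
six features across all labelled pools, intercept fitted then discarded.
Coefficients are negated so lower E = better. A rank-deficient design
raises an error naming the collinear features (identified by QR with
column pivoting).

**Random search.** Three rounds of 10,000 uniform samples within
per-weight ranges, starting at [0, 1]⁶. After each round the next range is
the envelope of the top 100 combinations, except where the envelope pins
against the current range boundary (within 1% of the range width): a
pinned upper edge expands to 10× the current upper bound, a pinned lower
edge shrinks to 1/10 of the current lower bound. The best combination
found so far is carried into every later round's candidate set, so the
recorded best objective never decreases. Final weights are the mean of
the last round's top 50 combinations. The objective is the sum over
targets of Pearson corr(−E, GDT-TS); pools with fewer than three labelled
models, constant quality, or constant features are skipped with a
warning, and a pool whose total score is constant under a candidate
contributes zero. The whole procedure is deterministic given the seed.

## Evaluation

Per target: Pearson corr(−E, GDT-TS) (and TM-score when every model in
the pool carries one), the quality of the rank-1 model, the best quality
among the top 5, and Z-scores of those selections against the pool's
population standard deviation (population, not sample, so that per-pool
Z-scores sum exactly to zero). Report-level summaries are the means over
targets plus the Z-score sums. Score ties in ranking break by model id.

## Synthetic benchmark generator

The generator serves two purposes and its defaults define the study
conditions: 75 targets × 400 decoys, planted weights equal to
`PUBLISHED_WEIGHTS`, Gaussian GDT-TS noise with sd 2, corruption rate 0.1.

**Feature-level pools** (`make_decoy_pools`): penalties drawn U[0, 1],
raw potentials Gaussian around target-specific locations (dope mean in
U(−115, −95), goap mean in U(−14, −10), sd 2, then normalized per
target). Quality is globally linear in the features:
GDT-TS = clip(q₀ − s·Σw·f + noise, 0, 100), with the scale s chosen so
the pre-clip quality has sd 9 and the offset q₀ so it has mean 37. This
centering keeps the pools in the poor-model regime while preserving
exact linearity, so noiseless regression recovers the planted direction
to machine precision. TM-score is an affine map of GDT-TS clipped to
[0, 1].

**On-disk fixture trees** (`write_fixture_tree`): idealized backbones
built by internal-coordinate chain extension (standard bond lengths and
angles; helix φ=−57° ψ=−47°, strand φ=−139° ψ=135°), written as PDB
files together with secondary-structure, accessibility, contact (RR
format) and score-table files. Decoy m000 derives from the uncorrupted
reference; later decoys are progressively noisier, with GDT-TS decaying
accordingly. Prediction corruption flips each secondary-structure or
accessibility symbol independently with probability ε and replaces each
true contact with a random distant pair with probability ε.

**Scope.** The generator plants a *linear* quality relation; it validates
the fitting and evaluation machinery, not the physical accuracy of the
feature definitions. Chains are single-chain, backbone + Cβ only, alanine
sequences; side-chain–dependent effects (other than the Cβ reference
atom) are out of scope.

## Numerical choices

- Sphere sampling uses a deterministic golden-spiral point set rather
  than random sampling, so areas are reproducible and the test suite can
  compare against closed-form single-sphere and two-sphere values.
- Exposure threshold 0.25 is inclusive; XOR penalties operate on byte
  comparisons of the binary strings.
- Contact confidence ties break by ascending residue-pair indices;
  ranking ties break by model id; `argsort` in the random search is
  stable — all orderings are fully deterministic.
- Population (N, not N−1) standard deviations are used for Z-scores.
- All random draws flow from explicit integer seeds through
  `numpy.random.default_rng`; derived seeds stay below 2³¹.

## Limitations

- Secondary-structure assignment covers α-helix and β-strand with the
  standard collapses; turns and bends are reported as coil.
- The accessibility surface ignores hydrogens and ligands.
- The published weights are taken as given; this package does not
  re-derive them from experimental decoy sets.
- The random search explores a non-negative orthant grown multiplicatively
  from [0, 1]; weights of mixed sign are reachable only by regression.
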