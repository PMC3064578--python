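# Methods

## Consensus model

Each interface predictor *p* assigns per-residue scores on one or more
protein chains. Scores are reduced to integer ranks because absolute
score scales are incomparable across predictors:

* **Per-chain ranking** (WHISCY, PIER, ProMate, PINUP): within each
  chain, residues are sorted best-to-worst and numbered 1, 2, …
  Ties are broken by residue order (chain, number, insertion code), so
  ranks stay dense and runs are reproducible.
* **Pooled partitioning** (cons-PPISP, SPPIDER): scores of all chains
  are pooled and sorted best-to-worst (ascending for cons-PPISP's
  converted cluster scores, descending for SPPIDER), then split into
  N contiguous partitions, N = ⌊total scored residues / number of
  chains⌋. A residue's rank is its partition index. Partition sizes
  differ by at most one, with the remainder assigned to the earliest
  (best) partitions to keep resolution among top scores; residues with
  exactly equal scores receive the partition of the first of them.
* All ranks are capped at 30. cons-PPISP cluster output is first
  converted to scores 100·c + n − 1; residues in no cluster score
  10 000 and predicted-buried residues 100 000, so sentinel residues
  always sort behind any clustered residue and are excluded from
  ranking. PIER scores are pre-filtered to residues with ≥ 15% relative
  side-chain or main-chain accessibility.

A threshold set **T** assigns one cutoff per predictor; the prediction
is the union of each predictor's residues with rank ≤ cutoff. This is a
*consensus* (union of top lists), not a meta-score: agreement between
predictors shrinks the union, disagreement grows it, which makes the
prediction size an indicator of signal strength and anticorrelates it
with the difficulty of the chain.

### Greedy training

All cutoffs start at 0 (empty prediction). Each step tentatively
increments every predictor's cutoff by one, computes the training
specificity TP/(TP+FP) of each resulting selection, and keeps the best;
the procedure repeats until all training residues are selected,
yielding a trajectory of threshold sets indexed by selection size. The
training universe is restricted to residues ranked by *every* predictor
(chains or residues any predictor failed on are discarded). Two
numerical choices the procedure itself does not determine:

* **Tie-breaking:** equal-specificity increments go to the earliest
  predictor in the fixed order WHISCY, PIER, ProMate, cons-PPISP,
  SPPIDER, PINUP.
* **Termination:** a predictor whose cutoff has reached its highest
  assigned rank is no longer a candidate (further increments could
  never select anything), which bounds the trajectory length.
  Specificity is undefined at the empty set, so the first step chooses
  among the single-selection candidates; training data without any
  interface residue is rejected.

### Presets

Three published cutoff presets name operating points of increasing
overprediction (order: WHISCY, PIER, ProMate, PINUP, cons-PPISP,
SPPIDER; the last two count score partitions):

| preset   | cutoffs              | intent                  |
|----------|----------------------|-------------------------|
| balanced | 4, 3, 6, 12, 0, 6    | prediction per se       |
| slight   | 6, 7, 11, 13, 11, 6  | mild overprediction     |
| heavy    | 14, 20, 19, 21, 14, 6| docking default         |

The SPPIDER preset is stored as "6 partitions"; the raw score value
sometimes quoted alongside it is dataset-specific and is not used.
When a predictor yields nothing on a chain, the consensus falls back to
the union over the remaining predictors.

## Ground truth and evaluation

* **Interface residue:** any heavy atom < 5 Å (strict) from the partner
  group in the reference complex.
* **Surface residue:** relative side-chain *or* main-chain solvent
  accessibility ≥ 15% in the unbound form.
* **Evaluation universe:** surface residues plus *all* interface
  residues. Interface residues missing or buried in the unbound form
  stay in the universe flagged *unpredictable*: they count as false
  negatives when missed, capping achievable sensitivity at (i−u)/i.
* Sensitivity = TP/(TP+FN); specificity = TP/(TP+FP) (the
  interface-prediction convention, i.e. precision). Undefined ratios
  return NaN, never 0. Per-chain evaluation tracks all-wrong chains and
  40% sensitivity/specificity flags; "overall" statistics are ratios of
  summed counts, not means of per-chain ratios. Method comparisons use
  a one-tailed Fisher exact test (direction an explicit argument) and
  Spearman/Pearson correlations, both via scipy.

### Solvent accessibility

Shrake–Rupley with 960 quasi-uniform sphere points per atom
(golden-spiral lattice), probe 1.4 Å, standard van der Waals radii by
element; implemented internally with a pluggable backend hook.
The **reference state** for relative accessibility is the residue's own
atoms computed in isolation, fully exposed, rather than a tabulated
per-residue-type area: this is exact for any atom subset — including
the reduced 5-atom pseudo-residues of the synthetic fixtures and
partially resolved residues in real files — and makes the ≥ 15%
threshold the sole contract. Side chain = all atoms outside
{N, CA, C, O, OXT}; glycine's CA counts as its side chain, following
the usual accessibility convention. A fully exposed free residue has
relative accessibility exactly 1 by construction; the implementation is
cross-checked against an independent SASA implementation (biotite) to
within 5% total area in the test suite.

## Restraints

Active residues = predicted residues present in the structure; passive
= surface residues with any heavy atom within 6.5 Å of any active
residue's heavy atoms, minus the active set. Per active residue one
ambiguous restraint targets all active+passive residues of the partner,
emitted as a CNS-dialect `assign` statement with the documented 2.0 Å
effective-distance defaults (the ambiguity is resolved by the docking
program's 1/r⁶-style averaging; this package only writes the table).
The reader parses exactly the dialect the writer emits. Per-trial
subsampling shuffles restraints with a seeded generator into n
near-equal partitions and keeps one — n = 8 discards 87.5% — forming a
disjoint cover with part sizes differing by ≤ 1. For restraint-free
docking the center-of-mass distance bound is
1 + (dxᵢ+dyᵢ+dzᵢ+dxⱼ+dyⱼ+dzⱼ)/12, with extents measured along the
principal axes of each protein's heavy-atom coordinate covariance (the
standard reading of the alignment-tensor axes).

## Decoy evaluation

Backbone = {N, CA, C, O}. l-RMSD: least-squares fit on receptor
backbone, RMSD over ligand backbone. i-RMSD: interface residues defined
on the reference (any heavy atom within 10 Å of the partner), fit and
RMSD over their backbone atoms. fnat: fraction of the reference's
cross-group residue contacts (5 Å heavy-atom, matching the interface
definition) present in the decoy. Stars: 1 ≡ (i-RMSD < 4 or
l-RMSD < 10) and fnat ≥ 0.1; 2 ≡ (< 2 or < 5) and ≥ 0.3; 3 ≡ (< 1 or
< 1) and ≥ 0.5; the fnat clauses are skipped at the rigid-body stage
and for symmetry-related complexes. Superposition uses a closed-form
SVD (Kabsch) solution with the reflection branch rejected,
cross-checked against an independent quaternion implementation.
Symmetric complexes are evaluated under every admissible chain
correspondence, each statistic taken from its own best mapping.
Enrichment of correct decoys among a top-n selection is the exact
hypergeometric tail P(X ≥ k); depletion P(X ≤ k); the tails share the
point mass at k.

## Post-prediction

Per chain, residues are ranked by the number of selected decoys (top
400 at the rigid-body stage, all refined decoys otherwise) in which
they have any heavy atom within 5 Å of the partner; the top N are
returned, N being the original number of consensus predictions for the
chain. Contacts are counted per residue-occurrence (a residue
contributes at most 1 per decoy), zero-contact residues are never
predicted even if N is not reached, and ties break by residue order.

## Synthetic fixtures

`simulate_scores` draws correlated binormal scores: per residue a
shared latent u ~ N(0,1), per predictor z = ρu + √(1−ρ²)ε + μ·[interface],
with μ = √2·Φ⁻¹(AUC) so each predictor's theoretical AUC equals the
requested signal strength; signal 1.0 adds a fixed margin of 100 for
complete separation. Defaults emulate the statistical shape of a
docking-benchmark training set: 6 chains × 130 residues (≈ the
benchmark's scored residues per chain), interface fraction 0.15,
AUC 0.7 (individual predictors are weak), inter-predictor correlation
0.3, and 14% of the interface flagged buried in every table (emulating
interface residues missing or buried in the unbound form, hence
unpredictable). Interface counts are planted exactly as round(0.15·L)
per chain so closed-loop tests are deterministic.

`toy_complex` builds two pseudo-backbone strands (N, CA, C, O, CB per
residue, 3.8 Å spacing) that touch CB-to-CB across a central window —
the planted interface — and bend apart outside it; `make_decoys`
applies rigid transforms to the ligand chain about its centroid, so a
pure translation t has l-RMSD exactly |t| and rotations have
closed-form RMSDs.

What the generators deliberately do **not** model: real side-chain
packing and chemistry, conformational change between bound and unbound
forms, predictor-specific failure modes (the six real predictors fail
in structured, not binormal, ways), energy-based decoy ranking, and
sequence redundancy between chains. Passing tests therefore certify
the algorithmic contracts — ranking, union semantics, greedy
optimality, geometry, exact statistics — not benchmark-level
performance of the six retired web predictors.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances chosen to exercise every code path while staying desk-scale:
≤ 8 chains × ≤ 130 residues for score simulation, 20-residue chains for
toy complexes, 50–200 decoys per ensemble, 50–60 random instances for
the enumeration oracles. These sizes are the package's own test
conditions; all statistics scale to larger inputs unchanged.

## Known limitations

* The AIR writer emits the table only; restraint energies and the
  docking protocol itself are out of scope.
* The accessibility reference state differs from tabulated-area tools
  (NACCESS-style); absolute relative-accessibility values can differ by
  a few percent near the 15% threshold, though the classification
  contract is preserved and tested.
* `best_of_mappings` assumes the caller supplies the admissible chain
  correspondences; it does not detect symmetry automatically.
* Per-chain ranking of tied scores is order-deterministic rather than
  fractional, so tied residues receive distinct ranks.
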