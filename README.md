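# cport

Consensus prediction of protein–protein interface residues, and the
surrounding toolkit for prediction-driven docking: restraint generation,
CAPRI-style evaluation of docking decoys, and interface post-prediction
from decoy contact frequencies.

## The problem

Individual interface predictors (WHISCY, PIER, ProMate, cons-PPISP,
SPPIDER, PINUP) disagree strongly; on most proteins at least one is
right, but one cannot tell which. For data-driven docking that is
tolerable — the docking engine copes with restraints that mix right and
wrong residues — but *missing* the interface entirely on either partner
is fatal. The consensus strategy here therefore **adds** predictions
instead of averaging scores: the predicted set is

```
P(T) = ⋃ₚ { residues r : rankₚ(r) ≤ Tₚ }
```

the union over predictors *p* of each predictor's top-*Tₚ* residues,
deliberately overpredicting so that some part of the true interface is
almost always covered.

Raw scores are first normalized to capped integer ranks (cap 30):
per-chain ranks for WHISCY/PIER/ProMate/PINUP, pooled score partitions
for cons-PPISP and SPPIDER, whose scores are comparable across
proteins. cons-PPISP cluster output is converted to a scalar score
100·c + n − 1 (cluster rank c, within-cluster rank n; 10 000 for
unclustered, 100 000 for buried residues). The cutoff vector **T** is
trained greedily: starting from all zeros, repeatedly increment the one
cutoff that maximizes training specificity TP/(TP+FP), until every
training residue is selected. Three named presets (balanced / slight /
heavy overprediction) are shipped; *heavy* — (WHISCY 14, PIER 20,
ProMate 19, PINUP 21, cons-PPISP 14, SPPIDER 6) — is the docking
default.

Downstream, predictions become **active** residues and their 6.5 Å
surface shell **passive** residues; each active residue yields one
ambiguous interaction restraint (AIR) to all active+passive residues of
the partner, written as a CNS-dialect `.tbl` file, with seeded random
subsampling (8 partitions keep 12.5%). Docking decoys are scored with
CAPRI criteria (i-RMSD, l-RMSD, fnat, 0–3 stars), enrichment of correct
decoys in a top selection is tested with the hypergeometric
distribution, and the interface can be *post-predicted* by ranking
residues by how often they form contacts across the selected decoys.

## Worked example

```
python examples/01_consensus_prediction.py
```

generates six synthetic predictor tables over 6 chains × 130 residues
with a planted 15% interface (per-predictor AUC 0.7), trains the greedy
trajectory and applies the heavy preset:

```
greedy trajectory: 176 steps
  after ~30 selections: sensitivity 0.21, specificity 0.62 (base rate of interface residues: 0.15)
heavy-overprediction preset (the docking default):
  predictions per chain: 64
  overall sensitivity:   0.71
  overall specificity:   0.22
  chains all-wrong:      0%
```

Specificity 0.62 at small selection sizes — four times the 0.15 base
rate — shows the consensus concentrating true interface residues at the
top of the trajectory; the heavy preset then spends specificity to buy
the sensitivity docking needs, and no chain is left with an entirely
wrong prediction. The other examples cover restraint generation
(`02_docking_restraints.py`), decoy evaluation with enrichment
statistics (`03_decoy_evaluation.py`) and interface post-prediction
(`04_postprediction.py`). A thin CLI wraps the same library calls
(`cport simulate / normalize / train / predict / evaluate / restraints /
capri-eval / postpredict`).

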