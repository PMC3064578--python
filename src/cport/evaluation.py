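"""Scoring interface predictions against ground-truth labels.

Sensitivity is the fraction of the interface that was predicted,
TP/(TP+FN); specificity here is the precision of the predictions,
TP/(TP+FP) — the convention of the interface-prediction literature, not
the TN-based definition.  Per-chain statistics additionally track the
failure modes that matter for data-driven docking: chains where every
prediction is wrong, and chains reaching 40% sensitivity and/or
specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from scipy import stats as sps

from .consensus import PredictionSet
from .residues import ResidueId
from .scores import ValidationError
from .structure import ResidueLabels


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(pred: PredictionSet | set[ResidueId], labels: ResidueLabels) -> ConfusionCounts:
    """Tally a prediction against labels over the evaluation universe.

    The universe is surface residues plus all interface residues;
    predictions outside it (e.g. residues buried in both forms) are
    ignored.  Unpredictable interface residues count as false negatives
    when missed.
    """
    predicted = pred.residues if isinstance(pred, PredictionSet) else set(pred)
    universe = labels.universe
    predicted = predicted & universe
    interface = labels.interface
    tp = len(predicted & interface)
    fp = len(predicted - interface)
    fn = len(interface - predicted)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def sensitivity(c: ConfusionCounts) -> float:
    """TP/(TP+FN); NaN when there are no interface residues."""
    denom = c.TP + c.FN
    return c.TP / denom if denom else math.nan


def specificity(c: ConfusionCounts) -> float:
    """TP/(TP+FP); NaN when nothing was predicted."""
    denom = c.TP + c.FP
    return c.TP / denom if denom else math.nan


@dataclass
class ChainStats:
    chain_id: str
    counts: ConfusionCounts
    n_predictions: int
    sensitivity: float
    specificity: float
    all_wrong: bool
    sens_ge_40: bool
    spec_ge_40: bool


@dataclass
class ChainEvaluation:
    """Per-chain statistics plus pooled ('overall') sensitivity/specificity.

    Pooled statistics are ratios of summed counts, not means of
    per-chain ratios.
    """

    per_chain: list[ChainStats] = field(default_factory=list)

    @property
    def pooled_counts(self) -> ConfusionCounts:
        return ConfusionCounts(
            sum(c.counts.TP for c in self.per_chain),
            sum(c.counts.FP for c in self.per_chain),
            sum(c.counts.TN for c in self.per_chain),
            sum(c.counts.FN for c in self.per_chain),
        )

    @property
    def overall_sensitivity(self) -> float:
        return sensitivity(self.pooled_counts)

    @property
    def overall_specificity(self) -> float:
        return specificity(self.pooled_counts)

    def fraction_all_wrong(self) -> float:
        return sum(c.all_wrong for c in self.per_chain) / len(self.per_chain)

    def fraction_sens_ge_40(self) -> float:
        return sum(c.sens_ge_40 for c in self.per_chain) / len(self.per_chain)

    def fraction_spec_ge_40(self) -> float:
        return sum(c.spec_ge_40 for c in self.per_chain) / len(self.per_chain)

    def mean_predictions_per_chain(self) -> float:
        return sum(c.n_predictions for c in self.per_chain) / len(self.per_chain)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tTP\tFP\tTN\tFN\tn_predictions\tsensitivity\tspecificity\tall_wrong\tsens_ge_40\tspec_ge_40\n")
            for c in self.per_chain:
                fh.write(
                    f"{c.chain_id}\t{c.counts.TP}\t{c.counts.FP}\t{c.counts.TN}\t{c.counts.FN}\t"
                    f"{c.n_predictions}\t{c.sensitivity:.4f}\t{c.specificity:.4f}\t"
                    f"{int(c.all_wrong)}\t{int(c.sens_ge_40)}\t{int(c.spec_ge_40)}\n"
                )
            fh.write(
                f"#overall\tsensitivity={self.overall_sensitivity:.4f}\t"
                f"specificity={self.overall_specificity:.4f}\t"
                f"all_wrong={self.fraction_all_wrong():.4f}\n"
            )


def evaluate_chains(
    preds: PredictionSet | Mapping[str, PredictionSet],
    labels: ResidueLabels,
    flag_threshold: float = 0.40,
) -> ChainEvaluation:
    """Evaluate per chain and pool counts for overall statistics.

    ``preds`` is either one PredictionSet spanning all chains, or a
    mapping chain id -> PredictionSet.  A chain is 'all wrong' when it
    has predictions but zero true positives.
    """
    if isinstance(preds, PredictionSet):
        per_chain_preds = {c: preds.restrict_to_chain(c) for c in labels.chains()}
    else:
        per_chain_preds = dict(preds)
    out = ChainEvaluation()
    for chain_id in sorted(per_chain_preds):
        pred = per_chain_preds[chain_id]
        chain_labels = ResidueLabels(
            {r: c for r, c in labels.classes.items() if r.chain_id == chain_id},
            {r for r in labels.unpredictable if r.chain_id == chain_id},
        )
        counts = confusion(pred, chain_labels)
        sens = sensitivity(counts)
        spec = specificity(counts)
        n_pred = len(pred.residues & chain_labels.universe)
        out.per_chain.append(
            ChainStats(
                chain_id=chain_id,
                counts=counts,
                n_predictions=n_pred,
                sensitivity=sens,
                specificity=spec,
                all_wrong=(counts.TP == 0 and n_pred > 0),
                sens_ge_40=(not math.isnan(sens) and sens >= flag_threshold),
                spec_ge_40=(not math.isnan(spec) and spec >= flag_threshold),
            )
        )
    return out


def fisher_one_tailed(a: int, b: int, c: int, d: int, alternative: str = "greater") -> float:
    """One-tailed Fisher exact test on the 2x2 table [[a, b], [c, d]].

    ``alternative='greater'`` asks whether the first row's success odds
    (a vs b) exceed the second row's (c vs d); 'less' is the reverse.
    Used to compare two methods' per-chain success counts.
    """
    if alternative not in ("greater", "less"):
        raise ValidationError("alternative must be 'greater' or 'less'")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(p)


def rank_correlation(x, y, method: str = "spearman") -> float:
    """Spearman rank or Pearson correlation coefficient."""
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    raise ValidationError(f"unknown correlation method {method!r}")
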