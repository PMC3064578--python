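"""Consensus interface prediction by union of per-predictor top ranks.

Instead of combining predictor scores into a new score, the consensus
*adds* predictions: a residue is predicted when its rank in any single
predictor is at or below that predictor's cutoff.  The cutoffs are
trained greedily — starting from all-zero cutoffs (an empty prediction)
the cutoff whose unit increment yields the highest training specificity
is raised, one step at a time, until every training residue is
predicted.  The trajectory of cutoff sets trades sensitivity against
specificity; three published presets (balanced / slight / heavy
overprediction) name points on it, of which heavy overprediction is the
default used to drive docking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import defaultdict
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .ranking import RankTable
from .residues import ResidueId
from .scores import PREDICTORS, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .structure import ResidueLabels


@dataclass(frozen=True)
class ThresholdSet:
    """One non-negative integer rank cutoff per predictor.

    A cutoff of 0 selects nothing from that predictor.
    """

    cutoffs: tuple[tuple[str, int], ...]
    label: str | None = None

    @classmethod
    def from_dict(cls, cutoffs: Mapping[str, int], label: str | None = None) -> "ThresholdSet":
        items = tuple(sorted(cutoffs.items()))
        for name, c in items:
            if c < 0:
                raise ValidationError(f"negative cutoff for {name}: {c}")
        return cls(items, label)

    def as_dict(self) -> dict[str, int]:
        return dict(self.cutoffs)

    def __getitem__(self, predictor: str) -> int:
        return self.as_dict()[predictor]

    def incremented(self, predictor: str) -> "ThresholdSet":
        d = self.as_dict()
        d[predictor] += 1
        return ThresholdSet.from_dict(d)

    def __le__(self, other: "ThresholdSet") -> bool:
        a, b = self.as_dict(), other.as_dict()
        return set(a) == set(b) and all(a[k] <= b[k] for k in a)


#: Published cutoff presets (WHISCY, PIER, ProMate, cons-PPISP, SPPIDER, PINUP).
#: cons-PPISP and SPPIDER cutoffs count score partitions, not per-chain ranks.
_PRESETS = {
    "balanced": {"WHISCY": 4, "PIER": 3, "ProMate": 6, "PINUP": 12, "cons-PPISP": 0, "SPPIDER": 6},
    "slight": {"WHISCY": 6, "PIER": 7, "ProMate": 11, "PINUP": 13, "cons-PPISP": 11, "SPPIDER": 6},
    "heavy": {"WHISCY": 14, "PIER": 20, "ProMate": 19, "PINUP": 21, "cons-PPISP": 14, "SPPIDER": 6},
}

#: The default preset used for docking restraints (heavy overprediction).
DEFAULT_PRESET = "heavy"


def preset(name: str = DEFAULT_PRESET) -> ThresholdSet:
    """Return a published cutoff preset by name (balanced / slight / heavy)."""
    try:
        cutoffs = _PRESETS[name]
    except KeyError:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None
    return ThresholdSet.from_dict(cutoffs, label=name)


@dataclass
class PredictionSet:
    """Predicted interface residues with per-residue provenance.

    ``provenance`` maps each predicted residue to the set of predictors
    that selected it at the threshold used.
    """

    provenance: dict[ResidueId, set[str]] = field(default_factory=dict)
    threshold: ThresholdSet | None = None

    @property
    def residues(self) -> set[ResidueId]:
        return set(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)

    def __contains__(self, rid: ResidueId) -> bool:
        return rid in self.provenance

    def by_chain(self) -> dict[str, list[ResidueId]]:
        out: dict[str, list[ResidueId]] = defaultdict(list)
        for rid in sorted(self.provenance):
            out[rid.chain_id].append(rid)
        return dict(out)

    def restrict_to_chain(self, chain_id: str) -> "PredictionSet":
        return PredictionSet(
            {r: set(p) for r, p in self.provenance.items() if r.chain_id == chain_id},
            self.threshold,
        )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tresnum\ticode\tpredictors\n")
            for rid in sorted(self.provenance):
                preds = ",".join(sorted(self.provenance[rid]))
                fh.write(f"{rid.chain_id}\t{rid.residue_number}\t{rid.insertion_code or '-'}\t{preds}\n")


def _as_rank_map(ranks: Iterable[RankTable] | Mapping[str, RankTable]) -> dict[str, RankTable]:
    if isinstance(ranks, Mapping):
        return dict(ranks)
    out = {}
    for t in ranks:
        if t.predictor_name in out:
            raise ValidationError(f"duplicate rank table for {t.predictor_name}")
        out[t.predictor_name] = t
    return out


def select_at_threshold(
    ranks: Iterable[RankTable] | Mapping[str, RankTable],
    thresholds: ThresholdSet,
) -> PredictionSet:
    """Union of each predictor's residues ranked at or below its cutoff."""
    rank_map = _as_rank_map(ranks)
    unknown = set(thresholds.as_dict()) - set(rank_map)
    if unknown:
        raise ValidationError(f"thresholds name unknown predictors: {sorted(unknown)}")
    provenance: dict[ResidueId, set[str]] = {}
    for name, cutoff in thresholds.cutoffs:
        table = rank_map[name]
        for rid, rank in table.entries.items():
            if rank <= cutoff:
                provenance.setdefault(rid, set()).add(name)
    return PredictionSet(provenance, thresholds)


def predict_consensus(
    ranks: Iterable[RankTable] | Mapping[str, RankTable],
    thresholds: ThresholdSet,
    available: set[str] | None = None,
) -> PredictionSet:
    """Consensus prediction, falling back to the available predictors.

    When a predictor failed on a chain, the consensus of the remaining
    predictors is used: ``available`` restricts the union to those
    predictor names.
    """
    rank_map = _as_rank_map(ranks)
    if available is not None:
        missing = available - set(rank_map)
        if missing:
            raise ValidationError(f"available predictors without rank tables: {sorted(missing)}")
        rank_map = {k: v for k, v in rank_map.items() if k in available}
        cutoffs = {k: v for k, v in thresholds.as_dict().items() if k in available}
        thresholds = ThresholdSet.from_dict(cutoffs, thresholds.label)
    return select_at_threshold(rank_map, thresholds)


@dataclass(frozen=True)
class TrajectoryStep:
    thresholds: ThresholdSet
    sensitivity: float
    specificity: float
    n_selected: int


@dataclass
class ThresholdTrajectory:
    """Greedy training output: a list of threshold sets of growing size.

    Consecutive steps differ by +1 in exactly one predictor's cutoff;
    the selected-set size is non-decreasing along the trajectory.
    """

    steps: list[TrajectoryStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)

    def __getitem__(self, i: int) -> TrajectoryStep:
        return self.steps[i]

    def at_size(self, n_predictions: int) -> TrajectoryStep:
        """First step whose selected set reaches ``n_predictions`` residues."""
        for step in self.steps:
            if step.n_selected >= n_predictions:
                return step
        return self.steps[-1]

    def write_tsv(self, path: str | Path, predictor_order: Sequence[str] | None = None) -> None:
        order = list(predictor_order or (self.steps and [n for n, _ in self.steps[0].thresholds.cutoffs]) or [])
        with open(path, "w") as fh:
            fh.write("step\t" + "\t".join(order) + "\tsensitivity\tspecificity\tn_selected\n")
            for i, step in enumerate(self.steps):
                d = step.thresholds.as_dict()
                cut = "\t".join(str(d[p]) for p in order)
                fh.write(f"{i}\t{cut}\t{step.sensitivity:.6f}\t{step.specificity:.6f}\t{step.n_selected}\n")


def greedy_train(
    ranks: Iterable[RankTable] | Mapping[str, RankTable],
    labels: "ResidueLabels",
    predictor_order: Sequence[str] | None = None,
) -> ThresholdTrajectory:
    """Train the consensus cutoffs by greedy specificity maximization.

    The training universe is restricted to residues ranked by *all*
    predictors (chains or residues any predictor failed on are
    discarded).  Starting from all-zero cutoffs, each step tries a unit
    increment of every predictor's cutoff and keeps the one with the
    highest training specificity TP/(TP+FP); ties go to the earliest
    predictor in ``predictor_order`` (default: the canonical order
    WHISCY, PIER, ProMate, cons-PPISP, SPPIDER, PINUP).  Training stops
    once every training residue is selected.
    """
    rank_map = _as_rank_map(ranks)
    if predictor_order is None:
        predictor_order = [p for p in PREDICTORS if p in rank_map]
        predictor_order += [p for p in sorted(rank_map) if p not in predictor_order]
    else:
        predictor_order = list(predictor_order)
        if set(predictor_order) != set(rank_map):
            raise ValidationError("predictor_order must name exactly the rank tables given")

    universe: set[ResidueId] | None = None
    for table in rank_map.values():
        universe = table.residues if universe is None else (universe & table.residues)
    if not universe:
        raise ValidationError("empty training universe: no residue is ranked by all predictors")

    interface = labels.interface & universe
    if not interface:
        raise ValidationError("no interface residues in the training universe; specificity is undefined")

    # precompute, per predictor, residues sorted by rank for incremental unions
    per_rank: dict[str, dict[int, set[ResidueId]]] = {}
    max_rank: dict[str, int] = {}
    for name, table in rank_map.items():
        buckets: dict[int, set[ResidueId]] = defaultdict(set)
        for rid, rank in table.entries.items():
            if rid in universe:
                buckets[rank].add(rid)
        per_rank[name] = dict(buckets)
        max_rank[name] = max(buckets) if buckets else 0

    def stats(selected: set[ResidueId]) -> tuple[float, float]:
        tp = len(selected & interface)
        n = len(selected)
        sens = tp / len(interface)
        spec = tp / n if n else math.nan
        return sens, spec

    cutoffs = {name: 0 for name in rank_map}
    selected: set[ResidueId] = set()
    steps = [TrajectoryStep(ThresholdSet.from_dict(cutoffs), 0.0, math.nan, 0)]

    # Each step increments one predictor's cutoff by 1.  A predictor whose
    # cutoff already reaches its highest assigned rank is no longer a
    # candidate (further increments can never select anything), which
    # bounds the trajectory length and guarantees termination.
    while len(selected) < len(universe):
        best: tuple[float, str, set[ResidueId]] | None = None
        for name in predictor_order:
            if cutoffs[name] >= max_rank[name]:
                continue
            candidate = selected | per_rank[name].get(cutoffs[name] + 1, set())
            if not candidate:
                continue  # specificity undefined on an empty selection
            _, spec = stats(candidate)
            if best is None or spec > best[0]:
                best = (spec, name, candidate)
        if best is None:
            raise ValidationError("ranks exhausted before all training residues were selected")
        _, name, candidate = best
        cutoffs[name] += 1
        selected = candidate
        sens, spec = stats(selected)
        steps.append(TrajectoryStep(ThresholdSet.from_dict(cutoffs), sens, spec, len(selected)))

    return ThresholdTrajectory(steps)
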