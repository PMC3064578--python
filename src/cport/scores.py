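"""Per-residue predictor score tables.

Six external interface predictors (WHISCY, PIER, ProMate, cons-PPISP,
SPPIDER, PINUP) each emit a per-residue score.  This module reads those
scores from a uniform TSV dialect into :class:`ScoreTable`, converts
cons-PPISP cluster assignments into scalar scores, and applies the
solvent-accessibility filter used for PIER.

Score direction is predictor configuration: raw WHISCY / PIER / ProMate
/ PINUP / SPPIDER scores are better when higher; converted cons-PPISP
cluster scores are better when lower.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

from .residues import ResidueId, make_residue_id

HIGHER_IS_BETTER = "higher_is_better"
LOWER_IS_BETTER = "lower_is_better"

#: Sentinel score for residues cons-PPISP left out of every cluster.
NO_CLUSTER_SCORE = 10_000.0
#: Sentinel score for residues cons-PPISP predicted to be buried.
BURIED_SCORE = 100_000.0

#: Canonical predictor names in the fixed tie-break order.
PREDICTORS = ("WHISCY", "PIER", "ProMate", "cons-PPISP", "SPPIDER", "PINUP")

#: Default score direction per predictor.
DEFAULT_DIRECTIONS = {
    "WHISCY": HIGHER_IS_BETTER,
    "PIER": HIGHER_IS_BETTER,
    "ProMate": HIGHER_IS_BETTER,
    "SPPIDER": HIGHER_IS_BETTER,
    "PINUP": HIGHER_IS_BETTER,
    "cons-PPISP": LOWER_IS_BETTER,
}

#: Predictors whose ranks come from pooled partitioning rather than
#: per-chain ranking.
POOLED_PREDICTORS = frozenset({"cons-PPISP", "SPPIDER"})


class ScoreParseError(ValueError):
    """A malformed score-table row; carries the offending line number."""


class ValidationError(ValueError):
    """Input violates a documented precondition."""


@dataclass
class ScoreTable:
    """Raw per-residue scores of one predictor over one or more chains.

    ``entries`` holds finite scores; residues with no score carry
    exactly one sentinel flag instead (``no_cluster`` or ``buried``).
    """

    predictor_name: str
    direction: str
    entries: dict[ResidueId, float] = field(default_factory=dict)
    no_cluster: set[ResidueId] = field(default_factory=set)
    buried: set[ResidueId] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.direction not in (HIGHER_IS_BETTER, LOWER_IS_BETTER):
            raise ValidationError(f"unknown score direction: {self.direction!r}")
        both = self.no_cluster & self.buried
        if both:
            raise ValidationError(f"residues flagged both no_cluster and buried: {sorted(both)}")
        flagged_and_scored = (self.no_cluster | self.buried) & set(self.entries)
        if flagged_and_scored:
            raise ValidationError(
                f"residues both scored and sentinel-flagged: {sorted(flagged_and_scored)}"
            )

    @property
    def residues(self) -> set[ResidueId]:
        """All residues the predictor reported on, scored or flagged."""
        return set(self.entries) | self.no_cluster | self.buried

    def score(self, residue: ResidueId) -> float:
        """Score of a residue; sentinel-flagged residues return the sentinel value."""
        if residue in self.entries:
            return self.entries[residue]
        if residue in self.no_cluster:
            return NO_CLUSTER_SCORE
        if residue in self.buried:
            return BURIED_SCORE
        raise KeyError(residue)

    def chains(self) -> list[str]:
        return sorted({r.chain_id for r in self.entries})

    def sort_key(self, residue: ResidueId) -> tuple:
        """Best-first comparison key: (score in best-first direction, residue order)."""
        s = self.entries[residue]
        return ((-s if self.direction == HIGHER_IS_BETTER else s), residue)


@dataclass
class ClusterAssignment:
    """cons-PPISP output: residues grouped into ranked clusters.

    ``entries`` maps a residue to (cluster rank c, within-cluster rank
    n), both 1-based.  Within each cluster the within-cluster ranks must
    be 1..k with no gaps or duplicates.
    """

    entries: dict[ResidueId, tuple[int, int]] = field(default_factory=dict)
    unclustered: set[ResidueId] = field(default_factory=set)
    buried: set[ResidueId] = field(default_factory=set)

    def __post_init__(self) -> None:
        by_cluster: dict[int, list[int]] = {}
        for rid, (c, n) in self.entries.items():
            if c < 1 or n < 1:
                raise ValidationError(f"cluster ranks must be positive: {rid} -> ({c}, {n})")
            by_cluster.setdefault(c, []).append(n)
        for c, ns in by_cluster.items():
            if sorted(ns) != list(range(1, len(ns) + 1)):
                raise ValidationError(f"cluster {c} within-cluster ranks are not 1..{len(ns)}: {sorted(ns)}")


def convert_ppisp_clusters(assignment: ClusterAssignment) -> ScoreTable:
    """Convert a cons-PPISP cluster assignment to scalar scores.

    A residue in cluster c at within-cluster rank n gets score
    100*c + n - 1, so cluster order dominates and scores are unique for
    clusters of up to 100 residues.  Unclustered residues get 10 000,
    buried residues 100 000; lower scores are better.
    """
    overlap = set(assignment.entries) & (assignment.unclustered | assignment.buried)
    if overlap:
        raise ValidationError(f"residues both clustered and flagged: {sorted(overlap)}")
    entries = {rid: 100.0 * c + n - 1 for rid, (c, n) in assignment.entries.items()}
    return ScoreTable(
        predictor_name="cons-PPISP",
        direction=LOWER_IS_BETTER,
        entries=entries,
        no_cluster=set(assignment.unclustered),
        buried=set(assignment.buried),
    )


def _parse_rows(lines: Iterable[str]) -> Iterator[tuple[int, list[str]]]:
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line.split()


def read_score_table(
    path: str | Path | IO[str],
    predictor_name: str,
    direction: str | None = None,
) -> ScoreTable:
    """Read one predictor's scores from a whitespace/tab separated file.

    Columns: chain, residue number, [insertion code], score.  The score
    field may be ``NA`` (no prediction for that residue) or ``BURIED``.
    An optional one-line header starting with ``chain`` is skipped.
    Duplicate residues are an error.
    """
    if direction is None:
        direction = DEFAULT_DIRECTIONS.get(predictor_name, HIGHER_IS_BETTER)
    if hasattr(path, "read"):
        lines = list(path)  # type: ignore[arg-type]
    else:
        lines = Path(path).read_text().splitlines()

    entries: dict[ResidueId, float] = {}
    no_cluster: set[ResidueId] = set()
    buried: set[ResidueId] = set()
    seen: set[ResidueId] = set()
    for lineno, fields in _parse_rows(lines):
        if lineno == 1 and fields[0].lower() in ("chain", "chain_id"):
            continue
        if len(fields) == 3:
            chain, resnum_s, value = fields
            icode = ""
        elif len(fields) == 4:
            chain, resnum_s, icode, value = fields
            if icode in ("-", "."):  # placeholder for an absent insertion code
                icode = ""
        else:
            raise ScoreParseError(f"line {lineno}: expected 3 or 4 columns, got {len(fields)}")
        try:
            rid = make_residue_id(chain, int(resnum_s), icode)
        except ValueError:
            raise ScoreParseError(f"line {lineno}: bad residue number {resnum_s!r}") from None
        if rid in seen:
            raise ValidationError(f"line {lineno}: duplicate residue {rid}")
        seen.add(rid)
        upper = value.upper()
        if upper == "NA":
            no_cluster.add(rid)
        elif upper == "BURIED":
            buried.add(rid)
        else:
            try:
                score = float(value)
            except ValueError:
                raise ScoreParseError(f"line {lineno}: bad score {value!r}") from None
            entries[rid] = score
    return ScoreTable(predictor_name, direction, entries, no_cluster, buried)


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write the canonical TSV form (chain, resnum, icode, score|NA|BURIED)."""
    with open(path, "w") as fh:
        fh.write("chain\tresnum\ticode\tscore\n")
        for rid in sorted(table.residues):
            if rid in table.entries:
                value = repr(table.entries[rid])
            elif rid in table.no_cluster:
                value = "NA"
            else:
                value = "BURIED"
            fh.write(f"{rid.chain_id}\t{rid.residue_number}\t{rid.insertion_code or '-'}\t{value}\n")


def filter_by_accessibility(
    table: ScoreTable,
    accessibility: Mapping[ResidueId, tuple[float, float]],
    threshold: float = 0.15,
) -> ScoreTable:
    """Restrict a score table to solvent-exposed residues.

    A residue is kept when its relative side-chain OR main-chain
    accessibility is at least ``threshold`` (default 15%).  Used to
    filter PIER predictions, which score buried residues too.
    Accessibility values may come from :class:`cport.structure.AccessibilityTable`
    or any mapping residue -> (side-chain fraction, main-chain fraction).
    """
    missing = sorted(r for r in table.entries if r not in accessibility)
    if missing:
        raise ValidationError(f"residues missing from accessibility table: {missing}")
    kept = {
        rid: s
        for rid, s in table.entries.items()
        if max(accessibility[rid]) >= threshold
    }
    return ScoreTable(
        predictor_name=table.predictor_name,
        direction=table.direction,
        entries=kept,
        no_cluster=set(table.no_cluster),
        buried=set(table.buried),
    )
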