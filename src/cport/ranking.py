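"""Rank normalization of heterogeneous predictor scores.

Raw predictor scores are incomparable across predictors, so the
consensus works on integer ranks instead.  Two schemes are used:

* per-chain ranking (WHISCY, PIER, ProMate, PINUP): scores are ranked
  best-to-worst within each chain;
* pooled partitioning (cons-PPISP, SPPIDER): scores of all chains are
  pooled, sorted best-to-worst and split into N contiguous partitions,
  where N is the average number of scored residues per chain; a
  residue's rank is the index of its partition.  This is appropriate
  for predictors whose scores are comparable across proteins.

All ranks are capped at 30: beyond the top ~30 residues the ordering
carries no usable signal for the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict
from typing import Iterable

from pathlib import Path

from .residues import ResidueId, make_residue_id
from .scores import ScoreTable, ValidationError

DEFAULT_RANK_CAP = 30


@dataclass
class RankTable:
    """Capped integer ranks for one predictor (1 = best)."""

    predictor_name: str
    entries: dict[ResidueId, int] = field(default_factory=dict)
    cap: int = DEFAULT_RANK_CAP
    unranked: set[ResidueId] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = {r: k for r, k in self.entries.items() if not (1 <= k <= self.cap)}
        if bad:
            raise ValidationError(f"ranks outside [1, {self.cap}]: {bad}")

    @property
    def residues(self) -> set[ResidueId]:
        return set(self.entries)

    def chains(self) -> list[str]:
        return sorted({r.chain_id for r in self.entries})


def rank_per_chain(table: ScoreTable, cap: int = DEFAULT_RANK_CAP) -> RankTable:
    """Rank scores best-to-worst within each chain, capping at ``cap``.

    Ties are broken by residue order (chain, number, insertion code) so
    ranks stay dense and deterministic.  Sentinel-flagged residues are
    not ranked.
    """
    by_chain: dict[str, list[ResidueId]] = defaultdict(list)
    for rid in table.entries:
        by_chain[rid.chain_id].append(rid)
    entries: dict[ResidueId, int] = {}
    for chain_rids in by_chain.values():
        chain_rids.sort(key=table.sort_key)
        for pos, rid in enumerate(chain_rids, start=1):
            entries[rid] = min(pos, cap)
    return RankTable(
        predictor_name=table.predictor_name,
        entries=entries,
        cap=cap,
        unranked=set(table.no_cluster) | set(table.buried),
    )


def pooled_partition_ranks(
    tables: ScoreTable | Iterable[ScoreTable],
    cap: int = DEFAULT_RANK_CAP,
) -> RankTable:
    """Rank by pooled partitioning across chains.

    Accepts one ScoreTable covering all chains, or several tables (one
    per chain) sharing predictor and direction.  N = floor(mean scored
    residues per chain); the pooled best-to-worst score list is split
    into N contiguous partitions whose sizes differ by at most one
    (remainder going to the earliest partitions); rank = partition
    index, capped.  Residues with equal scores receive the rank of the
    first (best) of them, so ties never straddle a partition boundary.
    """
    if isinstance(tables, ScoreTable):
        tables = [tables]
    tables = list(tables)
    if not tables:
        raise ValidationError("no score tables given")
    predictor = tables[0].predictor_name
    direction = tables[0].direction
    for t in tables[1:]:
        if t.predictor_name != predictor or t.direction != direction:
            raise ValidationError("pooled tables must share predictor and direction")

    merged = ScoreTable(predictor, direction)
    for t in tables:
        dup = set(t.entries) & set(merged.entries)
        if dup:
            raise ValidationError(f"duplicate residues across pooled tables: {sorted(dup)}")
        merged.entries.update(t.entries)
        merged.no_cluster |= t.no_cluster
        merged.buried |= t.buried

    scored = sorted(merged.entries, key=merged.sort_key)
    total = len(scored)
    if total == 0:
        raise ValidationError("no scored residues to pool")
    n_chains = len({r.chain_id for r in scored})
    n_partitions = max(1, total // n_chains)

    base, rem = divmod(total, n_partitions)
    # partition index (1-based) for each sorted position
    position_rank: list[int] = []
    for block in range(1, n_partitions + 1):
        size = base + (1 if block <= rem else 0)
        position_rank.extend([block] * size)

    entries: dict[ResidueId, int] = {}
    pos = 0
    while pos < total:
        # group of equal scores takes the rank of its first member
        end = pos
        s = merged.entries[scored[pos]]
        while end < total and merged.entries[scored[end]] == s:
            end += 1
        rank = min(position_rank[pos], cap)
        for rid in scored[pos:end]:
            entries[rid] = rank
        pos = end
    return RankTable(
        predictor_name=predictor,
        entries=entries,
        cap=cap,
        unranked=merged.no_cluster | merged.buried,
    )


def write_rank_tables(tables: Iterable[RankTable] | dict[str, RankTable], path: str | Path) -> None:
    """Serialize rank tables as one TSV (predictor, chain, resnum, icode, rank)."""
    if isinstance(tables, dict):
        tables = list(tables.values())
    with open(path, "w") as fh:
        fh.write("predictor\tchain\tresnum\ticode\trank\tcap\n")
        for table in tables:
            for rid in sorted(table.entries):
                fh.write(
                    f"{table.predictor_name}\t{rid.chain_id}\t{rid.residue_number}\t"
                    f"{rid.insertion_code or '-'}\t{table.entries[rid]}\t{table.cap}\n"
                )


def read_rank_tables(path: str | Path) -> dict[str, RankTable]:
    """Read back the TSV written by :func:`write_rank_tables`."""
    tables: dict[str, RankTable] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1 or not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise ValidationError(f"line {lineno}: expected 6 columns, got {len(fields)}")
        predictor, chain, resnum, icode, rank, cap = fields
        table = tables.setdefault(predictor, RankTable(predictor, cap=int(cap)))
        rid = make_residue_id(chain, int(resnum), "" if icode == "-" else icode)
        if rid in table.entries:
            raise ValidationError(f"line {lineno}: duplicate residue {rid}")
        table.entries[rid] = int(rank)
    for table in tables.values():
        RankTable(table.predictor_name, dict(table.entries), table.cap)  # re-validate
    return tables
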