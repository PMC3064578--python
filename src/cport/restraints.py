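"""From interface predictions to ambiguous docking restraints.

Predicted residues become *active* residues; surface residues within
6.5 A of any active residue become *passive*.  For every active residue
one ambiguous interaction restraint (AIR) is defined to the set of all
active and passive residues of the partner, written in CNS dialect for
consumption by data-driven docking.  Because heavy overprediction mixes
wrong predictions with right ones, a random 1 - 1/n fraction of the
restraints is discarded per docking trial (n=8 partitions keep 12.5%,
i.e. discard 87.5%).  For ab initio (restraint-free) docking the
center-of-mass distance bound is derived from the protein extents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .consensus import PredictionSet
from .residues import ResidueId, make_residue_id
from .scores import ValidationError
from .structure import ComplexStructure

PASSIVE_RADIUS = 6.5
DEFAULT_PARTITIONS = 8
DEFAULT_EFFECTIVE_DISTANCE = 2.0


@dataclass
class ActivePassive:
    """Active (predicted) and passive (surrounding surface) residues of one chain."""

    chain_id: str
    active: tuple[ResidueId, ...]
    passive: tuple[ResidueId, ...]

    def __post_init__(self) -> None:
        overlap = set(self.active) & set(self.passive)
        if overlap:
            raise ValidationError(f"residues both active and passive: {sorted(overlap)}")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tresnum\ticode\trole\n")
            for role, rids in (("active", self.active), ("passive", self.passive)):
                for rid in rids:
                    fh.write(f"{rid.chain_id}\t{rid.residue_number}\t{rid.insertion_code or '-'}\t{role}\n")


def define_active_passive(
    pred: PredictionSet | set[ResidueId],
    surface: set[ResidueId],
    structure: ComplexStructure,
    chain_id: str | None = None,
    radius: float = PASSIVE_RADIUS,
) -> ActivePassive:
    """Active = predicted residues present in the structure; passive =
    surface residues with any heavy atom within ``radius`` of any active
    residue's heavy atoms, minus the active set."""
    predicted = pred.residues if isinstance(pred, PredictionSet) else set(pred)
    residx = structure.residue_index()
    if chain_id is None:
        chains = {r.chain_id for r in predicted if r in residx}
        if len(chains) != 1:
            raise ValidationError("predictions span several chains; pass chain_id explicitly")
        chain_id = chains.pop()
    active = sorted(r for r in predicted if r in residx and r.chain_id == chain_id)
    if not active:
        return ActivePassive(chain_id, (), ())
    active_atoms = np.concatenate([structure.coords[residx[r]] for r in active])
    tree = cKDTree(active_atoms)
    passive = []
    for rid in sorted(surface):
        if rid.chain_id != chain_id or rid in set(active) or rid not in residx:
            continue
        d, _ = tree.query(structure.coords[residx[rid]], k=1)
        if np.min(d) <= radius:
            passive.append(rid)
    return ActivePassive(chain_id, tuple(active), tuple(passive))


@dataclass(frozen=True)
class Restraint:
    """One ambiguous restraint: anchor active residue vs partner residue set."""

    anchor: ResidueId
    targets: tuple[ResidueId, ...]
    distance: float = DEFAULT_EFFECTIVE_DISTANCE
    lower: float = DEFAULT_EFFECTIVE_DISTANCE
    upper: float = 0.0


@dataclass
class AIRTable:
    """Ambiguous interaction restraints for one receptor/ligand pairing."""

    restraints: tuple[Restraint, ...] = ()
    header: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.restraints)


def build_air_table(
    ap_receptor: ActivePassive,
    ap_ligand: ActivePassive,
    effective_distance: float = DEFAULT_EFFECTIVE_DISTANCE,
) -> AIRTable:
    """One restraint per active residue, targeting all partner active+passive residues."""
    if not ap_receptor.active or not ap_ligand.active:
        raise ValidationError("both chains need at least one active residue; docking would be unrestrained")
    restraints = []
    for ap, partner in ((ap_receptor, ap_ligand), (ap_ligand, ap_receptor)):
        targets = tuple(sorted(set(partner.active) | set(partner.passive)))
        for anchor in ap.active:
            restraints.append(
                Restraint(anchor, targets, effective_distance, effective_distance, 0.0)
            )
    return AIRTable(tuple(restraints))


def _selection(rid: ResidueId) -> str:
    icode = f" and insert {rid.insertion_code}" if rid.insertion_code else ""
    return f"(resid {rid.residue_number} and segid {rid.chain_id}{icode})"


def write_air_table(
    table: AIRTable | None = None,
    path: str | Path | None = None,
    ap_receptor: ActivePassive | None = None,
    ap_ligand: ActivePassive | None = None,
    effective_distance: float = DEFAULT_EFFECTIVE_DISTANCE,
    header: dict[str, str] | None = None,
) -> AIRTable:
    """Write a CNS-dialect ambiguous-restraint file (ambig .tbl).

    Either pass a prebuilt ``table``, or the two ActivePassive sets to
    build one.  Per active residue one ``assign`` statement enumerates
    the OR-combination over all partner active+passive residues.  The
    emitted text is deterministic for a fixed input.  Returns the table
    written, so ``read_air_table(write_air_table(...))`` round-trips.
    """
    if table is None:
        if ap_receptor is None or ap_ligand is None:
            raise ValidationError("need a table or both ActivePassive sets")
        table = build_air_table(ap_receptor, ap_ligand, effective_distance)
    if path is None:
        raise ValidationError("need an output path")
    lines = []
    lines.append("! Ambiguous interaction restraints (CNS dialect).")
    lines.append("! One assign per active residue; targets are OR-combined and")
    lines.append("! evaluated with the docking program's effective-distance")
    lines.append("! (1/r^6-style) ambiguity averaging.")
    for key, value in {**table.header, **(header or {})}.items():
        lines.append(f"! {key}: {value}")
    for r in table.restraints:
        lines.append(f"assign {_selection(r.anchor)}")
        lines.append("       (")
        for k, target in enumerate(r.targets):
            prefix = "        " if k == 0 else "     or "
            lines.append(prefix + _selection(target))
        lines.append(f"       ) {r.distance:.1f} {r.lower:.1f} {r.upper:.1f}")
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")
    return table


def read_air_table(path: str | Path) -> AIRTable:
    """Read back a .tbl file emitted by :func:`write_air_table`.

    This parses only the dialect this package writes; it is not a
    general CNS restraint parser.
    """
    import re

    sel_re = re.compile(r"\(resid\s+(-?\d+)\s+and\s+segid\s+(\S+?)(?:\s+and\s+insert\s+(\S+))?\)")
    header: dict[str, str] = {}
    restraints: list[Restraint] = []
    anchor: ResidueId | None = None
    targets: list[ResidueId] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("!"):
            if ":" in line:
                key, _, value = line[1:].partition(":")
                header[key.strip()] = value.strip()
            continue
        if line.startswith("assign"):
            m = sel_re.search(line)
            if not m:
                raise ValidationError(f"cannot parse assign line: {line!r}")
            anchor = make_residue_id(m.group(2), int(m.group(1)), m.group(3))
            targets = []
        elif line.startswith(")"):
            parts = line[1:].split()
            if anchor is None or len(parts) != 3:
                raise ValidationError(f"cannot parse distance line: {line!r}")
            d, lo, up = (float(p) for p in parts)
            restraints.append(Restraint(anchor, tuple(targets), d, lo, up))
            anchor = None
        else:
            m = sel_re.search(line)
            if m:
                targets.append(make_residue_id(m.group(2), int(m.group(1)), m.group(3)))
    return AIRTable(tuple(restraints), header)


def random_restraint_subset(
    table: AIRTable,
    n_partitions: int = DEFAULT_PARTITIONS,
    seed: int = 0,
) -> AIRTable:
    """Keep one of ``n_partitions`` random near-equal parts of the restraints.

    With the default 8 partitions, 87.5% of the restraints are
    discarded at random, mirroring per-trial restraint subsampling in
    data-driven docking.  The partition is a disjoint cover with part
    sizes differing by at most one; the same seed always keeps the same
    part.
    """
    if n_partitions < 1:
        raise ValidationError("n_partitions must be >= 1")
    parts = partition_restraints(table, n_partitions, seed)
    return AIRTable(parts[0], dict(table.header))


def partition_restraints(
    table: AIRTable,
    n_partitions: int,
    seed: int,
) -> list[tuple[Restraint, ...]]:
    """Seeded shuffle of the restraints split into near-equal parts."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(table.restraints))
    shuffled = [table.restraints[i] for i in order]
    base, rem = divmod(len(shuffled), n_partitions)
    parts = []
    pos = 0
    for k in range(n_partitions):
        size = base + (1 if k < rem else 0)
        parts.append(tuple(shuffled[pos:pos + size]))
        pos += size
    return parts


@dataclass(frozen=True)
class ComDimensions:
    """Extents of a protein along its principal axes, in Angstrom."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) < 0:
            raise ValidationError("extents must be non-negative")


def principal_dimensions(structure: ComplexStructure, chains: Sequence[str] | None = None) -> ComDimensions:
    """Extents along the principal axes of the heavy-atom coordinates.

    The molecular alignment tensor axes are approximated by the
    eigenvectors of the coordinate covariance matrix; each extent is the
    max-min spread of the projections on one axis.
    """
    mask = structure.atom_mask(chains=chains)
    pts = structure.coords[mask]
    if len(pts) == 0:
        raise ValidationError("no atoms in selection")
    centered = pts - pts.mean(axis=0)
    if len(pts) == 1:
        return ComDimensions(0.0, 0.0, 0.0)
    _, vecs = np.linalg.eigh(np.cov(centered.T))
    proj = centered @ vecs
    ext = proj.max(axis=0) - proj.min(axis=0)
    dz, dy, dx = sorted(float(e) for e in ext)  # dx = largest
    return ComDimensions(dx, dy, dz)


def com_upper_bound(dims_i: ComDimensions, dims_j: ComDimensions) -> float:
    """Center-of-mass distance bound 1 + (dx_i+dy_i+dz_i+dx_j+dy_j+dz_j)/12."""
    total = dims_i.dx + dims_i.dy + dims_i.dz + dims_j.dx + dims_j.dy + dims_j.dz
    return 1.0 + total / 12.0
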