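"""Structures, interfaces, accessibility and ground-truth labels.

The geometric definitions used throughout:

* interface residue — any heavy atom closer than 5 A to the partner
  group in the reference complex;
* surface residue — relative side-chain or main-chain solvent
  accessibility of at least 15% in the unbound form;
* evaluation labels — interface taken from the reference complex,
  surface from the unbound form; interface residues missing or buried
  in the unbound form stay labelled interface but are flagged
  unpredictable, which caps the achievable sensitivity at (i-u)/i.

PDB reading and writing go through Biopython; coordinates and atom
metadata live in plain numpy arrays so distance computations stay
vectorized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .residues import ResidueId, make_residue_id
from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE, shrake_rupley
from .scores import ValidationError

BACKBONE_ATOMS = ("N", "CA", "C", "O")
#: Main-chain atom names for the accessibility split; OXT counts as main chain.
MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

INTERFACE_CUTOFF = 5.0
SURFACE_THRESHOLD = 0.15

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class ComplexStructure:
    """Heavy atoms of a (possibly multi-chain) structure, numpy-backed.

    Chains are partitioned into a receptor group and a ligand group;
    every cross-group distance operation (interface, contacts, RMSDs)
    refers to that partition.
    """

    residue_ids: list[ResidueId]          # per atom
    residue_names: list[str]              # per atom
    atom_names: list[str]                 # per atom
    elements: np.ndarray                  # per atom, element symbols
    coords: np.ndarray                    # (n_atoms, 3), Angstrom
    receptor_chains: tuple[str, ...] = ()
    ligand_chains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must be (n_atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise ValidationError("non-finite coordinates")
        n = len(self.coords)
        if not (len(self.residue_ids) == len(self.residue_names) == len(self.atom_names) == len(self.elements) == n):
            raise ValidationError("per-atom arrays have inconsistent lengths")

    # ---- indexing helpers -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for rid in self.residue_ids:
            seen.setdefault(rid.chain_id, None)
        return list(seen)

    def residues(self) -> list[ResidueId]:
        """Unique residues in atom order."""
        seen: dict[ResidueId, None] = {}
        for rid in self.residue_ids:
            seen.setdefault(rid, None)
        return list(seen)

    def residue_name(self, rid: ResidueId) -> str:
        idx = self.residue_index().get(rid)
        if idx is None:
            raise KeyError(rid)
        return self.residue_names[idx[0]]

    def residue_index(self) -> dict[ResidueId, list[int]]:
        if not hasattr(self, "_residx"):
            idx: dict[ResidueId, list[int]] = {}
            for i, rid in enumerate(self.residue_ids):
                idx.setdefault(rid, []).append(i)
            self._residx = idx
        return self._residx

    def atom_mask(self, chains: Sequence[str] | None = None, atom_names: Iterable[str] | None = None) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if chains is not None:
            chain_set = set(chains)
            mask &= np.array([rid.chain_id in chain_set for rid in self.residue_ids])
        if atom_names is not None:
            names = set(atom_names)
            mask &= np.array([a in names for a in self.atom_names])
        return mask

    def group_chains(self, group: str) -> tuple[str, ...]:
        if group == "receptor":
            return self.receptor_chains
        if group == "ligand":
            return self.ligand_chains
        raise ValidationError(f"unknown group {group!r}")

    def swapped_groups(self) -> "ComplexStructure":
        out = self.copy()
        out.receptor_chains, out.ligand_chains = self.ligand_chains, self.receptor_chains
        return out

    def copy(self) -> "ComplexStructure":
        return ComplexStructure(
            list(self.residue_ids),
            list(self.residue_names),
            list(self.atom_names),
            np.array(self.elements),
            self.coords.copy(),
            self.receptor_chains,
            self.ligand_chains,
        )

    def transformed(
        self,
        rotation: np.ndarray | None = None,
        translation: np.ndarray | Sequence[float] | None = None,
        chains: Sequence[str] | None = None,
        about: np.ndarray | Sequence[float] | None = None,
    ) -> "ComplexStructure":
        """Apply x' = R (x - about) + about + t to the selected chains.

        ``about`` defaults to the centroid of the selected atoms, so a
        pure rotation pivots in place and a pure translation shifts by
        exactly ``translation``.
        """
        out = self.copy()
        mask = self.atom_mask(chains=chains)
        pts = out.coords[mask]
        center = np.asarray(about, dtype=float) if about is not None else pts.mean(axis=0)
        if rotation is not None:
            pts = (pts - center) @ np.asarray(rotation, dtype=float).T + center
        if translation is not None:
            pts = pts + np.asarray(translation, dtype=float)
        out.coords[mask] = pts
        return out

    def restrict_chains(self, chains: Sequence[str]) -> "ComplexStructure":
        mask = self.atom_mask(chains=chains)
        keep = np.where(mask)[0]
        return ComplexStructure(
            [self.residue_ids[i] for i in keep],
            [self.residue_names[i] for i in keep],
            [self.atom_names[i] for i in keep],
            self.elements[keep],
            self.coords[keep],
            tuple(c for c in self.receptor_chains if c in chains),
            tuple(c for c in self.ligand_chains if c in chains),
        )

    # ---- PDB I/O ----------------------------------------------------------
    @classmethod
    def from_pdb(
        cls,
        path: str | Path,
        receptor_chains: Sequence[str] | None = None,
        ligand_chains: Sequence[str] | None = None,
    ) -> "ComplexStructure":
        """Parse the first model of a PDB file.

        Hydrogens, waters and heteroatom records are dropped; for
        disordered atoms the highest-occupancy conformer is kept
        (Biopython's default selection).  If no chain partition is
        given, the first chain is the receptor and the rest the ligand.
        """
        from Bio.PDB import PDBParser

        parser = PDBParser(QUIET=True)
        model = next(parser.get_structure("s", str(path)).get_models())
        residue_ids, residue_names, atom_names, elements, coords = [], [], [], [], []
        for chain in model:
            for residue in chain:
                hetflag, resseq, icode = residue.id
                if hetflag != " " or residue.resname.strip() in _WATER_NAMES:
                    continue
                rid = make_residue_id(chain.id, resseq, icode)
                for atom in residue:
                    element = (atom.element or "").strip().upper()
                    if element == "H" or (not element and atom.get_name().startswith("H")):
                        continue
                    residue_ids.append(rid)
                    residue_names.append(residue.resname.strip())
                    atom_names.append(atom.get_name().strip())
                    elements.append(element or atom.get_name().strip()[0])
                    coords.append(atom.coord)
        structure = cls(
            residue_ids,
            residue_names,
            atom_names,
            np.array(elements, dtype=object),
            np.array(coords, dtype=float),
        )
        all_chains = structure.chains
        if receptor_chains is None and ligand_chains is None:
            receptor_chains = all_chains[:1]
            ligand_chains = all_chains[1:]
        elif receptor_chains is None:
            receptor_chains = [c for c in all_chains if c not in set(ligand_chains or ())]
        elif ligand_chains is None:
            ligand_chains = [c for c in all_chains if c not in set(receptor_chains)]
        structure.receptor_chains = tuple(receptor_chains or ())
        structure.ligand_chains = tuple(ligand_chains or ())
        return structure

    def to_pdb(self, path: str | Path) -> None:
        """Write a minimal single-model PDB file."""
        from Bio.PDB import PDBIO, StructureBuilder

        builder = StructureBuilder.StructureBuilder()
        builder.init_structure("s")
        builder.init_model(0)
        current_chain = None
        current_rid = None
        serial = 1
        for i, rid in enumerate(self.residue_ids):
            if rid.chain_id != current_chain:
                builder.init_chain(rid.chain_id)
                builder.init_seg("    ")
                current_chain = rid.chain_id
                current_rid = None
            if rid != current_rid:
                builder.init_residue(self.residue_names[i], " ", rid.residue_number, rid.insertion_code or " ")
                current_rid = rid
            builder.init_atom(
                self.atom_names[i],
                self.coords[i].astype(np.float32),
                0.0,
                1.0,
                " ",
                self.atom_names[i].center(4) if len(self.atom_names[i]) < 4 else self.atom_names[i],
                serial,
                str(self.elements[i]),
            )
            serial += 1
        io = PDBIO()
        io.set_structure(builder.get_structure())
        io.save(str(path))


# ---- contacts and interfaces ---------------------------------------------

def residue_contacts(
    complex_structure: ComplexStructure,
    cutoff: float = INTERFACE_CUTOFF,
) -> set[tuple[ResidueId, ResidueId]]:
    """Cross-group residue pairs with heavy-atom distance strictly below cutoff.

    Pairs are (receptor residue, ligand residue).
    """
    cs = complex_structure
    if not cs.receptor_chains or not cs.ligand_chains:
        raise ValidationError("structure has no receptor/ligand partition")
    rec_mask = cs.atom_mask(chains=cs.receptor_chains)
    lig_mask = cs.atom_mask(chains=cs.ligand_chains)
    rec_idx = np.where(rec_mask)[0]
    lig_idx = np.where(lig_mask)[0]
    if len(rec_idx) == 0 or len(lig_idx) == 0:
        raise ValidationError("a group has no atoms")
    tree_r = cKDTree(cs.coords[rec_idx])
    tree_l = cKDTree(cs.coords[lig_idx])
    pairs = set()
    for ai, neighbours in enumerate(tree_r.query_ball_tree(tree_l, cutoff)):
        for bj in neighbours:
            i, j = rec_idx[ai], lig_idx[bj]
            d = np.linalg.norm(cs.coords[i] - cs.coords[j])
            if d < cutoff:  # strict: exactly-at-cutoff pairs are excluded
                pairs.add((cs.residue_ids[i], cs.residue_ids[j]))
    return pairs


def interface_residues(
    complex_structure: ComplexStructure,
    cutoff: float = INTERFACE_CUTOFF,
) -> set[ResidueId]:
    """Residues of either group with any heavy atom < cutoff from the partner."""
    pairs = residue_contacts(complex_structure, cutoff)
    out: set[ResidueId] = set()
    for r, l in pairs:
        out.add(r)
        out.add(l)
    return out


# ---- accessibility --------------------------------------------------------

@dataclass
class AccessibilityTable:
    """Relative side-chain / main-chain accessibility per residue."""

    entries: dict[ResidueId, tuple[float, float]] = field(default_factory=dict)

    def __getitem__(self, rid: ResidueId) -> tuple[float, float]:
        return self.entries[rid]

    def __contains__(self, rid: ResidueId) -> bool:
        return rid in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return self.entries.items()


def relative_accessibility(
    structure: ComplexStructure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    sasa_backend=None,
) -> AccessibilityTable:
    """Per-residue relative side-chain and main-chain accessibility.

    Absolute areas come from an internal Shrake-Rupley computation (or
    ``sasa_backend(coords, elements, probe)`` if given).  The reference
    state of a residue is the residue's own atoms computed in isolation,
    fully exposed; relative accessibility is the in-context area divided
    by that reference.  This reference is exact for any atom subset,
    including reduced synthetic residues, and makes a fully exposed free
    residue come out at exactly 1.  Glycine has no side-chain atoms
    beyond CA; following the usual accessibility convention its CA is
    counted as the side chain.
    """
    backend = sasa_backend or (lambda c, e, p: shrake_rupley(c, e, probe=p, n_points=n_points))
    areas = np.asarray(backend(structure.coords, structure.elements, probe))
    entries: dict[ResidueId, tuple[float, float]] = {}
    residx = structure.residue_index()
    for rid, atom_idx in residx.items():
        resname = structure.residue_names[atom_idx[0]]
        names = [structure.atom_names[i] for i in atom_idx]
        if resname == "GLY":
            side = [i for i, nm in zip(atom_idx, names) if nm == "CA"]
        else:
            side = [i for i, nm in zip(atom_idx, names) if nm not in MAIN_CHAIN_ATOMS]
        main = [i for i in atom_idx if i not in set(side)]

        iso = np.asarray(backend(structure.coords[atom_idx], structure.elements[atom_idx], probe))
        iso_by_atom = dict(zip(atom_idx, iso))

        def _rel(idx: list[int]) -> float:
            ref = sum(iso_by_atom[i] for i in idx)
            if ref <= 0.0:
                return 0.0
            return float(sum(areas[i] for i in idx) / ref)

        entries[rid] = (_rel(side), _rel(main))
    return AccessibilityTable(entries)


def surface_residues(
    acc: AccessibilityTable | Mapping[ResidueId, tuple[float, float]],
    threshold: float = SURFACE_THRESHOLD,
) -> set[ResidueId]:
    """Residues whose side-chain OR main-chain relative accessibility >= threshold."""
    items = acc.items() if hasattr(acc, "items") else acc
    return {rid for rid, (side, main) in items if side >= threshold or main >= threshold}


# ---- ground-truth labels --------------------------------------------------

INTERFACE = "interface"
SURFACE_NON_INTERFACE = "surface_non_interface"
BURIED_OR_MISSING = "buried_or_missing"


@dataclass
class ResidueLabels:
    """Ground-truth classes (interface / surface / buried-or-missing).

    ``unpredictable`` flags interface residues missing or buried in the
    unbound structure: they stay in the evaluation universe and count as
    false negatives when missed, but no predictor can ever select them.
    """

    classes: dict[ResidueId, str] = field(default_factory=dict)
    unpredictable: set[ResidueId] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = {r: c for r, c in self.classes.items() if c not in (INTERFACE, SURFACE_NON_INTERFACE, BURIED_OR_MISSING)}
        if bad:
            raise ValidationError(f"unknown label classes: {bad}")
        stray = self.unpredictable - {r for r, c in self.classes.items() if c == INTERFACE}
        if stray:
            raise ValidationError(f"unpredictable residues that are not interface: {sorted(stray)}")

    @property
    def interface(self) -> set[ResidueId]:
        return {r for r, c in self.classes.items() if c == INTERFACE}

    @property
    def surface_non_interface(self) -> set[ResidueId]:
        return {r for r, c in self.classes.items() if c == SURFACE_NON_INTERFACE}

    @property
    def universe(self) -> set[ResidueId]:
        """Evaluation universe: surface residues plus all interface residues."""
        return self.interface | self.surface_non_interface

    def chains(self) -> list[str]:
        return sorted({r.chain_id for r in self.universe})

    # -- printed-count arithmetic (all fractions of the universe/interface) --
    def interface_fraction(self) -> float:
        return len(self.interface) / len(self.universe)

    def unpredictable_fraction(self) -> float:
        """Fraction of interface residues that cannot be predicted."""
        return len(self.unpredictable) / len(self.interface)

    def max_achievable_sensitivity(self) -> float:
        """(i - u) / i for i interface residues of which u are unpredictable."""
        i = len(self.interface)
        return (i - len(self.unpredictable)) / i

    def predictable_fraction(self) -> float:
        """Fraction of the evaluation universe a perfect predictor could hit."""
        return (len(self.interface) - len(self.unpredictable)) / len(self.universe)

    @classmethod
    def from_sets(
        cls,
        interface: set[ResidueId],
        surface: set[ResidueId],
        unpredictable: set[ResidueId] | None = None,
        buried_or_missing: set[ResidueId] | None = None,
    ) -> "ResidueLabels":
        classes: dict[ResidueId, str] = {}
        for rid in buried_or_missing or set():
            classes[rid] = BURIED_OR_MISSING
        for rid in surface:
            classes[rid] = SURFACE_NON_INTERFACE
        for rid in interface:  # interface wins over surface
            classes[rid] = INTERFACE
        return cls(classes, set(unpredictable or set()) & interface)

    @classmethod
    def from_counts(cls, n_interface: int, n_unpredictable: int, n_universe: int, chain_id: str = "A") -> "ResidueLabels":
        """Synthetic labels with the given composition, for arithmetic checks."""
        if not (0 <= n_unpredictable <= n_interface <= n_universe):
            raise ValidationError("need 0 <= unpredictable <= interface <= universe")
        classes = {}
        unpredictable = set()
        for i in range(1, n_universe + 1):
            rid = ResidueId(chain_id, i)
            classes[rid] = INTERFACE if i <= n_interface else SURFACE_NON_INTERFACE
            if i <= n_unpredictable:
                unpredictable.add(rid)
        return cls(classes, unpredictable)


def make_labels(
    reference: ComplexStructure,
    unbound: ComplexStructure,
    interface_cutoff: float = INTERFACE_CUTOFF,
    surface_threshold: float = SURFACE_THRESHOLD,
    unbound_accessibility: AccessibilityTable | None = None,
) -> ResidueLabels:
    """Derive evaluation labels from a reference complex and its unbound form.

    Interface residues come from the reference complex (5 A heavy-atom
    rule); surface residues from the unbound form (15% accessibility
    rule).  Interface residues absent from, or buried in, the unbound
    form are kept as interface but flagged unpredictable.
    """
    iface = interface_residues(reference, interface_cutoff)
    if unbound_accessibility is None:
        unbound_accessibility = relative_accessibility(unbound)
    surface = surface_residues(unbound_accessibility, surface_threshold)
    unbound_present = set(unbound.residues())
    unpredictable = {r for r in iface if r not in unbound_present or r not in surface}
    buried = (set(reference.residues()) | unbound_present) - iface - surface
    return ResidueLabels.from_sets(iface, surface, unpredictable, buried)


# ---- contact counting over decoy ensembles --------------------------------

def contact_counts(
    ensemble,
    cutoff: float = INTERFACE_CUTOFF,
    top_k: int | None = None,
) -> dict[ResidueId, int]:
    """Number of selected decoys in which each residue contacts the partner.

    ``ensemble`` is a DecoyEnsemble or any iterable of ComplexStructure;
    ``top_k`` restricts the count to the first k decoys (rank order).
    """
    decoys = getattr(ensemble, "decoys", ensemble)
    decoys = list(decoys)
    if top_k is not None:
        decoys = decoys[:top_k]
    counts: dict[ResidueId, int] = {}
    for decoy in decoys:
        for rid in interface_residues(decoy, cutoff):
            counts[rid] = counts.get(rid, 0) + 1
    return counts


def write_labels_tsv(labels: ResidueLabels, path: str | Path) -> None:
    """Serialize labels (chain, resnum, icode, class, unpredictable flag)."""
    with open(path, "w") as fh:
        fh.write("chain\tresnum\ticode\tclass\tunpredictable\n")
        for rid in sorted(labels.classes):
            fh.write(
                f"{rid.chain_id}\t{rid.residue_number}\t{rid.insertion_code or '-'}\t"
                f"{labels.classes[rid]}\t{int(rid in labels.unpredictable)}\n"
            )


def read_labels_tsv(path: str | Path) -> ResidueLabels:
    """Read back the TSV written by :func:`write_labels_tsv`."""
    classes: dict[ResidueId, str] = {}
    unpredictable: set[ResidueId] = set()
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1 or not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValidationError(f"line {lineno}: expected 5 columns, got {len(fields)}")
        chain, resnum, icode, cls, unpred = fields
        rid = make_residue_id(chain, int(resnum), "" if icode == "-" else icode)
        if rid in classes:
            raise ValidationError(f"line {lineno}: duplicate residue {rid}")
        classes[rid] = cls
        if unpred.strip() == "1":
            unpredictable.add(rid)
    return ResidueLabels(classes, unpredictable)
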