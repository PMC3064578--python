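"""CAPRI-style evaluation of docking decoys against a reference complex.

Per decoy, three statistics are computed:

* l-RMSD — backbone RMSD over the ligand after least-squares fit on the
  receptor backbone;
* i-RMSD — backbone RMSD over the reference interface residues (any
  heavy atom within 10 A of the partner) after fitting on those same
  atoms;
* fnat — fraction of the reference's residue-residue contacts (5 A
  heavy-atom) reproduced in the decoy.

Stars: one star requires i-RMSD < 4 or l-RMSD < 10, and fnat >= 0.1;
two stars i-RMSD < 2 or l-RMSD < 5, and fnat >= 0.3; three stars
i-RMSD < 1 or l-RMSD < 1, and fnat >= 0.5.  At the rigid-body stage
(and for symmetry-related complexes) the fnat clauses are skipped.
Enrichment of correct decoys among a top-ranked selection is scored
with the hypergeometric distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .residues import ResidueId
from .scores import ValidationError
from .structure import BACKBONE_ATOMS, ComplexStructure, residue_contacts

IRMSD_INTERFACE_CUTOFF = 10.0
FNAT_CONTACT_CUTOFF = 5.0

#: (i-RMSD, l-RMSD, fnat) thresholds per star level, best first.
STAR_CRITERIA = (
    (3, 1.0, 1.0, 0.5),
    (2, 2.0, 5.0, 0.3),
    (1, 4.0, 10.0, 0.1),
)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping mobile onto target.

    Returns (R, t) with R @ x + t the superposed coordinates; the
    reflection branch is rejected so R is always a proper rotation.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValidationError("point sets must both be (n, 3)")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    diff = np.asarray(a, float) - np.asarray(b, float)
    return float(np.sqrt(np.einsum("ij,ij->", diff, diff) / len(diff)))


def _matched_coords(
    decoy: ComplexStructure,
    reference: ComplexStructure,
    residues: set[ResidueId] | None,
    chains: Sequence[str] | None,
    atom_names: Sequence[str] = BACKBONE_ATOMS,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of atoms shared by decoy and reference, in a fixed order."""
    wanted = set(atom_names)
    chain_set = set(chains) if chains is not None else None

    def index(cs: ComplexStructure) -> dict[tuple[ResidueId, str], int]:
        out = {}
        for i, rid in enumerate(cs.residue_ids):
            if chain_set is not None and rid.chain_id not in chain_set:
                continue
            if residues is not None and rid not in residues:
                continue
            if cs.atom_names[i] in wanted:
                out[(rid, cs.atom_names[i])] = i
        return out

    di, ri = index(decoy), index(reference)
    keys = sorted(set(di) & set(ri))
    if not keys:
        raise ValidationError("no shared atoms between decoy and reference in selection")
    return decoy.coords[[di[k] for k in keys]], reference.coords[[ri[k] for k in keys]]


def lrmsd(decoy: ComplexStructure, reference: ComplexStructure) -> float:
    """Ligand backbone RMSD after least-squares fit on the receptor backbone."""
    rec_d, rec_r = _matched_coords(decoy, reference, None, reference.receptor_chains)
    lig_d, lig_r = _matched_coords(decoy, reference, None, reference.ligand_chains)
    R, t = kabsch(rec_d, rec_r)
    return rmsd(lig_d @ R.T + t, lig_r)


def irmsd(
    decoy: ComplexStructure,
    reference: ComplexStructure,
    interface_cutoff: float = IRMSD_INTERFACE_CUTOFF,
) -> float:
    """Backbone RMSD over the reference-defined interface after interface fit."""
    pairs = residue_contacts(reference, interface_cutoff)
    iface = {r for pair in pairs for r in pair}
    if not iface:
        raise ValidationError("reference has no interface at the i-RMSD cutoff")
    d, r = _matched_coords(decoy, reference, iface, None)
    R, t = kabsch(d, r)
    return rmsd(d @ R.T + t, r)


def fnat(
    decoy: ComplexStructure,
    reference: ComplexStructure,
    contact_cutoff: float = FNAT_CONTACT_CUTOFF,
) -> float:
    """Fraction of the reference's cross-group residue contacts found in the decoy."""
    native = residue_contacts(reference, contact_cutoff)
    if not native:
        raise ValidationError("reference has no native contacts")
    found = residue_contacts(decoy, contact_cutoff)
    return len(native & found) / len(native)


def classify_stars(i_rmsd: float, l_rmsd: float, fnat_value: float, apply_fnat: bool = True) -> int:
    """CAPRI star level (0-3) from the three statistics.

    With ``apply_fnat=False`` (rigid-body stage, symmetry-related
    complexes) the fnat clauses are skipped.
    """
    for stars, i_max, l_max, f_min in STAR_CRITERIA:
        if (i_rmsd < i_max or l_rmsd < l_max) and (not apply_fnat or fnat_value >= f_min):
            return stars
    return 0


@dataclass(frozen=True)
class CapriResult:
    i_rmsd: float
    l_rmsd: float
    fnat: float
    stars: int


def evaluate_decoy(
    decoy: ComplexStructure,
    reference: ComplexStructure,
    apply_fnat: bool = True,
) -> CapriResult:
    i = irmsd(decoy, reference)
    l = lrmsd(decoy, reference)
    f = fnat(decoy, reference)
    return CapriResult(i, l, f, classify_stars(i, l, f, apply_fnat))


def apply_chain_mapping(decoy: ComplexStructure, mapping: Mapping[str, str]) -> ComplexStructure:
    """Relabel decoy chains (decoy chain -> reference chain) before evaluation."""
    out = decoy.copy()
    out.residue_ids = [
        ResidueId(mapping.get(r.chain_id, r.chain_id), r.residue_number, r.insertion_code)
        for r in decoy.residue_ids
    ]
    remap = lambda cs: tuple(mapping.get(c, c) for c in cs)
    out.receptor_chains = remap(decoy.receptor_chains)
    out.ligand_chains = remap(decoy.ligand_chains)
    if hasattr(out, "_residx"):
        del out._residx
    return out


def best_of_mappings(
    decoy: ComplexStructure,
    reference: ComplexStructure,
    mappings: Sequence[Mapping[str, str]],
    apply_fnat: bool = True,
) -> CapriResult:
    """Evaluate the decoy under every chain correspondence and keep the best.

    For symmetric (e.g. homodimeric) complexes the decoy fits the
    reference in more than one way; each statistic is taken from its own
    best mapping (lowest i-RMSD, lowest l-RMSD, highest fnat).
    """
    if not mappings:
        raise ValidationError("need at least one chain mapping")
    results = [evaluate_decoy(apply_chain_mapping(decoy, m), reference, apply_fnat) for m in mappings]
    i = min(r.i_rmsd for r in results)
    l = min(r.l_rmsd for r in results)
    f = max(r.fnat for r in results)
    return CapriResult(i, l, f, classify_stars(i, l, f, apply_fnat))


@dataclass
class DecoyEnsemble:
    """Ranked docking models sharing the reference's residue universe."""

    reference: ComplexStructure
    decoys: list[ComplexStructure] = field(default_factory=list)
    stage: str = "rigid_body"  # or "refined"

    def __post_init__(self) -> None:
        if self.stage not in ("rigid_body", "refined"):
            raise ValidationError(f"unknown stage {self.stage!r}")

    def __len__(self) -> int:
        return len(self.decoys)


def evaluate_ensemble(
    ensemble: DecoyEnsemble,
    apply_fnat: bool | None = None,
    mappings: Sequence[Mapping[str, str]] | None = None,
) -> list[CapriResult]:
    """Per-decoy CAPRI statistics in rank order.

    ``apply_fnat`` defaults to False at the rigid-body stage and True
    for refined decoys; explicit ``mappings`` trigger symmetry-aware
    evaluation (which never applies the fnat criterion).
    """
    if mappings is not None and len(mappings) > 1:
        apply_fnat = False
    if apply_fnat is None:
        apply_fnat = ensemble.stage == "refined"
    out = []
    for decoy in ensemble.decoys:
        if mappings is not None:
            out.append(best_of_mappings(decoy, ensemble.reference, mappings, apply_fnat))
        else:
            out.append(evaluate_decoy(decoy, ensemble.reference, apply_fnat))
    return out


def write_capri_tsv(results: Sequence[CapriResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\ti_rmsd\tl_rmsd\tfnat\tstars\n")
        for k, r in enumerate(results, start=1):
            fh.write(f"{k}\t{r.i_rmsd:.4f}\t{r.l_rmsd:.4f}\t{r.fnat:.4f}\t{r.stars}\n")


def enrichment_pvalue(
    n_total: int,
    k_correct_total: int,
    n_selected: int,
    k_correct_selected: int,
) -> tuple[float, float]:
    """Hypergeometric enrichment/depletion of correct decoys in a selection.

    Drawing ``n_selected`` of ``n_total`` decoys of which
    ``k_correct_total`` are correct, returns
    ``(P(X >= k_correct_selected), P(X <= k_correct_selected))``.
    The two tails share the point mass at k, so they sum to >= 1.
    """
    if not (0 <= k_correct_total <= n_total and 0 <= n_selected <= n_total):
        raise ValidationError("inconsistent hypergeometric parameters")
    if not (0 <= k_correct_selected <= min(k_correct_total, n_selected)):
        raise ValidationError("k_correct_selected out of range")
    dist = sps.hypergeom(n_total, k_correct_total, n_selected)
    p_enrich = float(dist.sf(k_correct_selected - 1))
    p_deplete = float(dist.cdf(k_correct_selected))
    return min(p_enrich, 1.0), min(p_deplete, 1.0)


def first_star_rank(results: Sequence[CapriResult], min_stars: int = 1) -> int | None:
    """1-based rank of the first decoy at or above ``min_stars``; None if absent."""
    for k, r in enumerate(results, start=1):
        if r.stars >= min_stars:
            return k
    return None
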