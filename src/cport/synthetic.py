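"""Synthetic fixtures: predictor score tables and toy docking systems.

Two generators cover everything the consensus pipeline consumes:

* :func:`simulate_scores` emits six predictor score tables over
  multi-chain proteins with a planted interface.  Scores follow a
  correlated binormal model: per predictor p, a residue's latent score
  is z_p = rho*u + sqrt(1-rho^2)*e_p + mu*[interface], with u a shared
  per-residue latent (inter-predictor correlation rho) and mu chosen so
  the predictor's theoretical AUC equals the requested signal strength
  (mu = sqrt(2) * Phi^-1(AUC)).  A signal of 1.0 separates the classes
  completely.  A fraction of the interface is flagged buried in every
  table, emulating interface residues missing or buried in the unbound
  form (unpredictable by construction).

* :func:`toy_complex` builds a two-chain pseudo-backbone complex (N,
  CA, C, O, CB per residue) whose chains touch across a central contact
  window, and :func:`make_decoys` derives rigid-body decoys with
  analytically known ligand RMSDs (a pure translation t has l-RMSD |t|
  after the receptor fit).

Defaults mirror the statistical shape of a docking-benchmark training
set: ~130 scored residues per chain, 15% of them interface, weak
individual predictors (AUC 0.7), moderate inter-predictor correlation,
and 14% of the interface unpredictable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .capri import DecoyEnsemble
from .residues import ResidueId
from .scores import (
    HIGHER_IS_BETTER,
    LOWER_IS_BETTER,
    PREDICTORS,
    ScoreTable,
    ValidationError,
)
from .structure import ComplexStructure, ResidueLabels

#: Perfect-separation margin used when signal == 1.0.
_PERFECT_MARGIN = 100.0


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic predictor-score generator."""

    n_chains: int = 6
    chain_length: int = 130
    interface_fraction: float = 0.15
    signal: float | Mapping[str, float] = 0.7
    correlation: float = 0.3
    unpredictable_fraction: float = 0.14
    predictors: Sequence[str] = PREDICTORS
    seed: int = 0

    def __post_init__(self) -> None:
        sig = self.signal_per_predictor()
        for name, s in sig.items():
            if not 0.0 <= s <= 1.0:
                raise ValidationError(f"signal for {name} must be in [0, 1]")
        if not 0.0 <= self.interface_fraction <= 1.0:
            raise ValidationError("interface_fraction must be in [0, 1]")
        if not 0.0 <= self.unpredictable_fraction <= 1.0:
            raise ValidationError("unpredictable_fraction must be in [0, 1]")
        if not 0.0 <= self.correlation <= 1.0:
            raise ValidationError("correlation must be in [0, 1]")

    def signal_per_predictor(self) -> dict[str, float]:
        if isinstance(self.signal, Mapping):
            missing = set(self.predictors) - set(self.signal)
            if missing:
                raise ValidationError(f"signal missing for predictors: {sorted(missing)}")
            return {p: float(self.signal[p]) for p in self.predictors}
        return {p: float(self.signal) for p in self.predictors}


def simulate_scores(spec: SyntheticSpec) -> tuple[dict[str, ScoreTable], ResidueLabels]:
    """Generate per-predictor score tables and matching ground-truth labels.

    Exactly round(chain_length * interface_fraction) interface residues
    are planted per chain; round(unpredictable_fraction * that) of them
    are flagged buried in every table.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    signals = spec.signal_per_predictor()

    tables = {
        name: ScoreTable(
            name,
            LOWER_IS_BETTER if name == "cons-PPISP" else HIGHER_IS_BETTER,
        )
        for name in spec.predictors
    }
    interface: set[ResidueId] = set()
    surface: set[ResidueId] = set()
    unpredictable: set[ResidueId] = set()

    for c in range(spec.n_chains):
        chain_id = chr(ord("A") + c)
        rids = [ResidueId(chain_id, i + 1) for i in range(spec.chain_length)]
        n_iface = round(spec.chain_length * spec.interface_fraction)
        iface_idx = rng.choice(spec.chain_length, size=n_iface, replace=False)
        iface = {rids[i] for i in iface_idx}
        n_unpred = round(spec.unpredictable_fraction * n_iface)
        unpred_idx = rng.choice(np.sort(iface_idx), size=n_unpred, replace=False) if n_unpred else []
        unpred = {rids[i] for i in unpred_idx}

        interface |= iface
        unpredictable |= unpred
        surface |= set(rids) - iface

        is_iface = np.array([r in iface for r in rids], dtype=float)
        u = rng.standard_normal(spec.chain_length)
        for name in spec.predictors:
            auc = signals[name]
            eps = rng.standard_normal(spec.chain_length)
            z = spec.correlation * u + np.sqrt(1.0 - spec.correlation**2) * eps
            if auc >= 1.0:
                z = z + _PERFECT_MARGIN * is_iface
            else:
                z = z + np.sqrt(2.0) * norm.ppf(auc) * is_iface
            table = tables[name]
            if table.direction == LOWER_IS_BETTER:
                z = -z
            for rid, score in zip(rids, z):
                if rid in unpred:
                    table.buried.add(rid)
                else:
                    table.entries[rid] = float(score)

    labels = ResidueLabels.from_sets(interface, surface, unpredictable)
    return tables, labels


# ---- toy structures -------------------------------------------------------

#: Pseudo-residue template: atom name, element, offset from CA (Angstrom).
_RESIDUE_TEMPLATE = (
    ("N", "N", (-1.20, 0.70, 0.00)),
    ("CA", "C", (0.00, 0.00, 0.00)),
    ("C", "C", (1.20, 0.70, 0.00)),
    ("O", "O", (1.30, 1.90, 0.00)),
    ("CB", "C", (0.00, -0.80, 1.20)),
)
_SPACING = 3.8  # consecutive CA distance along the strand


def toy_complex(
    n_residues_per_chain: int = 20,
    seed: int = 0,
    contact_window: int | None = None,
    jitter: float = 0.05,
) -> ComplexStructure:
    """Two-chain pseudo-backbone complex with a planted central interface.

    Chain A lies along x; chain B runs parallel above it with its CB
    atoms pointing down.  Within a central window of residues the
    chains are ~3.8 A apart (CB-CB) and in contact; outside it chain B
    bends away, so the interface is exactly the window on both chains.
    Small seeded jitter avoids degenerate geometry.
    """
    if n_residues_per_chain < 3:
        raise ValidationError("need at least 3 residues per chain")
    n = n_residues_per_chain
    if contact_window is None:
        contact_window = max(1, round(0.15 * n))
    rng = np.random.default_rng(seed)
    center = (n - 1) / 2.0
    half = contact_window / 2.0

    residue_ids, residue_names, atom_names, elements, coords = [], [], [], [], []

    def add_residue(chain: str, number: int, ca: np.ndarray, flip_z: bool) -> None:
        rid = ResidueId(chain, number)
        for name, element, offset in _RESIDUE_TEMPLATE:
            off = np.array(offset, float)
            if flip_z:
                off[2] = -off[2]
            xyz = ca + off + rng.normal(0.0, jitter, size=3)
            residue_ids.append(rid)
            residue_names.append("ALA")
            atom_names.append(name)
            elements.append(element)
            coords.append(xyz)

    for i in range(n):
        add_residue("A", i + 1, np.array([_SPACING * i, 0.0, 0.0]), flip_z=False)
    for i in range(n):
        overshoot = max(0.0, abs(i - center) - half)
        z = 6.2 + 6.0 * overshoot
        add_residue("B", i + 1, np.array([_SPACING * i, 0.3, z]), flip_z=True)

    return ComplexStructure(
        residue_ids,
        residue_names,
        atom_names,
        np.array(elements, dtype=object),
        np.array(coords),
        receptor_chains=("A",),
        ligand_chains=("B",),
    )


def make_decoys(
    reference: ComplexStructure,
    transforms: Sequence[tuple[np.ndarray | None, Sequence[float] | None]],
    stage: str = "rigid_body",
) -> DecoyEnsemble:
    """Rigid-body decoys: each (rotation, translation) moves the ligand group.

    The rotation pivots about the ligand centroid, then the translation
    is applied, so a pure translation t yields a decoy whose l-RMSD
    after the receptor fit is exactly |t|.
    """
    decoys = []
    for rotation, translation in transforms:
        decoys.append(
            reference.transformed(
                rotation=rotation,
                translation=translation,
                chains=reference.ligand_chains,
            )
        )
    return DecoyEnsemble(reference=reference, decoys=decoys, stage=stage)


def random_rigid_transforms(
    n: int,
    seed: int,
    max_angle: float = np.pi,
    max_shift: float = 10.0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded random rotations (uniform axis, angle <= max_angle) and shifts."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.0, max_angle)
        out.append((rotation_matrix(axis, angle), rng.uniform(-max_shift, max_shift, size=3)))
    return out


def rotation_matrix(axis: Sequence[float], angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (normalised) axis."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def planted_pose_ensemble(
    reference: ComplexStructure,
    n_decoys: int,
    native_fraction: float,
    seed: int,
    stage: str = "rigid_body",
) -> DecoyEnsemble:
    """Decoy ensemble in which a fraction of decoys sit at the native pose.

    Native decoys get tiny jitter-free identity transforms; the rest are
    scattered far from the native pose (shifts of 25-60 A), so planted
    star counts and contact frequencies are exactly recoverable.
    """
    if not 0.0 <= native_fraction <= 1.0:
        raise ValidationError("native_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_native = round(native_fraction * n_decoys)
    transforms: list[tuple[np.ndarray | None, np.ndarray | None]] = []
    for k in range(n_decoys):
        if k < n_native:
            transforms.append((None, None))
        else:
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            axis = rng.standard_normal(3)
            transforms.append(
                (rotation_matrix(axis, rng.uniform(0, np.pi)), direction * rng.uniform(25.0, 60.0))
            )
    order = rng.permutation(n_decoys)
    shuffled = [transforms[i] for i in order]
    return make_decoys(reference, shuffled, stage=stage)
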