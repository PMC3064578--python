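"""Interface post-prediction from docking decoy ensembles.

After docking, the residues most often in contact across the selected
solutions re-predict the interface, typically better than the original
consensus prediction that drove the docking.  Per chain, residues are
ranked by the number of selected decoys in which they contact the
partner, and the top N are taken, where N is the original number of
consensus predictions for that chain.
"""

from __future__ import annotations

import warnings
from typing import Mapping

from .capri import DecoyEnsemble
from .consensus import PredictionSet
from .scores import ValidationError
from .structure import INTERFACE_CUTOFF, contact_counts

RIGID_BODY_SELECTION = 400


def postpredict(
    ensemble: DecoyEnsemble,
    n_per_chain: Mapping[str, int],
    top_k_decoys: int | None = None,
    contact_cutoff: float = INTERFACE_CUTOFF,
) -> PredictionSet:
    """Predict the interface from decoy contact frequencies.

    ``top_k_decoys`` defaults to 400 for rigid-body ensembles and all
    decoys for refined ensembles.  Residues with zero contacts are
    never predicted, so a chain's prediction may be shorter than N.
    Ties are broken by residue order.
    """
    if len(ensemble) == 0:
        raise ValidationError("empty decoy ensemble")
    for chain, n in n_per_chain.items():
        if n < 1:
            raise ValidationError(f"n_per_chain must be >= 1 (chain {chain}: {n})")
    if top_k_decoys is None:
        top_k_decoys = RIGID_BODY_SELECTION if ensemble.stage == "rigid_body" else len(ensemble)

    counts = contact_counts(ensemble, cutoff=contact_cutoff, top_k=top_k_decoys)
    chain_residues = {}
    for rid in ensemble.reference.residues():
        chain_residues.setdefault(rid.chain_id, []).append(rid)

    provenance = {}
    for chain, n in n_per_chain.items():
        residues = chain_residues.get(chain, [])
        if not residues:
            raise ValidationError(f"chain {chain} not present in the ensemble")
        if n > len(residues):
            warnings.warn(
                f"n_per_chain[{chain}]={n} exceeds chain length {len(residues)}; clamping",
                stacklevel=2,
            )
            n = len(residues)
        contacting = [r for r in residues if counts.get(r, 0) > 0]
        contacting.sort(key=lambda r: (-counts[r], r))
        for rid in contacting[:n]:
            provenance[rid] = {"postprediction"}
    return PredictionSet(provenance)
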