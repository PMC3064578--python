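"""Interface post-prediction: re-predicting the interface from decoys.

When docking works even partially, residues that form contacts in many
top-ranked solutions pinpoint the interface better than the original
prediction did.  This script plants 60% native poses in an ensemble and
recovers the interface from contact frequencies alone.
"""

from cport import (
    DecoyEnsemble,
    interface_residues,
    planted_pose_ensemble,
    postpredict,
    toy_complex,
)

reference = toy_complex(20, seed=9)
interface = interface_residues(reference)
n_per_chain = {c: sum(r.chain_id == c for r in interface) for c in ("A", "B")}
print(f"planted interface: {len(interface)} residues "
      f"({n_per_chain['A']} on A, {n_per_chain['B']} on B)")

ensemble = planted_pose_ensemble(reference, 60, native_fraction=0.6, seed=9, stage="refined")
prediction = postpredict(ensemble, n_per_chain)

recovered = prediction.residues & interface
print(
    f"post-prediction from {len(ensemble)} decoys: {len(prediction)} residues, "
    f"{len(recovered)}/{len(interface)} of the interface recovered"
)
print(
    "Taking the top-N contact-forming residues (N = the original number of "
    "predictions per chain) recovers the planted interface exactly, because "
    "native-pose contacts out-vote the scattered wrong poses."
)
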