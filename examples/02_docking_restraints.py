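"""From predicted interface residues to ambiguous docking restraints.

Builds a toy two-chain complex, treats its true interface as the
prediction, derives active/passive residues, writes a CNS-dialect AIR
table, and subsamples it the way per-trial restraint discarding does.
"""

from pathlib import Path

from cport import (
    build_air_table,
    com_upper_bound,
    define_active_passive,
    interface_residues,
    principal_dimensions,
    random_restraint_subset,
    relative_accessibility,
    surface_residues,
    toy_complex,
    write_air_table,
)

reference = toy_complex(20, seed=1)
prediction = interface_residues(reference)  # stand-in for a consensus prediction

aps = {}
for chain in ("A", "B"):
    free_chain = reference.restrict_chains([chain])
    surface = surface_residues(relative_accessibility(free_chain))
    pred = {r for r in prediction if r.chain_id == chain}
    aps[chain] = define_active_passive(pred, surface, reference, chain_id=chain)
    print(
        f"chain {chain}: {len(aps[chain].active)} active residues, "
        f"{len(aps[chain].passive)} passive within the 6.5 A shell"
    )

table = build_air_table(aps["A"], aps["B"])
out = Path("ambig.tbl")
write_air_table(table, out)
print(f"wrote {len(table)} ambiguous restraints (one per active residue) to {out}")

kept = random_restraint_subset(table, n_partitions=8, seed=7)
print(
    f"per-trial subsampling keeps {len(kept)}/{len(table)} restraints "
    f"({1 - len(kept)/len(table):.1%} discarded at random)"
)

dims = principal_dimensions(reference, ["A"]), principal_dimensions(reference, ["B"])
print(
    f"center-of-mass upper bound for restraint-free docking: "
    f"{com_upper_bound(*dims):.2f} A (from the chains' principal-axis extents)"
)
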