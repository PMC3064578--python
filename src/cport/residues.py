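"""Residue identity shared by every per-residue quantity in the package.

Residues are identified by author numbering: chain identifier, residue
number and (optional) insertion code.  A blank insertion code and an
absent one compare equal, so predictor tables written without an icode
column match structures parsed from PDB files.
"""

from __future__ import annotations

from typing import NamedTuple


class ResidueId(NamedTuple):
    """Identifies one residue within one structure.

    Sort order (chain, number, icode) is the deterministic "residue
    order" used throughout for tie-breaking.
    """

    chain_id: str
    residue_number: int
    insertion_code: str = ""

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        icode = self.insertion_code or ""
        return f"{self.chain_id}{self.residue_number}{icode}"


def make_residue_id(chain_id: str, residue_number: int, insertion_code: str | None = "") -> ResidueId:
    """Normalise the insertion code: None, '' and ' ' all mean absent."""
    icode = (insertion_code or "").strip()
    return ResidueId(str(chain_id), int(residue_number), icode)
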