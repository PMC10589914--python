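"""Residue-contact interfaces between chains.

An interface is the set of inter-chain residue pairs whose minimum
inter-atomic distance (in a chosen atom mode) falls below a cutoff.  One
contact is kept per residue pair, carrying the minimum distance.  Hydrogens
and hetero residues (waters, ligands) never contribute.  Default cutoffs:
5.0 Angstrom for heavy-atom mode, 8.0 Angstrom for C-alpha mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from structkit.geometry import pairwise_min_distances
from structkit.structio import Chain, ResidueID

__all__ = [
    "Contact", "Interface", "compute_interface", "interface_residues",
    "interface_summary", "DEFAULT_CUTOFF", "DEFAULT_CA_CUTOFF",
]

DEFAULT_CUTOFF = 5.0      # Angstrom, heavy-atom mode
DEFAULT_CA_CUTOFF = 8.0   # Angstrom, CA mode


@dataclass
class ResidueRef:
    chain_id: str
    residue_id: ResidueID
    res_name: str


@dataclass
class Contact:
    res_a: ResidueRef
    res_b: ResidueRef
    distance: float
    kind: str  # "PP", "PN" or "NN"


@dataclass
class Interface:
    chain_a: str
    chain_b: str
    contacts: list[Contact]
    cutoff: float
    atom_mode: str

    def __len__(self) -> int:
        return len(self.contacts)


_KIND = {
    ("protein", "protein"): "PP",
    ("protein", "nucleic"): "PN",
    ("nucleic", "protein"): "PN",
    ("nucleic", "nucleic"): "NN",
}


def compute_interface(a: Chain, b: Chain, cutoff: float | None = None,
                      atom_mode: str = "heavy") -> Interface:
    """All residue-residue contacts between two different chains.

    A contact is recorded for every (protein or nucleic) residue pair whose
    minimum selected-atom distance is at or below the cutoff.  The contact
    kind (PP / PN / NN) is derived from the two residues' classification.
    """
    if a is b:
        raise ValueError("interface requires two different chain objects")
    if cutoff is None:
        cutoff = DEFAULT_CA_CUTOFF if atom_mode == "ca" else DEFAULT_CUTOFF
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    res_a = [r for r in a.residues if r.kind != "hetero"]
    res_b = [r for r in b.residues if r.kind != "hetero"]
    contacts: list[Contact] = []
    if res_a and res_b:
        dmat = pairwise_min_distances(res_a, res_b, atom_mode)
        ii, jj = np.nonzero(dmat <= cutoff)
        for i, j in zip(ii.tolist(), jj.tolist()):
            ra, rb = res_a[i], res_b[j]
            kind = _KIND.get((ra.kind, rb.kind))
            if kind is None:
                continue
            contacts.append(Contact(
                res_a=ResidueRef(a.chain_id, ra.id, ra.res_name),
                res_b=ResidueRef(b.chain_id, rb.id, rb.res_name),
                distance=float(dmat[i, j]), kind=kind))
    return Interface(chain_a=a.chain_id, chain_b=b.chain_id, contacts=contacts,
                     cutoff=cutoff, atom_mode=atom_mode)


def interface_residues(iface: Interface, side: str) -> list[ResidueID]:
    """Unique residues of one side ('a' or 'b') appearing in any contact,
    in chain (file) order of first appearance."""
    if side not in ("a", "b"):
        raise ValueError("side must be 'a' or 'b'")
    seen: list[ResidueID] = []
    for c in iface.contacts:
        rid = (c.res_a if side == "a" else c.res_b).residue_id
        if rid not in seen:
            seen.append(rid)
    return seen


def _fmt_rid(ref: ResidueRef) -> str:
    return f"{ref.chain_id}:{ref.res_name}:{ref.residue_id[0]}{ref.residue_id[1]}"


def interface_summary(iface: Interface) -> str:
    """TSV table of contacts: residue A, residue B, distance, kind."""
    lines = ["chain_a_res\tchain_b_res\tdistance\tkind"]
    for c in iface.contacts:
        lines.append(f"{_fmt_rid(c.res_a)}\t{_fmt_rid(c.res_b)}\t{c.distance:.3f}\t{c.kind}")
    return "\n".join(lines) + "\n"
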