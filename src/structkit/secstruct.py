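"""Secondary-structure assignment and SSE segmentation.

Two routes produce a per-residue H/E/C assignment:

* :func:`assign_internal` — a self-contained hydrogen-bond method in the
  Kabsch–Sander tradition: the backbone amide H is imputed, an electrostatic
  bond energy is evaluated for every CO(i)…NH(j) pair, bonds below
  -0.5 kcal/mol feed n-turn and bridge patterns, and a reduced 3-state
  alphabet (helix / strand / coil) is emitted;
* :func:`parse_dssp` — reads classic DSSP output and collapses its 8-state
  codes ({H,G,I} -> H, {E,B} -> E, rest -> C).

:func:`segment_sses` then groups maximal runs into SSE objects with fitted
axes (minimum lengths: 4 for helices, 3 for strands).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np

from structkit.geometry import AxisFit, fit_axis
from structkit.structio import Chain, ParseError, ResidueID

__all__ = [
    "SSAssignment", "SSE", "assign_internal", "parse_dssp", "segment_sses",
    "hbond_energy",
]

#: Kabsch–Sander electrostatic constants: partial charges product and the
#: dimensional factor converting 1/Angstrom to kcal/mol
KS_Q1Q2 = 0.084
KS_F = 332.0
#: bond is declared below this energy
HBOND_CUTOFF = -0.5
#: minimum SSE lengths
MIN_HELIX = 4
MIN_STRAND = 3


@dataclass
class SSAssignment:
    """Per-residue 3-state secondary structure for one chain."""

    states: list[str]                 # one of "H", "E", "C" per residue
    source: str = "internal"          # "internal" or "dssp_file"
    residue_ids: list[ResidueID] = field(default_factory=list)
    n_incomplete: int = 0             # residues forced to C for missing backbone

    def __len__(self) -> int:
        return len(self.states)

    def __str__(self) -> str:
        return "".join(self.states)


@dataclass
class SSE:
    """A maximal helix or strand run, with a fitted axis."""

    kind: str                # "H" or "E"
    start: ResidueID
    end: ResidueID
    residue_ids: list[ResidueID]
    axis: AxisFit
    start_index: int         # indices into the parent chain's residue list
    end_index: int

    def __len__(self) -> int:
        return len(self.residue_ids)


def hbond_energy(o: np.ndarray, c: np.ndarray, n: np.ndarray, h: np.ndarray) -> float:
    """Electrostatic CO…NH hydrogen-bond energy in kcal/mol.

    E = q1 q2 (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * f with the canonical
    q1 q2 = 0.084 e^2 and f = 332 kcal Angstrom / (mol e^2).
    """
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return 0.0  # atoms essentially overlapping: not a physical H-bond
    return KS_Q1Q2 * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn) * KS_F


def _backbone(chain: Chain):
    """Backbone coordinate table; None rows where atoms are missing."""
    rows = []
    for res in chain.residues:
        entry = {}
        for name in ("N", "CA", "C", "O"):
            a = res.get_atom(name)
            entry[name] = None if a is None else a.coords
        rows.append(entry)
    return rows


def _impute_hydrogens(bb) -> list:
    """Amide H position per residue: 1.01 Angstrom from N along the
    direction opposite the bisector of the C(prev)-N-CA angle.  The first
    residue (and any residue missing context) gets None."""
    hs: list = [None] * len(bb)
    for i in range(1, len(bb)):
        n, ca = bb[i]["N"], bb[i]["CA"]
        c_prev = bb[i - 1]["C"]
        if n is None or ca is None or c_prev is None:
            continue
        u = c_prev - n
        v = ca - n
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-6 or nv < 1e-6:
            continue
        bis = u / nu + v / nv
        nb = np.linalg.norm(bis)
        if nb < 1e-6:
            continue
        hs[i] = n - 1.01 * bis / nb
    return hs


def backbone_hbonds(chain: Chain) -> tuple[set[tuple[int, int]], int]:
    """All (i, j) pairs with a CO(i)…NH(j) bond below the energy cutoff.

    Returns the bond set (chain indices) and the count of residues with an
    incomplete backbone.  Pairs with |i - j| < 2 are excluded (covalently
    constrained neighbours cannot hydrogen-bond).
    """
    bb = _backbone(chain)
    hs = _impute_hydrogens(bb)
    n = len(bb)
    incomplete = sum(1 for e in bb if any(e[a] is None for a in ("N", "CA", "C", "O")))
    bonds: set[tuple[int, int]] = set()
    for i in range(n):
        o, c = bb[i]["O"], bb[i]["C"]
        if o is None or c is None:
            continue
        for j in range(n):
            if abs(i - j) < 2:
                continue
            nn, h = bb[j]["N"], hs[j]
            if nn is None or h is None:
                continue
            if np.linalg.norm(o - nn) > 5.2:  # energy cannot reach cutoff beyond this
                continue
            if hbond_energy(o, c, nn, h) < HBOND_CUTOFF:
                bonds.add((i, j))
    return bonds, incomplete


def assign_internal(chain: Chain) -> SSAssignment:
    """Assign H/E/C states from imputed-hydrogen backbone H-bond patterns.

    Helix: two consecutive 4-turns (bonds i->i+4 and i+1->i+5) mark residues
    i+1..i+4 as H.  Strand: parallel or antiparallel bridge patterns over the
    bond set mark both partners as E; helix takes precedence where both fire.
    Residues with missing backbone atoms are forced to coil and counted.
    """
    n = len(chain.residues)
    bonds, incomplete = backbone_hbonds(chain)

    def hb(i: int, j: int) -> bool:
        return 0 <= i < n and 0 <= j < n and (i, j) in bonds

    states = ["C"] * n

    # bridges -> strand
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            if abs(i - j) < 3:
                continue
            parallel = (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1))
            antiparallel = (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            if parallel or antiparallel:
                states[i] = "E"
                states[j] = "E"

    # 4-turns -> helix (takes precedence over strand)
    turn4 = [hb(i, i + 4) for i in range(n)]
    for i in range(1, n):
        if turn4[i - 1] and turn4[i]:
            for k in range(i + 1, min(i + 5, n)):
                states[k] = "H"

    # force incomplete-backbone residues to coil
    bb = _backbone(chain)
    for i, entry in enumerate(bb):
        if any(entry[a] is None for a in ("N", "CA", "C", "O")):
            states[i] = "C"

    return SSAssignment(states=states, source="internal",
                        residue_ids=[r.id for r in chain.residues],
                        n_incomplete=incomplete)


# ---------------------------------------------------------------------------
# DSSP output ingestion
# ---------------------------------------------------------------------------

_DSSP_COLLAPSE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def parse_dssp(source: Union[str, Iterable[str]], chain_id: str | None = None) -> SSAssignment:
    """Read classic DSSP output and collapse to 3 states.

    The body starts after the line beginning ``  #  RESIDUE``; fixed columns
    give residue number (6-10), insertion code (10), chain (11) and the
    summary structure code (16).  Chain-break records ('!' in the amino-acid
    column) are skipped.  If ``chain_id`` is given, only that chain is kept.
    """
    lines = source.splitlines() if isinstance(source, str) else [ln.rstrip("\n") for ln in source]
    try:
        start = next(i for i, ln in enumerate(lines) if ln.lstrip().startswith("#  RESIDUE"))
    except StopIteration:
        raise ParseError("DSSP header line '  #  RESIDUE ...' not found") from None
    states: list[str] = []
    rids: list[ResidueID] = []
    for ln in lines[start + 1:]:
        if len(ln) < 17 or ln[13] == "!":
            continue
        ch = ln[11].strip()
        if chain_id is not None and ch != chain_id:
            continue
        try:
            number = int(ln[5:10])
        except ValueError:
            continue
        icode = ln[10].strip()
        code = ln[16].strip()
        states.append(_DSSP_COLLAPSE.get(code, "C"))
        rids.append((number, icode))
    return SSAssignment(states=states, source="dssp_file", residue_ids=rids)


def segment_sses(assignment: SSAssignment, chain: Chain) -> list[SSE]:
    """Maximal H/E runs meeting the length minima, each with a fitted CA axis.

    Runs shorter than the minimum (4 for H, 3 for E) are demoted to coil.
    SSEs are returned in N-to-C order with disjoint residue intervals.
    """
    if len(assignment) != len(chain.residues):
        raise ValueError("assignment length does not match chain length")
    sses: list[SSE] = []
    i = 0
    n = len(assignment.states)
    while i < n:
        st = assignment.states[i]
        if st not in ("H", "E"):
            i += 1
            continue
        j = i
        while j < n and assignment.states[j] == st:
            j += 1
        length = j - i
        minimum = MIN_HELIX if st == "H" else MIN_STRAND
        if length >= minimum:
            run = chain.residues[i:j]
            ca = np.array([r.get_atom("CA").coords for r in run if r.get_atom("CA")])
            if ca.shape[0] >= 3:
                axis = fit_axis(ca)
                sses.append(SSE(kind=st, start=run[0].id, end=run[-1].id,
                                residue_ids=[r.id for r in run], axis=axis,
                                start_index=i, end_index=j - 1))
        i = j
    return sses
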