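"""Deterministic synthetic-structure generators with exact ground truth.

Chains are built by sequential internal-coordinate placement (the natural
extension of reference frames, "NeRF"): each backbone atom is positioned
from the previous three by ideal bond length, bond angle and torsion.  This
gives dependency-free poly-alanine ground truth for every structural module:

* :func:`make_ideal_helix` / :func:`make_ideal_strand` — single SSEs with
  canonical (phi, psi);
* :func:`make_hairpin` — two antiparallel strands placed at ideal
  beta-sheet pairing geometry, hydrogen-bond-competent by construction;
* :func:`make_scaffold` — two SSEs at a prescribed inter-axis geometry
  (distance D, packing angle theta) joined by a seeded jittered loop;
* :func:`make_dimer` — two chains with an exact number of residue contacts
  at an exact distance;
* :func:`make_random_dimer` — two randomly packed chains for oracle
  comparisons.

All generators are pure functions of their arguments (plus seed) and
regenerate bit-identical coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from structkit.geometry import Transform, apply_transform, fit_axis, kabsch
from structkit.secstruct import MIN_HELIX, MIN_STRAND, SSAssignment, segment_sses
from structkit.structio import Atom, Chain, Residue, Structure

__all__ = [
    "ScaffoldSpec", "make_ideal_helix", "make_ideal_strand", "make_hairpin",
    "make_scaffold", "scaffold_assignment", "scaffold_smotif", "make_dimer",
    "make_random_dimer",
    "make_dna_ladder",
]

# ideal backbone internal coordinates (Angstrom / degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O, A_N_CA_CB = 111.2, 116.2, 121.7, 120.5, 110.4
OMEGA = 180.0

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -120.0, 120.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position atom d with |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.sin(ang) * math.cos(tor),
                        bond * math.sin(ang) * math.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phis: list[float], psis: list[float]) -> list[dict]:
    """Sequential poly-alanine backbone (N, CA, C, O, CB) from torsion lists."""
    n_res = len(phis)
    assert len(psis) == n_res
    residues: list[dict] = []
    # seed frame: first residue laid flat in the xy-plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([B_N_CA, 0.0, 0.0])
    ang = math.radians(A_N_CA_C)
    c0 = ca0 + B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0]) * -1.0
    c0 = ca0 + B_CA_C * np.array([math.cos(math.pi - ang), math.sin(math.pi - ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[i - 1]
        n = _place(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psis[i - 1])
        ca = _place(prev["CA"], prev["C"], n, B_N_CA, A_C_N_CA, OMEGA)
        c = _place(prev["C"], n, ca, B_CA_C, A_N_CA_C, phis[i])
        residues.append({"N": n, "CA": ca, "C": c})
    # carbonyl O: trans to the next residue's N (torsion psi + 180)
    for i, res in enumerate(residues):
        res["O"] = _place(res["N"], res["CA"], res["C"], B_C_O, A_CA_C_O,
                          psis[i] + 180.0)
    # C-beta by tetrahedral construction at CA
    for res in residues:
        b1 = res["N"] - res["CA"]
        b2 = res["C"] - res["CA"]
        b1 = b1 / np.linalg.norm(b1)
        b2 = b2 / np.linalg.norm(b2)
        bis = (b1 + b2) / np.linalg.norm(b1 + b2)
        perp = np.cross(b1, b2)
        perp = perp / np.linalg.norm(perp)
        alpha = math.radians(51.9)  # yields angle(N, CA, CB) ~ 110.4 deg
        direction = -math.cos(alpha) * bis + math.sin(alpha) * perp
        res["CB"] = res["CA"] + B_CA_CB * direction
    return residues


_BB_ORDER = ("N", "CA", "C", "O", "CB")
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _to_chain(backbone: list[dict], chain_id: str = "A", first_number: int = 1,
              res_name: str = "ALA") -> Chain:
    residues = []
    serial = 0
    for i, bb in enumerate(backbone):
        atoms = []
        for name in _BB_ORDER:
            serial += 1
            atoms.append(Atom(serial=serial, name=name, element=_ELEMENT[name],
                              coords=np.asarray(bb[name], dtype=float)))
        residues.append(Residue(number=first_number + i, insertion_code="",
                                res_name=res_name, atoms=atoms))
    return Chain(chain_id=chain_id, residues=residues)


def make_ideal_helix(n: int, chain_id: str = "A", first_number: int = 1) -> Chain:
    """Ideal poly-alanine alpha helix (phi = -57, psi = -47), n >= 4."""
    if n < MIN_HELIX:
        raise ValueError(f"a helix needs at least {MIN_HELIX} residues")
    bb = _build_backbone([HELIX_PHI] * n, [HELIX_PSI] * n)
    return _to_chain(bb, chain_id=chain_id, first_number=first_number)


def make_ideal_strand(n: int, chain_id: str = "A", first_number: int = 1) -> Chain:
    """Ideal extended poly-alanine strand (phi = -120, psi = +120), n >= 3."""
    if n < MIN_STRAND:
        raise ValueError(f"a strand needs at least {MIN_STRAND} residues")
    bb = _build_backbone([STRAND_PHI] * n, [STRAND_PSI] * n)
    return _to_chain(bb, chain_id=chain_id, first_number=first_number)


def _axis_frame_transform(chain: Chain, target_dir: np.ndarray,
                          anchor: str, target_point: np.ndarray) -> Transform:
    """Rigid motion taking the chain's fitted CA axis onto a target line.

    ``anchor`` is 'n_start' or 'c_end'; that axis endpoint lands on
    ``target_point`` and the axis direction on ``target_dir``.
    """
    ca = np.array([r.get_atom("CA").coords for r in chain.residues])
    axis = fit_axis(ca)
    d0 = axis.direction
    d1 = np.asarray(target_dir, dtype=float)
    d1 = d1 / np.linalg.norm(d1)
    v = np.cross(d0, d1)
    c = float(np.dot(d0, d1))
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else _rotation_about(_any_perpendicular(d0), 180.0)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    p0 = getattr(axis, anchor)
    t = np.asarray(target_point, dtype=float) - R @ p0
    return Transform(R, t)


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, v)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    p = seed - np.dot(seed, v) * v
    return p / np.linalg.norm(p)


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * K @ K


# antiparallel beta-pairing placement (separation / axial shift / roll of the
# second strand about its own axis), chosen so the Kabsch-Sander energies of
# the cross-strand CO...NH pairs fall well below the bonding cutoff
HAIRPIN_SEPARATION = 4.0
HAIRPIN_AXIAL_SHIFT = 0.0
HAIRPIN_ROLL = 345.0


def make_hairpin(n_per_strand: int = 6, chain_id: str = "A") -> Chain:
    """Two-stranded antiparallel beta pairing in one chain.

    Strand one runs along +z; strand two is the same ideal strand flipped
    antiparallel and placed alongside at ideal sheet pairing geometry.  The
    two strands are consecutive in the chain (numbering leaves a 2-residue
    gap where a turn would sit); hydrogen-bond-competent pairing is
    guaranteed by the placement constants.
    """
    if n_per_strand < MIN_STRAND:
        raise ValueError(f"strands need at least {MIN_STRAND} residues")
    s1 = make_ideal_strand(n_per_strand)
    # align strand 1 axis to +z with its centroid at the origin
    t1 = _axis_frame_transform(s1, np.array([0.0, 0.0, 1.0]), "n_start",
                               np.zeros(3))
    s1 = apply_transform(t1, s1)
    ca1 = np.array([r.get_atom("CA").coords for r in s1.residues])
    axis1 = fit_axis(ca1)

    s2 = make_ideal_strand(n_per_strand)
    t2 = _axis_frame_transform(s2, np.array([0.0, 0.0, 1.0]), "n_start",
                               np.zeros(3))
    s2 = apply_transform(t2, s2)
    # roll about own axis, flip antiparallel about x, then offset
    roll = Transform(_rotation_about(np.array([0.0, 0.0, 1.0]), HAIRPIN_ROLL), np.zeros(3))
    flip = Transform(_rotation_about(np.array([1.0, 0.0, 0.0]), 180.0), np.zeros(3))
    shift = Transform(np.eye(3), np.array([HAIRPIN_SEPARATION, 0.0,
                                           axis1.c_end[2] + HAIRPIN_AXIAL_SHIFT]))
    for t in (roll, flip, shift):
        s2 = apply_transform(t, s2)

    residues = list(s1.residues)
    for k, r in enumerate(s2.residues):
        r.number = n_per_strand + 3 + k  # 2-residue turn gap
    residues += list(s2.residues)
    return Chain(chain_id=chain_id, residues=residues)


@dataclass
class ScaffoldSpec:
    """Prescription for a two-SSE scaffold with connecting loop."""

    sse1_kind: str = "H"
    sse2_kind: str = "H"
    sse1_len: int = 12
    sse2_len: int = 12
    loop_len: int = 5
    D: float = 10.0        # Angstrom between axis endpoints
    theta: float = 90.0    # degrees between axis directions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sse1_kind not in "HE" or self.sse2_kind not in "HE":
            raise ValueError("SSE kinds must be 'H' or 'E'")
        for kind, length in ((self.sse1_kind, self.sse1_len), (self.sse2_kind, self.sse2_len)):
            minimum = MIN_HELIX if kind == "H" else MIN_STRAND
            if length < minimum:
                raise ValueError(f"SSE of kind {kind} needs >= {minimum} residues")
        if self.loop_len < 0 or self.D < 0 or not (0.0 <= self.theta <= 180.0):
            raise ValueError("invalid scaffold geometry")


def _make_sse(kind: str, n: int) -> Chain:
    return make_ideal_helix(n) if kind == "H" else make_ideal_strand(n)


def make_scaffold(spec: ScaffoldSpec, chain_id: str = "A") -> Chain:
    """Two SSEs at exact prescribed geometry, joined by a jittered loop.

    SSE1 is placed with its fitted axis along +z and the axis C-end at the
    origin; SSE2 with its axis direction at ``theta`` from +z (in the xz
    plane) and its axis N-start at (D, 0, 0).  The inter-SSE vector is
    therefore perpendicular to the first axis (hoist 90 degrees) and the
    meridian is 0.  Loop CA positions interpolate the gap with a small
    seed-deterministic jitter; loop backbone atoms are laid out along the
    local chain direction.
    """
    s1 = _make_sse(spec.sse1_kind, spec.sse1_len)
    t1 = _axis_frame_transform(s1, np.array([0.0, 0.0, 1.0]), "c_end", np.zeros(3))
    s1 = apply_transform(t1, s1)

    theta = math.radians(spec.theta)
    m2 = np.array([math.sin(theta), 0.0, math.cos(theta)])
    s2 = _make_sse(spec.sse2_kind, spec.sse2_len)
    t2 = _axis_frame_transform(s2, m2, "n_start", np.array([spec.D, 0.0, 0.0]))
    s2 = apply_transform(t2, s2)

    # connect C-terminus of SSE1 to N-terminus of SSE2
    c_last = s1.residues[-1].get_atom("C").coords
    n_first = s2.residues[0].get_atom("N").coords
    gap = float(np.linalg.norm(n_first - c_last))
    if spec.loop_len > 0 and gap > 3.8 * (spec.loop_len + 1):
        raise ValueError(
            f"loop of {spec.loop_len} residues cannot span {gap:.1f} Angstrom "
            f"(max ~{3.8 * (spec.loop_len + 1):.1f})")
    if spec.loop_len == 0 and gap > 4.5:
        raise ValueError(f"SSEs {gap:.1f} Angstrom apart cannot abut (loop_len 0)")

    rng = np.random.default_rng(spec.seed)
    loop_res: list[dict] = []
    for k in range(spec.loop_len):
        frac = (k + 1) / (spec.loop_len + 1)
        ca = c_last + frac * (n_first - c_last)
        ca = ca + rng.normal(0.0, 0.25, size=3)  # deterministic jitter
        loop_res.append({"CA": ca})
    # local backbone around each loop CA, oriented along the chain direction
    anchors = [c_last] + [r["CA"] for r in loop_res] + [n_first]
    for k, res in enumerate(loop_res):
        prev_pt, next_pt = anchors[k], anchors[k + 2]
        tangent = next_pt - prev_pt
        tangent = tangent / max(np.linalg.norm(tangent), 1e-9)
        up = _any_perpendicular(tangent)
        ca = res["CA"]
        res["N"] = ca - 0.70 * tangent + 1.20 * up
        res["C"] = ca + 0.75 * tangent + 1.25 * up
        res["O"] = res["C"] + 1.23 * up
        res["CB"] = ca - 1.52 * up

    chain_residues = list(s1.residues)
    number = spec.sse1_len
    serial = sum(len(r.atoms) for r in chain_residues)
    for res in loop_res:
        number += 1
        atoms = []
        for name in _BB_ORDER:
            serial += 1
            atoms.append(Atom(serial=serial, name=name, element=_ELEMENT[name],
                              coords=res[name]))
        chain_residues.append(Residue(number=number, insertion_code="",
                                      res_name="ALA", atoms=atoms))
    for r in s2.residues:
        number += 1
        r.number = number
        chain_residues.append(r)
    return Chain(chain_id=chain_id, residues=chain_residues)


def scaffold_assignment(spec: ScaffoldSpec) -> SSAssignment:
    """Ground-truth per-residue states for a scaffold built from ``spec``."""
    states = ([spec.sse1_kind] * spec.sse1_len + ["C"] * spec.loop_len
              + [spec.sse2_kind] * spec.sse2_len)
    return SSAssignment(states=states, source="internal")


def scaffold_smotif(spec: ScaffoldSpec, chain: Chain):
    """The scaffold's single smotif, segmented from the ground-truth states."""
    from structkit.smotif import extract_smotifs
    sses = segment_sses(scaffold_assignment(spec), chain)
    motifs = extract_smotifs(sses, chain)
    if len(motifs) != 1:
        raise RuntimeError("scaffold did not produce exactly one smotif")
    return motifs[0]


# ---------------------------------------------------------------------------
# dimers
# ---------------------------------------------------------------------------

_RES_SPACING = 12.0  # Angstrom between residue sites within a dimer chain


def _ala_residue(number: int, serial0: int, origin: np.ndarray) -> Residue:
    """A compact free-standing alanine residue centred near ``origin``."""
    template = {
        "N": np.array([-0.70, 1.20, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([0.75, 1.25, 0.0]),
        "O": np.array([1.95, 1.25, 0.0]),
        "CB": np.array([0.0, -1.52, 0.0]),
    }
    atoms = []
    for k, name in enumerate(_BB_ORDER):
        atoms.append(Atom(serial=serial0 + k, name=name, element=_ELEMENT[name],
                          coords=origin + template[name]))
    return Residue(number=number, insertion_code="", res_name="ALA", atoms=atoms)


def _min_dist(res_a: Residue, res_b: Residue) -> float:
    xa = np.array([a.coords for a in res_a.heavy_atoms()])
    xb = np.array([a.coords for a in res_b.heavy_atoms()])
    from scipy.spatial.distance import cdist
    return float(cdist(xa, xb).min())


def make_dimer(n_contacts: int, contact_distance: float = 3.0, seed: int = 0,
               n_residues: int = 10) -> Structure:
    """Two protein chains with exactly ``n_contacts`` residue contacts.

    Residue sites sit on two parallel lines 12 Angstrom apart along the
    line, so residue pairs are either "designed" contacts or far apart.  For
    each designed contact the partner residue is translated along the
    inter-chain direction until the minimum heavy-atom distance equals
    ``contact_distance`` (within 0.005 Angstrom, by bisection); every other
    inter-chain residue pair is farther than ``contact_distance`` + 2.
    """
    if n_contacts < 0 or contact_distance <= 0:
        raise ValueError("need n_contacts >= 0 and a positive contact distance")
    if n_contacts > n_residues:
        raise ValueError("cannot design more contacts than residues per chain")
    separation = contact_distance + 12.0
    rng = np.random.default_rng(seed)
    chain_a = Chain(chain_id="A")
    chain_b = Chain(chain_id="B")
    serial = 1
    for i in range(n_residues):
        z = i * _RES_SPACING
        chain_a.residues.append(_ala_residue(i + 1, serial, np.array([0.0, 0.0, z])))
        serial += 5
        chain_b.residues.append(_ala_residue(i + 1, serial,
                                             np.array([separation, 0.0, z])))
        serial += 5
    contact_idx = rng.choice(n_residues, size=n_contacts, replace=False)
    u = np.array([-1.0, 0.0, 0.0])  # pull B toward A
    for i in sorted(int(x) for x in contact_idx):
        ra, rb = chain_a.residues[i], chain_b.residues[i]
        lo, hi = 0.0, separation - 0.5
        for _ in range(60):  # bisection on the translation magnitude
            mid = 0.5 * (lo + hi)
            d = _min_dist(ra, _translated(rb, mid * u))
            if d > contact_distance:
                lo = mid
            else:
                hi = mid
        t = 0.5 * (lo + hi)
        chain_b.residues[i] = _translated(rb, t * u)
        if abs(_min_dist(ra, chain_b.residues[i]) - contact_distance) > 0.01:
            raise RuntimeError("dimer contact placement failed to converge")
    return Structure(entry_id="DIMER", chains=[chain_a, chain_b])


def _translated(res: Residue, t: np.ndarray) -> Residue:
    from dataclasses import replace
    return Residue(number=res.number, insertion_code=res.insertion_code,
                   res_name=res.res_name,
                   atoms=[replace(a, coords=a.coords + t) for a in res.atoms])


def make_random_dimer(n_per_chain: int = 30, seed: int = 0,
                      box: float = 25.0) -> Structure:
    """Two chains of free-standing residues randomly packed in overlapping
    boxes; contact counts are irregular by design (for oracle comparisons)."""
    rng = np.random.default_rng(seed)
    chains = []
    serial = 1
    for chain_id, offset in (("A", 0.0), ("B", box * 0.4)):
        chain = Chain(chain_id=chain_id)
        for i in range(n_per_chain):
            origin = rng.uniform(0.0, box, size=3) + np.array([offset, 0.0, 0.0])
            chain.residues.append(_ala_residue(i + 1, serial, origin))
            serial += 5
        chains.append(chain)
    return Structure(entry_id="RNDDIM", chains=chains)


_DNA_ATOMS = {"P": np.array([0.0, 0.0, 0.0]),
              "C1'": np.array([1.5, 1.0, 0.0]),
              "N1": np.array([3.0, 1.5, 0.0])}


def make_dna_ladder(n: int, chain_id: str = "D", rise: float = 3.4) -> Chain:
    """A rigid single-strand DNA placeholder: repeating three-atom
    nucleotides stacked along +z (for protein-nucleic interface tests)."""
    bases = ["DA", "DC", "DG", "DT"]
    chain = Chain(chain_id=chain_id)
    serial = 1
    for i in range(n):
        origin = np.array([0.0, 0.0, i * rise])
        atoms = []
        for name, off in _DNA_ATOMS.items():
            atoms.append(Atom(serial=serial, name=name,
                              element="P" if name == "P" else ("N" if name == "N1" else "C"),
                              coords=origin + off))
            serial += 1
        chain.residues.append(Residue(number=i + 1, insertion_code="",
                                      res_name=bases[i % 4], atoms=atoms))
    return chain
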