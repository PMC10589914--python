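"""Super-secondary structures (smotifs) and their four-parameter loop geometry.

A smotif is a pair of consecutive secondary-structure elements plus the loop
that connects them.  Its geometry is summarised by four parameters computed
from the two fitted SSE axes (M1, M2, unit vectors oriented N->C) and the
inter-SSE vector Dv from the C-end of the first axis to the N-start of the
second:

* ``D``      — |Dv|, the inter-SSE distance in Angstrom;
* ``delta``  — the hoist angle between M1 and Dv, degrees in [0, 180];
* ``theta``  — the packing angle between M1 and M2, degrees in [0, 180];
* ``rho``    — the meridian angle: the right-handed rotation of M2 about M1
  measured from the (M1, Dv) half-plane containing Dv, degrees in [0, 360).

These parameters are invariant under rigid motion of the whole motif and
support geometric similarity search over a smotif library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from structkit.geometry import angle_between
from structkit.secstruct import SSE
from structkit.structio import Chain, ResidueID

__all__ = [
    "Smotif", "SmotifGeometry", "extract_smotifs", "compute_geometry",
    "geometry_distance", "search_similar", "DEFAULT_WEIGHTS",
]

#: weights for geometry_distance: (per Angstrom, per degree x3) with the
#: angular terms scaled by 1/15 so that 15 degrees counts like 1 Angstrom
DEFAULT_WEIGHTS = (1.0, 1.0 / 15.0, 1.0 / 15.0, 1.0 / 15.0)


@dataclass
class SmotifGeometry:
    D: float            # Angstrom
    delta: float        # degrees, [0, 180]
    theta: float        # degrees, [0, 180]
    rho: float          # degrees, [0, 360)
    loop_length: int
    degenerate: bool = False


@dataclass
class Smotif:
    """Two consecutive SSEs plus the connecting loop."""

    sse1: SSE
    sse2: SSE
    loop_residue_ids: list[ResidueID]
    motif_type: str          # "HH", "HE", "EH" or "EE"
    geometry: SmotifGeometry | None = None

    @property
    def loop_length(self) -> int:
        return len(self.loop_residue_ids)


def extract_smotifs(sses: list[SSE], chain: Chain) -> list[Smotif]:
    """One smotif per consecutive SSE pair of a chain, with geometry computed.

    The loop is the residue run strictly between the first SSE's end and the
    second SSE's start (length 0 when the SSEs abut).  Fewer than two SSEs
    yield an empty list.
    """
    motifs: list[Smotif] = []
    for s1, s2 in zip(sses, sses[1:]):
        loop = [r.id for r in chain.residues[s1.end_index + 1:s2.start_index]]
        m = Smotif(sse1=s1, sse2=s2, loop_residue_ids=loop,
                   motif_type=s1.kind + s2.kind)
        m.geometry = compute_geometry(m)
        motifs.append(m)
    return motifs


def compute_geometry(s: Smotif) -> SmotifGeometry:
    """Compute (D, delta, theta, rho) from the two fitted SSE axes."""
    m1 = s.sse1.axis.direction
    m2 = s.sse2.axis.direction
    dv = s.sse2.axis.n_start - s.sse1.axis.c_end
    dist = float(np.linalg.norm(dv))
    theta = angle_between(m1, m2)
    if dist < 1e-6:
        return SmotifGeometry(D=dist, delta=float("nan"), theta=theta,
                              rho=float("nan"), loop_length=s.loop_length,
                              degenerate=True)
    delta = angle_between(m1, dv)
    # rho: right-handed rotation of M2's component perpendicular to M1,
    # measured from the half-plane through Dv
    e1 = dv - np.dot(dv, m1) * m1
    n1 = np.linalg.norm(e1)
    if n1 < 1e-9:
        # Dv parallel to M1: the reference half-plane is undefined; adopt
        # an arbitrary but deterministic perpendicular reference
        seed = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(seed, m1)) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        e1 = seed - np.dot(seed, m1) * m1
        n1 = np.linalg.norm(e1)
    e1 /= n1
    e2 = np.cross(m1, e1)
    proj = m2 - np.dot(m2, m1) * m1
    if np.linalg.norm(proj) < 1e-9:
        rho = 0.0  # M2 parallel to M1: meridian undefined, conventionally 0
    else:
        rho = math.degrees(math.atan2(float(np.dot(proj, e2)), float(np.dot(proj, e1)))) % 360.0
        if rho >= 360.0 - 1e-9:
            rho = 0.0
    return SmotifGeometry(D=dist, delta=delta, theta=theta, rho=rho,
                          loop_length=s.loop_length)


def geometry_distance(g1: SmotifGeometry, g2: SmotifGeometry,
                      weights: tuple[float, float, float, float] = DEFAULT_WEIGHTS) -> float:
    """Weighted Euclidean distance between two smotif geometries.

    The meridian difference is circular: min(|r1-r2|, 360-|r1-r2|).
    Degenerate geometries (undefined delta/rho) are rejected.
    """
    if g1.degenerate or g2.degenerate:
        raise ValueError("cannot compare degenerate smotif geometry")
    d_rho = abs(g1.rho - g2.rho)
    d_rho = min(d_rho, 360.0 - d_rho)
    terms = (g1.D - g2.D, g1.delta - g2.delta, g1.theta - g2.theta, d_rho)
    return math.sqrt(sum((w * t) ** 2 for w, t in zip(weights, terms)))


def search_similar(query: Smotif, library: list[Smotif], k: int,
                   same_type: bool = True, loop_length_tolerance: int = 0,
                   weights: tuple[float, float, float, float] = DEFAULT_WEIGHTS) -> list[Smotif]:
    """The k library smotifs geometrically nearest the query.

    ``same_type`` restricts candidates to the query's motif type with loop
    length within ``loop_length_tolerance``.  Ties are broken by library
    order; ``k`` larger than the library returns the full sorted candidate
    list.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not library:
        raise ValueError("empty smotif library")
    qg = query.geometry or compute_geometry(query)
    candidates = []
    for idx, s in enumerate(library):
        if same_type:
            if s.motif_type != query.motif_type:
                continue
            if abs(s.loop_length - query.loop_length) > loop_length_tolerance:
                continue
        sg = s.geometry or compute_geometry(s)
        candidates.append((geometry_distance(qg, sg, weights), idx, s))
    candidates.sort(key=lambda t: (t[0], t[1]))
    return [s for _, _, s in candidates[:k]]
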