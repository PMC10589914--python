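import math

import numpy as np
import pytest

from structkit.fixtures import ScaffoldSpec, make_scaffold, scaffold_assignment, scaffold_smotif
from structkit.geometry import AxisFit, apply_transform
from structkit.secstruct import SSE, SSAssignment, segment_sses
from structkit.smotif import (
    Smotif,
    SmotifGeometry,
    compute_geometry,
    extract_smotifs,
    geometry_distance,
    search_similar,
)

from conftest import random_rigid_transform


def synthetic_smotif(D=10.0, theta=90.0, delta=90.0, rho=0.0, loop_len=5,
                     kind="HH", length=10.0):
    """Fabricate a smotif with axes at an exact prescribed geometry."""
    m1 = np.array([0.0, 0.0, 1.0])
    dv_dir = np.array([math.sin(math.radians(delta)), 0.0,
                       math.cos(math.radians(delta))])
    c_end1 = np.zeros(3)
    n_start2 = c_end1 + D * dv_dir
    # m2 at angle theta from m1, rotated rho about m1 from the (m1, Dv) plane
    e1 = dv_dir - np.dot(dv_dir, m1) * m1
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(m1, e1)
    th, rh = math.radians(theta), math.radians(rho)
    m2 = (math.cos(th) * m1
          + math.sin(th) * (math.cos(rh) * e1 + math.sin(rh) * e2))
    ax1 = AxisFit(point=c_end1 - length * m1 / 2, direction=m1,
                  n_start=c_end1 - length * m1, c_end=c_end1)
    ax2 = AxisFit(point=n_start2 + length * m2 / 2, direction=m2,
                  n_start=n_start2, c_end=n_start2 + length * m2)
    sse1 = SSE(kind=kind[0], start=(1, ""), end=(10, ""),
               residue_ids=[(i, "") for i in range(1, 11)], axis=ax1,
               start_index=0, end_index=9)
    sse2 = SSE(kind=kind[1], start=(11 + loop_len, ""), end=(20 + loop_len, ""),
               residue_ids=[(i, "") for i in range(11 + loop_len, 21 + loop_len)],
               axis=ax2, start_index=10 + loop_len, end_index=19 + loop_len)
    return Smotif(sse1=sse1, sse2=sse2,
                  loop_residue_ids=[(10 + i, "") for i in range(1, loop_len + 1)],
                  motif_type=kind)


class TestExtractSmotifs:
    def test_scaffold_single_hh(self, scaffold, scaffold_spec):
        sses = segment_sses(scaffold_assignment(scaffold_spec), scaffold)
        motifs = extract_smotifs(sses, scaffold)
        assert len(motifs) == 1
        assert motifs[0].motif_type == "HH"
        assert motifs[0].loop_length == scaffold_spec.loop_len

    def test_beta_hairpin_ee(self):
        spec = ScaffoldSpec(sse1_kind="E", sse2_kind="E", sse1_len=5,
                            sse2_len=5, loop_len=3, D=6.0, theta=160.0, seed=3)
        chain = make_scaffold(spec)
        sses = segment_sses(scaffold_assignment(spec), chain)
        motifs = extract_smotifs(sses, chain)
        assert len(motifs) == 1
        assert motifs[0].motif_type == "EE"

    def test_three_sses_share_middle(self, scaffold):
        n = len(scaffold.residues)
        states = "H" * 8 + "C" * 2 + "H" * 8 + "C" * 2 + "E" * (n - 20)
        sses = segment_sses(SSAssignment(states=list(states)), scaffold)
        motifs = extract_smotifs(sses, scaffold)
        assert len(motifs) == 2
        assert motifs[0].sse2 is motifs[1].sse1
        assert motifs[0].motif_type == "HH" and motifs[1].motif_type == "HE"

    def test_fewer_than_two_sses(self, scaffold):
        assert extract_smotifs([], scaffold) == []


class TestComputeGeometry:
    def test_parallel_helices(self):
        g = compute_geometry(synthetic_smotif(theta=0.0))
        assert g.theta <= 2.0

    def test_antiparallel(self):
        g = compute_geometry(synthetic_smotif(theta=180.0))
        assert g.theta >= 178.0

    @pytest.mark.parametrize("D", [5.0, 10.0, 15.0])
    @pytest.mark.parametrize("theta", [30.0, 90.0, 150.0])
    def test_scaffold_grid_recovery(self, D, theta):
        spec = ScaffoldSpec(D=D, theta=theta, loop_len=6, seed=1)
        g = scaffold_smotif(spec, make_scaffold(spec)).geometry
        assert abs(g.D - D) <= 1.0
        assert abs(g.theta - theta) <= 5.0

    @pytest.mark.parametrize("rho", [0.0, 45.0, 137.0, 250.0, 359.0])
    def test_rho_roundtrip(self, rho):
        g = compute_geometry(synthetic_smotif(rho=rho))
        assert g.rho == pytest.approx(rho, abs=1e-6)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        s = synthetic_smotif(D=8.0, theta=70.0, delta=60.0, rho=120.0)
        g0 = compute_geometry(s)
        for _ in range(5):
            t = random_rigid_transform(rng)
            def move(ax):
                return AxisFit(point=t(ax.point), direction=t.rotation @ ax.direction,
                               n_start=t(ax.n_start), c_end=t(ax.c_end))
            s2 = Smotif(sse1=SSE(s.sse1.kind, s.sse1.start, s.sse1.end,
                                 s.sse1.residue_ids, move(s.sse1.axis),
                                 s.sse1.start_index, s.sse1.end_index),
                        sse2=SSE(s.sse2.kind, s.sse2.start, s.sse2.end,
                                 s.sse2.residue_ids, move(s.sse2.axis),
                                 s.sse2.start_index, s.sse2.end_index),
                        loop_residue_ids=s.loop_residue_ids,
                        motif_type=s.motif_type)
            g = compute_geometry(s2)
            for name in ("D", "delta", "theta", "rho"):
                assert getattr(g, name) == pytest.approx(getattr(g0, name), abs=1e-6)

    def test_degenerate_flagged(self):
        g = compute_geometry(synthetic_smotif(D=0.0))
        assert g.degenerate


class TestGeometryDistance:
    def test_identity_zero(self):
        g = SmotifGeometry(D=10.0, delta=90.0, theta=45.0, rho=10.0, loop_length=5)
        assert geometry_distance(g, g) == 0.0

    def test_rho_wraparound(self):
        g1 = SmotifGeometry(D=10.0, delta=90.0, theta=45.0, rho=350.0, loop_length=5)
        g2 = SmotifGeometry(D=10.0, delta=90.0, theta=45.0, rho=10.0, loop_length=5)
        assert geometry_distance(g1, g2, weights=(1, 1, 1, 1)) == pytest.approx(20.0)

    def test_symmetry_over_random_pairs(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            a = SmotifGeometry(D=rng.uniform(0, 20), delta=rng.uniform(0, 180),
                               theta=rng.uniform(0, 180), rho=rng.uniform(0, 360),
                               loop_length=3)
            b = SmotifGeometry(D=rng.uniform(0, 20), delta=rng.uniform(0, 180),
                               theta=rng.uniform(0, 180), rho=rng.uniform(0, 360),
                               loop_length=3)
            assert geometry_distance(a, b) == pytest.approx(geometry_distance(b, a))

    def test_degenerate_rejected(self):
        good = SmotifGeometry(D=10.0, delta=90.0, theta=45.0, rho=0.0, loop_length=5)
        bad = SmotifGeometry(D=0.0, delta=float("nan"), theta=45.0,
                             rho=float("nan"), loop_length=5, degenerate=True)
        with pytest.raises(ValueError, match="degenerate"):
            geometry_distance(good, bad)


class TestSearchSimilar:
    def _library(self, n=20):
        return [synthetic_smotif(theta=30.0 + 5.0 * i) for i in range(n)]

    def test_query_in_library_ranks_first(self):
        lib = self._library()
        hits = search_similar(lib[7], lib, k=3)
        assert hits[0] is lib[7]
        assert geometry_distance(compute_geometry(hits[0]), compute_geometry(lib[7])) == 0.0

    def test_k_exceeds_library(self):
        lib = self._library(5)
        assert len(search_similar(lib[0], lib, k=50)) == 5

    def test_ranking_matches_bruteforce(self):
        lib = self._library()
        query = synthetic_smotif(theta=97.0)
        hits = search_similar(query, lib, k=len(lib))
        qg = compute_geometry(query)
        expected = sorted(range(len(lib)),
                          key=lambda i: (geometry_distance(qg, compute_geometry(lib[i])), i))
        got = [next(i for i, s in enumerate(lib) if s is h) for h in hits]
        assert got == expected

    def test_type_and_loop_length_restriction(self):
        lib = self._library(5) + [synthetic_smotif(theta=90.0, kind="HE")]
        query = synthetic_smotif(theta=90.0, kind="HE")
        hits = search_similar(query, lib, k=10, same_type=True)
        assert all(h.motif_type == "HE" for h in hits)

    def test_bad_k(self):
        lib = self._library(3)
        with pytest.raises(ValueError, match="k"):
            search_similar(lib[0], lib, k=0)
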