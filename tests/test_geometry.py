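"""Collective-variable and geometric-primitive correctness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gqfold import (
    ContactSet,
    CVVector,
    DegenerateGeometryError,
    Nucleotide,
    Structure,
    build_native_contacts,
    compute_drmsd,
    compute_ion_coordination,
    compute_q,
    compute_rg,
    compute_torsion,
    evaluate_cv_vector,
)
from gqfold.geometry import rational_switch

from conftest import random_rigid_motion, transform_structure


def _single_atom_structure(points, role="X", ions=()):
    nts = [
        Nucleotide(index=i + 1, name="G", atoms={role: np.asarray(p, float)})
        for i, p in enumerate(points)
    ]
    return Structure(nucleotides=nts, ions=np.asarray(list(ions), float).reshape(-1, 3))


class TestTorsion:
    @pytest.mark.parametrize(
        "pts, expected",
        [
            ([(1, 0, 0), (0, 0, 0), (0, 1, 0), (1, 1, 0)], 0.0),        # planar cis
            ([(1, 0, 0), (0, 0, 0), (0, 1, 0), (-1, 1, 0)], -180.0),    # planar trans
        ],
    )
    def test_planar_cases(self, pts, expected):
        assert compute_torsion(*pts) == pytest.approx(expected, abs=1e-10)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_mirror_flips_sign_and_reversal_preserves(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-1, 1, (4, 3))
        try:
            angle = compute_torsion(*pts)
        except DegenerateGeometryError:
            return
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert compute_torsion(*mirrored) == pytest.approx(-angle, abs=1e-8) or (
            abs(angle) == pytest.approx(180.0, abs=1e-8)
        )
        assert compute_torsion(*pts[::-1]) == pytest.approx(angle, abs=1e-8)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            compute_torsion((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
        with pytest.raises(DegenerateGeometryError):
            compute_torsion((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_range_convention(self):
        # trans is reported as -180, never +180
        assert compute_torsion((1, 0, 0), (0, 0, 0), (0, 1, 0), (-1, 1, 0)) == -180.0


class TestRadiusOfGyration:
    def test_single_point_is_zero(self):
        s = _single_atom_structure([(0.3, 0.2, 0.1)])
        assert compute_rg(s, ("X",)) == 0.0

    def test_two_points(self):
        s = _single_atom_structure([(0, 0, 0), (0.4, 0, 0)])
        assert compute_rg(s, ("X",)) == pytest.approx(0.2)

    def test_square(self):
        a = 0.2
        s = _single_atom_structure([(0, 0, 0), (a, 0, 0), (a, a, 0), (0, a, 0)])
        assert compute_rg(s, ("X",)) == pytest.approx(a / np.sqrt(2), rel=1e-9)

    def test_empty_selection_rejected(self, native):
        with pytest.raises(ValueError):
            compute_rg(native, ("NOPE",))


class TestNativeContacts:
    def test_two_nucleotide_cutoffs(self):
        s = _single_atom_structure([(0, 0, 0), (0.3, 0, 0)])
        assert build_native_contacts(s, ("X",), cutoff=0.45, min_separation=1).n_total == 1
        assert build_native_contacts(s, ("X",), cutoff=0.2, min_separation=1).n_total == 0

    def test_adjacent_nucleotides_excluded_by_default(self):
        s = _single_atom_structure([(0, 0, 0), (0.3, 0, 0)])
        assert build_native_contacts(s, ("X",), cutoff=0.45).n_total == 0

    def test_matches_brute_force_on_toy_quadruplex(self, native):
        roles = ("O6", "N9", "C8")
        cs = build_native_contacts(native, roles, cutoff=0.45)
        count = 0
        nts = native.nucleotides
        for a in range(len(nts)):
            for b in range(a + 1, len(nts)):
                if abs(nts[b].index - nts[a].index) < 2:
                    continue
                for ra in roles:
                    for rb in roles:
                        d = np.linalg.norm(nts[a].atom(ra) - nts[b].atom(rb))
                        if d < 0.45:
                            count += 1
        assert cs.n_total == count > 0

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            ContactSet(pairs=[(3, "X", 1, "X", 0.3)])


class TestQ:
    def test_native_is_one_and_stretched_is_zero(self, native, contacts):
        assert compute_q(native, contacts) == 1.0
        far = native.copy()
        for nt in far.nucleotides:
            for role in nt.atoms:
                nt.atoms[role] = nt.atoms[role] * 3.0
        assert compute_q(far, contacts) == 0.0

    def test_half_formed_fraction(self):
        # 2 of 4 contacts within lambda * native
        pts = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)]
        s = _single_atom_structure(pts)
        pairs = [
            (1, "X", 3, "X", 2.0), (1, "X", 4, "X", 3.0),   # formed (d == native)
            (2, "X", 4, "X", 0.5), (1, "X", 3, "X", 0.5),   # broken (d >= 1.2 * native)
        ]
        assert compute_q(s, ContactSet(pairs=pairs)) == 0.5

    def test_empty_contacts_rejected(self, native):
        with pytest.raises(ValueError):
            compute_q(native, ContactSet(pairs=[]))

    def test_smooth_converges_to_sharp(self, native, contacts):
        # pointwise convergence away from the switching discontinuity: pairs
        # within 0.5 % of the cutoff are excused from the comparison
        rng = np.random.default_rng(5)
        for _ in range(20):
            fr = native.copy()
            for nt in fr.nucleotides:
                for role in nt.atoms:
                    nt.atoms[role] = nt.atoms[role] + rng.normal(0, 0.05, 3)
            sharp = compute_q(fr, contacts, mode="sharp")
            smooth = compute_q(fr, contacts, mode="smooth", steepness=500.0)
            from gqfold.geometry import _contact_distances
            d = _contact_distances(fr, contacts)
            d0 = 1.2 * np.array([p[4] for p in contacts.pairs])
            boundary = np.mean(np.abs(d / d0 - 1.0) < 5e-3)
            assert abs(smooth - sharp) <= boundary + 0.01


class TestDRMSD:
    def test_self_is_zero(self, native):
        assert compute_drmsd(native, native) == 0.0

    def test_rigid_motion_invariance(self, native):
        rng = np.random.default_rng(2)
        for _ in range(5):
            rot, shift = random_rigid_motion(rng)
            moved = transform_structure(native, rot, shift)
            assert compute_drmsd(moved, native) == pytest.approx(0.0, abs=1e-9)
            assert compute_rg(moved, ("C4'",)) == pytest.approx(
                compute_rg(native, ("C4'",)), abs=1e-9)

    def test_hand_worked_value(self):
        # native pairwise distances (0.3, 0.3, 0.6) vs (0.4, 0.4, 0.8)
        nat = _single_atom_structure([(0, 0, 0), (0.3, 0, 0), (0.6, 0, 0)])
        fr = _single_atom_structure([(0, 0, 0), (0.4, 0, 0), (0.8, 0, 0)])
        assert compute_drmsd(fr, nat, ("X",)) == pytest.approx(
            np.sqrt(0.06 / 3), rel=1e-6)

    def test_selection_mismatch_rejected(self, native):
        short = _single_atom_structure([(0, 0, 0), (1, 0, 0), (2, 0, 0)], role="C4'")
        with pytest.raises(ValueError):
            compute_drmsd(short, native)


class TestIonCoordination:
    def test_no_ions_is_zero(self):
        s = _single_atom_structure([(0, 0, 0)], role="O6")
        assert compute_ion_coordination(s) == 0.0

    def test_single_close_ion(self):
        s = _single_atom_structure([(0, 0, 0)], role="O6", ions=[(0.1, 0, 0)])
        assert compute_ion_coordination(s, r0=0.35) == 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        o6 = rng.uniform(0, 1, (12, 3))
        ions = rng.uniform(0, 1, (3, 3))
        s = _single_atom_structure(o6, role="O6", ions=ions)
        expected = sum(
            1 for i in ions for p in o6 if np.linalg.norm(i - p) < 0.35
        )
        assert compute_ion_coordination(s, r0=0.35) == expected

    def test_smooth_converges_to_sharp(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            o6 = rng.uniform(0, 0.8, (6, 3))
            ions = rng.uniform(0, 0.8, (2, 3))
            s = _single_atom_structure(o6, role="O6", ions=ions)
            sharp = compute_ion_coordination(s, mode="sharp")
            smooth = compute_ion_coordination(s, mode="smooth", steepness=500.0)
            assert smooth == pytest.approx(sharp, abs=0.01)


class TestSwitching:
    def test_limit_value_at_r0(self):
        assert rational_switch(np.array([0.35]), 0.35)[0] == pytest.approx(0.6)

    def test_monotone_bounds(self):
        r = np.linspace(0.01, 1.2, 200)
        s = rational_switch(r, 0.35)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))


class TestCVVector:
    def test_native_vector(self, native, contacts):
        v = evaluate_cv_vector(native, native, contacts)
        assert v.q == 1.0 and v.drmsd == 0.0

    def test_consistency_with_standalone_ops(self, native, contacts):
        rng = np.random.default_rng(9)
        fr = native.copy()
        for nt in fr.nucleotides:
            for role in nt.atoms:
                nt.atoms[role] = nt.atoms[role] + rng.normal(0, 0.03, 3)
        v = evaluate_cv_vector(fr, native, contacts)
        assert v.q == compute_q(fr, contacts)
        assert v.drmsd == compute_drmsd(fr, native)
        assert v.n_ion == compute_ion_coordination(fr)
        assert v.rg == compute_rg(fr, ("C4'",))

    def test_extended_chain_ordering(self, native, contacts):
        far = native.copy()
        for nt in far.nucleotides:
            for role in nt.atoms:
                nt.atoms[role] = nt.atoms[role] * 2.5
        v = evaluate_cv_vector(far, native, contacts)
        assert v.q < 0.05 and v.drmsd > 0
        assert v.rg > evaluate_cv_vector(native, native, contacts).rg

    def test_out_of_range_q_rejected(self):
        with pytest.raises(ValueError):
            CVVector(q=1.5, drmsd=0.0, n_ion=0.0, rg=0.0)
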