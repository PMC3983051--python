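"""Leader clustering, H-bond maps, ion binding, syn/anti, pathway graphs."""

import numpy as np
import pytest

from gqfold import (
    Trajectory,
    build_pathway_graph,
    classify_glycosidic,
    glycosidic_summary,
    hbond_map,
    ion_binding_profile,
    leader_cluster,
)
from gqfold.ensemble import collapse_labels


def _scaled(native, alpha):
    fr = native.copy()
    for nt in fr.nucleotides:
        for role in nt.atoms:
            nt.atoms[role] = alpha * nt.atoms[role]
    return fr


class TestLeaderCluster:
    def test_single_cluster_when_threshold_large(self, small_ensemble):
        _spec, traj = small_ensemble
        cs = leader_cluster(traj.frames[:50], threshold=100.0)
        assert cs.n_clusters == 1
        assert cs.populations[0] == 1.0
        assert cs.representatives == [0]

    def test_two_cluster_populations(self, native):
        # F1, F2 close; F3 far from both
        frames = [_scaled(native, 1.0), _scaled(native, 1.02), _scaled(native, 1.5)]
        cs = leader_cluster(frames, threshold=0.3)
        assert cs.n_clusters == 2
        assert list(cs.membership) == [0, 0, 1]
        assert np.allclose(sorted(cs.populations), [1 / 3, 2 / 3])
        assert cs.representatives == [0, 2]

    def test_threshold_limits(self, native):
        frames = [_scaled(native, a) for a in (1.0, 1.3, 1.6, 1.9)]
        assert leader_cluster(frames, threshold=1e-9).n_clusters == 4
        assert leader_cluster(frames, threshold=1e9).n_clusters == 1

    def test_populations_sum_to_one(self, small_ensemble):
        _spec, traj = small_ensemble
        cs = leader_cluster(traj, threshold=0.05)
        assert cs.populations.sum() == pytest.approx(1.0)
        assert len(cs.membership) == len(traj)

    def test_matches_independent_reference(self, native):
        # brute-force oracle: full pairwise distance matrix, then the same
        # sequential pass
        from gqfold.geometry import compute_drmsd

        rng = np.random.default_rng(12)
        frames = [_scaled(native, 1.0 + 0.12 * rng.integers(0, 5)) for _ in range(40)]
        n = len(frames)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dist[i, j] = dist[j, i] = compute_drmsd(frames[i], frames[j], ("C4'",))
        for thr in (0.1, 0.3, 0.5):
            reps, mem = [], []
            for i in range(n):
                for k, r in enumerate(reps):
                    if dist[i, r] < thr:
                        mem.append(k)
                        break
                else:
                    mem.append(len(reps))
                    reps.append(i)
            cs = leader_cluster(frames, threshold=thr)
            assert cs.representatives == reps
            assert list(cs.membership) == mem


class TestHBondMap:
    def test_planted_probabilities_within_binomial_ci(self, native, small_ensemble):
        spec, traj = small_ensemble
        h = hbond_map(traj, native=native)
        n = len(traj)
        for (i, j), p in spec.hbond_probs.items():
            half = 2.576 * np.sqrt(p * (1 - p) / n)
            assert abs(h.pair(i, j) - p) <= half + 1e-9, (i, j)

    def test_always_and_never_pairs(self, native, small_ensemble):
        _spec, traj = small_ensemble
        h = hbond_map(traj, native=native)
        m = h.matrix
        assert m.max() <= 1.0 and m.min() >= 0.0
        assert np.allclose(np.diag(m), 0.0)
        # native closure bond (D0 of 10 -> A0 of 1) is never perturbed
        assert h.pair(1, 10) == 1.0
        # a far pair with no donors/acceptors nearby never bonds
        assert h.pair(2, 6) == 0.0

    def test_duplication_invariance(self, native, small_ensemble):
        _spec, traj = small_ensemble
        sub = traj.frames[:40]
        t1 = Trajectory(frames=sub, times=np.arange(40.0))
        t2 = Trajectory(frames=sub + sub, times=np.arange(80.0))
        a = hbond_map(t1, native=native)
        b = hbond_map(t2, native=native)
        assert np.allclose(a.matrix, b.matrix)

    def test_native_annotation(self, native, small_ensemble):
        _spec, traj = small_ensemble
        h = hbond_map(traj, native=native)
        first = native.nucleotides[0].index
        assert h.native[1 - first, 4 - first]       # tetrad ring bond
        assert not h.native[2 - first, 9 - first]   # planted non-native pair


class TestIonBinding:
    def test_planted_occupancies(self, small_ensemble):
        spec, traj = small_ensemble
        prof = ion_binding_profile(traj)
        q0, q1 = spec.ion_site_occupancies
        expected_count = q0 + q1
        n = len(traj)
        sig = np.sqrt((q0 * (1 - q0) + q1 * (1 - q1)) / n)
        assert abs(prof.mean_bound_count - expected_count) <= 3 * sig + 1e-9
        # middle-layer nucleotides see either site, boundary layers one site
        for k, p in zip(prof.indices, prof.probabilities):
            layer = (k - 1) % 3
            planted = {0: q0, 1: 1 - (1 - q0) * (1 - q1), 2: q1}[layer]
            assert abs(p - planted) <= 2.576 * np.sqrt(planted * (1 - planted) / n) + 1e-9

    def test_no_ions_all_zero(self, native):
        fr = native.copy()
        fr.ions = np.zeros((0, 3))
        traj = Trajectory(frames=[fr, fr.copy()], times=np.array([0.0, 1.0]))
        prof = ion_binding_profile(traj)
        assert prof.mean_bound_count == 0.0
        assert np.all(prof.probabilities == 0.0)

    def test_single_fixed_ion(self, native):
        fr = native.copy()
        fr.ions = (fr.nucleotides[0].atom("O6") + np.array([0.1, 0, 0]))[None, :]
        traj = Trajectory(frames=[fr], times=np.array([0.0]))
        prof = ion_binding_profile(traj)
        assert prof.probabilities[0] == 1.0
        assert prof.mean_bound_count == 1.0


class TestGlycosidic:
    def test_constant_windows(self):
        t = np.arange(10.0)
        anti = classify_glycosidic(np.full(10, 180.0), t)
        assert anti.classification == "anti" and anti.n_transitions == 0
        syn = classify_glycosidic(np.full(10, 0.0), t)
        assert syn.classification == "syn"

    def test_noiseless_telegraph_exact_transitions(self):
        rng = np.random.default_rng(3)
        states = [0]
        for _ in range(499):
            states.append(states[-1] ^ (rng.random() < 0.1))
        chi = np.where(np.array(states) == 0, 55.0, -120.0)
        tr = classify_glycosidic(chi, np.arange(500.0))
        planted = int(np.sum(np.array(states)[1:] != np.array(states)[:-1]))
        assert tr.n_transitions == planted
        assert tr.classification == "fluctuating"

    def test_dwell_recovery_on_markov_input(self, small_ensemble):
        spec, traj = small_ensemble
        summaries = glycosidic_summary(traj)
        indices = [nt.index for nt in traj.frames[0].nucleotides]
        for idx, (syn_tau, anti_tau) in spec.chi_dwell.items():
            tr = summaries[indices.index(idx)]
            assert tr.classification == "fluctuating"
            if tr.n_transitions >= 20:
                est = np.mean([d for d in tr.mean_dwell.values() if d is not None])
                assert syn_tau / 1.5 <= est <= syn_tau * 1.5

    def test_fluctuation_rule_thresholds(self):
        t = np.arange(100.0)
        # one brief excursion: occupancy high but 2 transitions -> fluctuating
        chi = np.full(100, -120.0)
        chi[50:52] = 30.0
        tr = classify_glycosidic(chi, t)
        assert tr.n_transitions == 2 and tr.classification == "fluctuating"


class TestPathwayGraph:
    def test_single_chain(self):
        g = build_pathway_graph([["A", "B", "C"]])
        assert g.edges == {("A", "B"): 1, ("B", "C"): 1}
        assert g.n_trajectories == 1

    def test_multiplicity_split(self):
        seqs = [["A", "B", "D"]] * 8 + [["A", "C", "D"]] + [["A", "D"]]
        g = build_pathway_graph(seqs)
        assert g.edges[("A", "B")] == 8 and g.edges[("B", "D")] == 8
        assert g.edges[("A", "C")] == 1 and g.edges[("A", "D")] == 1
        assert g.paths[("A", "B", "D")] == 8
        assert g.n_trajectories == 10

    def test_run_length_collapse(self):
        assert collapse_labels(["A", "A", "B"]) == ("A", "B")
        g = build_pathway_graph([["A", "A", "B"]])
        assert g.edges == {("A", "B"): 1}

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_pathway_graph([[]])

    def test_dot_and_json_exports(self):
        g = build_pathway_graph([["A", "B"], ["A", "B"]])
        assert '"A" -> "B" [label="2"]' in g.to_dot()
        d = g.to_json_dict()
        assert d["edges"][0]["count"] == 2
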