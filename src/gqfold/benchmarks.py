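"""Reproducible validation experiments on toy landscapes and synthetic
ensembles.

Each function runs one self-contained benchmark of the method stack at its
documented study conditions and returns plain numbers: metadynamics
free-energy recovery on the double well, the exchange criterion against its
closed form, a full BEMD integration with basin identification, Boltzmann
sampling of the unbiased dynamics, leader clustering against a brute-force
reference, planted-parameter recovery on the intermediate ensemble, and the
unfolding-pathway split.
"""

from __future__ import annotations

import numpy as np

from . import bemd, ensemble, fel, synthetic
from .config import KB
from .geometry import ContactSet, Structure, compute_drmsd

TEMPERATURE = 300.0
KBT = KB * TEMPERATURE

#: metadynamics benchmark protocol: hills well below kBT, deposited slower
#: than the intra-well relaxation time (~70 ps at D = kBT/gamma), profile
#: averaged over the post-fill plateau
METAD_SCHEDULE = dict(dt=2e-4, deposit_stride=0.02, exchange_stride=1.0,
                      sample_stride=1e-3, total_time=100.0)
METAD_HILL = dict(width=0.1, height=0.05)
DOUBLE_WELL_BARRIER = 5.0  # kJ/mol


def metad_double_well_recovery(seeds=(1, 2, 3)) -> dict:
    """|F_est(0) - h| on U = h (x^2 - 1)^2, per seed and averaged."""
    land = synthetic.make_analytic_landscape("double_well", h=DOUBLE_WELL_BARRIER)
    sched = bemd.Schedule(**METAD_SCHEDULE)
    errors = []
    for seed in seeds:
        run = bemd.run_metadynamics_1d(land, sched, seed=int(seed),
                                       temperature=TEMPERATURE, **METAD_HILL)
        barrier = float(np.interp(0.0, run.grid, run.profile))  # profile min is 0
        errors.append(abs(barrier - DOUBLE_WELL_BARRIER))
    return {
        "errors_kj_mol": errors,
        "mean_abs_error_kj_mol": float(np.mean(errors)),
        "n_steps_per_seed": sched.n_steps,
    }


def exchange_criterion_check(seed: int = 0, n_trials: int = 10_000) -> dict:
    """Empirical swap acceptance for a planted Delta = -kB*T and for empty
    biases, against min(1, exp(Delta/kBT))."""
    bias = bemd.GaussianBias("x")
    bias.deposit_kernel(0.0, 0.1, KBT, t=0.0)
    rng = np.random.default_rng(seed)
    cv = bemd.CoordinateCV("x", 0)

    def planted_pair():
        a = bemd.ReplicaState(0, np.array([1.0]), bias, cv, TEMPERATURE,
                              np.random.default_rng(0))
        b = bemd.ReplicaState(1, np.array([0.0]), bemd.GaussianBias(None), None,
                              TEMPERATURE, np.random.default_rng(1))
        return a, b

    accepted = sum(
        bemd.attempt_exchange(*planted_pair(), 0.0, rng) for _ in range(n_trials)
    )
    empty_accepted = sum(
        bemd.attempt_exchange(
            bemd.ReplicaState(0, np.array([0.5]), bemd.GaussianBias(None), None,
                              TEMPERATURE, np.random.default_rng(2)),
            bemd.ReplicaState(1, np.array([1.5]), bemd.GaussianBias(None), None,
                              TEMPERATURE, np.random.default_rng(3)),
            0.0, rng)
        for _ in range(n_trials)
    )
    return {
        "planted_acceptance": accepted / n_trials,
        "planted_target": float(np.exp(-1.0)),
        "empty_bias_acceptance": empty_accepted / n_trials,
        "n_trials": n_trials,
    }


def bemd_two_basin_integration(seed: int = 1, total_time: float = 20.0) -> dict:
    """2 biased + 2 neutral replicas on the two-basin landscape: basin count
    and locations from the neutral-replica FEL, exchange-curve linearity."""
    land = synthetic.make_analytic_landscape("two_basin_2d", h=5.0)
    cvs = [bemd.CoordinateCV("x", 0, grid_range=land.domain),
           bemd.CoordinateCV("y", 1, grid_range=land.domain)]
    sched = bemd.Schedule(dt=2e-4, deposit_stride=0.02, exchange_stride=0.005,
                          sample_stride=2e-3, total_time=total_time)
    res = bemd.run_bemd(land, cvs, n_biased=2, n_neutral=2, schedule=sched,
                        widths=[0.1, 0.1], height=0.1, temperature=TEMPERATURE,
                        seed=seed, x0=(1.0, 0.0))
    neutral = [i for i, r in enumerate(res.replicas) if r.cv is None]
    samples = np.vstack([res.traces[i] for i in neutral])
    surface = fel.estimate_fel(samples, bins=24, min_count=5, axes=("x", "y"),
                               temperature=TEMPERATURE)
    basins = fel.identify_basins(surface, temperature=TEMPERATURE)
    locations = [
        (float(surface.centers(0)[b[0]]), float(surface.centers(1)[b[1]]))
        for b, _v in basins.minima
    ]
    basin_bins = [tuple(int(i) for i in b) for b, _v in basins.minima]
    planted_bins = [
        tuple(int(np.searchsorted(surface.edges[k], m[k]) - 1) for k in range(2))
        for m in land.minima
    ]
    bin_widths = [float(np.diff(surface.edges[k]).max()) for k in range(2)]
    diags = fel.exchange_diagnostics(res.exchange_logs)
    r2 = [r.r_squared for r in diags.replicas if r.r_squared is not None]
    return {
        "n_basins": basins.n_basins,
        "basin_locations": locations,
        "basin_bins": basin_bins,
        "planted_minima": [tuple(m) for m in land.minima],
        "planted_bins": planted_bins,
        "bin_widths": bin_widths,
        "min_r_squared": float(min(r2)) if r2 else None,
        "mean_acceptance": float(np.mean(
            [r.mean_acceptance for r in diags.replicas])),
        "n_samples": int(samples.shape[0]),
    }


def boltzmann_sampling_check(seed: int = 1, n_steps: int = 100_000) -> dict:
    """Chi-square agreement of unbiased Langevin samples on the double well
    with the analytic Boltzmann bin probabilities."""
    land = synthetic.make_analytic_landscape("double_well", h=DOUBLE_WELL_BARRIER)
    samples = bemd.run_langevin(land, [1.0], n_steps, dt=2e-3, friction=1.0,
                                temperature=TEMPERATURE, seed=seed)
    chk = fel.boltzmann_check(samples[:, 0], land.energy,
                              temperature=TEMPERATURE, n_bins=10)
    return {
        "chi2": chk.chi2, "dof": chk.dof, "pvalue": chk.pvalue,
        "n_bins": chk.dof + 1, "n_samples": chk.n_samples,
        "n_effective": chk.n_effective,
    }


def _reference_leader(frames: list[Structure], threshold: float):
    """Brute-force reference: precompute the full pairwise dRMSD matrix,
    then run the sequential pass on it (independent of the streaming path)."""
    n = len(frames)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = compute_drmsd(frames[i], frames[j], ("C4'",))
    reps: list[int] = []
    member = []
    for i in range(n):
        for k, r in enumerate(reps):
            if dist[i, r] < threshold:
                member.append(k)
                break
        else:
            member.append(len(reps))
            reps.append(i)
    return reps, member


def leader_clustering_reference_check(seed: int = 0,
                                      thresholds=(0.1, 0.3, 0.5)) -> dict:
    """Exact agreement of leader clustering with the brute-force reference
    on 100 mixed-stage synthetic frames, per threshold."""
    native = synthetic.make_toy_quadruplex()
    trajs, _labels = synthetic.make_unfolding_set(
        native, [(("a", "b", "c", "d"), 5)], frames_per_stage=5,
        noise=0.07, stage_scale_step=0.2, seed=seed)
    frames = [fr for tr in trajs for fr in tr.frames]
    assert len(frames) == 100
    mismatches = 0
    cluster_counts = {}
    for thr in thresholds:
        cs = ensemble.leader_cluster(frames, threshold=thr)
        reps, member = _reference_leader(frames, thr)
        same = (cs.representatives == reps and list(cs.membership) == member
                and np.allclose(cs.populations,
                                np.bincount(member) / len(frames)))
        mismatches += 0 if same else 1
        cluster_counts[thr] = cs.n_clusters
    return {"mismatched_thresholds": mismatches, "n_frames": len(frames),
            "cluster_counts": cluster_counts}


def parameter_recovery(seed: int = 0, n_frames: int = 2000) -> dict:
    """Recovery of every planted statistic of the default intermediate
    ensemble: H-bond probabilities, ion occupancies and bound count,
    syn/anti telegraph dwell and classification."""
    native = synthetic.make_toy_quadruplex()
    spec = synthetic.default_intermediate_spec(seed=seed)
    spec.n_frames = n_frames
    traj = synthetic.make_intermediate_ensemble(spec, native)

    hmap = ensemble.hbond_map(traj, native=native)
    first = native.nucleotides[0].index
    native_pairs = [(i, j) for (i, j) in spec.hbond_probs
                    if hmap.native[i - first, j - first]]
    nonnative_pairs = [(i, j) for (i, j) in spec.hbond_probs
                       if not hmap.native[i - first, j - first]]
    hb = {
        "native_planted": spec.hbond_probs[native_pairs[0]],
        "native_recovered": [hmap.pair(i, j) for i, j in native_pairs],
        "nonnative_planted": spec.hbond_probs[nonnative_pairs[0]],
        "nonnative_recovered": [hmap.pair(i, j) for i, j in nonnative_pairs],
    }

    profile = ensemble.ion_binding_profile(traj)
    traces = ensemble.glycosidic_summary(traj)
    indices = [nt.index for nt in traj.frames[0].nucleotides]
    dwells, transitions, classifications = [], [], []
    for idx, (tau_syn, _tau_anti) in spec.chi_dwell.items():
        tr = traces[indices.index(idx)]
        classifications.append(tr.classification)
        transitions.append(tr.n_transitions)
        dwells.append(float(np.mean(
            [d for d in tr.mean_dwell.values() if d is not None])))
    return {
        "n_frames": n_frames,
        "hbond": hb,
        "ion_mean_bound_count": profile.mean_bound_count,
        "ion_planted_count": float(sum(spec.ion_site_occupancies)),
        "dwell_planted_ns": float(spec.chi_dwell[next(iter(spec.chi_dwell))][0]),
        "dwell_recovered_ns": dwells,
        "n_transitions": transitions,
        "classifications": classifications,
    }


def pathway_split_recovery(seed: int = 0) -> dict:
    """Edge-count recovery on the planted 8/1/1 unfolding split after stage
    labeling by leader clustering of the pooled frames."""
    native = synthetic.make_toy_quadruplex()
    pathways = [
        (("native", "triplex", "hairpin", "unfolded"), 8),
        (("native", "misfolded", "unfolded"), 1),
        (("native", "unfolded"), 1),
    ]
    trajs, true_labels = synthetic.make_unfolding_set(
        native, pathways, n_trajectories=10, seed=seed)
    frames = [fr for tr in trajs for fr in tr.frames]
    cs = ensemble.leader_cluster(frames, threshold=0.45)
    seqs, k = [], 0
    for tr in trajs:
        seqs.append([int(c) for c in cs.membership[k:k + len(tr.frames)]])
        k += len(tr.frames)
    recovered = ensemble.build_pathway_graph(seqs)
    truth = ensemble.build_pathway_graph(true_labels)
    return {
        "recovered_edge_counts": sorted(recovered.edges.values(), reverse=True),
        "true_edge_counts": sorted(truth.edges.values(), reverse=True),
        "recovered_path_counts": sorted(recovered.paths.values(), reverse=True),
        "n_trajectories": 10,
    }


def cv_worked_examples() -> dict:
    """Exact CV identities: Q and dRMSD on the native reference, rigid-motion
    invariance, and the three-point dRMSD hand value."""
    from .geometry import (Nucleotide, build_native_contacts, compute_q,
                           compute_rg)

    native = synthetic.make_toy_quadruplex()
    contacts = build_native_contacts(native)
    q_native = compute_q(native, contacts)
    drmsd_native = compute_drmsd(native, native)

    rng = np.random.default_rng(0)
    th = rng.uniform(0, np.pi)
    rot = np.array([[np.cos(th), -np.sin(th), 0],
                    [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    moved = native.copy()
    for nt in moved.nucleotides:
        for role in nt.atoms:
            nt.atoms[role] = rot @ nt.atoms[role] + np.array([1.0, -2.0, 0.5])
    invariance = max(
        abs(compute_drmsd(moved, native)),
        abs(compute_rg(moved, ("C4'",)) - compute_rg(native, ("C4'",))),
    )

    def chain(ds):
        pts = np.zeros((3, 3))
        pts[1, 0] = ds[0]
        pts[2, 0] = ds[1]
        return Structure(nucleotides=[
            Nucleotide(i + 1, "G", {"X": pts[i]}) for i in range(3)])

    hand = compute_drmsd(chain((0.4, 0.8)), chain((0.3, 0.6)), ("X",))
    return {
        "q_native": q_native,
        "n_contacts": contacts.n_total,
        "drmsd_native_nm": drmsd_native,
        "rigid_motion_residual_nm": float(invariance),
        "drmsd_worked_example_nm": float(hand),
        "drmsd_worked_example_expected_nm": float(np.sqrt(0.06 / 3.0)),
    }
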