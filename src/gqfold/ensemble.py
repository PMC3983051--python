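"""Per-intermediate ensemble statistics.

Given conformational ensembles of a folding intermediate (here synthetic
stand-ins for conventional-MD trajectories), this module computes the
quantities used to characterise each state: leader clustering of frames,
pairwise hydrogen-bond formation-probability maps, per-nucleotide cation
binding probabilities and mean bound-ion counts, syn/anti classification of
the glycosidic torsion per nucleotide, and directed pathway graphs over
stage-label sequences of unfolding trajectories.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from . import config
from .geometry import (
    Structure,
    Trajectory,
    compute_drmsd,
    compute_torsion,
)

SYN, ANTI = "syn", "anti"


# ---------------------------------------------------------------------------
# Leader clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterSet:
    """One-pass leader clustering result.

    ``representatives[k]`` is the frame index that founded cluster k (its
    first-seen member); ``membership[i]`` is the cluster of frame i;
    ``populations`` are normalised cluster fractions in creation order.
    """

    representatives: list[int]
    membership: np.ndarray
    populations: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def _distance_vectors(frames, atom_selection) -> np.ndarray:
    """Condensed pairwise-distance vector per frame (for fast dRMSD)."""
    mats = []
    for fr in frames:
        pts = np.concatenate([
            fr.coords(role) for role in atom_selection
        ]) if isinstance(atom_selection, (list, tuple)) else fr.coords(atom_selection)
        iu = np.triu_indices(pts.shape[0], k=1)
        mats.append(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)[iu])
    return np.asarray(mats)


def leader_cluster(
    frames,
    threshold: float = config.CLUSTER_THRESHOLD,
    distance=None,
    atom_selection=("C4'",),
) -> ClusterSet:
    """Sequential leader algorithm over trajectory frames.

    Each frame is compared with the representatives of the clusters created
    so far, in creation order; it joins the FIRST representative within
    ``threshold`` (dRMSD by default), otherwise it founds a new cluster.
    The result is inherently order-dependent, as is the original recipe.
    """
    if isinstance(frames, Trajectory):
        frames = frames.frames
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    if not threshold > 0:
        raise ValueError("threshold must be positive")

    if distance is None:
        dv = _distance_vectors(frames, atom_selection)

        def distance_to_rep(i, rep):
            return float(np.sqrt(np.mean((dv[i] - dv[rep]) ** 2)))
    else:
        def distance_to_rep(i, rep):
            return float(distance(frames[i], frames[rep]))

    reps: list[int] = []
    member = np.empty(len(frames), dtype=int)
    for i in range(len(frames)):
        for k, rep in enumerate(reps):
            if distance_to_rep(i, rep) < threshold:
                member[i] = k
                break
        else:
            member[i] = len(reps)
            reps.append(i)
    pops = np.bincount(member, minlength=len(reps)) / len(frames)
    return ClusterSet(representatives=reps, membership=member, populations=pops)


# ---------------------------------------------------------------------------
# Hydrogen-bond probability maps
# ---------------------------------------------------------------------------


@dataclass
class HBondMap:
    """Pairwise hydrogen-bond formation probabilities over an ensemble.

    ``matrix[i, j]`` is the fraction of frames in which nucleotides i+first
    and j+first share at least one donor-acceptor contact (symmetric, zero
    diagonal); ``native[i, j]`` marks pairs bonded in the native reference.
    """

    matrix: np.ndarray
    native: np.ndarray
    indices: list[int]

    def pair(self, i: int, j: int) -> float:
        first = self.indices[0]
        return float(self.matrix[i - first, j - first])


def _hbond_contacts(structure: Structure, donors, acceptors, cutoff: float) -> np.ndarray:
    """Boolean (n, n) matrix: any donor(i)-acceptor(j) pair within cutoff."""
    don = np.stack([structure.coords(r) for r in donors], axis=1)      # (n, nd, 3)
    acc = np.stack([structure.coords(r) for r in acceptors], axis=1)   # (n, na, 3)
    d = np.linalg.norm(don[:, :, None, None, :] - acc[None, None, :, :, :], axis=-1)
    formed = np.any(d <= cutoff, axis=(1, 3))
    formed = formed | formed.T
    np.fill_diagonal(formed, False)
    return formed


def hbond_map(
    trajectory: Trajectory,
    native: Structure | None = None,
    donors=config.DONOR_ROLES,
    acceptors=config.ACCEPTOR_ROLES,
    cutoff: float = config.HBOND_CUTOFF,
) -> HBondMap:
    """Fraction of frames, per nucleotide pair, with a donor-acceptor
    contact within ``cutoff`` (distance-only criterion on the reduced
    representation; an angular criterion applies only with explicit H).

    Pairs are annotated native/non-native against the same criterion
    evaluated on ``native`` (all False when no native is given).
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    n = trajectory.frames[0].n_nucleotides
    counts = np.zeros((n, n))
    for fr in trajectory.frames:
        counts += _hbond_contacts(fr, donors, acceptors, cutoff)
    native_mask = (
        _hbond_contacts(native, donors, acceptors, cutoff)
        if native is not None else np.zeros((n, n), dtype=bool)
    )
    return HBondMap(
        matrix=counts / len(trajectory),
        native=native_mask,
        indices=[nt.index for nt in trajectory.frames[0].nucleotides],
    )


# ---------------------------------------------------------------------------
# Ion binding
# ---------------------------------------------------------------------------


@dataclass
class IonBindingProfile:
    """Cation binding statistics: per-nucleotide probability that at least
    one ion sits within the cutoff of its O6, and the mean number of bound
    ions per frame (each ion counted once even if near several O6)."""

    probabilities: np.ndarray
    mean_bound_count: float
    indices: list[int]


def ion_binding_profile(
    trajectory: Trajectory,
    cutoff: float = config.ION_BOUND_CUTOFF,
    binding_role: str = "O6",
) -> IonBindingProfile:
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    n = trajectory.frames[0].n_nucleotides
    bound_frames = np.zeros(n)
    bound_ions_total = 0.0
    for fr in trajectory.frames:
        targets = fr.coords(binding_role)
        if fr.ions.shape[0] == 0:
            continue
        d = np.linalg.norm(fr.ions[:, None, :] - targets[None, :, :], axis=-1)
        near = d < cutoff
        bound_frames += np.any(near, axis=0)
        bound_ions_total += float(np.sum(np.any(near, axis=1)))
    return IonBindingProfile(
        probabilities=bound_frames / len(trajectory),
        mean_bound_count=bound_ions_total / len(trajectory),
        indices=[nt.index for nt in trajectory.frames[0].nucleotides],
    )


# ---------------------------------------------------------------------------
# Glycosidic syn/anti classification
# ---------------------------------------------------------------------------


@dataclass
class GlycosidicTrace:
    """Two-state reading of one nucleotide's glycosidic torsion series.

    ``states`` holds "syn"/"anti" per sample from the angular windows;
    ``classification`` is the single state when it occupies at least the
    occupancy threshold with fewer than the transition threshold of state
    changes, otherwise "fluctuating".  ``mean_dwell`` maps each visited
    state to its mean dwell time in ns (None when never visited).
    """

    chi: np.ndarray
    times: np.ndarray
    states: np.ndarray
    classification: str
    n_transitions: int
    mean_dwell: dict


def chi_series(trajectory: Trajectory, nucleotide_index: int) -> np.ndarray:
    """Glycosidic torsion (O4'-C1'-N9-C8) of one nucleotide over frames."""
    first = trajectory.frames[0].nucleotides[0].index
    k = nucleotide_index - first
    out = np.empty(len(trajectory))
    for f, fr in enumerate(trajectory.frames):
        nt = fr.nucleotides[k]
        out[f] = compute_torsion(nt.atom("O4'"), nt.atom("C1'"), nt.atom("N9"), nt.atom("C8"))
    return out


def classify_glycosidic(
    chi: np.ndarray,
    times: np.ndarray,
    syn_window: tuple[float, float] = config.SYN_WINDOW,
    occupancy_threshold: float = config.FLUCTUATION_OCCUPANCY,
    transition_threshold: int = config.FLUCTUATION_TRANSITIONS,
) -> GlycosidicTrace:
    """Map a torsion series to syn/anti states and classify the nucleotide.

    chi in (syn_lo, syn_hi] degrees is syn, anti otherwise.  Mean dwell
    times are computed from uncensored runs (the first and last runs touch
    the trajectory boundaries and are dropped when enough runs exist).
    """
    chi = np.asarray(chi, dtype=float)
    times = np.asarray(times, dtype=float)
    if chi.size < 2 or chi.size != times.size:
        raise ValueError("need matching chi/time series of length >= 2")
    lo, hi = syn_window
    is_syn = (chi > lo) & (chi <= hi)
    states = np.where(is_syn, SYN, ANTI)
    changes = np.flatnonzero(states[1:] != states[:-1])
    n_trans = len(changes)

    frac_syn = float(np.mean(is_syn))
    if frac_syn >= occupancy_threshold and n_trans < transition_threshold:
        classification = SYN
    elif (1.0 - frac_syn) >= occupancy_threshold and n_trans < transition_threshold:
        classification = ANTI
    else:
        classification = "fluctuating"

    dt = float(np.median(np.diff(times))) if times.size > 1 else 0.0
    # runs: (state, start, end-exclusive)
    bounds = np.concatenate([[0], changes + 1, [len(states)]])
    runs = [(states[bounds[k]], bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]
    interior = runs[1:-1] if len(runs) >= 3 else runs
    dwell: dict = {SYN: None, ANTI: None}
    for st in (SYN, ANTI):
        lens = [(e - s) * dt for state, s, e in interior if state == st]
        if lens:
            dwell[st] = float(np.mean(lens))
    return GlycosidicTrace(
        chi=chi, times=times, states=states, classification=classification,
        n_transitions=n_trans, mean_dwell=dwell,
    )


def glycosidic_summary(trajectory: Trajectory, **kwargs) -> list[GlycosidicTrace]:
    """Per-nucleotide glycosidic traces for a whole trajectory."""
    return [
        classify_glycosidic(chi_series(trajectory, nt.index), trajectory.times, **kwargs)
        for nt in trajectory.frames[0].nucleotides
    ]


# ---------------------------------------------------------------------------
# Pathway graphs
# ---------------------------------------------------------------------------


@dataclass
class PathwayGraph:
    """Directed stage-transition graph aggregated over trajectories.

    ``edges`` maps (from, to) to the number of trajectories traversing that
    transition; ``paths`` maps each run-length-collapsed stage tuple to its
    multiplicity.  The path multiplicities sum to the trajectory count.
    """

    nodes: list
    edges: dict
    paths: dict

    @property
    def n_trajectories(self) -> int:
        return sum(self.paths.values())

    def to_json_dict(self) -> dict:
        return {
            "nodes": [str(n) for n in self.nodes],
            "edges": [
                {"from": str(a), "to": str(b), "count": c}
                for (a, b), c in sorted(self.edges.items(), key=lambda kv: -kv[1])
            ],
            "paths": [
                {"stages": [str(s) for s in p], "count": c}
                for p, c in sorted(self.paths.items(), key=lambda kv: -kv[1])
            ],
        }

    def to_dot(self) -> str:
        lines = ["digraph pathways {"]
        for (a, b), c in sorted(self.edges.items(), key=lambda kv: -kv[1]):
            lines.append(f'  "{a}" -> "{b}" [label="{c}"];')
        lines.append("}")
        return "\n".join(lines)


def collapse_labels(sequence) -> tuple:
    """Run-length collapse: A,A,B,B,B,A -> (A, B, A)."""
    out = []
    for s in sequence:
        if not out or out[-1] != s:
            out.append(s)
    return tuple(out)


def build_pathway_graph(label_sequences) -> PathwayGraph:
    """Aggregate stage-label sequences into a directed pathway graph.

    Consecutive distinct labels in each sequence become directed edges; edge
    counts and per-path multiplicities are accumulated over trajectories.
    """
    sequences = [list(s) for s in label_sequences]
    if not sequences:
        raise ValueError("need at least one label sequence")
    edges: Counter = Counter()
    paths: Counter = Counter()
    nodes: list = []
    for seq in sequences:
        if len(seq) == 0:
            raise ValueError("empty label sequence")
        path = collapse_labels(seq)
        paths[path] += 1
        for s in path:
            if s not in nodes:
                nodes.append(s)
        for a, b in zip(path[:-1], path[1:]):
            edges[(a, b)] += 1
    return PathwayGraph(nodes=nodes, edges=dict(edges), paths=dict(paths))
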