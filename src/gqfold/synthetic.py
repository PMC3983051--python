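"""Synthetic inputs: toy quadruplex structures, conformational ensembles
with planted statistical structure, analytic landscapes, and labeled
unfolding-trajectory sets.

The generators emulate, at pseudo-atom resolution, the statistical features
the analysis stages measure: a stacked-tetrad native reference with channel
cations, ensembles whose pairwise hydrogen bonds follow planted Bernoulli
probabilities, per-site cation occupancies, two-state glycosidic torsion
dynamics with planted dwell times, and trajectory sets that follow planted
unfolding pathways.  Everything is bit-reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import config
from .bemd import AnalyticLandscape
from .geometry import Nucleotide, Structure, Trajectory

#: torsion-state centres used when realising chi angles, degrees
SYN_CENTER = 55.0
ANTI_CENTER = -120.0
#: thermal libration width of realised chi angles, degrees; kept at 5 sigma
#: from the syn/anti window edges so state labels follow the planted
#: dynamics, not noise tails
CHI_NOISE = 6.0


def _place_fourth_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Position D such that |CD| = bond, angle(B,C,D) = angle, and the
    dihedral A-B-C-D equals torsion (natural extension reference frame)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(180.0 - angle_deg)
    tor = np.radians(torsion_deg)
    d_local = bond * np.array([
        np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# Toy quadruplex
# ---------------------------------------------------------------------------

#: radial placement (nm from the channel axis) of the pseudo-atom roles
_RADII = {"O6": 0.18, "C8": 0.45, "N9": 0.55, "C1'": 0.70, "C4'": 0.95}
#: donor/acceptor ring radii and angular offsets (degrees from the base angle)
_HB_GEOM = {"D0": (0.35, +20.5), "A0": (0.35, -20.5), "D1": (0.55, +10.0), "A1": (0.55, -10.0)}


def make_toy_quadruplex(
    n_repeats: int = 4,
    repeat_len: int = 3,
    rise: float = 0.34,
    chi_native=None,
    noise: float = 0.0,
    seed: int = 0,
) -> Structure:
    """Deterministic stacked-tetrad pseudo-atom quadruplex.

    ``repeat_len`` tetrad layers of ``n_repeats`` guanines each, indexed
    repeat-major and 1-based; channel cation sites between layers.  Each
    nucleotide carries the core roles (C4', O4', C1', N9, C8, O6) plus two
    hydrogen-bond donor (D0, D1) and acceptor (A0, A1) points; within each
    tetrad, D0 of a guanine pairs with A0 of its ring neighbour at ~0.29 nm,
    mirroring the Hoogsteen bonding pattern.  ``chi_native`` maps nucleotide
    index to its native glycosidic state ("syn"/"anti"); the default puts
    the first repeat syn and the rest anti, a mixed pattern as in hybrid
    (3+1) topologies.
    """
    if n_repeats < 2 or repeat_len < 1:
        raise ValueError("need n_repeats >= 2 and repeat_len >= 1")
    if not rise > 0:
        raise ValueError("rise must be positive")
    rng = np.random.default_rng(seed)
    n_nt = n_repeats * repeat_len
    if chi_native is None:
        chi_native = {
            k * repeat_len + ell + 1: ("syn" if k == 0 else "anti")
            for k in range(n_repeats) for ell in range(repeat_len)
        }

    nucleotides = []
    for k in range(n_repeats):
        theta = 2.0 * np.pi * k / n_repeats
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        for ell in range(repeat_len):
            idx = k * repeat_len + ell + 1
            z = np.array([0.0, 0.0, ell * rise])
            atoms = {}
            for role in ("O6", "N9", "C1'", "C4'"):
                atoms[role] = _RADII[role] * u + z
            # O4' sits off the C1'-N9 axis so the chi torsion is defined
            atoms["O4'"] = atoms["C1'"] + np.array([0.0, 0.0, 0.12]) + 0.06 * u
            chi0 = SYN_CENTER if chi_native.get(idx, "anti") == "syn" else ANTI_CENTER
            atoms["C8"] = _place_fourth_atom(
                atoms["O4'"], atoms["C1'"], atoms["N9"], 0.14, 125.0, chi0)
            for role, (r, off) in _HB_GEOM.items():
                phi = theta + np.radians(off)
                atoms[role] = np.array([r * np.cos(phi), r * np.sin(phi), z[2]])
            if noise > 0:
                for role in atoms:
                    atoms[role] = atoms[role] + rng.normal(0.0, noise, 3)
            nucleotides.append(Nucleotide(
                index=idx, name="G", atoms=atoms, repeat=k, tetrad=ell))
    nucleotides.sort(key=lambda nt: nt.index)
    ions = np.array([
        [0.0, 0.0, (ell + 0.5) * rise] for ell in range(repeat_len - 1)
    ]).reshape(-1, 3)
    return Structure(nucleotides=nucleotides, ions=ions)


def channel_sites(native: Structure) -> np.ndarray:
    """The native cation channel sites (the native ion positions)."""
    return native.ions.copy()


# ---------------------------------------------------------------------------
# Intermediate ensembles with planted statistics
# ---------------------------------------------------------------------------


@dataclass
class EnsembleSpec:
    """Planted statistical structure of a synthetic intermediate ensemble.

    ``hbond_probs`` maps a directed (donor nucleotide, acceptor nucleotide)
    pair to its per-frame contact probability; ``ion_site_occupancies`` give
    the per-channel-site occupation probability; ``chi_dwell`` maps a
    nucleotide index to (mean syn dwell, mean anti dwell) in ns for
    two-state Markov torsion dynamics (nucleotides absent from the map keep
    their native state).
    """

    n_frames: int = 2000
    frame_stride: float = 1.0       # ns
    hbond_probs: dict = field(default_factory=dict)
    ion_site_occupancies: tuple = (1.0, 0.5)
    chi_dwell: dict = field(default_factory=dict)
    noise: float = 0.01             # nm, on core pseudo-atoms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for pair, p in self.hbond_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"hbond probability for pair {pair} outside [0, 1]")
        for q in self.ion_site_occupancies:
            if not 0.0 <= q <= 1.0:
                raise ValueError("ion occupancy outside [0, 1]")
        for idx, dwells in self.chi_dwell.items():
            if any(not d > 0 for d in dwells):
                raise ValueError(f"non-positive chi dwell time for nucleotide {idx}")


#: planted in-contact and out-of-contact donor-acceptor distance ranges, nm;
#: they straddle the 0.35 nm criterion with margin on both sides
CONTACT_RANGE = (0.28, 0.33)
NO_CONTACT_RANGE = (0.5, 0.8)


def default_intermediate_spec(seed: int = 0) -> EnsembleSpec:
    """The packaged study conditions for parameter-recovery runs: three
    native hydrogen bonds at probability 0.9, two non-native at 0.3, channel
    site occupancies (1.0, 0.5), and two nucleotides with 10 ns syn/anti
    telegraph dynamics, over 2000 frames at 1 ns stride."""
    return EnsembleSpec(
        n_frames=2000,
        frame_stride=1.0,
        hbond_probs={(1, 4): 0.9, (4, 7): 0.9, (7, 10): 0.9, (2, 9): 0.3, (6, 12): 0.3},
        ion_site_occupancies=(1.0, 0.5),
        chi_dwell={5: (10.0, 10.0), 8: (10.0, 10.0)},
        noise=0.01,
        seed=seed,
    )


def _assign_hbond_roles(spec: EnsembleSpec, native: Structure, cutoff: float):
    """Choose a (donor role, acceptor role) pair for each planted bond.

    Native pairs (bonded in the reference) keep the D0/A0 points that form
    the native bond; non-native pairs prefer the spare D1/A1 points so that
    moving them never breaks a native bond.  Reusing an already-claimed
    donor or acceptor point is an error naming the pair.
    """
    from .ensemble import _hbond_contacts

    native_contacts = _hbond_contacts(native, config.DONOR_ROLES, config.ACCEPTOR_ROLES, cutoff)
    first = native.nucleotides[0].index
    used: set[tuple[int, str]] = set()
    assignment = {}
    for (i, j), _p in sorted(spec.hbond_probs.items()):
        is_native = bool(native_contacts[i - first, j - first])
        prefs = (
            [("D0", "A0"), ("D1", "A1"), ("D0", "A1"), ("D1", "A0")]
            if is_native else
            [("D1", "A1"), ("D1", "A0"), ("D0", "A1"), ("D0", "A0")]
        )
        for dr, ar in prefs:
            if (i, dr) not in used and (j, ar) not in used:
                used.add((i, dr))
                used.add((j, ar))
                assignment[(i, j)] = (dr, ar, is_native)
                break
        else:
            raise ValueError(
                f"infeasible hydrogen-bond planting: no free donor/acceptor for pair ({i}, {j})"
            )
    return assignment


def make_intermediate_ensemble(spec: EnsembleSpec, native: Structure) -> Trajectory:
    """Frames realising the planted statistics of ``spec`` around ``native``.

    Per frame: each planted pair is in contact with its Bernoulli
    probability (donor moved to a distance inside/outside the geometric
    criterion along a fixed outward direction), channel sites are occupied
    per their planted probabilities (an unoccupied site's ion is parked in
    a far reservoir), glycosidic torsions follow two-state Markov dynamics
    with the planted dwell times, and the core atoms get Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    cutoff = config.HBOND_CUTOFF
    assignment = _assign_hbond_roles(spec, native, cutoff)
    first = native.nucleotides[0].index

    # fixed outward directions with clearance validation
    all_acceptors = {
        (nt.index, ar): nt.atom(ar)
        for nt in native.nucleotides for ar in config.ACCEPTOR_ROLES
    }
    acc_cloud = np.array(list(all_acceptors.values()))
    z_mid = acc_cloud[:, 2].mean()
    directions = {}
    for (i, j), (dr, ar, _is_native) in assignment.items():
        a = native.nucleotides[j - first].atom(ar)
        # move the donor outward from the channel axis and away from the
        # stack in z: the acceptor rings are concentric and layered, so
        # this direction gains clearance from everything as d grows
        radial = np.array([a[0], a[1], 0.0])
        if np.linalg.norm(radial) > 1e-9:
            radial /= np.linalg.norm(radial)
        z_sign = -1.0 if a[2] <= z_mid else 1.0
        u = radial + np.array([0.0, 0.0, 2.0 * z_sign])
        u /= np.linalg.norm(u)
        # clearance along the whole placement segment, with margin beyond
        # the criterion.  In-contact placements may graze OTHER acceptor
        # points of i or j (same pair, same statistic) but no third
        # nucleotide's; out-of-contact placements must in addition clear
        # every acceptor of j itself, or the pair would stay bonded.
        legs = [(CONTACT_RANGE, True), (NO_CONTACT_RANGE, False)]
        for (d_lo, d_hi), in_contact_leg in legs:
            for d in np.linspace(d_lo, d_hi, 20):
                pos = a + d * u
                for (m, mar), acc in all_acceptors.items():
                    if m == i or (in_contact_leg and m == j):
                        continue
                    if np.linalg.norm(pos - acc) < cutoff + 0.02:
                        raise ValueError(
                            f"infeasible hydrogen-bond planting for pair ({i}, {j}): "
                            f"placement collides with acceptor {mar} of nucleotide {m}"
                        )
        directions[(i, j)] = u

    n_sites = len(spec.ion_site_occupancies)
    sites = channel_sites(native)
    if n_sites > sites.shape[0]:
        raise ValueError(
            f"spec plants {n_sites} ion sites but the native has {sites.shape[0]}")
    reservoir = np.array([
        [4.0 + 0.5 * k, 4.0, 0.0] for k in range(n_sites)
    ])

    # chi state machinery
    chi_state: dict[int, int] = {}   # 0 = syn, 1 = anti
    for idx in spec.chi_dwell:
        nt = native.nucleotides[idx - first]
        native_chi = _native_chi(nt)
        chi_state[idx] = 0 if -90.0 < native_chi <= 90.0 else 1

    frames = []
    dt = spec.frame_stride
    core_noise_roles = ("C4'", "O4'", "C1'", "N9", "O6")
    for _f in range(spec.n_frames):
        fr = native.copy()
        # core-atom noise (donor/acceptor points stay exact for margin safety)
        if spec.noise > 0:
            for nt in fr.nucleotides:
                for role in core_noise_roles:
                    nt.atoms[role] = nt.atoms[role] + rng.normal(0.0, spec.noise, 3)
        # chi dynamics, then C8 placement from the (noisy) sugar/base frame
        for nt in fr.nucleotides:
            idx = nt.index
            if idx in chi_state:
                tau = spec.chi_dwell[idx][chi_state[idx]]
                if rng.random() < 1.0 - np.exp(-dt / tau):
                    chi_state[idx] = 1 - chi_state[idx]
                center = SYN_CENTER if chi_state[idx] == 0 else ANTI_CENTER
                chi = center + rng.normal(0.0, CHI_NOISE)
            else:
                chi = _native_chi(native.nucleotides[idx - first]) + rng.normal(0.0, CHI_NOISE)
            nt.atoms["C8"] = _place_fourth_atom(
                nt.atoms["O4'"], nt.atoms["C1'"], nt.atoms["N9"], 0.14, 125.0, chi)
        # hydrogen-bond planting
        for (i, j), (dr, ar, _nat) in assignment.items():
            p = spec.hbond_probs[(i, j)]
            lo, hi = CONTACT_RANGE if rng.random() < p else NO_CONTACT_RANGE
            d = rng.uniform(lo, hi)
            a = fr.nucleotides[j - first].atom(ar)
            fr.nucleotides[i - first].atoms[dr] = a + d * directions[(i, j)]
        # ion occupancies
        ions = np.empty((n_sites, 3))
        for k, q in enumerate(spec.ion_site_occupancies):
            if rng.random() < q:
                ions[k] = sites[k] + rng.normal(0.0, 0.01, 3)
            else:
                ions[k] = reservoir[k]
        fr.ions = ions
        frames.append(fr)
    times = np.arange(spec.n_frames) * dt
    return Trajectory(frames=frames, times=times)


def _native_chi(nt: Nucleotide) -> float:
    from .geometry import compute_torsion

    return compute_torsion(nt.atom("O4'"), nt.atom("C1'"), nt.atom("N9"), nt.atom("C8"))


# ---------------------------------------------------------------------------
# Analytic landscapes
# ---------------------------------------------------------------------------


def make_analytic_landscape(name: str, **params) -> AnalyticLandscape:
    """Named analytic test surfaces with exact gradients.

    ``double_well``: U(x) = h (x^2 - 1)^2, barrier height h (kJ/mol) at
    x = 0 relative to the minima at x = +-1.
    ``two_basin_2d``: U = h (x^2 - 1)^2 + ky y^2 / 2, minima (+-1, 0).
    ``multi_basin_2d``: Gaussian wells at given centres plus a quartic
    confinement.
    """
    if name == "double_well":
        h = float(params.pop("h", 5.0))
        _no_extra(params, name)

        def u(x):
            return float(h * (x[0] ** 2 - 1.0) ** 2)

        def g(x):
            return np.array([4.0 * h * x[0] * (x[0] ** 2 - 1.0)])

        return AnalyticLandscape(name, 1, u, g, domain=(-2.0, 2.0),
                                 minima=((-1.0,), (1.0,)))
    if name == "two_basin_2d":
        h = float(params.pop("h", 5.0))
        ky = float(params.pop("ky", 10.0))
        _no_extra(params, name)

        def u2(x):
            return float(h * (x[0] ** 2 - 1.0) ** 2 + 0.5 * ky * x[1] ** 2)

        def g2(x):
            return np.array([4.0 * h * x[0] * (x[0] ** 2 - 1.0), ky * x[1]])

        return AnalyticLandscape(name, 2, u2, g2, domain=(-2.0, 2.0),
                                 minima=((-1.0, 0.0), (1.0, 0.0)))
    if name == "multi_basin_2d":
        centers = np.asarray(params.pop("centers", [(-1.0, 0.0), (1.0, 0.0), (0.0, 1.0)]), float)
        depths = np.asarray(params.pop("depths", [10.0, 10.0, 6.0]), float)
        widths = np.asarray(params.pop("widths", [0.35] * len(centers)), float)
        conf = float(params.pop("confinement", 2.0))
        scale = float(params.pop("confinement_scale", 1.5))
        _no_extra(params, name)
        if not (len(centers) == len(depths) == len(widths)):
            raise ValueError("centers, depths and widths must have equal length")

        def u3(x):
            r2 = np.sum((centers - np.asarray(x)[:2]) ** 2, axis=1)
            wells = -np.sum(depths * np.exp(-r2 / (2.0 * widths**2)))
            return float(wells + conf * ((x[0] / scale) ** 4 + (x[1] / scale) ** 4))

        def g3(x):
            dx = np.asarray(x)[:2] - centers
            e = depths * np.exp(-np.sum(dx**2, axis=1) / (2.0 * widths**2))
            grad = np.sum((e / widths**2)[:, None] * dx, axis=0)
            grad += 4.0 * conf * np.array([x[0] ** 3, x[1] ** 3]) / scale**4
            return grad

        return AnalyticLandscape(name, 2, u3, g3, domain=(-2.5, 2.5),
                                 minima=tuple(map(tuple, centers)))
    raise ValueError(f"unknown landscape {name!r}")


def _no_extra(params: dict, name: str) -> None:
    if params:
        raise ValueError(f"unknown parameters for landscape {name!r}: {sorted(params)}")


# ---------------------------------------------------------------------------
# Unfolding-trajectory sets
# ---------------------------------------------------------------------------


def make_unfolding_set(
    native: Structure,
    pathways,
    n_trajectories: int | None = None,
    frames_per_stage: int = 5,
    frame_stride: float = 1.0,
    noise: float = 0.02,
    stage_scale_step: float = 0.5,
    seed: int = 0,
):
    """Trajectory sets following planted stage sequences.

    ``pathways`` is a list of (stage-label sequence, multiplicity); the
    multiplicities must sum to ``n_trajectories`` when given.  Each distinct
    stage label is realised as the native structure uniformly scaled by
    1 + stage_scale_step * rank (progressively swollen states), which makes
    consecutive stages separable by dRMSD well beyond the clustering
    thresholds.  Returns (list of Trajectory, list of true per-frame label
    sequences).
    """
    pathways = [(tuple(p), int(m)) for p, m in pathways]
    total = sum(m for _p, m in pathways)
    if n_trajectories is not None and total != n_trajectories:
        raise ValueError(
            f"pathway multiplicities sum to {total}, not n_trajectories={n_trajectories}")
    stages: list = []
    for p, _m in pathways:
        for s in p:
            if s not in stages:
                stages.append(s)
    scale = {s: 1.0 + stage_scale_step * k for k, s in enumerate(stages)}

    rng = np.random.default_rng(seed)
    trajectories = []
    labels = []
    for p, m in pathways:
        for _rep in range(m):
            frames = []
            frame_labels = []
            for stage in p:
                alpha = scale[stage]
                for _k in range(frames_per_stage):
                    fr = native.copy()
                    for nt in fr.nucleotides:
                        for role in nt.atoms:
                            nt.atoms[role] = alpha * nt.atoms[role] + rng.normal(0, noise, 3)
                    fr.ions = alpha * fr.ions
                    frames.append(fr)
                    frame_labels.append(stage)
            times = np.arange(len(frames)) * frame_stride
            trajectories.append(Trajectory(frames=frames, times=times))
            labels.append(frame_labels)
    return trajectories, labels
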