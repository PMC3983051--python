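"""Geometric primitives and the four collective variables.

The four CVs used to drive and project the sampling of quadruplex folding:

* ``Q`` — fraction of native contacts between the guanine bases, in [0, 1];
* ``dRMSD`` — root-mean-square deviation of internal pairwise backbone
  (C4') distances from the native structure, nm;
* ``N_ion`` — coordination number between cations and guanine O6 atoms;
* ``R_g`` — radius of gyration of the backbone, nm.

Sharp (counting) and smooth (differentiable, for biasing) variants are
provided for Q and N_ion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import config


class DegenerateGeometryError(ValueError):
    """Raised when a torsion is requested for coincident/collinear points."""


class AtomRoleError(KeyError):
    """Raised when a nucleotide lacks a required pseudo-atom role."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Nucleotide:
    """One residue: a 1-based index, a residue name, named pseudo-atoms.

    ``atoms`` maps an internal role name (``C4'``, ``O6``, ``D0`` ...) to a
    3-vector of coordinates in nm.  ``repeat`` and ``tetrad`` are optional
    labels for G-repeat membership and tetrad-layer membership.
    """

    index: int
    name: str
    atoms: dict[str, np.ndarray]
    repeat: int | None = None
    tetrad: int | None = None

    def atom(self, role: str) -> np.ndarray:
        try:
            return self.atoms[role]
        except KeyError:
            raise AtomRoleError(
                f"nucleotide {self.index} ({self.name}) has no atom role {role!r}"
            ) from None


@dataclass
class Structure:
    """A single conformation: ordered nucleotides plus cation positions."""

    nucleotides: list[Nucleotide]
    ions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self) -> None:
        self.ions = np.asarray(self.ions, dtype=float).reshape(-1, 3)
        idx = [n.index for n in self.nucleotides]
        if idx and idx != list(range(idx[0], idx[0] + len(idx))):
            raise ValueError("nucleotide indices must be unique and contiguous")
        for n in self.nucleotides:
            for role, xyz in n.atoms.items():
                n.atoms[role] = np.asarray(xyz, dtype=float).reshape(3)
                if not np.all(np.isfinite(n.atoms[role])):
                    raise ValueError(
                        f"non-finite coordinates for atom {role!r} of nucleotide {n.index}"
                    )
        if self.ions.size and not np.all(np.isfinite(self.ions)):
            raise ValueError("non-finite ion coordinates")

    @property
    def n_nucleotides(self) -> int:
        return len(self.nucleotides)

    def coords(self, role: str, indices: list[int] | None = None) -> np.ndarray:
        """Coordinates of one atom role across nucleotides, shape (n, 3).

        ``indices`` are 1-based nucleotide indices; default all nucleotides.
        """
        nts = self.nucleotides if indices is None else [
            self.nucleotides[i - self.nucleotides[0].index] for i in indices
        ]
        return np.array([n.atom(role) for n in nts])

    def copy(self) -> "Structure":
        return Structure(
            nucleotides=[
                Nucleotide(
                    n.index, n.name, {r: c.copy() for r, c in n.atoms.items()},
                    n.repeat, n.tetrad,
                )
                for n in self.nucleotides
            ],
            ions=self.ions.copy(),
        )


@dataclass
class Trajectory:
    """Time-ordered snapshots sharing one topology."""

    frames: list[Structure]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.frames:
            ref = [(n.index, n.name, tuple(sorted(n.atoms))) for n in self.frames[0].nucleotides]
            for k, fr in enumerate(self.frames[1:], start=1):
                top = [(n.index, n.name, tuple(sorted(n.atoms))) for n in fr.nucleotides]
                if top != ref:
                    raise ValueError(f"frame {k} topology differs from frame 0")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class ContactSet:
    """Native contacts: (i, role_i, j, role_j, native distance nm), i < j."""

    pairs: list[tuple[int, str, int, str, float]]

    def __post_init__(self) -> None:
        for i, _, j, _, d in self.pairs:
            if not i < j:
                raise ValueError(f"contact pair ({i},{j}) violates i < j ordering")
            if not d > 0:
                raise ValueError(f"contact pair ({i},{j}) has non-positive native distance")

    @property
    def n_total(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class CVVector:
    """The four collective variables of one frame."""

    q: float
    drmsd: float
    n_ion: float
    rg: float

    def __post_init__(self) -> None:
        vals = (self.q, self.drmsd, self.n_ion, self.rg)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite CV value")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q={self.q} outside [0, 1]")


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


def compute_torsion(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of four points, degrees in [-180, 180).

    Raises :class:`DegenerateGeometryError` for coincident consecutive points
    or three collinear consecutive points, where the dihedral is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for k, b in enumerate((b1, b2, b3)):
        if np.linalg.norm(b) < 1e-12:
            raise DegenerateGeometryError(f"consecutive points {k + 1},{k + 2} coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("three consecutive points are collinear")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, b2 / np.linalg.norm(b2)), n2)
    angle = np.degrees(np.arctan2(y, x))
    if angle >= 180.0:  # arctan2 returns (-180, 180]; fold +180 to -180
        angle -= 360.0
    return float(angle)


def compute_rg(structure: Structure, atom_selection=("C4'",)) -> float:
    """Mass-uniform radius of gyration of the selected atom roles, nm."""
    pts = _select_points(structure, atom_selection)
    if pts.shape[0] == 0:
        raise ValueError("empty atom selection for radius of gyration")
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def _select_points(structure: Structure, atom_selection) -> np.ndarray:
    pts = []
    for n in structure.nucleotides:
        for role in atom_selection:
            if role in n.atoms:
                pts.append(n.atoms[role])
    return np.asarray(pts, dtype=float).reshape(-1, 3)


def rational_switch(r: np.ndarray, r0: float, exponents=config.SWITCHING_EXPONENTS,
                    steepness: float = 1.0) -> np.ndarray:
    """Rational switching s(r) = (1-(r/r0)^n)/(1-(r/r0)^m), n < m.

    ``steepness`` scales both exponents; as it grows the function approaches
    the sharp step 1_{r<r0}.  The removable singularity at r = r0 is filled
    with the limit value n/m.
    """
    n, m = exponents
    n = n * steepness
    m = m * steepness
    x = np.asarray(r, dtype=float) / r0
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        xn, xm = x**n, x**m
        s = np.where(np.abs(xm - 1.0) < 1e-12, n / m, (1.0 - xn) / (1.0 - xm))
    return np.where(np.isfinite(s), s, 0.0)


# ---------------------------------------------------------------------------
# Collective variables
# ---------------------------------------------------------------------------


def build_native_contacts(
    native: Structure,
    atom_roles=("O6", "N9", "C8"),
    cutoff: float = config.NATIVE_CONTACT_CUTOFF,
    min_separation: int = config.MIN_CONTACT_SEPARATION,
    residue_filter=None,
) -> ContactSet:
    """All inter-nucleotide atom pairs closer than ``cutoff`` in the native.

    Pairs on nucleotides separated by fewer than ``min_separation`` residues
    are excluded (trivially bonded neighbours).  ``residue_filter`` optionally
    restricts to a predicate on :class:`Nucleotide` (e.g. guanines only).
    """
    nts = [n for n in native.nucleotides if residue_filter is None or residue_filter(n)]
    pairs: list[tuple[int, str, int, str, float]] = []
    for a_pos, na in enumerate(nts):
        for nb in nts[a_pos + 1:]:
            if abs(nb.index - na.index) < min_separation:
                continue
            for ra in atom_roles:
                pa = na.atom(ra)
                for rb in atom_roles:
                    d = float(np.linalg.norm(pa - nb.atom(rb)))
                    if d < cutoff:
                        pairs.append((na.index, ra, nb.index, rb, d))
    return ContactSet(pairs=pairs)


def _contact_distances(structure: Structure, contacts: ContactSet) -> np.ndarray:
    first = structure.nucleotides[0].index
    d = np.empty(contacts.n_total)
    for k, (i, ra, j, rb, _) in enumerate(contacts.pairs):
        pa = structure.nucleotides[i - first].atom(ra)
        pb = structure.nucleotides[j - first].atom(rb)
        d[k] = np.linalg.norm(pa - pb)
    return d


def compute_q(
    structure: Structure,
    contacts: ContactSet,
    mode: str = "sharp",
    lam: float = config.LAMBDA_CONTACT,
    steepness: float = 1.0,
) -> float:
    """Fraction of native contacts formed, in [0, 1].

    ``sharp``: fraction of pairs with current distance < lam * native
    distance.  ``smooth``: mean rational switching value per pair with
    r0 = lam * native distance, for differentiable biasing.
    """
    if contacts.n_total == 0:
        raise ValueError("empty contact set")
    d = _contact_distances(structure, contacts)
    d_native = np.array([p[4] for p in contacts.pairs])
    if mode == "sharp":
        return float(np.mean(d < lam * d_native))
    if mode == "smooth":
        s = np.array([
            rational_switch(dk, lam * dn, steepness=steepness)
            for dk, dn in zip(d, d_native)
        ])
        return float(np.clip(np.mean(s), 0.0, 1.0))
    raise ValueError(f"unknown mode {mode!r}")


def compute_drmsd(structure: Structure, native: Structure, atom_selection=("C4'",)) -> float:
    """Distance-RMSD: sqrt(mean over i<j of (d_ij - d_ij^native)^2), nm.

    Rigid-motion invariant by construction (only internal distances enter).
    """
    p = _select_points(structure, atom_selection)
    pn = _select_points(native, atom_selection)
    if p.shape != pn.shape:
        raise ValueError(
            f"selection mismatch: {p.shape[0]} atoms in frame vs {pn.shape[0]} in native"
        )
    if p.shape[0] < 3:
        raise ValueError("need at least 3 selected atoms for dRMSD")
    iu = np.triu_indices(p.shape[0], k=1)
    d = np.linalg.norm(p[:, None] - p[None, :], axis=-1)[iu]
    dn = np.linalg.norm(pn[:, None] - pn[None, :], axis=-1)[iu]
    return float(np.sqrt(np.mean((d - dn) ** 2)))


def compute_ion_coordination(
    structure: Structure,
    target_role: str = "O6",
    r0: float = config.ION_R0,
    mode: str = "sharp",
    steepness: float = 1.0,
) -> float:
    """Coordination count between cations and the target atom role.

    ``sharp`` counts (ion, atom) pairs with distance < r0; ``smooth`` sums
    the rational switching values.  Zero ions give 0.
    """
    if structure.ions.shape[0] == 0:
        return 0.0
    targets = _select_points(structure, (target_role,))
    if targets.shape[0] == 0:
        return 0.0
    d = np.linalg.norm(structure.ions[:, None, :] - targets[None, :, :], axis=-1)
    if mode == "sharp":
        return float(np.sum(d < r0))
    if mode == "smooth":
        return float(np.sum(rational_switch(d, r0, steepness=steepness)))
    raise ValueError(f"unknown mode {mode!r}")


def evaluate_cv_vector(
    structure: Structure,
    native: Structure,
    contacts: ContactSet,
    mode: str = "sharp",
    backbone_role: str = "C4'",
    ion_r0: float = config.ION_R0,
    lam: float = config.LAMBDA_CONTACT,
) -> CVVector:
    """All four CVs of one frame, computed with the standalone operations."""
    return CVVector(
        q=compute_q(structure, contacts, mode=mode, lam=lam),
        drmsd=compute_drmsd(structure, native, atom_selection=(backbone_role,)),
        n_ion=compute_ion_coordination(structure, r0=ion_r0, mode=mode),
        rg=compute_rg(structure, atom_selection=(backbone_role,)),
    )


def cv_trace(
    trajectory: Trajectory,
    native: Structure,
    contacts: ContactSet,
    **kwargs,
):
    """CV vectors for every frame; returns (times, list of CVVector)."""
    return trajectory.times, [
        evaluate_cv_vector(fr, native, contacts, **kwargs) for fr in trajectory.frames
    ]
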