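"""PDB and tabular I/O.

Structures travel as PDB (single model = Structure, multi-model =
Trajectory) through biotite; pseudo-atom roles are resolved via a
configurable atom-name map.  Coordinates are nm internally and Angstrom on
file, per the PDB convention.  Analysis products are written as CSV/JSON
with units embedded in the headers.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from . import config
from .geometry import Nucleotide, Structure, Trajectory

log = logging.getLogger("gqfold")

_NM_PER_ANGSTROM = 0.1


class PDBFormatError(ValueError):
    """Raised for unparseable or role-incomplete PDB input."""


def _element_for_role(role: str) -> str:
    return role[0] if role[0] in "CON" else "X"


def _structure_to_atoms(structure: Structure):
    n_atoms = sum(len(nt.atoms) for nt in structure.nucleotides) + structure.ions.shape[0]
    arr = bst.AtomArray(n_atoms)
    k = 0
    for nt in structure.nucleotides:
        for role in sorted(nt.atoms):
            arr.coord[k] = nt.atoms[role] / _NM_PER_ANGSTROM
            arr.res_id[k] = nt.index
            arr.res_name[k] = nt.name
            arr.atom_name[k] = role
            arr.element[k] = _element_for_role(role)
            arr.chain_id[k] = "A"
            arr.hetero[k] = False
            k += 1
    for i in range(structure.ions.shape[0]):
        arr.coord[k] = structure.ions[i] / _NM_PER_ANGSTROM
        arr.res_id[k] = 1000 + i
        arr.res_name[k] = "K"
        arr.atom_name[k] = "K"
        arr.element[k] = "K"
        arr.chain_id[k] = "B"
        arr.hetero[k] = True
        k += 1
    return arr


def write_structure(path, structure: Structure) -> None:
    f = PDBFile()
    f.set_structure(_structure_to_atoms(structure))
    f.write(str(path))


def write_trajectory(path, trajectory: Trajectory) -> None:
    """Multi-model PDB, one MODEL per frame (times are not stored by the
    format; supply the stride again when reading back)."""
    stack = bst.stack([_structure_to_atoms(fr) for fr in trajectory.frames])
    f = PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def _atoms_to_structure(arr, role_map, require_roles) -> Structure:
    nucleotides: dict[int, Nucleotide] = {}
    ions = []
    unknown = 0
    for k in range(arr.array_length()):
        name = arr.atom_name[k].strip()
        role = role_map.get(name)
        if role is None:
            unknown += 1
            continue
        xyz = np.asarray(arr.coord[k], dtype=float) * _NM_PER_ANGSTROM
        if role == "ION":
            ions.append(xyz)
            continue
        rid = int(arr.res_id[k])
        nt = nucleotides.get(rid)
        if nt is None:
            nt = Nucleotide(index=rid, name=str(arr.res_name[k]).strip(), atoms={})
            nucleotides[rid] = nt
        nt.atoms[role] = xyz
    if unknown:
        log.info("ignored %d atoms with unmapped names", unknown)
    if not nucleotides:
        raise PDBFormatError("no mappable nucleotide atoms found")
    ordered = [nucleotides[i] for i in sorted(nucleotides)]
    if require_roles:
        missing = [
            (nt.index, role)
            for nt in ordered for role in require_roles if role not in nt.atoms
        ]
        if missing:
            desc = ", ".join(f"nucleotide {i} lacks {r}" for i, r in missing[:8])
            raise PDBFormatError(f"mandatory atom roles missing: {desc}")
    return Structure(nucleotides=ordered, ions=np.asarray(ions).reshape(-1, 3))


def read_structure(path, role_map=None, require_roles=config.CORE_ROLES) -> Structure:
    """Single-model PDB to Structure (first model of a multi-model file)."""
    role_map = role_map or config.DEFAULT_ROLE_MAP
    f = PDBFile.read(str(path))
    arr = f.get_structure(model=1)
    return _atoms_to_structure(arr, role_map, require_roles)


def read_trajectory(path, role_map=None, frame_stride: float = 1.0,
                    require_roles=config.CORE_ROLES) -> Trajectory:
    """Multi-model PDB to Trajectory; frame times are k * frame_stride ns."""
    role_map = role_map or config.DEFAULT_ROLE_MAP
    f = PDBFile.read(str(path))
    stack = f.get_structure()
    frames = [
        _atoms_to_structure(stack[m], role_map, require_roles)
        for m in range(stack.stack_depth())
    ]
    return Trajectory(frames=frames, times=np.arange(len(frames)) * frame_stride)


# ---------------------------------------------------------------------------
# Tabular exports
# ---------------------------------------------------------------------------


def write_cv_trace_csv(path, times, cv_vectors) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_ns", "q", "drmsd_nm", "n_ion", "rg_nm"])
        for t, v in zip(times, cv_vectors):
            w.writerow([f"{t:.6g}", f"{v.q:.6g}", f"{v.drmsd:.6g}",
                        f"{v.n_ion:.6g}", f"{v.rg:.6g}"])


def write_kernels_csv(path, bias) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["center", "width", "height_kj_mol", "deposit_time_ns"])
        for k in bias.kernels:
            w.writerow([f"{k.center:.6g}", f"{k.width:.6g}",
                        f"{k.height:.6g}", f"{k.deposit_time:.6g}"])


def write_exchange_log_csv(path, logs) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_ns", "replica_a", "replica_b", "accepted"])
        seen = set()
        for i, log_i in enumerate(logs):
            for t, partner, acc in log_i:
                key = (t, min(i, partner), max(i, partner))
                if key in seen:
                    continue
                seen.add(key)
                w.writerow([f"{t:.6g}", key[1], key[2], int(acc)])


def fel_to_json_dict(fel) -> dict:
    return {
        "axes": list(fel.axes),
        "edges": [e.tolist() for e in fel.edges],
        "values_kj_mol": np.where(fel.mask, fel.values, None).tolist(),
        "mask": fel.mask.astype(int).tolist(),
    }


def write_fel_json(path, fel) -> None:
    Path(path).write_text(json.dumps(fel_to_json_dict(fel), indent=1))


def write_fel_csv(path, fel) -> None:
    """Long format: one supported bin per row with bin centers."""
    centers = [fel.centers(k) for k in range(fel.ndim)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([f"{ax}_center" for ax in fel.axes] + ["free_energy_kj_mol"])
        for idx in np.argwhere(fel.mask):
            row = [f"{centers[k][idx[k]]:.6g}" for k in range(fel.ndim)]
            w.writerow(row + [f"{fel.values[tuple(idx)]:.6g}"])


def write_cluster_csv(path, clusters) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "cluster", "is_representative"])
        reps = set(clusters.representatives)
        for i, c in enumerate(clusters.membership):
            w.writerow([i, int(c), int(i in reps)])


def write_hbond_csv(path, hmap) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["nucleotide_i", "nucleotide_j", "probability", "native"])
        n = hmap.matrix.shape[0]
        for a in range(n):
            for b in range(a + 1, n):
                w.writerow([hmap.indices[a], hmap.indices[b],
                            f"{hmap.matrix[a, b]:.6g}", int(hmap.native[a, b])])


def write_ion_profile_csv(path, profile) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["nucleotide", "binding_probability"])
        for idx, p in zip(profile.indices, profile.probabilities):
            w.writerow([idx, f"{p:.6g}"])
        w.writerow(["mean_bound_count", f"{profile.mean_bound_count:.6g}"])


def write_glycosidic_csv(path, traces, indices) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["nucleotide", "classification", "n_transitions",
                    "mean_dwell_syn_ns", "mean_dwell_anti_ns"])
        for idx, tr in zip(indices, traces):
            w.writerow([
                idx, tr.classification, tr.n_transitions,
                "" if tr.mean_dwell["syn"] is None else f"{tr.mean_dwell['syn']:.6g}",
                "" if tr.mean_dwell["anti"] is None else f"{tr.mean_dwell['anti']:.6g}",
            ])
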